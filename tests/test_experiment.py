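"""Study-point loop, stopping rule, strata, sensitivity bounds, policies."""

import numpy as np
import pytest

import trailrisk as tr

from conftest import make_registry


class TestSampleTrailYears:
    def test_full_window_is_deterministic(self, rng):
        years = list(range(1996, 2007))
        trail = tr.sample_trail_years(years, 11, rng)
        assert trail.years == tuple(years)

    def test_oversized_k_rejected(self, rng):
        with pytest.raises(ValueError):
            tr.sample_trail_years(list(range(1996, 2007)), 12, rng)

    def test_single_year_draws_are_uniform(self):
        rng = np.random.default_rng(61)
        years = list(range(1996, 2007))
        draws = [tr.sample_trail_years(years, 1, rng).years[0]
                 for _ in range(11_000)]
        p = 1 / 11
        se = np.sqrt(p * (1 - p) / 11_000)
        counts = np.bincount(np.array(draws) - 1996, minlength=11)
        assert (np.abs(counts / 11_000 - p) < 3 * se).all()

    def test_same_seed_same_sequence(self):
        years = list(range(1996, 2007))
        a = [tr.sample_trail_years(years, 3, np.random.default_rng(5)).years
             for _ in range(1)]
        b = [tr.sample_trail_years(years, 3, np.random.default_rng(5)).years
             for _ in range(1)]
        assert a == b


class TestStoppingRule:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            tr.StoppingRule(delta=0.0)
        with pytest.raises(ValueError):
            tr.StoppingRule(min_iterations=20, max_iterations=10)

    def test_zero_variance_stops_at_minimum(self):
        reg = make_registry([
            {"gender": "F", "dob": "1980-01-01", "trail": "H3A2T5"}
            for _ in range(4)])
        result = tr.run_study_point(
            reg, tr.GeneralizationLevel("year", 3, True), k=2, seed=1)
        assert result.n_iterations == tr.StoppingRule().min_iterations
        assert result.mean == 0.0

    def test_full_window_trail_runs_once(self, toy_registry):
        enc = tr.encode_sentinels(toy_registry)
        result = tr.run_study_point(
            enc, tr.GeneralizationLevel("full", 6, True), k=11, seed=2)
        assert result.n_iterations == 1

    def test_iterations_stay_within_bounds(self):
        cfg = tr.SyntheticConfig(
            n_persons=800, seed=62,
            universe=tr.build_postal_universe(40, 20.0, seed=62))
        reg = tr.encode_sentinels(tr.qc_filter(
            tr.generate_population(cfg))[0])
        rule = tr.StoppingRule()
        for k in (1, 3, 6):
            res = tr.run_study_point(
                reg, tr.GeneralizationLevel("year", 2, True), k=k,
                rule=rule, seed=63)
            assert rule.min_iterations <= res.n_iterations <= rule.max_iterations

    def test_lag_mode_also_terminates(self):
        reg = make_registry([
            {"gender": "M", "dob": "1970-01-01", "trail": "H3A2T5"}
            for _ in range(3)])
        rule = tr.StoppingRule(mode="lag")
        res = tr.run_study_point(
            reg, tr.GeneralizationLevel("year", 6, True), k=1,
            rule=rule, seed=3)
        assert res.n_iterations <= rule.max_iterations


class TestRunStudyPoint:
    def test_running_mean_matches_trace(self, toy_registry):
        enc = tr.encode_sentinels(toy_registry)
        res = tr.run_study_point(
            enc, tr.GeneralizationLevel("year", 3, True), k=2, seed=4)
        assert res.mean == pytest.approx(np.mean(res.values))
        assert all(0.0 <= v <= 1.0 for v in res.values)

    def test_zayatz_method_needs_a_design(self, toy_registry):
        with pytest.raises(ValueError, match="SamplingDesign"):
            tr.run_study_point(
                toy_registry, tr.GeneralizationLevel(), k=1, method="zayatz")

    def test_zayatz_census_design_equals_exact(self, toy_registry):
        enc = tr.encode_sentinels(toy_registry)
        level = tr.GeneralizationLevel("full", 6, True)
        exact = tr.run_study_point(enc, level, k=11, method="exact", seed=5)
        census = tr.run_study_point(
            enc, level, k=11, method="zayatz",
            design=tr.SamplingDesign(enc.n_persons, enc.n_persons), seed=5)
        assert census.mean == pytest.approx(exact.mean)

    def test_empty_registry_rejected(self, toy_registry):
        empty = toy_registry.subset(np.zeros(5, dtype=bool))
        with pytest.raises(ValueError, match="empty"):
            tr.run_study_point(empty, tr.GeneralizationLevel(), k=1)


@pytest.fixture(scope="module")
def registry():
    cfg = tr.SyntheticConfig(
        n_persons=2_000, seed=64,
        universe=tr.build_postal_universe(100, 20.0, seed=64),
        demography=tr.DemographyModel.cross_sectional())
    return tr.generate_population(cfg)


class TestMonotonicity:

    def test_coarsening_never_increases_exact_uniqueness(self, registry):
        trail = tr.TrailSpec((1997, 2002))

        def u(level):
            keys = tr.build_quasi_identifiers(registry, level, trail)
            return tr.exact_uniqueness(tr.frequency_spectrum(keys)).value

        for chars in range(1, 7):
            assert u(tr.GeneralizationLevel("year", chars - 1, True)) <= \
                u(tr.GeneralizationLevel("year", chars, True))
        assert u(tr.GeneralizationLevel("month_year", 3, True)) <= \
            u(tr.GeneralizationLevel("full", 3, True))
        assert u(tr.GeneralizationLevel("year", 3, True)) <= \
            u(tr.GeneralizationLevel("month_year", 3, True))
        assert u(tr.GeneralizationLevel("year", 3, False)) <= \
            u(tr.GeneralizationLevel("year", 3, True))

    def test_longer_trails_never_decrease_uniqueness(self, registry):
        # deterministic superset case: nested trails on a fixed registry
        level = tr.GeneralizationLevel("suppressed", 6, False)
        nested = [(1999,), (1999, 2003), (1997, 1999, 2003),
                  tuple(range(1996, 2007))]
        values = []
        for years in nested:
            keys = tr.build_quasi_identifiers(
                registry, level, tr.TrailSpec(tuple(sorted(years))))
            values.append(
                tr.exact_uniqueness(tr.frequency_spectrum(keys)).value)
        assert values == sorted(values)


class TestStratifyYouthAdult:
    def test_child_is_youth(self):
        reg = make_registry([
            {"gender": "F", "dob": "1990-05-05", "trail": "H3A2T5"}])
        youth, adult = tr.stratify_youth_adult(reg, tr.TrailSpec((1996,)))
        assert youth.n_persons == 1 and adult.n_persons == 0

    def test_1950_birth_is_adult_for_any_trail(self):
        reg = make_registry([
            {"gender": "M", "dob": "1950-01-20", "trail": "H3A2T5"}])
        for years in [(1996,), (1996, 2006), (2001, 2003, 2005)]:
            youth, adult = tr.stratify_youth_adult(reg, tr.TrailSpec(years))
            assert adult.n_persons == 1

    def test_partition_is_exhaustive_and_disjoint(self):
        cfg = tr.SyntheticConfig(n_persons=500, seed=65)
        reg = tr.generate_population(cfg)
        trail = tr.TrailSpec((1998, 2004))
        youth, adult = tr.stratify_youth_adult(reg, trail)
        assert youth.n_persons + adult.n_persons == 500
        assert not set(youth.frame["person_id"]) & set(adult.frame["person_id"])

    def test_all_vs_any_rule(self):
        # born 1980: age 18 in 1998 (youth), 22 in 2002 (adult)
        reg = make_registry([
            {"gender": "F", "dob": "1980-07-01", "trail": "H3A2T5"}])
        trail = tr.TrailSpec((1998, 2002))
        youth_all, _ = tr.stratify_youth_adult(reg, trail, rule="all")
        youth_any, _ = tr.stratify_youth_adult(reg, trail, rule="any")
        assert youth_all.n_persons == 0
        assert youth_any.n_persons == 1

    def test_youth_share_calibration(self):
        # the default demography yields roughly 30% youth mid-window
        cfg = tr.SyntheticConfig.metropolitan(20_000, seed=66)
        reg = tr.generate_population(cfg)
        youth, _ = tr.stratify_youth_adult(reg, tr.TrailSpec((2001,)))
        assert abs(youth.n_persons / 20_000 - 0.30) < 0.05


class TestSensitivityBounds:
    @pytest.mark.parametrize("u,r,expected_max", [
        (0.20, 0.06, 0.248),   # low-risk point: can rise to ~25%
        (0.05, 0.06, 0.107),   # 5% observed: can rise to ~10%
    ])
    def test_upper_bounds(self, u, r, expected_max):
        _, u_max = tr.sensitivity_bounds(tr.SensitivityInput(u, r))
        assert u_max == pytest.approx(expected_max)

    def test_lower_bound(self):
        u_min, _ = tr.sensitivity_bounds(tr.SensitivityInput(0.20, 0.06))
        assert u_min == pytest.approx(0.188)

    def test_no_removals_collapses_the_interval(self):
        u_min, u_max = tr.sensitivity_bounds(tr.SensitivityInput(0.37, 0.0))
        assert u_min == u_max == pytest.approx(0.37)

    def test_bounds_ordered_and_in_unit_interval(self):
        for u in (0.0, 0.3, 1.0):
            for r in (0.0, 0.06, 1.0):
                lo, hi = tr.sensitivity_bounds(tr.SensitivityInput(u, r))
                assert 0.0 <= lo <= hi <= 1.0


class TestPolicyTable:
    def _result(self, mean):
        return tr.EstimateResult(
            level=tr.GeneralizationLevel("year", 3, True), k=1,
            stratum="all", mean=mean, n_iterations=10, values=[mean])

    def test_threshold_classification(self):
        table = tr.policy_table(
            [self._result(m) for m in (0.03, 0.12, 0.50)])
        assert table["acceptable_strict"].tolist() == [True, False, False]
        assert table["acceptable_relaxed"].tolist() == [True, True, False]

    def test_strict_implies_relaxed(self):
        means = np.linspace(0, 1, 21)
        table = tr.policy_table([self._result(float(m)) for m in means])
        assert (table["acceptable_strict"] <= table["acceptable_relaxed"]).all()

    def test_boundary_is_acceptable(self):
        table = tr.policy_table([self._result(0.05)])
        assert bool(table["acceptable_strict"].iloc[0])
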