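import numpy as np
import pytest
from scipy.stats import poisson

from fertgrowth import (
    PredictorSpec,
    build_model_subset,
    default_paperlike_truth,
    inject_missingness,
    read_truth,
    recovery_truth,
    simulate,
    standardize,
    validate_records,
    write_dataset,
)
from fertgrowth.synthetic import TruthSet, mi_group_truth


class TestSimulate:
    def test_full_inflation_every_woman_has_one_birth(self):
        truth = recovery_truth(n_populations=2, women_per_population=50, theta=1.0, seed=3)
        ds = simulate(truth)
        assert (ds.records.live_births == 1).all()

    def test_mean_parity_law_of_large_numbers(self):
        # all women old, no hierarchy or inflation, near-saturated curve:
        # sample mean parity -> asymptote M = 5 within 3 standard errors
        truth = TruthSet(
            n_populations=1,
            women_per_population=1000,
            alpha=float(np.log(5.0)),
            log_k=float(np.log(2.0)),  # k large: fully saturated at age 85
            log_b=0.0,
            a0=0.0,
            sigma_pop=0.0,
            sigma_u=0.0,
            theta=0.0,
            seed=12,
            age_range=(85.0, 85.0),
        )
        ds = simulate(truth)
        se = np.sqrt(5.0 / 1000)
        assert abs(ds.records.live_births.mean() - 5.0) < 3 * se

    def test_same_seed_byte_identical_csv(self, tmp_path):
        truth = default_paperlike_truth(n_women=300, seed=8)
        for d in ("a", "b"):
            write_dataset(simulate(truth), tmp_path / d)
        assert (tmp_path / "a/data.csv").read_bytes() == (tmp_path / "b/data.csv").read_bytes()
        assert (tmp_path / "a/populations.csv").read_bytes() == (
            tmp_path / "b/populations.csv"
        ).read_bytes()

    def test_passes_data_model_validation(self):
        truth = default_paperlike_truth(n_women=500, seed=4)
        ds = simulate(truth)
        validate_records(ds.records, ds.meta, [p.spec() for p in truth.predictors])

    def test_one_inflation_visible_in_parity_one_excess(self):
        # empirical P(y=1) should exceed the Poisson prediction by roughly
        # theta * (1 - Pois(1; lam)) on average
        truth = recovery_truth(n_populations=3, women_per_population=2000,
                               mu_beta=0.0, sigma_beta=0.0, sigma_pop=0.0,
                               theta=0.25, seed=6)
        ds = simulate(truth)
        k, b = np.exp(truth.log_k), np.exp(truth.log_b)
        lam = np.exp(truth.alpha) * (-np.expm1(-k * (ds.records.age - truth.a0))) ** b
        expected = np.mean(0.75 * poisson.pmf(1, lam) + 0.25)
        observed = (ds.records.live_births == 1).mean()
        assert observed == pytest.approx(expected, abs=0.02)

    def test_degenerate_truth_rejected(self):
        with pytest.raises(ValueError):
            simulate(
                TruthSet(
                    n_populations=1, women_per_population=1, alpha=1.0,
                    log_k=-2.0, log_b=0.0, a0=0.0, sigma_pop=0.0, sigma_u=0.0,
                    theta=0.0, seed=1,
                )
            )

    def test_within_population_z_moments(self):
        truth = recovery_truth(n_populations=4, women_per_population=200, seed=2)
        ds = simulate(truth)
        std = standardize(ds.records, PredictorSpec("focal", "zscore"))
        for _, grp in std.groupby("population_id"):
            assert abs(grp["focal__z"].mean()) < 1e-9
            assert abs(grp["focal__z"].std(ddof=1) - 1) < 1e-9


class TestPaperlikeScenario:
    def test_group_cf_targets(self):
        truth = default_paperlike_truth()
        assert truth.group_cf_targets["subsistence_type"]["hunter-gatherer"] == 4.6
        assert truth.group_cf_targets["market_integration"]["low"] == 5.5
        assert truth.group_cf_targets["market_integration"]["high"] == 3.53

    def test_default_scale(self):
        truth = default_paperlike_truth()
        assert truth.n_populations == 27
        assert sum(truth.women_per_population) == 10_250

    def test_population_truth_reconciles_group_margins(self):
        # log-scale group means of the per-population truth hit the targets
        truth = default_paperlike_truth()
        lam = np.array(
            [np.log((truth.true_cf(o) - truth.theta) / (1 - truth.theta))
             for o in truth.pop_log_m_offsets]
        )
        for grouping, col in [
            ("market_integration", truth.market_integration),
            ("subsistence_type", truth.subsistence),
        ]:
            for level, target in truth.group_cf_targets[grouping].items():
                mask = np.array([c == level for c in col])
                geo = truth.theta + (1 - truth.theta) * np.exp(lam[mask].mean())
                assert geo == pytest.approx(target, abs=0.02), (grouping, level)

    def test_truth_round_trips_through_yaml(self, tmp_path):
        truth = default_paperlike_truth(n_women=270, seed=5)
        truth.to_yaml(tmp_path / "truth.yaml")
        back = read_truth(tmp_path / "truth.yaml")
        assert back.alpha == truth.alpha
        assert back.pop_log_m_offsets == truth.pop_log_m_offsets
        assert [p.name for p in back.predictors] == [p.name for p in truth.predictors]
        # and the regenerated data is identical
        a, b = simulate(truth), simulate(back)
        assert a.records.equals(b.records)

    def test_mi_group_truth_cf_levels(self):
        truth = mi_group_truth(cf_low=5.5, cf_high=3.5)
        lows = [truth.true_cf(o) for o, m in
                zip(truth.pop_log_m_offsets, truth.market_integration) if m == "low"]
        np.testing.assert_allclose(lows, 5.5, rtol=1e-10)


class TestMissingness:
    def test_blanked_sites_shrink_subset(self):
        truth = default_paperlike_truth(n_women=540, seed=9)
        ds = simulate(truth)
        blank = [f"pop{j:02d}" for j in range(27)
                 if j not in {0, 1, 2, 3, 4, 5, 6, 7}]
        out = inject_missingness(ds, {"farming_activities": blank})
        spec = PredictorSpec("farming_activities", "zscore")
        sub = build_model_subset(standardize(out.records, spec), out.meta, spec)
        assert sub.n_populations == 8

    def test_blanked_cells_missing_not_zero(self):
        truth = default_paperlike_truth(n_women=270, seed=9)
        ds = simulate(truth)
        out = inject_missingness(ds, {"income": ["pop00"]})
        cells = out.records.loc[out.records.population_id == "pop00", "income"]
        assert cells.isna().all()
        assert out.n_blanked["income"] == len(cells)

    def test_empty_spec_identity(self):
        truth = default_paperlike_truth(n_women=270, seed=9)
        ds = simulate(truth)
        out = inject_missingness(ds, {})
        assert out.records.equals(ds.records)

    def test_subset_size_equals_complement_exactly(self):
        truth = recovery_truth(n_populations=5, women_per_population=40, seed=13)
        ds = simulate(truth)
        out = inject_missingness(ds, {"focal": ["pop01", "pop03"]})
        spec = PredictorSpec("focal", "zscore")
        sub = build_model_subset(standardize(out.records, spec), out.meta, spec)
        assert sub.n == 3 * 40
        assert sub.pop_ids == ["pop00", "pop02", "pop04"]

    def test_blanking_everything_rejected(self):
        truth = recovery_truth(n_populations=2, women_per_population=20, seed=1)
        ds = simulate(truth)
        with pytest.raises(ValueError, match="every predictor"):
            inject_missingness(ds, {"focal": ["pop00", "pop01"]})
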