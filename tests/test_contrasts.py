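import numpy as np
import pandas as pd
import pytest

from fertgrowth import (
    ModelDataset,
    ModelSpec,
    PosteriorDraws,
    PredictorSpec,
    contrast_1sd,
    group_cf_contrast,
    predict_cf,
    report,
    results_table,
)


def _manual_post(n_draws=40, J=2, theta=0.0, alpha=np.log(4.0), mu_beta=0.1,
                 k=5.0, b=1.0, a0=0.0, group_by=None, delta=None, meta=None):
    """Hand-built posterior with identical draws: closed-form checks."""
    shape = (1, n_draws)
    params = {
        "alpha": np.full(shape, alpha),
        "k": np.full(shape, k),
        "b": np.full(shape, b),
        "sigma_pop": np.full(shape, 0.1),
        "alpha_pop": np.zeros(shape + (J,)),
        "theta": np.full(shape, theta),
    }
    if mu_beta is not None:
        params["mu_beta"] = np.full(shape, mu_beta)
        params["sigma_beta"] = np.full(shape, 0.05)
        params["beta_pop"] = np.zeros(shape + (J,))
    if delta is not None:
        params["delta"] = np.tile(np.asarray(delta, float), shape + (1,))
    pop_ids = [f"p{j}" for j in range(J)]
    meta_df = meta
    if meta_df is None:
        meta_df = pd.DataFrame(
            {
                "population_id": pop_ids,
                "subsistence_type": ["hunter-gatherer", "agriculturalist"][:J],
                "market_integration": ["low", "high"][:J],
                "n_women": [5] * J,
            }
        )
    dataset = ModelDataset(
        y=[1] * J,
        age=[50.0] * J,
        pop_index=list(range(J)),
        pop_ids=pop_ids,
        z=np.zeros(J) if mu_beta is not None else None,
        predictor=PredictorSpec("focal", "zscore") if mu_beta is not None else None,
        meta=meta_df,
    )
    spec = ModelSpec(
        predictor=dataset.predictor, group_by=group_by, a0=a0, woman_effect=False
    )
    return PosteriorDraws(params=params, dataset=dataset, spec=spec)


# with k=5, a0=0: lambda(60) = M to double precision (curve saturated)


class TestPredictCf:
    def test_degenerate_posterior_theta_zero(self):
        post = _manual_post(theta=0.0, alpha=np.log(5.0), mu_beta=None)
        cf = predict_cf(post, "pooled")
        assert cf.cf_median == pytest.approx(5.0, rel=1e-9)
        assert (cf.hpdi.lower, cf.hpdi.upper) == (cf.cf_median, cf.cf_median)

    def test_one_inflation_expectation_formula(self):
        post = _manual_post(theta=0.2, alpha=np.log(5.0), mu_beta=None)
        cf = predict_cf(post, "pooled")
        assert cf.cf_median == pytest.approx(0.2 + 0.8 * 5.0, rel=1e-9)

    def test_population_scope_resolves_ids_and_rejects_unknown(self):
        post = _manual_post()
        by_idx = predict_cf(post, "population", population=1)
        by_id = predict_cf(post, "population", population="p1")
        assert by_idx.cf_median == by_id.cf_median
        with pytest.raises(ValueError, match="absent"):
            predict_cf(post, "population", population="nope")

    @pytest.mark.parametrize("lam60", [0.4, 5.0])
    def test_cf_sensitivity_to_inflation_has_sign_of_one_minus_lambda(self, lam60):
        # dE[y]/dtheta = 1 - lambda(60): inflation raises CF only below parity 1
        eps = 1e-4
        cfs = [
            predict_cf(_manual_post(theta=t, alpha=np.log(lam60), mu_beta=None),
                       "pooled").cf_median
            for t in (0.3, 0.3 + eps)
        ]
        deriv = (cfs[1] - cfs[0]) / eps
        assert deriv == pytest.approx(1.0 - lam60, rel=1e-6)

    def test_conditioning_on_z(self):
        post = _manual_post(alpha=np.log(4.0), mu_beta=0.1)
        cf0 = predict_cf(post, "pooled", z=0.0)
        cf1 = predict_cf(post, "pooled", z=1.0)
        assert cf1.cf_median / cf0.cf_median == pytest.approx(np.exp(0.1), rel=1e-9)


class TestContrast1Sd:
    def test_null_effect_gives_zero(self):
        post = _manual_post(mu_beta=0.0)
        c = contrast_1sd(post, "pooled")
        assert c.delta_cf_median == 0.0

    def test_saturated_closed_form(self):
        # theta=0, alpha=log 4, mu_beta=0.1, saturated age: dCF = 4(e^0.1 - 1)
        post = _manual_post(theta=0.0, alpha=np.log(4.0), mu_beta=0.1)
        c = contrast_1sd(post, "pooled")
        assert c.delta_cf_median == pytest.approx(4 * (np.exp(0.1) - 1), rel=1e-9)
        assert c.delta_cf_median == pytest.approx(0.4207, abs=1e-4)

    def test_antisymmetry(self, small_fit):
        _, _, post = small_fit
        c = contrast_1sd(post, "pooled")
        cf1 = predict_cf(post, "pooled", z=1.0).draws
        cf0 = predict_cf(post, "pooled", z=0.0).draws
        np.testing.assert_allclose(c.draws, cf1 - cf0, rtol=1e-12)
        np.testing.assert_allclose(-(cf0 - cf1), c.draws, rtol=1e-12)

    def test_population_scope_uses_population_slope(self, small_fit):
        _, _, post = small_fit
        pooled = contrast_1sd(post, "pooled")
        per_pop = [
            contrast_1sd(post, "population", j)
            for j in range(post.dataset.n_populations)
        ]
        meds = [c.delta_cf_median for c in per_pop]
        assert len(set(round(m, 6) for m in meds)) > 1  # slopes genuinely vary
        # pooled (population-mean) contrast sits inside the per-population hull
        assert min(meds) - 0.3 < pooled.delta_cf_median < max(meds) + 0.3

    def test_requires_focal_predictor(self):
        post = _manual_post(mu_beta=None)
        with pytest.raises(ValueError, match="focal predictor"):
            contrast_1sd(post, "pooled")


class TestGroupContrast:
    def test_identical_groups_null_contrast(self):
        post = _manual_post(mu_beta=None, group_by="market_integration",
                            delta=[0.0, 0.0])
        preds, contrasts = group_cf_contrast(post, "market_integration")
        assert len(preds) == 2 and len(contrasts) == 1
        assert contrasts[0].delta_cf_median == 0.0
        assert contrasts[0].pp == pytest.approx(0.5)

    def test_three_levels_emit_three_pairwise(self):
        meta = pd.DataFrame(
            {
                "population_id": ["p0", "p1", "p2"],
                "subsistence_type": ["hunter-gatherer"] * 3,
                "market_integration": ["low", "medium", "high"],
                "n_women": [5] * 3,
            }
        )
        post = _manual_post(J=3, mu_beta=None, group_by="market_integration",
                            delta=[0.3, 0.0, -0.3], meta=meta)
        preds, contrasts = group_cf_contrast(post, "market_integration")
        assert [p.scope_id for p in preds] == ["low", "medium", "high"]
        assert len(contrasts) == 3
        hi_lo = next(c for c in contrasts if c.scope_id == "high - low")
        assert hi_lo.delta_cf_median < 0

    def test_wrong_grouping_rejected(self):
        post = _manual_post(mu_beta=None, group_by="market_integration", delta=[0, 0])
        with pytest.raises(ValueError, match="subsistence_type"):
            group_cf_contrast(post, "subsistence_type")


class TestReport:
    def test_row_count_and_schema(self, small_fit, tmp_path):
        _, ds, post = small_fit
        results = [contrast_1sd(post, "pooled")] + [
            contrast_1sd(post, "population", j)
            for j in range(post.dataset.n_populations)
        ]
        table = report(results, ds.meta, tmp_path, predictions=[predict_cf(post)])
        pop_rows = table[table.scope == "population"]
        assert len(pop_rows) == post.dataset.n_populations
        assert (table.columns == [
            "predictor", "scope", "scope_id", "cf_or_delta", "median",
            "hpdi_lower", "hpdi_upper", "pp", "label", "n",
        ]).all()
        assert (tmp_path / "contrasts.csv").exists()
        assert (tmp_path / "forest_focal.png").exists()

    def test_labels_closed_vocabulary(self, small_fit):
        _, _, post = small_fit
        table = results_table([contrast_1sd(post, "pooled")])
        assert set(table.label) <= {"strong", "moderate", "weak"}

    def test_strong_label_for_high_pp(self):
        post = _manual_post(theta=0.0, alpha=np.log(4.0), mu_beta=0.2)
        c = contrast_1sd(post, "pooled")
        assert c.pp >= 0.9 and c.label == "strong"

    def test_empty_report_rejected(self):
        with pytest.raises(ValueError):
            results_table([])
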