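"""Headline quantities: predicted cumulative fertility at age 60 (CF~),
1-SD predictor contrasts (ΔCF~), group-level CF by subsistence type or
market-integration level, and machine-readable/forest-plot reporting.

CF is the posterior expectation of live births at age 60 under the
one-inflated Poisson outcome, E[y] = θ + (1−θ)·λ(60) — computed per draw and
then summarized (median + 90% HPDI), never as a summary of summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import MI_LEVELS, SUBSISTENCE_TYPES
from .inference import Hpdi, PosteriorDraws, evidence_label, hpdi, posterior_probability

__all__ = [
    "CumulativeFertilityPrediction",
    "ContrastResult",
    "predict_cf",
    "contrast_1sd",
    "group_cf_contrast",
    "report",
]

PREDICTION_AGE = 60.0


@dataclass
class CumulativeFertilityPrediction:
    scope: str                    # woman | population | subsistence_type | mi_level | pooled
    scope_id: object
    cf_median: float
    hpdi: Hpdi
    draws: np.ndarray             # retained for downstream contrasts
    n: int = 0

    def __post_init__(self) -> None:
        if self.cf_median < 0:
            raise ValueError("cumulative fertility cannot be negative")


@dataclass
class ContrastResult:
    predictor: str
    scope: str
    scope_id: object
    delta_cf_median: float
    hpdi: Hpdi
    pp: float
    label: str
    n_populations: int
    draws: np.ndarray


def _theta_draws(post: PosteriorDraws, population: int | None) -> np.ndarray:
    theta = post.params["theta"]
    if theta.ndim == 3:  # per-population inflation
        if population is None:
            return theta.mean(axis=-1).reshape(-1)
        return theta[..., population].reshape(-1)
    return theta.reshape(-1)


def _k_draws(post: PosteriorDraws, population: int | None) -> np.ndarray:
    if "k_pop" in post.params and population is not None:
        return post.params["k_pop"][..., population].reshape(-1)
    return post.params["k"].reshape(-1)


def _cf_from_logm(post: PosteriorDraws, log_m: np.ndarray, population: int | None) -> np.ndarray:
    """Per-draw E[y | age 60] from per-draw log asymptotes."""
    k = _k_draws(post, population)
    b = post.params["b"].reshape(-1)
    theta = _theta_draws(post, population)
    s60 = -np.expm1(-k * (PREDICTION_AGE - post.spec.a0))
    lam60 = np.exp(log_m) * s60**b
    return theta + (1.0 - theta) * lam60


def _log_m_draws(
    post: PosteriorDraws,
    scope: str,
    population: int | None = None,
    group: int | None = None,
    woman: int | None = None,
    z: float = 0.0,
) -> np.ndarray:
    p = post.params
    log_m = p["alpha"].reshape(-1).copy()
    if scope in ("population", "woman"):
        if population is None:
            raise ValueError("population index required for this scope")
        if population < 0 or population >= post.dataset.n_populations:
            raise ValueError(
                f"population index {population} not in the model subset "
                f"(J={post.dataset.n_populations})"
            )
        log_m = log_m + p["alpha_pop"][..., population].reshape(-1)
        if post.spec.group_by is not None:
            pop_group, _ = post.dataset.group_index(post.spec.group_by)
            log_m = log_m + p["delta"][..., pop_group[population]].reshape(-1)
        if "mu_beta" in p:
            slope = (p["mu_beta"] + p["beta_pop"][..., population]).reshape(-1)
            log_m = log_m + slope * z
        if scope == "woman":
            if woman is None:
                raise ValueError("woman index required for woman scope")
            log_m = log_m + p["u"][..., woman].reshape(-1)
    elif scope in ("subsistence_type", "mi_level"):
        if group is None:
            raise ValueError("group index required for group scope")
        log_m = log_m + p["delta"][..., group].reshape(-1)
    elif scope == "pooled":
        if "mu_beta" in p:
            log_m = log_m + p["mu_beta"].reshape(-1) * z
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return log_m


def predict_cf(
    post: PosteriorDraws,
    scope: str = "pooled",
    population=None,
    group=None,
    woman: int | None = None,
    z: float = 0.0,
    mass: float = 0.9,
) -> CumulativeFertilityPrediction:
    """Posterior predicted cumulative fertility at age 60 for one scope.

    ``population``/``group`` accept either a dense index or the id/level
    label.  Population scope sets the woman-level deviation to 0; woman
    scope includes it.  ``z`` conditions on a focal-predictor value (in
    within-population SD units).
    """
    pop_idx = _resolve_population(post, population) if population is not None else None
    grp_idx, scope_id = None, None
    if scope in ("subsistence_type", "mi_level"):
        grouping = "market_integration" if scope == "mi_level" else "subsistence_type"
        if post.spec.group_by != grouping:
            raise ValueError(f"model was not fitted with group_by={grouping!r}")
        _, levels = post.dataset.group_index(grouping)
        grp_idx = group if isinstance(group, (int, np.integer)) else levels.index(group)
        scope_id = levels[grp_idx]
    elif scope in ("population", "woman"):
        scope_id = post.dataset.pop_ids[pop_idx]

    log_m = _log_m_draws(post, scope, pop_idx, grp_idx, woman, z)
    cf = _cf_from_logm(post, log_m, pop_idx)
    n = post.dataset.n if pop_idx is None else int(np.sum(post.dataset.pop_index == pop_idx))
    return CumulativeFertilityPrediction(
        scope=scope,
        scope_id=scope_id,
        cf_median=float(np.median(cf)),
        hpdi=hpdi(cf, mass),
        draws=cf,
        n=n,
    )


def _resolve_population(post: PosteriorDraws, population) -> int:
    if isinstance(population, (int, np.integer)):
        return int(population)
    try:
        return post.dataset.pop_ids.index(population)
    except ValueError:
        raise ValueError(f"population {population!r} absent from the model subset") from None


def contrast_1sd(
    post: PosteriorDraws,
    scope: str = "pooled",
    population=None,
    mass: float = 0.9,
) -> ContrastResult:
    """ΔCF~ for +1 within-population SD of the focal predictor.

    Per draw: CF(z=1) − CF(z=0).  Pooled scope uses the cross-cultural mean
    slope μ_β (β_pop = 0); population scope uses μ_β + β_pop[j].  For binary
    predictors z=1 vs z=0 is exactly the category-1 minus category-0
    contrast.
    """
    if "mu_beta" not in post.params:
        raise ValueError("model was not fitted with a focal predictor")
    pop_idx = _resolve_population(post, population) if population is not None else None
    cf1 = _cf_from_logm(post, _log_m_draws(post, scope, pop_idx, z=1.0), pop_idx)
    cf0 = _cf_from_logm(post, _log_m_draws(post, scope, pop_idx, z=0.0), pop_idx)
    delta = cf1 - cf0
    pp = posterior_probability(delta)
    name = post.dataset.predictor.name if post.dataset.predictor is not None else "predictor"
    return ContrastResult(
        predictor=name,
        scope=scope,
        scope_id=post.dataset.pop_ids[pop_idx] if pop_idx is not None else "pooled",
        delta_cf_median=float(np.median(delta)),
        hpdi=hpdi(delta, mass),
        pp=pp,
        label=evidence_label(pp),
        n_populations=post.dataset.n_populations,
        draws=delta,
    )


def group_cf_contrast(
    post: PosteriorDraws,
    grouping: str,
    mass: float = 0.9,
) -> tuple[list[CumulativeFertilityPrediction], list[ContrastResult]]:
    """Per-group CF~ and all pairwise ΔCF~ for a categorical group model.

    Groups are ordered low < medium < high for market integration and in the
    canonical subsistence order otherwise; each pairwise contrast is
    later-group minus earlier-group (e.g. high − low).
    """
    if post.spec.group_by != grouping:
        raise ValueError(f"model was not fitted with group_by={grouping!r}")
    _, levels = post.dataset.group_index(grouping)
    scope = "mi_level" if grouping == "market_integration" else "subsistence_type"
    preds = [predict_cf(post, scope=scope, group=g, mass=mass) for g in range(len(levels))]
    contrasts = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            delta = preds[j].draws - preds[i].draws
            pp = posterior_probability(delta)
            contrasts.append(
                ContrastResult(
                    predictor=grouping,
                    scope=scope,
                    scope_id=f"{levels[j]} - {levels[i]}",
                    delta_cf_median=float(np.median(delta)),
                    hpdi=hpdi(delta, mass),
                    pp=pp,
                    label=evidence_label(pp),
                    n_populations=post.dataset.n_populations,
                    draws=delta,
                )
            )
    return preds, contrasts


def results_table(results, predictions=()) -> pd.DataFrame:
    """Flatten contrasts (and optional CF predictions) to the output schema."""
    rows = []
    for pr in predictions:
        rows.append(
            dict(
                predictor=getattr(pr, "predictor", ""),
                scope=pr.scope,
                scope_id=pr.scope_id,
                cf_or_delta="cf",
                median=pr.cf_median,
                hpdi_lower=pr.hpdi.lower,
                hpdi_upper=pr.hpdi.upper,
                pp="",
                label="",
                n=pr.n,
            )
        )
    for res in results:
        rows.append(
            dict(
                predictor=res.predictor,
                scope=res.scope,
                scope_id=res.scope_id,
                cf_or_delta="delta_cf",
                median=res.delta_cf_median,
                hpdi_lower=res.hpdi.lower,
                hpdi_upper=res.hpdi.upper,
                pp=res.pp,
                label=res.label,
                n=res.n_populations,
            )
        )
    if not rows:
        raise ValueError("nothing to report")
    return pd.DataFrame(rows)


def report(results, meta=None, out_dir=None, predictions=(), make_figures=True):
    """Write the results CSV (and a forest plot per predictor) to ``out_dir``.

    Population rows are faceted by market-integration level and colored by
    subsistence type when ``meta`` is given.  Returns the table.
    """
    table = results_table(results, predictions)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "contrasts.csv", index=False, float_format="%.6g")
        if make_figures:
            for predictor, sub in _group_results(results):
                _forest_plot(predictor, sub, meta, out_dir / f"forest_{predictor}.png")
    return table


def _group_results(results):
    by = {}
    for r in results:
        by.setdefault(r.predictor, []).append(r)
    return sorted(by.items())


_SUBSISTENCE_COLORS = dict(
    zip(SUBSISTENCE_TYPES, ["#d95f02", "#1b9e77", "#7570b3", "#e7298a", "#66a61e"])
)


def _forest_plot(predictor, results, meta, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pop_rows = [r for r in results if r.scope == "population"]
    other = [r for r in results if r.scope != "population"]

    def mi_rank(r):
        if meta is None:
            return 0
        row = meta.loc[meta["population_id"] == r.scope_id]
        return MI_LEVELS.index(row["market_integration"].iloc[0]) if len(row) else 0

    pop_rows.sort(key=lambda r: (mi_rank(r), str(r.scope_id)))
    rows = other + pop_rows
    fig, ax = plt.subplots(figsize=(6, 0.45 * max(len(rows), 4) + 1))
    for i, r in enumerate(rows):
        color = "black"
        if meta is not None and r.scope == "population":
            row = meta.loc[meta["population_id"] == r.scope_id]
            if len(row):
                color = _SUBSISTENCE_COLORS.get(row["subsistence_type"].iloc[0], "black")
        ax.plot([r.hpdi.lower, r.hpdi.upper], [i, i], color=color, lw=2)
        ax.plot(r.delta_cf_median, i, "o", color=color)
    ax.axvline(0, color="grey", ls=":")
    ax.set_yticks(range(len(rows)))
    ax.set_yticklabels([str(r.scope_id) for r in rows], fontsize=8)
    ax.set_xlabel("ΔCF (births per +1 SD)")
    ax.set_title(predictor, fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
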