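"""Model fitting and the posterior summarization primitives used throughout:
90% highest-posterior-density intervals, posterior probability of sign, and
the strong/moderate/weak evidence labels.

Evidence is labelled from the posterior probability (PP) that the quantity
lies on the median's side of zero: PP >= 0.9 "strong", 0.8 <= PP < 0.9
"moderate", PP < 0.8 "weak".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import ModelDataset
from .fertility_model import ModelSpec
from .hmc import nuts_sample
from .posterior import OipGrowthPosterior

__all__ = [
    "Hpdi",
    "EvidenceSummary",
    "PosteriorDraws",
    "fit",
    "hpdi",
    "eti",
    "posterior_probability",
    "evidence_label",
    "summarize_draws",
]


@dataclass(frozen=True)
class Hpdi:
    lower: float
    upper: float
    mass: float = 0.9


@dataclass(frozen=True)
class EvidenceSummary:
    posterior_median: float
    hpdi: Hpdi
    pp: float
    label: str


@dataclass
class PosteriorDraws:
    """Named posterior draws of one fitted model, with diagnostics.

    Arrays are shaped (chain, draw) for scalars and (chain, draw, J) for
    per-population vectors; the originating dataset and spec are retained so
    downstream prediction can reconstruct the growth curve.
    """

    params: dict
    dataset: ModelDataset
    spec: ModelSpec
    sampler_stats: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws of ``name`` with chains concatenated: (chain*draw, ...)."""
        v = self.params[name]
        return v.reshape(-1, *v.shape[2:])

    def to_frame(self, include_woman_effects: bool = False) -> pd.DataFrame:
        """Draws as a columnar table: ``chain``, ``draw``, then one column per
        scalar parameter; vector parameters expand to ``name[i]`` columns
        (population order = ``dataset.pop_ids``)."""
        cols = {}
        nc, nd = self.n_chains, self.n_draws
        cols["chain"] = np.repeat(np.arange(nc), nd)
        cols["draw"] = np.tile(np.arange(nd), nc)
        for name, v in self.params.items():
            if name == "u" and not include_woman_effects:
                continue
            if v.ndim == 2:
                cols[name] = v.reshape(-1)
            else:
                for i in range(v.shape[-1]):
                    cols[f"{name}[{i}]"] = v[..., i].reshape(-1)
        return pd.DataFrame(cols)

    def save_draws(self, path, **kwargs) -> None:
        """Serialize draws to CSV (see :meth:`to_frame` for the header contract)."""
        self.to_frame(**kwargs).to_csv(path, index=False)

    def diagnostics(self, include_woman_effects: bool = False) -> pd.DataFrame:
        """R-hat and bulk/tail ESS per scalar parameter column.

        The per-woman deviations ``u`` (one nuisance parameter per woman)
        are excluded unless ``include_woman_effects`` is set.
        """
        import arviz as az

        params = self.params
        if not include_woman_effects:
            params = {k: v for k, v in params.items() if k != "u"}
        idata = az.from_dict(posterior=params)
        rhat = az.rhat(idata)
        ess = az.ess(idata)
        ess_tail = az.ess(idata, method="tail")
        rows = []
        for name in params:
            r = np.atleast_1d(rhat[name].values)
            e = np.atleast_1d(ess[name].values)
            et = np.atleast_1d(ess_tail[name].values)
            for i in range(r.size):
                label = name if r.size == 1 else f"{name}[{i}]"
                rows.append((label, float(r.flat[i]), float(e.flat[i]), float(et.flat[i])))
        df = pd.DataFrame(rows, columns=["parameter", "rhat", "ess_bulk", "ess_tail"])
        df["divergences"] = self.sampler_stats.get("divergences", 0)
        return df


def fit(dataset: ModelDataset, spec: ModelSpec) -> PosteriorDraws:
    """Fit the hierarchical one-inflated Poisson growth model by NUTS.

    Deterministic given (seed, chains, data).  Warns — never silently passes
    — when any R-hat exceeds 1.01 or post-warmup divergences occurred.
    """
    if dataset.n == 0:
        raise ValueError("empty dataset")
    post = OipGrowthPosterior(dataset, spec)
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.chains)
    chains = []
    stats = {"divergences": 0, "step_size": [], "accept_stat": []}
    for ss in seeds:
        rng = np.random.default_rng(ss)
        x0 = post.initial_point(rng)
        res = nuts_sample(
            post, x0, spec.warmup, spec.samples, rng, target_accept=spec.target_accept
        )
        chains.append(res.draws)
        stats["divergences"] += res.divergences
        stats["step_size"].append(res.step_size)
        stats["accept_stat"].append(res.accept_stat)
    raw = np.asarray(chains)  # (chain, draw, dim)

    params = _constrain(raw, post)
    draws = PosteriorDraws(params=params, dataset=dataset, spec=spec, sampler_stats=stats)

    diag = draws.diagnostics()
    bad = diag[diag["rhat"] > 1.01]
    if stats["divergences"] > 0:
        warnings.warn(
            f"{stats['divergences']} post-warmup divergences; treat results with caution",
            stacklevel=2,
        )
    if not bad.empty:
        worst = bad.sort_values("rhat", ascending=False).iloc[0]
        warnings.warn(
            f"{len(bad)} parameters with R-hat > 1.01 (worst {worst.parameter}: "
            f"{worst.rhat:.3f}); chains may not have converged",
            stacklevel=2,
        )
    return draws


def _constrain(raw: np.ndarray, post: OipGrowthPosterior) -> dict:
    """Map unconstrained draws to the natural parameterization."""
    from scipy.special import expit

    sl = post.index.slices
    get = lambda name: raw[..., sl[name]]
    out: dict[str, np.ndarray] = {}
    out["alpha"] = get("alpha")[..., 0]
    out["k"] = np.exp(get("log_k")[..., 0])
    out["b"] = np.exp(get("log_b")[..., 0])
    out["sigma_pop"] = np.exp(get("log_sigma_pop")[..., 0])
    out["alpha_pop"] = get("alpha_pop")
    if "mu_beta" in sl:
        out["mu_beta"] = get("mu_beta")[..., 0]
        out["sigma_beta"] = np.exp(get("log_sigma_beta")[..., 0])
        out["beta_pop"] = get("beta_pop")
    if "delta" in sl:
        out["delta"] = get("delta")
    if "log_sigma_u" in sl:
        out["sigma_u"] = np.exp(get("log_sigma_u")[..., 0])
        out["u"] = out["sigma_u"][..., None] * get("eta_u")
    if "log_sigma_k" in sl:
        out["sigma_k"] = np.exp(get("log_sigma_k")[..., 0])
        out["k_pop"] = out["k"][..., None] * np.exp(out["sigma_k"][..., None] * get("eta_k"))
    if "gamma_birth_year" in sl:
        out["gamma_birth_year"] = get("gamma_birth_year")[..., 0]
    lt = get("logit_theta")
    out["theta"] = expit(lt[..., 0]) if lt.shape[-1] == 1 else expit(lt)
    return out


def hpdi(draws, mass: float = 0.9) -> Hpdi:
    """Shortest contiguous interval over sorted draws holding ceil(mass*n) draws.

    Ties between equally short windows are broken toward the lowest lower
    bound (the first window in sorted order).
    """
    x = np.asarray(draws, dtype=float).ravel()
    if x.size < 10:
        raise ValueError("need at least 10 draws")
    if not np.all(np.isfinite(x)):
        raise ValueError("draws must be finite")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    x = np.sort(x)
    n = x.size
    m = int(np.ceil(mass * n))
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))  # first minimum -> lowest lower bound
    return Hpdi(lower=float(x[i]), upper=float(x[i + m - 1]), mass=mass)


def eti(draws, mass: float = 0.9) -> Hpdi:
    """Equal-tailed credible interval (companion to :func:`hpdi`)."""
    x = np.asarray(draws, dtype=float).ravel()
    lo, hi = np.quantile(x, [(1 - mass) / 2, 1 - (1 - mass) / 2])
    return Hpdi(lower=float(lo), upper=float(hi), mass=mass)


def posterior_probability(draws) -> float:
    """PP: the larger of Pr(d > 0) and Pr(d < 0), zeros split evenly."""
    x = np.asarray(draws, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty draw vector")
    if not np.all(np.isfinite(x)):
        raise ValueError("draws must be finite")
    n = x.size
    zeros = np.count_nonzero(x == 0)
    pos = np.count_nonzero(x > 0) + zeros / 2.0
    neg = np.count_nonzero(x < 0) + zeros / 2.0
    return max(pos, neg) / n


def evidence_label(pp: float) -> str:
    """'strong' iff PP >= 0.9, 'moderate' iff 0.8 <= PP < 0.9, else 'weak'."""
    if not 0.5 <= pp <= 1.0:
        raise ValueError(f"pp must lie in [0.5, 1], got {pp}")
    if pp >= 0.9:
        return "strong"
    if pp >= 0.8:
        return "moderate"
    return "weak"


def summarize_draws(draws, mass: float = 0.9) -> EvidenceSummary:
    """Median + HPDI + PP + label for one scalar draw vector."""
    x = np.asarray(draws, dtype=float).ravel()
    pp = posterior_probability(x)
    return EvidenceSummary(
        posterior_median=float(np.median(x)),
        hpdi=hpdi(x, mass),
        pp=pp,
        label=evidence_label(pp),
    )
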