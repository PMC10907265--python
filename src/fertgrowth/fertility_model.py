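"""Likelihood core: saturating growth curve for expected parity and the
one-inflated Poisson outcome distribution.

Cumulative live births y for a woman of age a are modelled as

    y ~ OIP(lambda(a), theta)
    P(y) = theta * [y == 1] + (1 - theta) * Poisson(y; lambda)

where the rate (expected parity under the Poisson branch) follows a
saturating growth function of age,

    lambda(a) = M * (1 - exp(-k * (a - a0)))^b      for a > a0, else 0.

M is the asymptotic expected parity, k the yearly rate of approach to the
asymptote, b a shape/elasticity parameter (b = 1 recovers the monomolecular
curve), and a0 an optional age anchor below which expected parity is zero.
Predictors and hierarchy enter through log M (see :mod:`fertgrowth.posterior`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, gammaln

__all__ = [
    "GrowthParams",
    "ModelSpec",
    "growth_rate",
    "oip_logpmf",
    "oip_mean",
    "oip_rvs",
    "linear_predictor",
    "loglik_dataset",
    "DEFAULT_PRIORS",
]


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of the saturating age–parity curve."""

    M: float
    k: float
    b: float
    a0: float = 0.0

    def __post_init__(self) -> None:
        if not (self.M > 0 and self.k > 0 and self.b > 0):
            raise ValueError("GrowthParams requires M, k, b > 0")


#: Weakly informative defaults; prior-predictive parity at age 60 spans ~1–15.
DEFAULT_PRIORS: dict[str, tuple[float, float]] = {
    "alpha": (np.log(5.0), 1.0),          # Normal on baseline log asymptote
    "mu_beta": (0.0, 0.5),                # Normal on pooled predictor slope
    "log_k": (np.log(0.05), 0.5),         # Normal on log rate
    "log_b": (0.0, 0.5),                  # Normal on log shape
    "sigma": (0.0, 0.5),                  # Half-Normal scale for all sigmas
    "theta_beta": (2.0, 18.0),            # Beta on one-inflation mass
    "delta": (0.0, 1.0),                  # Normal on group-level log M shifts
    "gamma_birth_year": (0.0, 0.5),       # Normal on birth-year slope
}


@dataclass
class ModelSpec:
    """Configuration of one fitted model (one focal predictor, or one grouping).

    Exactly one of ``predictor`` / ``group_by`` is focal (both may be absent
    for an intercept-only fit).  Population intercepts on log M are always
    present; ``k_pop_effects`` optionally adds population effects on log k.
    ``theta_scope`` is ``"global"`` (one inflation mass) or ``"population"``.
    """

    predictor: object | None = None          # PredictorSpec of the focal predictor
    group_by: str | None = None              # "market_integration" | "subsistence_type"
    woman_effect: bool = True                # woman-level normal deviation on log M
    k_pop_effects: bool = False
    theta_scope: str = "global"
    birth_year_control: bool = False
    a0: float = 10.0
    priors: dict = field(default_factory=dict)
    chains: int = 2
    warmup: int = 500
    samples: int = 500
    seed: int = 0
    target_accept: float = 0.9

    def prior(self, name: str) -> tuple[float, float]:
        return self.priors.get(name, DEFAULT_PRIORS[name])

    def __post_init__(self) -> None:
        if self.theta_scope not in ("global", "population"):
            raise ValueError("theta_scope must be 'global' or 'population'")
        if self.predictor is not None and self.group_by is not None:
            raise ValueError("a model has one focal term: predictor or group_by, not both")


def growth_rate(age, params: GrowthParams):
    """Expected parity lambda(age) under the growth curve; vectorized in age."""
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise ValueError("age must be non-negative")
    a = np.clip(age - params.a0, 0.0, None)
    s = -np.expm1(-params.k * a)
    lam = params.M * s**params.b
    return lam if lam.ndim else float(lam)


def oip_logpmf(y, lam, theta):
    """Log pmf of the one-inflated Poisson; broadcasts over inputs.

    ``pmf(y) = theta*[y==1] + (1-theta)*Poisson(y; lam)``.  Stable for large
    y via log-space mixing.
    """
    y = np.asarray(y)
    lam = np.asarray(lam, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any((theta < 0) | (theta >= 1)):
        raise ValueError("theta must lie in [0, 1)")
    if np.any(lam <= 0):
        raise ValueError("lambda must be positive")
    if np.any(y < 0) or np.any(np.asarray(y) % 1 != 0):
        raise ValueError("y must be a non-negative integer")
    y = y.astype(np.int64)
    y, lam, theta = np.broadcast_arrays(y, lam, theta)
    log_pois = y * np.log(lam) - lam - gammaln(y + 1.0)
    base = np.log1p(-theta) + log_pois
    with np.errstate(divide="ignore"):  # log(0) -> -inf is the right limit
        log_theta = np.log(theta)
    out = np.where(y == 1, np.logaddexp(log_theta, base), base)
    return out if out.ndim else float(out)


def oip_mean(lam, theta):
    """E[y] = theta + (1 - theta) * lambda."""
    return theta + (1.0 - theta) * np.asarray(lam, dtype=float)


def oip_rvs(rng: np.random.Generator, lam, theta):
    """Draw one-inflated Poisson counts; vectorized over lam."""
    lam = np.asarray(lam, dtype=float)
    inflated = rng.random(lam.shape) < theta
    y = rng.poisson(lam)
    y[inflated] = 1
    return y


def linear_predictor(z, pop_index, alpha, alpha_pop, mu_beta=0.0, beta_pop=None, u=0.0):
    """log M per woman: alpha + alpha_pop[j] + (mu_beta + beta_pop[j]) z + u.

    ``z`` may be None (no focal predictor).  ``alpha_pop``/``beta_pop`` are
    per-population vectors; ``u`` a per-woman deviation (scalar 0 to omit).
    """
    alpha_pop = np.asarray(alpha_pop, dtype=float)
    pop_index = np.asarray(pop_index, dtype=np.intp)
    if pop_index.size and (pop_index.min() < 0 or pop_index.max() >= alpha_pop.shape[0]):
        raise IndexError("population index out of range")
    m = alpha + alpha_pop[pop_index]
    if z is not None:
        slope = mu_beta if beta_pop is None else mu_beta + np.asarray(beta_pop, dtype=float)[pop_index]
        m = m + slope * np.asarray(z, dtype=float)
    return m + u


def loglik_dataset(dataset, growth: GrowthParams | None = None, *, log_m=None,
                   k=None, b=None, a0=0.0, theta=0.0):
    """Total one-inflated Poisson log-likelihood of a dataset.

    Either pass shared ``growth`` params, or per-woman ``log_m`` with scalar
    ``k``, ``b``, ``a0``.  Raises naming the first record whose contribution
    is non-finite (e.g. y > 0 at lambda = 0).
    """
    age = dataset.age
    y = dataset.y
    if growth is not None:
        lam = growth_rate(age, growth)
    else:
        a = np.clip(age - a0, 0.0, None)
        lam = np.exp(log_m) * (-np.expm1(-k * a)) ** b
    if np.any(lam <= 0):
        i = int(np.argmax(lam <= 0))
        raise ValueError(f"record {i}: lambda = 0 at age {age[i]:g} (age <= a0?)")
    ll = oip_logpmf(y, lam, theta)
    if not np.all(np.isfinite(ll)):
        i = int(np.argmax(~np.isfinite(np.atleast_1d(ll))))
        raise ValueError(f"record {i}: non-finite log-likelihood (y={y[i]}, lambda={lam[i]:g})")
    return float(np.sum(ll))
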