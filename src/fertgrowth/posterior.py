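"""Unconstrained log posterior (with analytic gradient) of the hierarchical
one-inflated Poisson growth model.

Parameterization (all unconstrained; J populations, N women, G groups):

* ``alpha``            baseline log asymptote
* ``log_k``, ``log_b`` growth-curve rate and shape on the log scale
* ``log_sigma_pop``, ``alpha_pop[J]`` population intercepts on log M
* ``mu_beta``, ``log_sigma_beta``, ``beta_pop[J]``  pooled slope + population
  slopes of the focal standardized predictor (if any)
* ``delta[G]``         fixed group-level shifts of log M (if group_by)
* ``log_sigma_u``, ``eta_u[N]``       non-centered woman-level deviations (optional)
* ``logit_theta``      one-inflation mass (scalar, or length J when
  ``theta_scope == "population"``)
* ``log_sigma_k``, ``eta_k[J]``       optional population effects on log k
* ``gamma_birth_year`` optional linear birth-year control on log M

Population-level effects use the centered parameterization (each site
contributes hundreds of women, so the effects are data-identified and
centering avoids the funnel that cripples mixing of the group scales);
woman-level deviations, identified by a single count each, stay
non-centered (``eta_u``, scaled by ``sigma_u``).  Half-Normal hyperpriors on
sigmas and the Beta prior on theta include the log/logit Jacobians, so the
density is with respect to the unconstrained coordinates HMC samples in.
The gradient is assembled analytically and is checked against finite
differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, gammaln

from .data_model import ModelDataset
from .fertility_model import ModelSpec


@dataclass
class ParamIndex:
    """Name -> slice layout of the flat unconstrained vector."""

    slices: dict
    dim: int

    def unpack(self, x: np.ndarray) -> dict:
        return {k: x[..., s] for k, s in self.slices.items()}


def build_index(dataset: ModelDataset, spec: ModelSpec) -> ParamIndex:
    J = dataset.n_populations
    slices: dict = {}
    pos = 0

    def add(name: str, size: int) -> None:
        nonlocal pos
        slices[name] = slice(pos, pos + size)
        pos += size

    add("alpha", 1)
    add("log_k", 1)
    add("log_b", 1)
    add("log_sigma_pop", 1)
    add("alpha_pop", J)
    if spec.predictor is not None:
        add("mu_beta", 1)
        add("log_sigma_beta", 1)
        add("beta_pop", J)
    if spec.group_by is not None:
        _, levels = dataset.group_index(spec.group_by)
        add("delta", len(levels))
    if spec.woman_effect:
        add("log_sigma_u", 1)
        add("eta_u", dataset.n)
    if spec.k_pop_effects:
        add("log_sigma_k", 1)
        add("eta_k", J)
    if spec.birth_year_control:
        add("gamma_birth_year", 1)
    add("logit_theta", J if spec.theta_scope == "population" else 1)
    return ParamIndex(slices, pos)


class OipGrowthPosterior:
    """Callable log-density + gradient for one model fit.

    ``__call__(x) -> (logp, grad)`` on the flat unconstrained vector.
    """

    def __init__(self, dataset: ModelDataset, spec: ModelSpec):
        if np.any(dataset.age <= spec.a0):
            raise ValueError(
                f"all ages must exceed the growth anchor a0={spec.a0:g}; "
                f"min age is {dataset.age.min():g}"
            )
        self.dataset = dataset
        self.spec = spec
        self.index = build_index(dataset, spec)
        self.J = dataset.n_populations
        self.N = dataset.n
        self.a = dataset.age - spec.a0
        self.y = dataset.y.astype(float)
        self.lgamma_y1 = gammaln(dataset.y + 1.0)
        self.is1 = (dataset.y == 1).astype(float)
        self.pidx = dataset.pop_index
        self.z = dataset.z
        if spec.group_by is not None:
            pop_group, self.group_levels = dataset.group_index(spec.group_by)
            self.gidx = pop_group[self.pidx]
            self.G = len(self.group_levels)
        else:
            self.gidx = None
            self.G = 0

    # -- helpers -----------------------------------------------------------
    def _bincount(self, values: np.ndarray) -> np.ndarray:
        return np.bincount(self.pidx, weights=values, minlength=self.J)

    def initial_point(self, rng: np.random.Generator) -> np.ndarray:
        """Weakly jittered start near the prior centers."""
        x = np.zeros(self.index.dim)
        p = self.index.slices
        sp = self.spec
        x[p["alpha"]] = sp.prior("alpha")[0]
        x[p["log_k"]] = sp.prior("log_k")[0]
        x[p["log_b"]] = sp.prior("log_b")[0]
        x[p["log_sigma_pop"]] = np.log(0.2)
        if "log_sigma_beta" in p:
            x[p["log_sigma_beta"]] = np.log(0.1)
        if "log_sigma_u" in p:
            x[p["log_sigma_u"]] = np.log(0.1)
        if "log_sigma_k" in p:
            x[p["log_sigma_k"]] = np.log(0.1)
        a, b = sp.prior("theta_beta")
        x[p["logit_theta"]] = np.log(a / b)
        x += 0.05 * rng.standard_normal(self.index.dim)
        return x

    # -- density -----------------------------------------------------------
    def __call__(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        p = self.index.slices
        sp = self.spec
        grad = np.zeros_like(x)

        alpha = x[p["alpha"]][0]
        log_k = x[p["log_k"]][0]
        log_b = x[p["log_b"]][0]
        log_sigma_pop = x[p["log_sigma_pop"]][0]
        alpha_pop = x[p["alpha_pop"]]
        sigma_pop = np.exp(log_sigma_pop)
        b = np.exp(log_b)

        m = alpha + alpha_pop[self.pidx]

        if self.z is not None:
            mu_beta = x[p["mu_beta"]][0]
            log_sigma_beta = x[p["log_sigma_beta"]][0]
            beta_pop = x[p["beta_pop"]]
            sigma_beta = np.exp(log_sigma_beta)
            m = m + (mu_beta + beta_pop[self.pidx]) * self.z
        if self.gidx is not None:
            delta = x[p["delta"]]
            m = m + delta[self.gidx]
        if sp.woman_effect:
            log_sigma_u = x[p["log_sigma_u"]][0]
            eta_u = x[p["eta_u"]]
            sigma_u = np.exp(log_sigma_u)
            m = m + sigma_u * eta_u
        if sp.birth_year_control:
            gamma = x[p["gamma_birth_year"]][0]
            m = m + gamma * self.dataset.birth_year_z

        if sp.k_pop_effects:
            log_sigma_k = x[p["log_sigma_k"]][0]
            eta_k = x[p["eta_k"]]
            sigma_k = np.exp(log_sigma_k)
            k_row = np.exp(log_k + sigma_k * eta_k[self.pidx])
        else:
            k_row = np.exp(log_k)

        lt = x[p["logit_theta"]]
        theta_vec = expit(lt)
        theta_row = theta_vec[self.pidx] if sp.theta_scope == "population" else theta_vec[0]

        # growth curve and likelihood, all length-N vectors
        ka = k_row * self.a
        s = -np.expm1(-ka)                      # in (0, 1)
        log_s = np.log(s)
        log_lam = m + b * log_s
        lam = np.exp(log_lam)
        log_pois = self.y * log_lam - lam - self.lgamma_y1
        base = np.log1p(-theta_row) + log_pois
        log_theta = np.log(theta_row)
        ones = self.is1 > 0
        logp_row = np.where(ones, np.logaddexp(log_theta, base), base)
        loglik = float(np.sum(logp_row))

        # dl/dlog_lam and dl/dtheta per row; r = (1-theta)*pois / pmf <= 1
        r = np.exp(base - logp_row)
        g_loglam = r * (self.y - lam)
        g_theta = -r / (1.0 - theta_row)
        # + [y==1]/pmf, only where the inflation mass applies (pmf >= theta there)
        g_theta = g_theta + np.where(ones, np.exp(np.clip(-logp_row, None, 700.0)), 0.0) * ones

        # chain rule into log M, log k, log b
        g_m = g_loglam
        g_logb_row = g_loglam * b * log_s
        # d log_lam / d log k_row = b * ka * (1-s) / s
        g_logk_row = g_loglam * b * ka * (1.0 - s) / s

        lp = loglik

        # alpha
        mu0, sd0 = sp.prior("alpha")
        lp += -0.5 * ((alpha - mu0) / sd0) ** 2
        grad[p["alpha"]] = np.sum(g_m) - (alpha - mu0) / sd0**2

        # population intercepts (centered) + Half-Normal sigma (log Jacobian)
        gsum_pop = self._bincount(g_m)
        _, sd_s = sp.prior("sigma")
        lp += -self.J * log_sigma_pop - 0.5 * np.sum(alpha_pop**2) / sigma_pop**2
        lp += -0.5 * (sigma_pop / sd_s) ** 2 + log_sigma_pop
        grad[p["alpha_pop"]] = gsum_pop - alpha_pop / sigma_pop**2
        grad[p["log_sigma_pop"]] = (
            np.sum(alpha_pop**2) / sigma_pop**2 - self.J
            - (sigma_pop / sd_s) ** 2 + 1.0
        )

        if self.z is not None:
            gz = g_m * self.z
            gsum_z = self._bincount(gz)
            mu_b0, sd_b0 = sp.prior("mu_beta")
            lp += -0.5 * ((mu_beta - mu_b0) / sd_b0) ** 2
            grad[p["mu_beta"]] = np.sum(gz) - (mu_beta - mu_b0) / sd_b0**2
            lp += -self.J * log_sigma_beta - 0.5 * np.sum(beta_pop**2) / sigma_beta**2
            lp += -0.5 * (sigma_beta / sd_s) ** 2 + log_sigma_beta
            grad[p["beta_pop"]] = gsum_z - beta_pop / sigma_beta**2
            grad[p["log_sigma_beta"]] = (
                np.sum(beta_pop**2) / sigma_beta**2 - self.J
                - (sigma_beta / sd_s) ** 2 + 1.0
            )

        if self.gidx is not None:
            mu_d, sd_d = sp.prior("delta")
            lp += -0.5 * np.sum(((delta - mu_d) / sd_d) ** 2)
            grad[p["delta"]] = (
                np.bincount(self.gidx, weights=g_m, minlength=self.G)
                - (delta - mu_d) / sd_d**2
            )

        if sp.woman_effect:
            lp += -0.5 * np.sum(eta_u**2)
            lp += -0.5 * (sigma_u / sd_s) ** 2 + log_sigma_u
            grad[p["eta_u"]] = sigma_u * g_m - eta_u
            grad[p["log_sigma_u"]] = (
                sigma_u * np.dot(eta_u, g_m) - (sigma_u / sd_s) ** 2 + 1.0
            )

        if sp.birth_year_control:
            mu_g, sd_g = sp.prior("gamma_birth_year")
            lp += -0.5 * ((gamma - mu_g) / sd_g) ** 2
            grad[p["gamma_birth_year"]] = (
                np.sum(g_m * self.dataset.birth_year_z) - (gamma - mu_g) / sd_g**2
            )

        # log k (global) and optional population spread
        mu_k0, sd_k0 = sp.prior("log_k")
        lp += -0.5 * ((log_k - mu_k0) / sd_k0) ** 2
        grad[p["log_k"]] = np.sum(g_logk_row) - (log_k - mu_k0) / sd_k0**2
        if sp.k_pop_effects:
            gsum_k = self._bincount(g_logk_row)
            lp += -0.5 * np.sum(eta_k**2)
            lp += -0.5 * (sigma_k / sd_s) ** 2 + log_sigma_k
            grad[p["eta_k"]] = sigma_k * gsum_k - eta_k
            grad[p["log_sigma_k"]] = (
                sigma_k * np.dot(eta_k, gsum_k) - (sigma_k / sd_s) ** 2 + 1.0
            )

        # log b
        mu_b, sd_b = sp.prior("log_b")
        lp += -0.5 * ((log_b - mu_b) / sd_b) ** 2
        grad[p["log_b"]] = np.sum(g_logb_row) - (log_b - mu_b) / sd_b**2

        # theta: Beta(a,b) prior with logit Jacobian -> a*log(theta)+b*log(1-theta)
        a_t, b_t = sp.prior("theta_beta")
        lp += float(np.sum(a_t * np.log(theta_vec) + b_t * np.log1p(-theta_vec)))
        if sp.theta_scope == "population":
            g_theta_pop = np.bincount(self.pidx, weights=g_theta, minlength=self.J)
            grad[p["logit_theta"]] = (
                g_theta_pop * theta_vec * (1.0 - theta_vec)
                + a_t * (1.0 - theta_vec) - b_t * theta_vec
            )
        else:
            grad[p["logit_theta"]] = (
                np.sum(g_theta) * theta_vec[0] * (1.0 - theta_vec[0])
                + a_t * (1.0 - theta_vec[0]) - b_t * theta_vec[0]
            )

        if not np.isfinite(lp):
            return -np.inf, grad
        return lp, grad
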