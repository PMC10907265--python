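"""A compact No-U-Turn sampler with dual-averaging step-size adaptation and
mass-matrix estimation.

The target is supplied as a callable ``logp_grad(x) -> (logp, grad)`` on an
unconstrained vector.  Warmup adapts the step size throughout (dual
averaging, target acceptance statistic configurable) and re-estimates the
mass matrix once, halfway through warmup, from the draws collected so far —
a dense matrix for low-dimensional targets (where parameter correlations,
e.g. between growth-curve rate and shape, otherwise force deep trees) and a
diagonal one above ``dense_mass_max`` dimensions (hierarchical fits with
per-woman effects).  Sampling is fully deterministic given the
:class:`numpy.random.Generator`.

Divergences are flagged when the Hamiltonian error along a trajectory
exceeds 1000 nats; the doubling stops there and the draw is taken from the
valid part of the tree (the standard Stan behaviour).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NutsResult", "nuts_sample"]

_MAX_DELTA_H = 1000.0


@dataclass
class NutsResult:
    draws: np.ndarray                 # (n_draws, dim)
    step_size: float
    divergences: int
    accept_stat: float                # mean Metropolis acceptance statistic
    tree_depths: np.ndarray
    inv_mass: np.ndarray


class _Metric:
    """Euclidean metric; diagonal (vector) or dense (Cholesky of covariance)."""

    def __init__(self, inv_mass):
        self.inv_mass = inv_mass
        self.dense = inv_mass.ndim == 2
        if self.dense:
            # momenta ~ N(0, C^{-1}) where C = inv_mass: r = L^{-T} xi, C = L L^T
            self._chol = np.linalg.cholesky(inv_mass)

    def sample_momentum(self, rng, dim):
        xi = rng.standard_normal(dim)
        if self.dense:
            return np.linalg.solve(self._chol.T, xi)
        return xi / np.sqrt(self.inv_mass)

    def velocity(self, r):
        if self.dense:
            return self.inv_mass @ r
        return self.inv_mass * r

    def kinetic(self, r):
        return 0.5 * float(np.dot(r, self.velocity(r)))


def _leapfrog(logp_grad, metric, x, r, grad, eps):
    r = r + 0.5 * eps * grad
    x = x + eps * metric.velocity(r)
    logp, grad = logp_grad(x)
    r = r + 0.5 * eps * grad
    return x, r, logp, grad


class _Tree:
    """Recursive NUTS tree (slice variant, Hoffman & Gelman alg. 3)."""

    __slots__ = ("logp_grad", "eps", "metric", "log_u", "h0", "rng",
                 "divergent", "n_accept", "n_steps")

    def __init__(self, logp_grad, eps, metric, log_u, h0, rng):
        self.logp_grad = logp_grad
        self.eps = eps
        self.metric = metric
        self.log_u = log_u
        self.h0 = h0
        self.rng = rng
        self.divergent = False
        self.n_accept = 0.0
        self.n_steps = 0

    def build(self, x, r, grad, logp, v, depth):
        if depth == 0:
            x1, r1, logp1, grad1 = _leapfrog(
                self.logp_grad, self.metric, x, r, grad, v * self.eps
            )
            h = -logp1 + self.metric.kinetic(r1)
            delta_h = h - self.h0
            if not np.isfinite(h) or delta_h > _MAX_DELTA_H:
                self.divergent = True
                n_valid = 0
            else:
                n_valid = int(self.log_u <= -h)
            self.n_accept += min(1.0, np.exp(-delta_h)) if np.isfinite(delta_h) else 0.0
            self.n_steps += 1
            return x1, r1, grad1, logp1, x1, r1, grad1, logp1, x1, n_valid, True
        (xm, rm, gm, lpm, xp, rp, gp, lpp, xq, n1, ok1) = self.build(
            x, r, grad, logp, v, depth - 1
        )
        if not ok1 or self.divergent:
            return xm, rm, gm, lpm, xp, rp, gp, lpp, xq, n1, False
        if v < 0:
            (xm, rm, gm, lpm, _, _, _, _, xq2, n2, ok2) = self.build(
                xm, rm, gm, lpm, v, depth - 1
            )
        else:
            (_, _, _, _, xp, rp, gp, lpp, xq2, n2, ok2) = self.build(
                xp, rp, gp, lpp, v, depth - 1
            )
        if n2 > 0 and self.rng.random() < n2 / max(n1 + n2, 1):
            xq = xq2
        n = n1 + n2
        ok = ok2 and not self.divergent and _no_u_turn(self.metric, xm, xp, rm, rp)
        return xm, rm, gm, lpm, xp, rp, gp, lpp, xq, n, ok


def _no_u_turn(metric, xm, xp, rm, rp):
    dx = xp - xm
    return (np.dot(dx, metric.velocity(rm)) >= 0) and (
        np.dot(dx, metric.velocity(rp)) >= 0
    )


def _find_initial_step(logp_grad, x0, metric, rng):
    eps = 1.0
    logp, grad = logp_grad(x0)
    r = metric.sample_momentum(rng, x0.shape[0])
    h0 = -logp + metric.kinetic(r)
    _, r1, logp1, _ = _leapfrog(logp_grad, metric, x0, r, grad, eps)
    h1 = -logp1 + metric.kinetic(r1)
    d = h0 - h1 if np.isfinite(h1) else -np.inf
    direction = 1.0 if d > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        _, r1, logp1, _ = _leapfrog(logp_grad, metric, x0, r, grad, eps)
        h1 = -logp1 + metric.kinetic(r1)
        d = h0 - h1 if np.isfinite(h1) else -np.inf
        if direction * d <= direction * np.log(0.5):
            break
    return float(np.clip(eps, 1e-8, 10.0))


def nuts_sample(
    logp_grad,
    x0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.85,
    max_depth: int = 10,
    dense_mass_max: int = 80,
) -> NutsResult:
    """Run one NUTS chain; returns post-warmup draws and sampler statistics."""
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        return _nuts_sample(
            logp_grad, x0, n_warmup, n_draws, rng, target_accept, max_depth,
            dense_mass_max,
        )


def _nuts_sample(logp_grad, x0, n_warmup, n_draws, rng, target_accept, max_depth,
                 dense_mass_max):
    x = np.asarray(x0, dtype=float).copy()
    dim = x.shape[0]
    metric = _Metric(np.ones(dim))

    logp, grad = logp_grad(x)
    if not np.isfinite(logp):
        raise RuntimeError("non-finite log density at the initial point")

    eps = _find_initial_step(logp_grad, x, metric, rng)
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    mass_window: list[np.ndarray] = []
    # two-stage metric estimation: a crude early update to escape the
    # identity metric quickly, then a refined one at mid-warmup
    mass_update_at = {n_warmup // 4, n_warmup // 2}
    collect_from = max(10, n_warmup // 10)
    adapt_iter = 0

    draws = np.empty((n_draws, dim))
    depths = np.empty(n_warmup + n_draws, dtype=np.int8)
    divergences = 0
    accept_stats = []

    for it in range(n_warmup + n_draws):
        warm = it < n_warmup
        r0 = metric.sample_momentum(rng, dim)
        h0 = -logp + metric.kinetic(r0)
        log_u = -h0 + np.log(rng.random())

        tree = _Tree(logp_grad, eps, metric, log_u, h0, rng)
        xm = xp = x
        rm = rp = r0
        gm = gp = grad
        lpm = lpp = logp
        x_new = x
        n = 1
        depth = 0
        ok = True
        while ok and depth < max_depth:
            v = 1.0 if rng.random() < 0.5 else -1.0
            if v < 0:
                (xm, rm, gm, lpm, _, _, _, _, xq, n2, ok2) = tree.build(
                    xm, rm, gm, lpm, v, depth
                )
            else:
                (_, _, _, _, xp, rp, gp, lpp, xq, n2, ok2) = tree.build(
                    xp, rp, gp, lpp, v, depth
                )
            if ok2 and n2 > 0 and rng.random() < min(1.0, n2 / n):
                x_new = xq
            n += n2
            ok = ok2 and _no_u_turn(metric, xm, xp, rm, rp)
            depth += 1
        depths[it] = depth
        if tree.divergent and not warm:
            divergences += 1
        if x_new is not x:
            logp, grad = logp_grad(x_new)
            x = x_new

        astat = tree.n_accept / max(tree.n_steps, 1)
        if warm:
            adapt_iter += 1
            h_bar = (1 - 1 / (adapt_iter + t0)) * h_bar + (target_accept - astat) / (
                adapt_iter + t0
            )
            log_eps = mu - np.sqrt(adapt_iter) / gamma * h_bar
            w = adapt_iter**-kappa
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            if it >= collect_from:
                mass_window.append(x.copy())
            if it + 1 in mass_update_at and len(mass_window) >= 10:
                sample = np.asarray(mass_window)
                if dim <= dense_mass_max and sample.shape[0] > dim + 10:
                    cov = np.cov(sample, rowvar=False)
                    # regularize toward the diagonal (Stan-style shrinkage)
                    w_n = sample.shape[0]
                    shrink = w_n / (w_n + 5.0)
                    cov = shrink * cov + (1 - shrink) * 1e-3 * np.eye(dim)
                    metric = _Metric(cov)
                else:
                    var = np.var(sample, axis=0)
                    metric = _Metric(np.clip(var, 1e-6, None))
                mass_window = []
                eps = _find_initial_step(logp_grad, x, metric, rng)
                mu = np.log(10.0 * eps)
                log_eps_bar, h_bar, adapt_iter = 0.0, 0.0, 0
            if it + 1 == n_warmup:
                eps = float(np.exp(log_eps_bar))
        else:
            draws[it - n_warmup] = x
            accept_stats.append(astat)

    return NutsResult(
        draws=draws,
        step_size=eps,
        divergences=divergences,
        accept_stat=float(np.mean(accept_stats)) if accept_stats else float("nan"),
        tree_depths=depths[n_warmup:],
        inv_mass=metric.inv_mass,
    )
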