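"""Adaptive random-walk Metropolis engine shared by the model-fitting modules.

A multivariate Gaussian random-walk proposal whose covariance is adapted
towards the running posterior covariance (Haario-style) and whose global
scale is tuned towards a 0.234 acceptance rate by Robbins-Monro updates.
Adaptation weight decays as ``t^-0.6`` (diminishing adaptation), so the
chain remains ergodic while the proposal keeps tracking the target.
Chains are seeded independently from one :class:`numpy.random.SeedSequence`,
making every fit exactly reproducible.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

TARGET_ACCEPT = 0.234


def laplace_init(logpost: Callable[[np.ndarray], float], x0: np.ndarray,
                 rel_step: float = 1e-4):
    """Posterior mode and Gaussian curvature approximation.

    Maximizes the log-posterior from ``x0`` (L-BFGS, numerical gradient)
    and inverts a finite-difference Hessian at the mode.  The result seeds
    the random-walk proposal covariance and the chain starting points,
    which removes most of the burn-in cost of covariance adaptation.
    """
    from scipy.optimize import minimize

    neg = lambda x: -logpost(x)
    res = minimize(neg, np.asarray(x0, float), method="L-BFGS-B")
    xm = res.x
    d = xm.size
    h = rel_step * np.maximum(1.0, np.abs(xm))
    H = np.empty((d, d))
    f0 = logpost(xm)
    fp = np.array([logpost(xm + h[i] * _e(d, i)) for i in range(d)])
    fm = np.array([logpost(xm - h[i] * _e(d, i)) for i in range(d)])
    for i in range(d):
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
        for j in range(i + 1, d):
            fpp = logpost(xm + h[i] * _e(d, i) + h[j] * _e(d, j))
            H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + f0) / (h[i] * h[j])
    # covariance = inverse negative Hessian, guarded against indefiniteness
    w, V = np.linalg.eigh(-H)
    w = np.clip(w, 1e-4, None)
    cov = (V / w) @ V.T
    return xm, cov


def _e(d, i):
    v = np.zeros(d)
    v[i] = 1.0
    return v


def adaptive_rwm(logpost: Callable[[np.ndarray], float], x0: np.ndarray,
                 n_iter: int, n_burnin: int, rng: np.random.Generator,
                 thin: int = 1, cov0: np.ndarray | None = None):
    """One adaptive random-walk Metropolis chain.

    Returns
    -------
    draws : (n_kept, d) array of post-burn-in states (thinned)
    lps : (n_kept,) log-posterior at each kept state
    accept_rate : overall acceptance fraction
    """
    x = np.asarray(x0, dtype=float).copy()
    d = x.size
    lp = float(logpost(x))
    if not np.isfinite(lp):
        raise ValueError("log-posterior not finite at the initial point")

    mean = x.copy()
    cov = np.eye(d) * 0.01 if cov0 is None else np.asarray(cov0, float).copy()
    log_scale = np.log(2.38 / np.sqrt(d))
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(d))

    total = n_burnin + n_iter
    n_kept = n_iter // thin
    draws = np.empty((n_kept, d))
    lps = np.empty(n_kept)
    n_acc = 0
    k = 0
    for t in range(total):
        # scale-mixture proposal: occasional long jumps explore skewed tails
        big = rng.random() < 0.1
        step = np.exp(log_scale) * (3.0 if big else 1.0)
        prop = x + step * (chol @ rng.standard_normal(d))
        lp_prop = float(logpost(prop))
        acc_p = np.exp(min(0.0, lp_prop - lp)) if np.isfinite(lp_prop) else 0.0
        if rng.random() < acc_p:
            x, lp = prop, lp_prop
            n_acc += 1
        if t < n_burnin:
            # adapt scale and covariance during burn-in, then freeze: the
            # sampling phase is a fixed (mixture) Metropolis kernel
            g = min(0.2, (t + 1.0) ** -0.6)
            if not big:   # only small steps inform the base scale
                log_scale += g * (acc_p - TARGET_ACCEPT)
            delta = x - mean
            mean += g * delta
            cov += g * (np.outer(delta, delta) - cov)
            if t >= 25:
                try:
                    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(d))
                except np.linalg.LinAlgError:
                    pass
        if t >= n_burnin and (t - n_burnin) % thin == 0 and k < n_kept:
            draws[k] = x
            lps[k] = lp
            k += 1
    return draws, lps, n_acc / total


def run_chains(logpost, init: Callable[[np.random.Generator], np.ndarray] | np.ndarray,
               n_chains: int, n_iter: int, n_burnin: int, seed: int,
               thin: int = 1, laplace: bool = True):
    """Run ``n_chains`` independent adaptive RWM chains.

    ``init`` is either a fixed starting point or a callable drawing a
    starting point from a chain-specific generator.  With ``laplace=True``
    (default) a posterior-mode search seeds all chains: the proposal
    covariance starts at the Laplace covariance and chains start at the
    mode plus a dispersed perturbation (one proposal-sd per coordinate),
    keeping between-chain diagnostics informative.

    Returns (draws ``(n_chains, n_kept, d)``, logposts, accept rates).
    """
    seeds = np.random.SeedSequence(seed).spawn(n_chains + 1)
    cov0 = None
    xmap = None
    if laplace:
        rng0 = np.random.default_rng(seeds[-1])
        x0 = init(rng0) if callable(init) else np.asarray(init, float)
        try:
            xmap, cov0 = laplace_init(logpost, x0)
        except Exception:
            xmap, cov0 = None, None
    all_draws, all_lps, rates = [], [], []
    for c in range(n_chains):
        rng = np.random.default_rng(seeds[c])
        if xmap is not None:
            sd = np.sqrt(np.diag(cov0))
            x0 = xmap + rng.standard_normal(xmap.size) * sd
            if not np.isfinite(logpost(x0)):
                x0 = xmap
        else:
            x0 = init(rng) if callable(init) else np.asarray(init, float)
        dr, lp, ar = adaptive_rwm(logpost, x0, n_iter, n_burnin, rng, thin,
                                  cov0=cov0)
        all_draws.append(dr)
        all_lps.append(lp)
        rates.append(ar)
    return np.stack(all_draws), np.stack(all_lps), np.asarray(rates)


def invlogit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p) - np.log1p(-p)


def gauss_hermite_normal(n_nodes: int):
    """Nodes/weights for E[f(Z)], Z ~ N(0,1), by Gauss-Hermite quadrature.

    Weights sum to 1; nodes are on the standard-normal scale.
    """
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    return x * np.sqrt(2.0), w / np.sqrt(np.pi)
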