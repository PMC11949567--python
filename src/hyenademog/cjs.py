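"""Bayesian Cormack-Jolly-Seber survival with detection heterogeneity.

The model conditions on each individual's first detection and estimates a
2-month apparent-survival probability for every (age class x sex) cell,
together with a shared detection model.  In the primary model the
detection probability of individual *i* is ``invlogit(mu_p + eps_i)``
with ``eps_i ~ Normal(0, sigma_p^2)``; the individual effects are
integrated out of the likelihood by Gauss-Hermite quadrature, so the
sampler works on the small hyperparameter vector only.  Survival between
occasions *t* and *t+1* uses the age class at occasion *t*; a cub crossing
its first birthday mid-interval transitions at the occasion boundary.

Priors are uninformative: every survival cell and the mean detection
probability are uniform on (0, 1), and ``sigma_p`` is uniform on
(0, ``sigma_upper``).

Annual survival is the 2-month rate to the 6th power, except for cubs:
cubs first become observable at a mean age of 2.41 months, leaving 9.59
months (= 4.795 two-month steps) of their first year, so the cub rate is
annualized with exponent 4.795.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from hyenademog._kernels import cjs_loglik_rows
from hyenademog._mcmc import invlogit, logit, gauss_hermite_normal
from hyenademog.encounters import (
    AGE_CLASSES, SEXES, EncounterHistory, _add_years, _as_date,
)
from hyenademog.synthetic_data import FIRST_DETECTABLE_AGE_MONTHS

RHAT_THRESHOLD = 1.1


@dataclass
class McmcConfig:
    """Sampler settings: 3 chains x 5000 kept iterations after 500 burn-in."""

    n_chains: int = 3
    n_iter: int = 5000
    n_burnin: int = 500
    thin: int = 1
    seed: int = 0
    sigma_upper: float = 10.0   # upper bound of the uniform prior on sigma_p

    def __post_init__(self):
        if self.n_iter <= 0 or self.n_burnin < 0:
            raise ValueError("need n_iter > 0 and n_burnin >= 0")
        if self.n_chains < 2:
            raise ValueError("need >= 2 chains for between-chain diagnostics")


@dataclass
class CjsParams:
    """Point parameters of the CJS model (used by the likelihood oracle).

    ``phi`` maps ``(age_class, sex)`` (or just ``age_class``) to the
    2-month survival probability; detection is ``invlogit(mu_p + eps)``.
    """

    phi: Mapping
    mu_p: float
    sigma_p: float = 0.0
    epsilon: Mapping | None = None

    def phi_for(self, age_class: str, sex: str) -> float:
        key = (age_class, sex)
        if key in self.phi:
            return float(self.phi[key])
        return float(self.phi[age_class])


def cjs_log_likelihood(history_row, first: int, params: CjsParams,
                       age_path: Sequence[str], sex: str = "F",
                       epsilon: float | None = None,
                       n_quad: int = 20) -> float:
    """Log-probability of one encounter history after first capture.

    The latent alive/dead path is marginalized by a two-state forward
    recursion.  If ``params.sigma_p > 0`` and no individual effect is
    supplied, the detection effect is integrated out by ``n_quad``-node
    Gauss-Hermite quadrature.

    ``age_path[t]`` is the age class at occasion ``t`` (entries before
    ``first`` are ignored).
    """
    y = np.asarray(history_row)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("history entries must be 0/1")
    T = y.size
    if not (0 <= first < T) or y[first] != 1:
        raise ValueError("history_row[first] must be 1")
    if y[:first].any():
        raise ValueError("detection before first capture")

    phis = np.array([params.phi_for(age_path[t], sex) for t in range(T - 1)]) \
        if T > 1 else np.empty(0)

    if epsilon is None and params.epsilon is not None:
        raise ValueError("pass the individual's epsilon explicitly")
    if epsilon is not None:
        eps_nodes, wts = np.array([float(epsilon)]), np.array([1.0])
    elif params.sigma_p > 0:
        z, wts = gauss_hermite_normal(n_quad)
        eps_nodes = params.sigma_p * z
    else:
        eps_nodes, wts = np.array([0.0]), np.array([1.0])

    L = 0.0
    for eps, w in zip(eps_nodes, wts):
        p = 1.0 / (1.0 + np.exp(-(params.mu_p + eps)))
        a, d = 1.0, 0.0
        for t in range(first, T - 1):
            an = a * phis[t]
            dn = d + a * (1.0 - phis[t])
            if y[t + 1] == 1:
                a, d = an * p, 0.0
            else:
                a, d = an * (1.0 - p), dn
        L += w * (a + d)
    if L <= 0.0:
        return -np.inf
    return float(np.log(L))


# ---------------------------------------------------------------------------
# model assembly

@dataclass
class _Design:
    y: np.ndarray
    first: np.ndarray
    phi_idx: np.ndarray        # (n, T-1) int64 into the cell vector
    cells: list                # [(age_class, sex), ...]
    p_group: np.ndarray        # (n,) int64
    p_levels: list             # sex labels, or ["all"]
    collared_mask: np.ndarray | None   # (n, T-1) float, adults x collared


def _build_design(history: EncounterHistory, p_model: str,
                  collared_effect: bool) -> _Design:
    y = np.ascontiguousarray(history.matrix, dtype=np.uint8)
    first = np.ascontiguousarray(history.first_detection, dtype=np.int64)
    n, T = y.shape
    if T < 2:
        raise ValueError("need at least 2 occasions")
    age = history.age_class
    sex = history.sex

    cell_of = {}
    cells: list = []
    phi_idx = np.zeros((n, T - 1), dtype=np.int64)
    for i in range(n):
        for t in range(first[i], T - 1):
            a = int(age[i, t])
            if a < 0:   # not yet born at midpoint; earliest detectable class
                a = 0
            key = (AGE_CLASSES[a], str(sex[i]))
            if key not in cell_of:
                cell_of[key] = len(cells)
                cells.append(key)
            phi_idx[i, t] = cell_of[key]

    if p_model == "sex":
        p_levels = [s for s in SEXES if (sex == s).any()]
        lev = {s: g for g, s in enumerate(p_levels)}
        p_group = np.array([lev[str(s)] for s in sex], dtype=np.int64)
    else:
        p_levels = ["all"]
        p_group = np.zeros(n, dtype=np.int64)

    mask = None
    if collared_effect:
        adult = np.zeros((n, T - 1), dtype=float)
        for i in range(n):
            for t in range(first[i], T - 1):
                if age[i, t] == 2 and history.collared[i, t]:
                    adult[i, t] = 1.0
        mask = adult
    return _Design(y=y, first=first, phi_idx=phi_idx, cells=cells,
                   p_group=p_group, p_levels=p_levels, collared_mask=mask)


@dataclass
class CjsFit:
    """Posterior draws and summaries of a CJS fit.

    ``draws`` maps parameter names (``phi[adult,F]``, ``mu_p``,
    ``sigma_p``, ``p[F]``, ``beta_collared``) to ``(n_chains, n_kept)``
    arrays on the natural scale.
    """

    draws: dict
    cells: list
    p_model: str
    rhat: dict
    ess: dict
    converged: bool
    accept_rates: np.ndarray
    mcmc: McmcConfig
    first_detect_age_months: float = FIRST_DETECTABLE_AGE_MONTHS

    def phi_draws(self, age_class: str, sex: str) -> np.ndarray:
        return self.draws[f"phi[{age_class},{sex}]"].ravel()

    def survival_table(self, cri: float = 0.95) -> pd.DataFrame:
        """2-month and annualized survival per cell (per-draw annualization)."""
        lo, hi = 100 * (1 - cri) / 2, 100 * (1 + cri) / 2
        rows = []
        for age_class, sex in self.cells:
            step = self.phi_draws(age_class, sex)
            ann = annualize(step, age_class, self.first_detect_age_months)
            rows.append({
                "age_class": age_class, "sex": sex,
                "phi_2mo_mean": step.mean(),
                "phi_2mo_lo": np.percentile(step, lo),
                "phi_2mo_hi": np.percentile(step, hi),
                "phi_annual_mean": ann.mean(),
                "phi_annual_lo": np.percentile(ann, lo),
                "phi_annual_hi": np.percentile(ann, hi),
            })
        return pd.DataFrame(rows).sort_values(["age_class", "sex"]).reset_index(drop=True)

    def detection_mean_draws(self, n_quad: int = 20) -> np.ndarray:
        """Per-draw population mean of the bi-monthly detection probability."""
        if self.p_model == "individual_re":
            mu = self.draws["mu_p"].ravel()
            sig = self.draws["sigma_p"].ravel()
            z, w = gauss_hermite_normal(n_quad)
            return invlogit(mu[:, None] + sig[:, None] * z[None, :]) @ w
        if self.p_model == "sex":
            return np.mean([v.ravel() for k, v in self.draws.items()
                            if k.startswith("p[")], axis=0)
        raise ValueError("fixed-p fit carries no detection posterior")

    def detection_summary(self) -> dict:
        d = self.detection_mean_draws()
        return {"p_mean": float(d.mean()),
                "p_lo": float(np.percentile(d, 2.5)),
                "p_hi": float(np.percentile(d, 97.5))}


class _CjsModel:
    """Parameter bookkeeping for the component-wise CJS sampler.

    The parameter vector is ``[t_phi (K logits), p-block, beta?]`` where
    the p-block is ``(mu_p, t_sigma)`` for the heterogeneity model, one
    logit per present sex for the sex model, and empty for fixed p.
    Collared-adult transitions get *twin* survival cells whose value is
    ``invlogit(logit(phi) + beta)``, so the likelihood kernel only ever
    sees a vector of survival probabilities indexed per transition.
    """

    def __init__(self, design: _Design, p_model: str, sigma_upper: float,
                 quad_nodes: int, collared_effect: bool,
                 p_fixed: float | None):
        self.design = design
        self.p_model = p_model
        self.sigma_upper = sigma_upper
        self.collared = collared_effect
        self.y, self.first = design.y, design.first
        n = self.y.shape[0]
        self.n = n
        self.K = len(design.cells)
        self.G = len(design.p_levels)

        phi_idx = design.phi_idx.copy()
        self.twin: dict[int, int] = {}
        E = self.K
        if collared_effect:
            mask = design.collared_mask.astype(bool)
            for k, (a, _s) in enumerate(design.cells):
                if a == "adult":
                    sel = mask & (design.phi_idx == k)
                    if sel.any():
                        self.twin[k] = E
                        phi_idx[sel] = E
                        E += 1
            if not self.twin:
                raise ValueError("no collared adult transitions in the data")
        self.E = E
        self.phi_idx = np.ascontiguousarray(phi_idx)

        active = np.zeros_like(phi_idx, dtype=bool)
        for i in range(n):
            active[i, self.first[i]:] = True
        self.rows_of_ext = [
            np.flatnonzero(((phi_idx == e) & active).any(axis=1)).astype(np.int64)
            for e in range(E)]
        self.rows_of_cell = []
        for k in range(self.K):
            rows = self.rows_of_ext[k]
            if k in self.twin:
                rows = np.union1d(rows, self.rows_of_ext[self.twin[k]])
            self.rows_of_cell.append(np.ascontiguousarray(rows))
        if collared_effect:
            self.rows_beta = np.ascontiguousarray(
                np.unique(np.concatenate(
                    [self.rows_of_ext[e] for e in self.twin.values()])))
        self.rows_all = np.arange(n, dtype=np.int64)
        self.rows_group = [np.flatnonzero(design.p_group == g).astype(np.int64)
                           for g in range(self.G)]

        if p_model == "individual_re":
            self.nodes, self.wts = gauss_hermite_normal(quad_nodes)
            self.n_p = 2
        else:
            self.nodes, self.wts = np.array([0.0]), np.array([1.0])
            self.n_p = self.G if p_model == "sex" else 0
        self.n_par = self.K + self.n_p + (1 if collared_effect else 0)
        self.p_fixed_logit = None
        if p_model == "fixed":
            self.p_fixed_logit = float(logit(np.clip(p_fixed, 1e-12, 1 - 1e-12)))

    # -- parameter-vector views ------------------------------------------
    def phi_values(self, theta: np.ndarray) -> np.ndarray:
        vals = np.empty(self.E)
        vals[:self.K] = invlogit(theta[:self.K])
        for k, e in self.twin.items():
            vals[e] = invlogit(theta[k] + theta[-1])
        return vals

    def p_arrays(self, theta: np.ndarray):
        if self.p_model == "individual_re":
            return np.full(self.n, theta[self.K]), self.sigma_upper * invlogit(theta[self.K + 1])
        if self.p_model == "sex":
            return theta[self.K:self.K + self.G][self.design.p_group], 0.0
        return np.full(self.n, self.p_fixed_logit), 0.0

    def log_prior(self, theta: np.ndarray) -> float:
        phi = invlogit(theta[:self.K])
        lp = float(np.sum(np.log(phi) + np.log1p(-phi)))
        if self.p_model == "individual_re":
            pbar = invlogit(theta[self.K])
            sig = self.sigma_upper * invlogit(theta[self.K + 1])
            lp += np.log(pbar) + np.log1p(-pbar)
            lp += np.log(sig) + np.log(self.sigma_upper - sig) - np.log(self.sigma_upper)
        elif self.p_model == "sex":
            ps = invlogit(theta[self.K:self.K + self.G])
            lp += float(np.sum(np.log(ps) + np.log1p(-ps)))
        if self.collared:
            lp += -0.5 * (theta[-1] / 2.5) ** 2   # weak Normal(0, 2.5)
        return lp

    def loglik_rows(self, phi_vals, p_base, sigma, rows) -> np.ndarray:
        out = np.empty(rows.size)
        cjs_loglik_rows(self.y, self.first, phi_vals, self.phi_idx,
                        p_base, sigma, self.nodes, self.wts, rows, out)
        return out

    def full_logpost(self, theta: np.ndarray) -> float:
        phi_vals = self.phi_values(theta)
        p_base, sigma = self.p_arrays(theta)
        ll = self.loglik_rows(phi_vals, p_base, sigma, self.rows_all).sum()
        return float(ll + self.log_prior(theta))

    def init_point(self, rng: np.random.Generator) -> np.ndarray:
        x = np.empty(self.n_par)
        x[:self.K] = rng.uniform(0.5, 2.5, self.K)
        pos = self.K
        if self.p_model == "individual_re":
            x[pos] = rng.uniform(-1.0, 1.0)
            x[pos + 1] = rng.uniform(-3.0, -1.0)
            pos += 2
        elif self.p_model == "sex":
            x[pos:pos + self.G] = rng.uniform(-1.0, 1.0, self.G)
            pos += self.G
        if self.collared:
            x[pos] = rng.normal(0.0, 0.3)
        return x


def _sample_cjs_chain(model: _CjsModel, x0: np.ndarray, scales: np.ndarray,
                      p_cov: np.ndarray | None, n_iter: int, n_burnin: int,
                      thin: int, rng: np.random.Generator):
    """One chain of component-wise (phi cells, beta) + blocked (p) Metropolis.

    Per-coordinate proposals re-evaluate only the individuals whose
    likelihood the coordinate touches; proposal scales adapt to a 0.44
    (coordinate) / 0.30 (p-block) acceptance target during burn-in, then
    freeze.
    """
    theta = x0.copy()
    K, n_par = model.K, model.n_par
    phi_vals = model.phi_values(theta)
    p_base, sigma = model.p_arrays(theta)
    logLi = np.full(model.n, np.nan)
    logLi[:] = model.loglik_rows(phi_vals, p_base, sigma, model.rows_all)
    if not np.isfinite(logLi.sum()):
        raise ValueError("non-finite likelihood at the starting point")

    s = scales.copy()                      # per-coordinate proposal sd
    log_sp = 0.0                           # p-block log scale multiplier
    has_p = model.n_p > 0
    if has_p:
        p_sl = slice(K, K + model.n_p)
        if p_cov is None:
            p_cov = np.eye(model.n_p) * 0.01
        p_chol = np.linalg.cholesky(p_cov + 1e-10 * np.eye(model.n_p))

    def cell_prior(k, tk):
        ph = 1.0 / (1.0 + np.exp(-tk))
        return np.log(ph) + np.log1p(-ph)

    n_kept = n_iter // thin
    draws = np.empty((n_kept, n_par))
    kept = 0
    total = n_burnin + n_iter
    for it in range(total):
        adapt = it < n_burnin
        g = min(0.2, (it + 1.0) ** -0.6) if adapt else 0.0

        # --- survival cells, one at a time
        for k in range(K):
            tk_new = theta[k] + s[k] * rng.standard_normal()
            rows = model.rows_of_cell[k]
            new_vals = phi_vals.copy()
            new_vals[k] = 1.0 / (1.0 + np.exp(-tk_new))
            if k in model.twin:
                new_vals[model.twin[k]] = 1.0 / (1.0 + np.exp(-(tk_new + theta[-1])))
            new_ll = model.loglik_rows(new_vals, p_base, sigma, rows)
            delta = (new_ll.sum() - logLi[rows].sum()
                     + cell_prior(k, tk_new) - cell_prior(k, theta[k]))
            acc = np.exp(min(0.0, delta)) if np.isfinite(delta) else 0.0
            if rng.random() < acc:
                theta[k] = tk_new
                phi_vals = new_vals
                logLi[rows] = new_ll
            if adapt:
                s[k] *= np.exp(g * (acc - 0.44))

        # --- collaring contrast beta
        if model.collared:
            b_new = theta[-1] + s[-1] * rng.standard_normal()
            rows = model.rows_beta
            new_vals = phi_vals.copy()
            for k, e in model.twin.items():
                new_vals[e] = 1.0 / (1.0 + np.exp(-(theta[k] + b_new)))
            new_ll = model.loglik_rows(new_vals, p_base, sigma, rows)
            delta = (new_ll.sum() - logLi[rows].sum()
                     - 0.5 * (b_new / 2.5) ** 2 + 0.5 * (theta[-1] / 2.5) ** 2)
            acc = np.exp(min(0.0, delta)) if np.isfinite(delta) else 0.0
            if rng.random() < acc:
                theta[-1] = b_new
                phi_vals = new_vals
                logLi[rows] = new_ll
            if adapt:
                s[-1] *= np.exp(g * (acc - 0.44))

        # --- detection block
        if has_p:
            if model.p_model == "sex":
                # each sex level touches only its own individuals
                for gix in range(model.G):
                    j = K + gix
                    v_new = theta[j] + s[j] * rng.standard_normal()
                    rows = model.rows_group[gix]
                    pb_new = p_base.copy()
                    pb_new[rows] = v_new
                    new_ll = model.loglik_rows(phi_vals, pb_new, sigma, rows)
                    pv_new, pv_old = invlogit(v_new), invlogit(theta[j])
                    delta = (new_ll.sum() - logLi[rows].sum()
                             + np.log(pv_new) + np.log1p(-pv_new)
                             - np.log(pv_old) - np.log1p(-pv_old))
                    acc = np.exp(min(0.0, delta)) if np.isfinite(delta) else 0.0
                    if rng.random() < acc:
                        theta[j] = v_new
                        p_base = pb_new
                        logLi[rows] = new_ll
                    if adapt:
                        s[j] *= np.exp(g * (acc - 0.44))
            else:
                blk_new = theta[p_sl] + np.exp(log_sp) * (
                    p_chol @ rng.standard_normal(model.n_p))
                th_new = theta.copy()
                th_new[p_sl] = blk_new
                pb_new, sig_new = model.p_arrays(th_new)
                new_ll = model.loglik_rows(phi_vals, pb_new, sig_new,
                                           model.rows_all)
                delta = (new_ll.sum() - logLi.sum()
                         + model.log_prior(th_new) - model.log_prior(theta))
                acc = np.exp(min(0.0, delta)) if np.isfinite(delta) else 0.0
                if rng.random() < acc:
                    theta = th_new
                    p_base, sigma = pb_new, sig_new
                    logLi = new_ll
                if adapt:
                    log_sp += g * (acc - 0.30)

        if it >= n_burnin and (it - n_burnin) % thin == 0 and kept < n_kept:
            draws[kept] = theta
            kept += 1
    return draws


def _run_cjs_chains(model: _CjsModel, mcmc: McmcConfig):
    from hyenademog._mcmc import laplace_init

    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains + 1)
    rng0 = np.random.default_rng(seeds[-1])
    try:
        xmap, cov = laplace_init(model.full_logpost, model.init_point(rng0))
        sd = np.sqrt(np.clip(np.diag(cov), 1e-6, None))
    except Exception:
        xmap, cov, sd = None, None, None

    chains = []
    for c in range(mcmc.n_chains):
        rng = np.random.default_rng(seeds[c])
        if xmap is not None:
            x0 = xmap + rng.standard_normal(model.n_par) * sd
            scales = 2.4 * sd
            p_cov = cov[model.K:model.K + model.n_p,
                        model.K:model.K + model.n_p] if model.n_p else None
            if not np.isfinite(model.full_logpost(x0)):
                x0 = xmap.copy()
        else:
            x0 = model.init_point(rng)
            scales = np.full(model.n_par, 0.2)
            p_cov = None
        chains.append(_sample_cjs_chain(model, x0, scales, p_cov,
                                        mcmc.n_iter, mcmc.n_burnin,
                                        mcmc.thin, rng))
    return np.stack(chains)


def fit_cjs(history: EncounterHistory, mcmc: McmcConfig | None = None,
            p_model: str = "individual_re", quad_nodes: int = 20,
            collared_phi_effect: bool = False,
            p_fixed: float | None = None) -> CjsFit:
    """Fit the CJS model by adaptive Metropolis MCMC.

    ``p_model`` selects the detection structure: ``"individual_re"``
    (logit-normal individual heterogeneity, the primary model), ``"sex"``
    (sex-level fixed effects, no individual effect) or ``"fixed"``
    (detection pinned at ``p_fixed``; used for known-fate checks).

    Raises a prominent warning (and sets ``converged=False``) when any
    monitored parameter has split R-hat above 1.1.
    """
    if p_model not in ("individual_re", "sex", "fixed"):
        raise ValueError(f"unknown p_model {p_model!r}")
    if p_model == "fixed" and p_fixed is None:
        raise ValueError("p_model='fixed' requires p_fixed")
    mcmc = mcmc or McmcConfig()
    design = _build_design(history, p_model, collared_phi_effect)
    model = _CjsModel(design, p_model, mcmc.sigma_upper, quad_nodes,
                      collared_phi_effect, p_fixed)
    draws_t = _run_cjs_chains(model, mcmc)
    rates = np.full(mcmc.n_chains, np.nan)   # per-coordinate scheme
    K = len(design.cells)
    out: dict = {}
    for k, (a, s) in enumerate(design.cells):
        out[f"phi[{a},{s}]"] = invlogit(draws_t[:, :, k])
    if p_model == "individual_re":
        out["mu_p"] = draws_t[:, :, K]
        out["sigma_p"] = mcmc.sigma_upper * invlogit(draws_t[:, :, K + 1])
    elif p_model == "sex":
        for g, s in enumerate(design.p_levels):
            out[f"p[{s}]"] = invlogit(draws_t[:, :, K + g])
    if collared_phi_effect:
        out["beta_collared"] = draws_t[:, :, -1]

    diag = diagnostics(out)
    rhat = dict(zip(diag.index, diag["rhat"]))
    ess = dict(zip(diag.index, diag["ess"]))
    converged = all(np.isnan(v) or v <= RHAT_THRESHOLD for v in rhat.values())
    if not converged:
        bad = {k: round(v, 3) for k, v in rhat.items() if v > RHAT_THRESHOLD}
        warnings.warn(f"CJS fit did not converge: R-hat > {RHAT_THRESHOLD} "
                      f"for {bad}; treat the posterior with caution",
                      stacklevel=2)
    return CjsFit(draws=out, cells=design.cells, p_model=p_model, rhat=rhat,
                  ess=ess, converged=converged, accept_rates=rates, mcmc=mcmc)


def annualize(phi_step, age_class: str,
              first_detect_age_months: float = FIRST_DETECTABLE_AGE_MONTHS):
    """Annual survival from the 2-month rate.

    Non-cub classes use exponent 6.  Cubs are first observable at a mean
    age of ``first_detect_age_months``, so their estimated rate applies to
    the remaining ``12 - first_detect_age_months`` months of the first
    year: exponent ``(12 - first_detect_age_months) / 2`` (4.795 at the
    2.41-month default).
    """
    phi_step = np.asarray(phi_step, dtype=float)
    if np.any(phi_step <= 0) or np.any(phi_step > 1):
        raise ValueError("phi_step must lie in (0, 1]")
    if age_class not in AGE_CLASSES:
        raise ValueError(f"unknown age class {age_class!r}")
    expo = (12.0 - first_detect_age_months) / 2.0 if age_class == "cub" else 6.0
    out = phi_step ** expo
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# verification analyses

@dataclass
class CubMortality:
    """Den-based approximate cub mortality, assuming p = 1 at dens.

    ``mortality`` is the ratio of never-resighted-after-age-1 cubs to
    resighted ones — the convention that treats the resighted count as the
    at-risk denominator.  ``mortality_eligible_denom`` divides by all
    eligible cubs instead; both are reported.
    """

    n_first_as_cub: int
    n_eligible: int
    n_never_after: int
    mortality: float
    mortality_eligible_denom: float


def cub_mortality_from_counts(n_first_as_cub: int, n_eligible: int,
                              n_never_after: int) -> CubMortality:
    if n_eligible <= 0:
        raise ValueError("no cubs could have reached age 1 before study end")
    resighted = n_eligible - n_never_after
    if resighted <= 0:
        raise ValueError("no eligible cub was ever resighted after age 1")
    return CubMortality(
        n_first_as_cub=int(n_first_as_cub),
        n_eligible=int(n_eligible),
        n_never_after=int(n_never_after),
        mortality=n_never_after / resighted,
        mortality_eligible_denom=n_never_after / n_eligible,
    )


def approximate_cub_mortality(history: EncounterHistory,
                              individuals: pd.DataFrame | None = None
                              ) -> CubMortality:
    """Manual cub-mortality check: cubs at communal dens are assumed always
    detected, so a cub never seen after its first birthday is counted dead.

    Counts individuals first detected in the cub class, restricts to those
    whose first birthday precedes the end of the study window, and counts
    how many of those were never detected in a later age class.
    """
    if history.birth_date is None and individuals is None:
        raise ValueError("birth dates required (history.birth_date or individuals)")
    births = history.birth_date
    if births is None:
        bmap = dict(zip(individuals["id"], pd.to_datetime(individuals["birth_date"])))
        births = np.array([_as_date(bmap[i]) for i in history.ids], dtype=object)

    first = history.first_detection
    age = history.age_class
    end = history.grid.end
    n_first = n_elig = n_never = 0
    for i in range(history.n_individuals):
        if age[i, first[i]] != 0:
            continue
        n_first += 1
        if _add_years(_as_date(births[i]), 1) >= end:
            continue
        n_elig += 1
        later = (history.matrix[i] == 1) & (age[i] >= 1)
        if not later.any():
            n_never += 1
    return cub_mortality_from_counts(n_first, n_elig, n_never)


@dataclass
class CollaringReport:
    """Posterior contrast of a collaring effect on adult survival (logit)."""

    beta_mean: float
    beta_lo: float
    beta_hi: float
    no_effect: bool       # 95% credible interval spans zero
    fit: CjsFit


def collaring_effect(history: EncounterHistory,
                     mcmc: McmcConfig | None = None, **fit_kwargs
                     ) -> CollaringReport:
    """Refit the CJS model with a binary collared effect on adult survival.

    "No effect" is declared when the 95% credible interval of the
    logit-scale contrast spans zero.
    """
    col = history.collared.any(axis=1)
    if not col.any():
        raise ValueError("no collared individuals: contrast undefined")
    if col.all():
        raise ValueError("all individuals collared: contrast undefined")
    fit = fit_cjs(history, mcmc=mcmc, collared_phi_effect=True, **fit_kwargs)
    b = fit.draws["beta_collared"].ravel()
    lo, hi = np.percentile(b, [2.5, 97.5])
    return CollaringReport(beta_mean=float(b.mean()), beta_lo=float(lo),
                           beta_hi=float(hi), no_effect=bool(lo < 0 < hi),
                           fit=fit)


def diagnostics(draws: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Rank-normalized split R-hat and bulk ESS per parameter.

    ``draws`` maps names to ``(n_chains, n_draws)`` arrays; at least two
    chains are required.
    """
    import arviz as az

    first = next(iter(draws.values()))
    if np.asarray(first).ndim != 2 or np.asarray(first).shape[0] < 2:
        raise ValueError("diagnostics need draws shaped (n_chains >= 2, n_draws)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset({k: np.asarray(v) for k, v in draws.items()})
        rhat = az.rhat(ds)
        ess = az.ess(ds)
    return pd.DataFrame({
        "rhat": {k: float(rhat[k].values) for k in draws},
        "ess": {k: float(ess[k].values) for k in draws},
    })
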