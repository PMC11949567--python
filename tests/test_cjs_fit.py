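"""CJS fitting: determinism, closed-form checks, verifications, diagnostics."""

import datetime

import numpy as np
import pandas as pd
import pytest

from hyenademog import SimConfig, build_cjs_history, simulate_population
from hyenademog.cjs import (
    McmcConfig, approximate_cub_mortality, collaring_effect,
    cub_mortality_from_counts, diagnostics, fit_cjs,
)
from hyenademog.encounters import EncounterHistory, build_occasion_grid

D = datetime.date


def _single_class_history(matrix, grid):
    """EncounterHistory of all-adult females (hand-built covariates)."""
    m = np.asarray(matrix, dtype=np.uint8)
    n, T = m.shape
    return EncounterHistory(
        matrix=m, first_detection=m.argmax(axis=1).astype(np.int64),
        age_class=np.full((n, T), 2, dtype=np.int8),
        sex=np.array(["F"] * n), collared=np.zeros((n, T), bool),
        ids=np.array([f"x{i}" for i in range(n)], dtype=object), grid=grid)


class TestFitContracts:
    def test_same_seed_reproduces_draws(self, quick_mcmc):
        rng = np.random.default_rng(1)
        n, T = 60, 8
        y = np.zeros((n, T), dtype=np.uint8)
        y[:, 0] = 1
        alive = np.ones(n, bool)
        for t in range(1, T):
            alive &= rng.random(n) < 0.95
            y[:, t] = alive & (rng.random(n) < 0.6)
        grid = build_occasion_grid(D(2015, 6, 1), D(2016, 10, 1), 2)
        h = _single_class_history(y, grid)
        f1 = fit_cjs(h, quick_mcmc)
        f2 = fit_cjs(h, quick_mcmc)
        for k in f1.draws:
            assert np.array_equal(f1.draws[k], f2.draws[k])

    def test_known_fate_matches_product_binomial(self):
        """With p pinned at 1 the CJS likelihood reduces to independent
        Bernoulli survival: the posterior mean of phi must match the
        conjugate Beta(s+1, f+1) closed form."""
        rng = np.random.default_rng(42)
        n, T = 120, 6
        phi_true = 0.85
        alive = np.ones(n, bool)
        y = np.zeros((n, T), dtype=np.uint8)
        y[:, 0] = 1
        surv = fail = 0
        for t in range(1, T):
            step = rng.random(n) < phi_true
            surv += int((alive & step).sum())
            fail += int((alive & ~step).sum())
            alive &= step
            y[:, t] = alive          # p = 1: detected iff alive
        grid = build_occasion_grid(D(2015, 6, 1), D(2016, 6, 1), 2)
        h = _single_class_history(y, grid)
        fit = fit_cjs(h, McmcConfig(n_chains=2, n_iter=1500, n_burnin=300,
                                    seed=3),
                      p_model="fixed", p_fixed=1.0 - 1e-9)
        post = fit.phi_draws("adult", "F")
        closed_form = (surv + 1) / (surv + fail + 2)
        assert abs(post.mean() - closed_form) < 0.01

    def test_credible_intervals_shrink_with_sample_size(self):
        phi = {(a, s): v for a, v in
               [("cub", 0.75), ("subadult", 0.99), ("adult", 0.86)]
               for s in ("F", "M")}
        widths = {}
        for n_clans, label in [(2, "small"), (8, "large")]:
            cfg = SimConfig(seed=17, n_clans=n_clans, n_core_clans=n_clans,
                            initial_clan_size=15, recruitment_rate=4.0,
                            phi_annual=phi, sex_assignment_mode="random",
                            study_start=D(2013, 6, 1),
                            study_end=D(2017, 6, 1))
            ind, sig, state = simulate_population(cfg)
            h = build_cjs_history(sig, ind, state.grid)
            fit = fit_cjs(h, McmcConfig(n_chains=2, n_iter=800, n_burnin=300,
                                        seed=5))
            tab = fit.survival_table()
            widths[label] = float((tab.phi_2mo_hi - tab.phi_2mo_lo).mean())
        assert widths["large"] < widths["small"]

    def test_fit_requires_multiple_occasions(self, quick_mcmc):
        grid = build_occasion_grid(D(2015, 6, 1), D(2015, 8, 1), 2)
        h = _single_class_history(np.ones((5, 1)), grid)
        with pytest.raises(ValueError):
            fit_cjs(h, quick_mcmc)


class TestCubMortality:
    def test_reported_counts_reproduce_printed_rate(self):
        r = cub_mortality_from_counts(309, 279, 53)
        assert round(100 * r.mortality, 1) == 23.5
        assert round(100 * r.mortality_eligible_denom, 1) == 19.0

    def test_degenerate_counts(self):
        assert cub_mortality_from_counts(10, 10, 0).mortality == 0.0
        assert cub_mortality_from_counts(10, 10, 5).mortality == 1.0
        with pytest.raises(ValueError):
            cub_mortality_from_counts(5, 0, 0)

    def test_history_counts_match_independent_recount(self, small_sim,
                                                      small_history):
        h = small_history
        r = approximate_cub_mortality(h)
        # independent pandas recount from the raw arrays
        rows = pd.DataFrame({
            "first_class": h.age_class[np.arange(h.n_individuals),
                                       h.first_detection],
            "seen_older": [(h.matrix[i] & (h.age_class[i] >= 1)).any()
                           for i in range(h.n_individuals)],
            "birth": list(h.birth_date),
        })
        cubs = rows[rows.first_class == 0]
        eligible = cubs[[b.replace(year=b.year + 1) < h.grid.end
                         for b in cubs.birth]]
        never = (~eligible.seen_older).sum()
        assert r.n_first_as_cub == len(cubs)
        assert r.n_eligible == len(eligible)
        assert r.n_never_after == never


class TestCollaringEffect:
    def test_null_effect_interval_spans_zero(self):
        cfg = SimConfig(seed=31, n_clans=6, n_core_clans=6,
                        initial_clan_size=18, recruitment_rate=4.0,
                        sex_assignment_mode="random",
                        study_start=D(2013, 6, 1), study_end=D(2017, 6, 1))
        ind, sig, state = simulate_population(cfg)
        h = build_cjs_history(sig, ind, state.grid)
        rep = collaring_effect(h, McmcConfig(n_chains=2, n_iter=800,
                                             n_burnin=300, seed=8))
        assert rep.no_effect
        assert rep.beta_lo < 0 < rep.beta_hi

    def test_planted_collaring_cost_detected(self):
        cfg = SimConfig(seed=33, n_clans=10, n_core_clans=10,
                        initial_clan_size=20, recruitment_rate=4.0,
                        collared_per_clan=4, collared_phi_multiplier=0.5,
                        sex_assignment_mode="random",
                        study_start=D(2012, 6, 1), study_end=D(2018, 6, 1))
        ind, sig, state = simulate_population(cfg)
        h = build_cjs_history(sig, ind, state.grid)
        rep = collaring_effect(h, McmcConfig(n_chains=2, n_iter=800,
                                             n_burnin=300, seed=9))
        assert rep.beta_hi < 0           # survival cost excluded from zero
        assert not rep.no_effect

    def test_degenerate_collaring_rejected(self, small_history):
        h = small_history
        none = EncounterHistory(
            matrix=h.matrix, first_detection=h.first_detection,
            age_class=h.age_class, sex=h.sex,
            collared=np.zeros_like(h.collared), ids=h.ids, grid=h.grid,
            birth_date=h.birth_date)
        with pytest.raises(ValueError, match="no collared"):
            collaring_effect(none)
        every = EncounterHistory(
            matrix=h.matrix, first_detection=h.first_detection,
            age_class=h.age_class, sex=h.sex,
            collared=np.ones_like(h.collared), ids=h.ids, grid=h.grid,
            birth_date=h.birth_date)
        with pytest.raises(ValueError, match="all individuals"):
            collaring_effect(every)


class TestDiagnostics:
    def test_iid_chains_pass(self):
        rng = np.random.default_rng(0)
        d = {"x": rng.standard_normal((4, 2000))}
        out = diagnostics(d)
        assert 1.0 <= out.loc["x", "rhat"] < 1.01
        assert out.loc["x", "ess"] > 1000

    def test_autocorrelated_duplicated_chains_flag_low_ess(self):
        rng = np.random.default_rng(1)
        n = 2000
        ar = np.empty(n)
        ar[0] = 0.0
        for t in range(1, n):
            ar[t] = 0.995 * ar[t - 1] + rng.standard_normal() * 0.1
        d = {"x": np.stack([ar, ar])}
        out = diagnostics(d)
        assert out.loc["x", "ess"] < 0.05 * 2 * n   # strongly dependent draws

    def test_divergent_chain_raises_rhat(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal((1, 1000))
        b = rng.standard_normal((1, 1000)) + 10.0
        out = diagnostics({"x": np.vstack([a, b])})
        assert out.loc["x", "rhat"] > 1.1

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            diagnostics({"x": np.zeros((1, 100))})
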