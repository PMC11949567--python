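"""Simulator contracts: determinism, demography, detection, space use."""

import datetime

import numpy as np
import pandas as pd
import pytest

from hyenademog import SimConfig, simulate_population
from hyenademog.synthetic_data import simulate_sighting_locations
from hyenademog._mcmc import invlogit

D = datetime.date


def _one_year_config(**kw):
    """100 individuals, one clan, no recruitment, 7 occasions (6 transitions
    = one year of survival steps)."""
    level = kw.pop("phi", 0.86)
    phi = {(a, s): level for a in ("cub", "subadult", "adult")
           for s in ("F", "M")}
    return SimConfig(
        n_clans=1, initial_clan_size=100, recruitment_rate=0.0,
        study_start=D(2010, 6, 1), study_end=D(2011, 8, 1),
        phi_annual=phi, mu_p=-8.0, extra_sightings_rate=0.0,
        known_death_prob=0.0, collared_per_clan=0, **kw)


class TestDeterminism:
    def test_same_seed_byte_identical_tables(self):
        cfg = SimConfig(seed=5, n_clans=3, initial_clan_size=8,
                        study_start=D(2015, 6, 1), study_end=D(2016, 6, 1))
        a = simulate_population(cfg)
        b = simulate_population(cfg)
        assert a[0].to_csv(index=False) == b[0].to_csv(index=False)
        assert a[1].to_csv(index=False) == b[1].to_csv(index=False)

    def test_different_seeds_differ(self):
        base = dict(n_clans=3, initial_clan_size=8,
                    study_start=D(2015, 6, 1), study_end=D(2016, 6, 1))
        a = simulate_population(SimConfig(seed=5, **base))
        b = simulate_population(SimConfig(seed=6, **base))
        assert a[1].to_csv(index=False) != b[1].to_csv(index=False)


class TestDemography:
    def test_annual_survivors_match_binomial_expectation(self):
        """100 individuals at phi=0.86/yr for one year: mean survivors over
        replicates within 3 of 86 (binomial expectation)."""
        survivors = []
        for rep in range(300):
            _, _, state = simulate_population(_one_year_config(seed=1000 + rep))
            # occasion 0 holds the initial 100; occasion 6 is one year later
            survivors.append(int(state.alive[:, 6].sum()))
        assert abs(np.mean(survivors) - 86.0) < 3.0

    def test_survival_one_no_recruitment_conserves_population(self):
        cfg = _one_year_config(seed=3, phi=1.0)
        _, _, state = simulate_population(cfg)
        assert state.alive.sum(axis=0).tolist() == [100] * 7

    def test_runaway_recruitment_rejected(self):
        cfg = SimConfig(seed=0, n_clans=2, initial_clan_size=5,
                        recruitment_rate=2000.0, max_population=300,
                        study_start=D(2014, 6, 1), study_end=D(2016, 6, 1))
        with pytest.raises(RuntimeError, match="runaway"):
            simulate_population(cfg)

    def test_no_sighting_outside_life(self):
        cfg = SimConfig(seed=9, n_clans=3, initial_clan_size=10,
                        recruitment_rate=6.0, known_death_prob=1.0,
                        study_start=D(2014, 6, 1), study_end=D(2017, 6, 1))
        individuals, sightings, state = simulate_population(cfg)
        truth = state.individuals.set_index("id")
        ts = pd.to_datetime(sightings["datetime"])
        for i, t in zip(sightings["id"], ts):
            born = pd.Timestamp(truth.loc[i, "birth_date"])
            assert t >= born
            died = truth.loc[i, "death_date"]
            if died is not None:
                assert t.date() < died
        # detected implies alive, occasion-wise
        assert not (state.detected & ~state.alive).any()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(sigma_p=-1.0).validate()
        with pytest.raises(ValueError):
            SimConfig(phi_annual={("adult", "F"): 1.5}).validate()
        with pytest.raises(ValueError):
            SimConfig(study_start=D(2015, 1, 1),
                      study_end=D(2014, 1, 1)).validate()
        with pytest.raises(ValueError):
            SimConfig(n_clans=5, n_core_clans=0).validate()


class TestDetection:
    def test_heterogeneity_overdisperses_detection_counts(self):
        base = dict(n_clans=2, initial_clan_size=150, recruitment_rate=0.0,
                    study_start=D(2014, 6, 1), study_end=D(2017, 6, 1),
                    phi_annual={(a, s): 1.0 for a in ("cub", "subadult", "adult")
                                for s in ("F", "M")},
                    mu_p=0.0, extra_sightings_rate=0.0, seed=21)
        _, _, s0 = simulate_population(SimConfig(sigma_p=0.0, **base))
        _, _, s1 = simulate_population(SimConfig(sigma_p=1.0, **base))
        v0 = s0.detected.sum(axis=1).var()
        v1 = s1.detected.sum(axis=1).var()
        assert v1 > v0

    def test_marginal_detection_frequency_matches_logit_normal_mean(self):
        mu, sig = 0.3023, 0.8
        cfg = SimConfig(n_clans=2, initial_clan_size=250, recruitment_rate=0.0,
                        study_start=D(2014, 6, 1), study_end=D(2017, 6, 1),
                        phi_annual={(a, s): 1.0
                                    for a in ("cub", "subadult", "adult")
                                    for s in ("F", "M")},
                        mu_p=mu, sigma_p=sig, max_initial_age_years=8.0,
                        extra_sightings_rate=0.0, seed=13)
        _, _, state = simulate_population(cfg)
        z = np.random.default_rng(0).standard_normal(200_000)
        expected = invlogit(mu + sig * z).mean()
        observed = state.detected.mean()
        assert abs(observed - expected) < 0.02

    def test_unsexed_individuals_are_the_rarely_seen(self):
        cfg = SimConfig(seed=2, n_clans=4, initial_clan_size=15,
                        study_start=D(2014, 6, 1), study_end=D(2018, 6, 1))
        individuals, sightings, state = simulate_population(cfg)
        counts = sightings.groupby("id").size()
        mean_u = counts[individuals.loc[individuals.sex == "U", "id"]].mean()
        mean_known = counts[individuals.loc[individuals.sex != "U", "id"]].mean()
        assert mean_u < mean_known


class TestLocations:
    def test_empirical_spread_matches_configured_sd(self):
        cfg = SimConfig(n_clans=1, initial_clan_size=300, recruitment_rate=0.0,
                        clan_centers=np.array([[0.0, 0.0]]),
                        phi_annual={(a, s): 1.0
                                    for a in ("cub", "subadult", "adult")
                                    for s in ("F", "M")},
                        range_sd_dry=2.0, mu_p=2.0, extra_sightings_rate=1.0,
                        study_start=D(2014, 6, 1), study_end=D(2016, 6, 1),
                        seed=4)
        _, sightings, _ = simulate_population(cfg)
        dry = sightings[pd.to_datetime(sightings["datetime"]).dt.month.isin(
            range(5, 12))]
        assert len(dry) > 3000
        assert abs(dry["x_km"].std() - 2.0) < 0.1
        assert abs(dry["y_km"].std() - 2.0) < 0.1

    def test_wet_season_restricted_to_core_clans(self):
        cfg = SimConfig(seed=8, n_clans=11, n_core_clans=6,
                        initial_clan_size=10,
                        study_start=D(2014, 6, 1), study_end=D(2016, 6, 1))
        _, sightings, _ = simulate_population(cfg)
        months = pd.to_datetime(sightings["datetime"]).dt.month
        wet = sightings[months.isin([12, 1, 2, 3, 4])]
        core = {f"clan{c:02d}" for c in range(6)}
        assert len(wet) > 0
        assert set(wet["clan"]).issubset(core)

    def test_null_contraction_leaves_spreads_indistinguishable(self):
        cfg = SimConfig(seed=6, n_clans=2, n_core_clans=2,
                        initial_clan_size=150, recruitment_rate=0.0,
                        phi_annual={(a, s): 1.0
                                    for a in ("cub", "subadult", "adult")
                                    for s in ("F", "M")},
                        range_sd_dry=2.0, range_sd_wet=2.0,
                        wet_range_contraction=1.0, mu_p=2.0,
                        study_start=D(2014, 6, 1), study_end=D(2016, 6, 1))
        _, sightings, _ = simulate_population(cfg)
        months = pd.to_datetime(sightings["datetime"]).dt.month
        wet = sightings[months.isin([12, 1, 2, 3, 4])]
        dry = sightings[~months.isin([12, 1, 2, 3, 4])]
        for col in ("x_km", "y_km"):
            ratio = wet[col].std() / dry[col].std()
            assert 0.9 < ratio < 1.1

    def test_standalone_location_call_requires_skeleton(self):
        from hyenademog.synthetic_data import TrueState
        state = TrueState(individuals=pd.DataFrame(), alive=np.empty((0, 0)),
                          detected=np.empty((0, 0)), grid=None,
                          config=SimConfig())
        with pytest.raises(ValueError, match="skeleton"):
            simulate_sighting_locations(state, SimConfig())
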