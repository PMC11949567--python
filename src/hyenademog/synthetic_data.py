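"""Agent-based simulator of a clan-structured hyena population.

The generator emulates the structure of a long-term individual-based
monitoring study: ~11 clans observed June 2010 - November 2019, staggered
entry of individuals, three age classes with class-specific annual
survival, bi-monthly detection with individual logit-normal heterogeneity,
a wet-season (December-April) contraction of the surveyed area to a core
set of clans, and a sex-assignment process in which rarely seen animals
tend to remain of unknown sex.

Demography runs on the same 2-month occasion grid the survival analysis
uses, so simulated truth is directly comparable to model output: the
per-step survival probability is the annual rate raised to the power 1/6.
All randomness flows from a single seed; identical configurations produce
byte-identical output tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping

import numpy as np
import pandas as pd

from hyenademog.encounters import (
    WET_MONTHS, OccasionGrid, build_occasion_grid, assign_age_class, _as_date,
)

#: mean age (months) at which a den-dwelling cub first becomes observable
FIRST_DETECTABLE_AGE_MONTHS = 2.41

_DAYS_PER_MONTH = 365.25 / 12.0


def _default_phi() -> dict:
    # class-specific annual apparent survival; values typical of a
    # prey-rich, low-competition system (high adult and subadult survival)
    return {
        ("cub", "F"): 0.76, ("cub", "M"): 0.75,
        ("subadult", "F"): 0.99, ("subadult", "M"): 0.99,
        ("adult", "F"): 0.86, ("adult", "M"): 0.86,
    }


def _default_centers(n: int) -> np.ndarray:
    # clans laid out on a loose grid, ~9 km spacing, core clans central
    k = int(np.ceil(np.sqrt(n)))
    pts = [(9.0 * (i % k), 9.0 * (i // k)) for i in range(n)]
    return np.asarray(pts, dtype=float)


@dataclass
class SimConfig:
    """Ground-truth parameters of the simulated population.

    ``phi_annual`` maps ``(age_class, sex)`` to annual apparent survival;
    ``mu_p``/``sigma_p`` give the logit-scale mean and between-individual
    sd of the per-2-month detection probability.  Sex is revealed with
    probability ``1 - exp(-sex_reveal_rate * detections)`` so that rarely
    seen individuals stay unsexed ("U"); ``sex_assignment_mode='random'``
    instead reveals sex independently with ``sex_reveal_prob`` (useful for
    null experiments).  ``wet_range_contraction`` shrinks the spatial
    spread of wet-season sightings, and only the first ``n_core_clans``
    clans are surveyed in fully-wet months.
    """

    n_clans: int = 11
    clan_centers: np.ndarray | None = None
    initial_clan_size: int = 18
    study_start: date = date(2010, 6, 1)
    study_end: date = date(2019, 12, 1)
    phi_annual: Mapping = field(default_factory=_default_phi)
    recruitment_rate: float = 5.5          # expected cubs / clan / year
    mu_p: float = 0.3023                   # logit(0.575)
    sigma_p: float = 0.8
    sex_reveal_rate: float = 0.12          # k in 1 - exp(-k * n_detections)
    sex_assignment_mode: str = "detections"  # or "random"
    sex_reveal_prob: float = 0.66
    range_sd_wet: float = 2.0              # km
    range_sd_dry: float = 3.0              # km
    wet_range_contraction: float = 1.0
    n_core_clans: int | None = 6   # None -> all clans surveyed year-round
    first_detectable_age_months: float = FIRST_DETECTABLE_AGE_MONTHS
    known_death_prob: float = 0.02
    collared_per_clan: int = 2
    collared_phi_multiplier: float = 1.0   # <1 plants a collaring survival cost
    extra_sightings_rate: float = 0.8      # extra sightings per detection ~ Poisson
    max_population: int = 50_000
    max_initial_age_years: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_clans < 1:
            raise ValueError("n_clans must be >= 1")
        if _as_date(self.study_end) <= _as_date(self.study_start):
            raise ValueError("study_end must be after study_start")
        if self.sigma_p < 0:
            raise ValueError("sigma_p must be >= 0")
        for key, v in dict(self.phi_annual).items():
            if not (0.0 < v <= 1.0):
                raise ValueError(f"phi_annual[{key}]={v} outside (0, 1]")
        for name in ("recruitment_rate", "range_sd_wet", "range_sd_dry",
                     "extra_sightings_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 < self.wet_range_contraction <= 1.0):
            raise ValueError("wet_range_contraction must be in (0, 1]")
        if not (0.0 < self.collared_phi_multiplier <= 1.0):
            raise ValueError("collared_phi_multiplier must be in (0, 1]")
        if not (0 <= self.known_death_prob <= 1 and 0 <= self.sex_reveal_prob <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_core_clans is not None and not (
                1 <= min(self.n_core_clans, self.n_clans)):
            raise ValueError("n_core_clans must be >= 1")
        if self.sex_assignment_mode not in ("detections", "random"):
            raise ValueError("sex_assignment_mode must be 'detections' or 'random'")

    def centers(self) -> np.ndarray:
        if self.clan_centers is not None:
            c = np.asarray(self.clan_centers, dtype=float)
            if c.shape != (self.n_clans, 2):
                raise ValueError("clan_centers must have shape (n_clans, 2)")
            return c
        return _default_centers(self.n_clans)


@dataclass
class TrueState:
    """Latent truth underlying one simulated dataset.

    ``alive[i, t]`` is True while individual ``i`` is alive during
    occasion ``t``; ``detected`` is the realized occasion-level detection
    matrix (detected implies alive).  ``individuals`` covers *all* born
    individuals, including never-detected ones absent from the public
    tables.
    """

    individuals: pd.DataFrame   # id, clan, sex_true, birth_date, death_date, epsilon, collared
    alive: np.ndarray           # (N, T) bool
    detected: np.ndarray        # (N, T) bool
    grid: OccasionGrid
    config: SimConfig
    sightings: pd.DataFrame | None = None   # skeleton: id, datetime, clan, season flags

    def truth_dict(self) -> dict:
        """Ground-truth parameters for recovery tests (JSON-serializable)."""
        return {
            "phi_annual": {f"{a}:{s}": float(v)
                           for (a, s), v in dict(self.config.phi_annual).items()},
            "phi_2mo": {f"{a}:{s}": float(v) ** (1.0 / 6.0)
                        for (a, s), v in dict(self.config.phi_annual).items()},
            "mu_p": float(self.config.mu_p),
            "sigma_p": float(self.config.sigma_p),
            "epsilon": {str(i): float(e)
                        for i, e in zip(self.individuals["id"],
                                        self.individuals["epsilon"])},
        }

    def save_truth(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.truth_dict(), fh, indent=1)


def _occ_months(grid: OccasionGrid, t: int) -> list[tuple[date, date]]:
    """(start, end) of each calendar month inside occasion t."""
    from hyenademog.encounters import _add_months
    out = []
    m0 = grid.edges[t]
    while m0 < grid.edges[t + 1]:
        m1 = _add_months(m0, 1)
        out.append((m0, m1))
        m0 = m1
    return out


def _is_wet_month(m: int) -> bool:
    return m in WET_MONTHS


def simulate_population(config: SimConfig):
    """Simulate the population and its detection record.

    Returns
    -------
    individuals_table : DataFrame
        One row per *known* (ever-detected) individual: ``id, clan, sex,
        birth_date, death_date, collared``.  ``sex`` is "U" when the
        assignment draw failed; ``death_date`` is null unless the death
        happened to be discovered (probability ``known_death_prob``).
    sightings_table : DataFrame
        ``id, datetime, x_km, y_km, clan`` — every sighting of a known
        individual, with planar-km coordinates.
    state : TrueState
        Full latent truth for recovery tests.

    Raises
    ------
    RuntimeError
        If the population exceeds ``config.max_population`` (runaway
        recruitment).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    grid = build_occasion_grid(config.study_start, config.study_end, 2)
    T = grid.n_occasions
    phi = {k: float(v) for k, v in dict(config.phi_annual).items()}
    phi_step = {k: v ** (1.0 / 6.0) for k, v in phi.items()}
    centers = config.centers()

    # --- per-individual attribute lists, grown as individuals are born
    clan: list[int] = []
    sex_true: list[str] = []
    birth: list[date] = []
    eps: list[float] = []
    death_occ: list[int] = []   # first occasion the individual is dead; T if never
    collared: list[bool] = []

    def _new(n: int, c: int, births: list[date], col_flags=None):
        for j in range(n):
            clan.append(c)
            sex_true.append("F" if rng.random() < 0.5 else "M")
            birth.append(births[j])
            eps.append(float(rng.normal(0.0, config.sigma_p)))
            death_occ.append(T)
            collared.append(bool(col_flags[j]) if col_flags is not None else False)

    start = grid.start
    for c in range(config.n_clans):
        ages_d = rng.uniform(0.0, config.max_initial_age_years * 365.25,
                             size=config.initial_clan_size)
        births0 = [start - timedelta(days=float(a)) for a in ages_d]
        _new(config.initial_clan_size, c, births0)
    # collar a few adult females per clan (the focal-animal monitoring design)
    for c in range(config.n_clans):
        cand = [i for i in range(len(clan))
                if clan[i] == c and sex_true[i] == "F"
                and assign_age_class(birth[i], start) == "adult"]
        for i in cand[: config.collared_per_clan]:
            collared[i] = True

    alive_now = np.ones(len(clan), dtype=bool)
    occ_edges = grid.edges
    n_core = config.n_clans if config.n_core_clans is None \
        else min(config.n_core_clans, config.n_clans)
    core = set(range(n_core))

    alive_hist: list[np.ndarray] = []
    det_hist: list[np.ndarray] = []

    sight_id: list[int] = []
    sight_time: list[pd.Timestamp] = []
    sight_clan: list[int] = []
    sight_wet: list[bool] = []

    for t in range(T):
        # --- births during occasion t (none at t=0: initial cohort stands in)
        if t > 0 and config.recruitment_rate > 0:
            occ_days = (occ_edges[t + 1] - occ_edges[t]).days
            lam = config.recruitment_rate * occ_days / 365.25
            for c in range(config.n_clans):
                nb = int(rng.poisson(lam))
                if nb:
                    bdays = [occ_edges[t] + timedelta(days=float(d))
                             for d in rng.uniform(0, occ_days, size=nb)]
                    _new(nb, c, bdays)
                    alive_now = np.concatenate([alive_now, np.ones(nb, bool)])
        n = len(clan)
        if n > config.max_population:
            raise RuntimeError(
                f"population exploded to {n} > max_population="
                f"{config.max_population}: runaway recruitment")

        born_by_t = np.array([birth[i] < occ_edges[t + 1] for i in range(n)])
        alive_t = alive_now.copy() & born_by_t
        alive_hist.append(alive_t)

        # --- detection within occasion t
        det_t = np.zeros(n, dtype=bool)
        months = _occ_months(grid, t)
        for i in np.flatnonzero(alive_t):
            # allowed months: core clans any month; others dry months only
            if clan[i] in core:
                allowed = months
            else:
                allowed = [mm for mm in months if not _is_wet_month(mm[0].month)]
            if not allowed:
                continue
            detectable_from = birth[i] + timedelta(
                days=config.first_detectable_age_months * _DAYS_PER_MONTH)
            windows = [(max(a, detectable_from), b) for a, b in allowed
                       if b > detectable_from]
            if not windows:
                continue
            p_i = 1.0 / (1.0 + np.exp(-(config.mu_p + eps[i])))
            if rng.random() < p_i:
                det_t[i] = True
                n_s = 1 + int(rng.poisson(config.extra_sightings_rate))
                spans = np.array([(b - a).days or 1 for a, b in windows], float)
                pick = rng.choice(len(windows), size=n_s, p=spans / spans.sum())
                for w in pick:
                    a, b = windows[w]
                    dt = rng.uniform(0.0, max((b - a).days, 1e-6))
                    ts = pd.Timestamp(a) + pd.Timedelta(days=float(dt))
                    sight_id.append(i)
                    sight_time.append(ts)
                    sight_clan.append(clan[i])
                    sight_wet.append(_is_wet_month(ts.month))
        det_hist.append(det_t)

        # --- survival to occasion t+1, by age class and sex; the class is
        # evaluated at the occasion midpoint, matching the survival model
        if t < T - 1:
            mid = grid.midpoint(t)
            for i in np.flatnonzero(alive_t):
                ac = assign_age_class(birth[i], max(mid, birth[i]))
                step = phi_step[(ac, sex_true[i])]
                if collared[i] and config.collared_phi_multiplier != 1.0:
                    step = (phi[(ac, sex_true[i])]
                            * config.collared_phi_multiplier) ** (1.0 / 6.0)
                if rng.random() > step:
                    alive_now[i] = False
                    death_occ[i] = t + 1

    n = len(clan)
    alive = np.zeros((n, T), dtype=bool)
    detected = np.zeros((n, T), dtype=bool)
    for t in range(T):
        alive[: len(alive_hist[t]), t] = alive_hist[t]
        detected[: len(det_hist[t]), t] = det_hist[t]

    death_dates = []
    for i in range(n):
        if death_occ[i] >= T:
            death_dates.append(None)
        else:
            death_dates.append(occ_edges[death_occ[i]])

    ids = np.array([f"H{i:04d}" for i in range(n)], dtype=object)
    truth = pd.DataFrame({
        "id": ids, "clan": [f"clan{c:02d}" for c in clan],
        "sex_true": sex_true, "birth_date": birth,
        "death_date": death_dates, "epsilon": eps, "collared": collared,
    })
    state = TrueState(individuals=truth, alive=alive, detected=detected,
                      grid=grid, config=config)

    det_counts = detected.sum(axis=1)
    known = det_counts > 0

    # --- sex assignment: more detections -> more chances to be sexed
    if config.sex_assignment_mode == "detections":
        p_reveal = 1.0 - np.exp(-config.sex_reveal_rate * det_counts)
    else:
        p_reveal = np.full(n, config.sex_reveal_prob)
    revealed = rng.random(n) < p_reveal
    sex_obs = np.where(revealed, truth["sex_true"], "U")

    # --- known deaths: a death is only discovered occasionally
    died = np.array([d is not None for d in death_dates])
    discovered = died & known & (rng.random(n) < config.known_death_prob)
    death_obs = [death_dates[i] if discovered[i] else None for i in range(n)]

    individuals_table = pd.DataFrame({
        "id": ids, "clan": truth["clan"], "sex": sex_obs,
        "birth_date": [b.isoformat() for b in birth],
        "death_date": [d.isoformat() if d else None for d in death_obs],
        "collared": collared,
    })[known].reset_index(drop=True)

    sightings_table = pd.DataFrame({
        "id": ids[np.array(sight_id, dtype=int)] if sight_id else np.array([], dtype=object),
        "datetime": sight_time,
        "clan": [f"clan{c:02d}" for c in sight_clan],
        "_wet": sight_wet,
        "_clan_idx": np.array(sight_clan, dtype=int) if sight_clan else np.array([], int),
    })
    state.sightings = sightings_table
    sightings_table = simulate_sighting_locations(state, config, rng=rng)
    return individuals_table, sightings_table, state


def simulate_sighting_locations(state: TrueState, config: SimConfig,
                                rng: np.random.Generator | None = None
                                ) -> pd.DataFrame:
    """Attach planar-km coordinates to the sighting skeleton in ``state``.

    Coordinates are bivariate-normal around the clan center with a
    season-specific spread: ``range_sd_dry`` in dry months and
    ``range_sd_wet * wet_range_contraction`` in wet months.
    """
    if state.sightings is None:
        raise ValueError("state carries no sighting skeleton; run simulate_population")
    if rng is None:
        rng = np.random.default_rng(config.seed + 104729)
    s = state.sightings
    centers = config.centers()
    n = len(s)
    if n == 0:
        return pd.DataFrame(columns=["id", "datetime", "x_km", "y_km", "clan"])
    wet = s["_wet"].to_numpy(bool)
    sd = np.where(wet, config.range_sd_wet * config.wet_range_contraction,
                  config.range_sd_dry)
    cxy = centers[s["_clan_idx"].to_numpy(int)]
    xy = cxy + rng.normal(0.0, 1.0, size=(n, 2)) * sd[:, None]
    out = pd.DataFrame({
        "id": s["id"].to_numpy(),
        "datetime": [ts.isoformat() for ts in s["datetime"]],
        "x_km": np.round(xy[:, 0], 5),
        "y_km": np.round(xy[:, 1], 5),
        "clan": s["clan"].to_numpy(),
    })
    return out.sort_values(["datetime", "id"], kind="stable").reset_index(drop=True)
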