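"""Occasion grids, season labels, age classes and encounter histories.

Sighting records are binned onto a calendar grid of equal-width occasions
(2 months for the open-population survival analysis) or onto monthly bins
within each wet/dry season (for the closed-population abundance models).
All bins are half-open calendar intervals ``[start, end)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from datetime import date, datetime

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AGE_CLASSES = ("cub", "subadult", "adult")
CUB, SUBADULT, ADULT = 0, 1, 2
SEXES = ("F", "M", "U")

#: months belonging to the wet season, in within-season order (Dec..Apr)
WET_MONTHS = (12, 1, 2, 3, 4)
#: months belonging to the dry season (May..Nov)
DRY_MONTHS = (5, 6, 7, 8, 9, 10, 11)


def _add_months(d: date, months: int) -> date:
    """Add calendar months to a date, clamping the day-of-month."""
    m = d.month - 1 + months
    y = d.year + m // 12
    m = m % 12 + 1
    # clamp day (only matters for day > 28)
    last = [31, 29 if (y % 4 == 0 and (y % 100 != 0 or y % 400 == 0)) else 28,
            31, 30, 31, 30, 31, 31, 30, 31, 30, 31][m - 1]
    return date(y, m, min(d.day, last))


def _add_years(d: date, years: int) -> date:
    return _add_months(d, 12 * years)


def _as_date(x) -> date:
    if isinstance(x, datetime):
        return x.date()
    if isinstance(x, date):
        return x
    return pd.Timestamp(x).date()


@dataclass(frozen=True)
class OccasionGrid:
    """Contiguous half-open calendar occasions of equal month width.

    Attributes
    ----------
    start : date
        First day of the first occasion.
    width_months : int
        Width of every occasion, in calendar months.
    n_occasions : int
        Number of occasions.
    edges : tuple of date
        ``n_occasions + 1`` bin edges; occasion ``t`` is
        ``[edges[t], edges[t + 1])``.
    """

    start: date
    width_months: int
    n_occasions: int
    edges: tuple = field(repr=False, default=())

    @property
    def end(self) -> date:
        return self.edges[-1]

    def midpoint(self, t: int) -> date:
        """Calendar midpoint of occasion ``t`` (used for age evaluation)."""
        a, b = self.edges[t], self.edges[t + 1]
        return a + (b - a) / 2

    @property
    def midpoints(self) -> list:
        return [self.midpoint(t) for t in range(self.n_occasions)]

    def index_of(self, d) -> int:
        """Occasion index containing date ``d``; -1 if outside the grid."""
        d = _as_date(d)
        if d < self.start or d >= self.end:
            return -1
        months = (d.year - self.start.year) * 12 + (d.month - self.start.month)
        return months // self.width_months


def build_occasion_grid(start, end, width_months: int = 2) -> OccasionGrid:
    """Build a grid of contiguous ``width_months``-wide occasions on [start, end).

    Raises
    ------
    ValueError
        If the span is not a whole number of occasions; the message names
        the remainder in months.
    """
    start, end = _as_date(start), _as_date(end)
    if end <= start:
        raise ValueError(f"end ({end}) must be after start ({start})")
    if width_months < 1:
        raise ValueError("width_months must be >= 1")
    months = (end.year - start.year) * 12 + (end.month - start.month)
    if end.day != start.day or months <= 0:
        raise ValueError(
            f"span [{start}, {end}) is not a whole number of months "
            f"(day-of-month must match)"
        )
    rem = months % width_months
    if rem:
        raise ValueError(
            f"span of {months} months is not divisible by width "
            f"{width_months}: remainder of {rem} month(s)"
        )
    n = months // width_months
    edges = tuple(_add_months(start, width_months * t) for t in range(n + 1))
    return OccasionGrid(start=start, width_months=width_months,
                        n_occasions=n, edges=edges)


def season_of(d) -> tuple[str, int]:
    """Return ``(season, season_year)`` for a date.

    May-November is the dry season of the calendar year; December-April is
    the wet season, with December attached to the *following* year's label
    (wet-2011 spans December 2010 to April 2011).
    """
    d = _as_date(d)
    if 5 <= d.month <= 11:
        return ("dry", d.year)
    if d.month == 12:
        return ("wet", d.year + 1)
    return ("wet", d.year)


def assign_age_class(birth_date, at) -> str:
    """Age class at date ``at``: cub (<1 y), subadult (1-3 y), adult (>=3 y).

    Boundaries are assigned upward: exactly 1 year old is a subadult and
    exactly 3 years old is an adult.
    """
    birth_date, at = _as_date(birth_date), _as_date(at)
    if at < birth_date:
        raise ValueError(f"evaluation date {at} precedes birth date {birth_date}")
    if at < _add_years(birth_date, 1):
        return "cub"
    if at < _add_years(birth_date, 3):
        return "subadult"
    return "adult"


def _age_code(birth_date: date, at: date) -> int:
    return AGE_CLASSES.index(assign_age_class(birth_date, at))


@dataclass
class EncounterHistory:
    """Individuals x occasions binary detection matrix with covariates.

    ``matrix[i, t] = 1`` iff individual ``i`` was sighted at least once in
    occasion ``t``.  ``age_class[i, t]`` is the age-class code (0 cub,
    1 subadult, 2 adult) at the occasion midpoint, or -1 before birth.
    """

    matrix: np.ndarray          # (n, T) uint8
    first_detection: np.ndarray  # (n,) int64
    age_class: np.ndarray       # (n, T) int8
    sex: np.ndarray             # (n,) unicode, in {F, M, U}
    collared: np.ndarray        # (n, T) bool
    ids: np.ndarray             # (n,) object/unicode
    grid: OccasionGrid
    birth_date: np.ndarray | None = None  # (n,) object of date
    n_dropped_deaths: int = 0
    n_dropped_sightings: int = 0

    @property
    def n_individuals(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.matrix.shape[1]


def build_cjs_history(sightings: pd.DataFrame, individuals: pd.DataFrame,
                      grid: OccasionGrid) -> EncounterHistory:
    """Bin sightings into the occasion grid, one row per surviving individual.

    Individuals with a recorded (known) death are excluded — the open model
    used downstream conditions on resightings only, and mixing in recovered
    deaths would require a joint recovery/recapture likelihood.  Sightings
    outside the grid span are dropped with a warning.  Repeat detections
    within one occasion collapse to a single 1.

    Parameters
    ----------
    sightings : DataFrame with columns ``id`` and ``datetime``.
    individuals : DataFrame with columns ``id``, ``sex``, ``birth_date``
        and optionally ``death_date`` and ``collared``.
    """
    ind = individuals.copy()
    known_dead = ind["death_date"].notna() if "death_date" in ind else pd.Series(False, index=ind.index)
    n_dropped_deaths = int(known_dead.sum())
    ind = ind.loc[~known_dead]
    logger.info("excluded %d known deaths: %d -> %d individuals",
                n_dropped_deaths, len(individuals), len(ind))

    unknown = set(sightings["id"]) - set(individuals["id"])
    if unknown:
        raise ValueError(f"sightings reference unknown individuals: {sorted(unknown)[:5]}")

    occ = sightings["datetime"].map(grid.index_of).to_numpy()
    outside = occ < 0
    n_dropped_sightings = int(outside.sum())
    if n_dropped_sightings:
        warnings.warn(
            f"dropped {n_dropped_sightings} sighting(s) outside the occasion grid "
            f"[{grid.start}, {grid.end})", stacklevel=2)
    s = sightings.loc[~outside].copy()
    s["occ"] = occ[~outside]
    s = s[s["id"].isin(set(ind["id"]))]

    detected_ids = pd.unique(s["id"])
    ind = ind.set_index("id").loc[detected_ids]
    n = len(detected_ids)
    T = grid.n_occasions
    idx = {i: k for k, i in enumerate(detected_ids)}

    matrix = np.zeros((n, T), dtype=np.uint8)
    matrix[[idx[i] for i in s["id"]], s["occ"].to_numpy()] = 1
    first = matrix.argmax(axis=1).astype(np.int64)

    births = [_as_date(b) for b in ind["birth_date"]]
    mids = grid.midpoints
    age = np.full((n, T), -1, dtype=np.int8)
    for k, b in enumerate(births):
        for t, m in enumerate(mids):
            if m >= b:
                age[k, t] = _age_code(b, m)

    if "collared" in ind:
        col = ind["collared"].fillna(False).astype(bool).to_numpy()
    else:
        col = np.zeros(n, dtype=bool)
    collared = np.repeat(col[:, None], T, axis=1)

    return EncounterHistory(
        matrix=matrix, first_detection=first, age_class=age,
        sex=ind["sex"].astype(str).to_numpy(), collared=collared,
        ids=np.asarray(detected_ids, dtype=object), grid=grid,
        birth_date=np.asarray(births, dtype=object),
        n_dropped_deaths=n_dropped_deaths,
        n_dropped_sightings=n_dropped_sightings,
    )


@dataclass
class SeasonWindow:
    """One season's monthly closed-capture data.

    The matrix holds only individuals detected at least once in the window
    (the closed models condition the augmented likelihood on the observed
    rows); the coordinates of *all* member sightings in the window are
    retained for the kernel utilization distribution.
    """

    season: str                 # "wet" | "dry"
    year: int
    ids: np.ndarray             # (n,) member individual ids
    matrix: np.ndarray          # (n, 5 or 7) uint8 monthly detections
    x: np.ndarray               # coordinates (km) of member sightings
    y: np.ndarray
    months: tuple               # within-season month order

    @property
    def n_occasions(self) -> int:
        return self.matrix.shape[1]


def build_seasonal_histories(sightings: pd.DataFrame,
                             individuals: pd.DataFrame | None = None
                             ) -> list[SeasonWindow]:
    """Group sightings into wet (Dec-Apr, 5 bins) / dry (May-Nov, 7 bins) windows.

    Returns one :class:`SeasonWindow` per (season, year) with at least one
    sighting, sorted chronologically.  Seasons with no sightings are simply
    omitted (logged).
    """
    s = sightings.copy()
    ts = pd.to_datetime(s["datetime"])
    sy = [season_of(t) for t in ts]
    s["season"] = [a for a, _ in sy]
    s["season_year"] = [b for _, b in sy]
    s["month"] = ts.dt.month

    windows = []
    for (season, year), g in s.groupby(["season", "season_year"]):
        months = WET_MONTHS if season == "wet" else DRY_MONTHS
        col = {m: j for j, m in enumerate(months)}
        ids = pd.unique(g["id"])
        idx = {i: k for k, i in enumerate(ids)}
        mat = np.zeros((len(ids), len(months)), dtype=np.uint8)
        mat[[idx[i] for i in g["id"]], [col[m] for m in g["month"]]] = 1
        x = g["x_km"].to_numpy(float) if "x_km" in g else np.array([])
        y = g["y_km"].to_numpy(float) if "y_km" in g else np.array([])
        windows.append(SeasonWindow(season=season, year=int(year),
                                    ids=np.asarray(ids, dtype=object),
                                    matrix=mat, x=x, y=y, months=months))
    # chronological order: a year's wet season (Dec prev - Apr) precedes its dry
    windows.sort(key=lambda w: (w.year, 0 if w.season == "wet" else 1))
    logger.info("built %d seasonal windows", len(windows))
    return windows
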