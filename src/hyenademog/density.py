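"""Kernel utilization distributions, isopleth areas, and density.

The seasonal study area is the 90th-percentile isopleth of a bivariate
Gaussian kernel utilization distribution (KUD) fit to all sighting
locations of the individuals in that season's abundance estimate.
Coordinates are planar kilometres throughout; the module is
projection-agnostic.  Density is abundance divided by area, computed per
posterior draw so the credible interval propagates exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy.ndimage import gaussian_filter

#: minimum number of points for a KUD fit
MIN_POINTS = 5


@dataclass
class KudSurface:
    """Utilization density on a regular planar grid (km).

    ``density[iy, ix]`` integrates to 1 over the grid (cell mass =
    density x cell_area).  ``coverage`` is the fraction of the kernel mass
    the grid captured before renormalization; isopleth levels above it are
    unreachable (truncation).
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    density: np.ndarray        # (ny, nx)
    bandwidth: float           # km
    n_points: int
    coverage: float

    @property
    def cell_area(self) -> float:
        return float((self.x_edges[1] - self.x_edges[0])
                     * (self.y_edges[1] - self.y_edges[0]))


def reference_bandwidth(points: np.ndarray) -> float:
    """Ad-hoc (reference) bandwidth of the bivariate normal kernel tradition:
    ``h = sqrt((var_x + var_y) / 2) * n^(-1/6)``.
    """
    pts = np.asarray(points, dtype=float)
    s2 = 0.5 * (pts[:, 0].var(ddof=1) + pts[:, 1].var(ddof=1))
    if s2 <= 0:
        raise ValueError("zero spatial variance: reference bandwidth undefined "
                         "(all points identical); pass a numeric bandwidth")
    return float(np.sqrt(s2) * len(pts) ** (-1.0 / 6.0))


def fit_kud(points, bandwidth="reference", grid_size: int = 400,
            pad_bandwidths: float = 4.0) -> KudSurface:
    """Bivariate Gaussian KUD on a regular grid.

    Points are binned onto the grid and convolved with an isotropic
    Gaussian of sd ``bandwidth`` (exact for cell sizes well below the
    bandwidth; the refinement invariance of downstream isopleth areas is
    the practical check).  The grid pads the point bounding box by
    ``pad_bandwidths * h`` so that essentially all kernel mass is captured.

    Parameters
    ----------
    points : (n, 2) array of planar km coordinates, n >= 5.
    bandwidth : positive float (km) or ``"reference"``.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) < MIN_POINTS:
        raise ValueError(f"need at least {MIN_POINTS} points, got {len(pts)}")
    if not np.isfinite(pts).all():
        raise ValueError("points contain non-finite coordinates")
    h = reference_bandwidth(pts) if isinstance(bandwidth, str) else float(bandwidth)
    if h <= 0:
        raise ValueError("bandwidth must be positive")

    pad = pad_bandwidths * h
    x0, x1 = pts[:, 0].min() - pad, pts[:, 0].max() + pad
    y0, y1 = pts[:, 1].min() - pad, pts[:, 1].max() + pad
    x_edges = np.linspace(x0, x1, grid_size + 1)
    y_edges = np.linspace(y0, y1, grid_size + 1)
    counts, _, _ = np.histogram2d(pts[:, 1], pts[:, 0],
                                  bins=[y_edges, x_edges])
    dy = y_edges[1] - y_edges[0]
    dx = x_edges[1] - x_edges[0]
    smoothed = gaussian_filter(counts, sigma=(h / dy, h / dx),
                               mode="constant", truncate=6.0)
    total = smoothed.sum()
    coverage = float(total / len(pts))
    dens = smoothed / (total * dx * dy)
    return KudSurface(x_edges=x_edges, y_edges=y_edges, density=dens,
                      bandwidth=h, n_points=len(pts), coverage=coverage)


def isopleth_area(surface: KudSurface, level: float = 0.90) -> float:
    """Area (km^2) of the smallest cell set holding ``level`` of the mass.

    Cells are ranked by density and accumulated until the requested
    utilization mass is reached; the area is cell count x cell area.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    if surface.coverage < level:
        raise ValueError(
            f"grid captures only {surface.coverage:.4f} of the kernel mass, "
            f"below the requested level {level}; refit with larger padding")
    mass = np.sort(surface.density.ravel())[::-1] * surface.cell_area
    cum = np.cumsum(mass)
    n_cells = int(np.searchsorted(cum, level)) + 1
    return n_cells * surface.cell_area


def isopleth_threshold(surface: KudSurface, level: float = 0.90) -> float:
    """Density value delimiting the ``level`` isopleth (for contouring)."""
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    dens = np.sort(surface.density.ravel())[::-1]
    cum = np.cumsum(dens) * surface.cell_area
    return float(dens[min(int(np.searchsorted(cum, level)), dens.size - 1)])


def isopleth_geojson(surface: KudSurface, level: float = 0.90) -> dict:
    """Isopleth boundary as a GeoJSON MultiPolygon (planar km coordinates)."""
    from skimage import measure

    thr = isopleth_threshold(surface, level)
    dx = surface.x_edges[1] - surface.x_edges[0]
    dy = surface.y_edges[1] - surface.y_edges[0]
    polys = []
    for contour in measure.find_contours(surface.density, thr):
        xs = surface.x_edges[0] + (contour[:, 1] + 0.5) * dx
        ys = surface.y_edges[0] + (contour[:, 0] + 0.5) * dy
        ring = [[float(x), float(y)] for x, y in zip(xs, ys)]
        if len(ring) >= 4:
            polys.append([ring])
    return {"type": "MultiPolygon", "coordinates": polys,
            "properties": {"level": level, "bandwidth_km": surface.bandwidth}}


@dataclass
class DensityEstimate:
    """Seasonal density: posterior N divided by the season's area."""

    season: str
    year: int
    n_median: float
    n_lo: float
    n_hi: float
    area_km2: float
    d_median: float
    d_lo: float
    d_hi: float
    area_source: str = "estimated"    # or "imputed_mean_wet"

    def as_dict(self) -> dict:
        return {
            "season": self.season, "year": self.year,
            "N_median": self.n_median, "N_lo": self.n_lo, "N_hi": self.n_hi,
            "area_km2": self.area_km2,
            "D_median": self.d_median, "D_lo": self.d_lo, "D_hi": self.d_hi,
            "area_source": self.area_source,
        }


def density(fit, area_km2: float, meta: Mapping | None = None,
            area_source: str = "estimated") -> DensityEstimate:
    """Convert abundance to density by per-draw division.

    ``fit`` is a :class:`~hyenademog.closed.ClosedFit` or a 1-D array of
    posterior N draws.  Summaries (median and 95% credible interval) are
    computed on the D = N / A draws; rounding happens only at reporting.
    """
    if area_km2 <= 0:
        raise ValueError("area must be positive")
    N = fit.n_draws_flat() if hasattr(fit, "n_draws_flat") else \
        np.asarray(fit, dtype=float).ravel()
    D = N / area_km2
    meta = meta or {}
    return DensityEstimate(
        season=str(meta.get("season", "")), year=int(meta.get("year", 0)),
        n_median=float(np.median(N)),
        n_lo=float(np.percentile(N, 2.5)), n_hi=float(np.percentile(N, 97.5)),
        area_km2=float(area_km2),
        d_median=float(np.median(D)),
        d_lo=float(np.percentile(D, 2.5)), d_hi=float(np.percentile(D, 97.5)),
        area_source=area_source,
    )


def impute_wet_area(areas: Mapping[int, float],
                    reference_years: Iterable[int] = range(2013, 2020)) -> float:
    """Mean wet-season area over the reference years (default 2013-2019).

    Used for early wet seasons whose sighting locations give no sound
    basis for an area estimate.  Raises if any reference year is missing,
    naming the gaps.
    """
    ref = sorted(reference_years)
    missing = [y for y in ref if y not in areas]
    if missing:
        raise ValueError(f"wet-season areas missing for years: {missing}")
    return float(np.mean([areas[y] for y in ref]))
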