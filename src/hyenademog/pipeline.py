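"""End-to-end orchestration: sightings -> survival, abundance, density.

``run_pipeline`` wires the stages together: encounter-history construction,
the CJS survival fit with its two verification analyses (den-based cub
mortality, collaring contrast), per-season closed-capture fits of both
detection models with DIC comparison, kernel-utilization areas, and the
final density table.  Every stage logs individual/row counts to a
machine-readable event log, and every output carries the seed and a config
hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from hyenademog.cjs import (
    CjsFit, CollaringReport, CubMortality, McmcConfig, approximate_cub_mortality,
    collaring_effect, fit_cjs,
)
from hyenademog.closed import ClosedFit, fit_closed
from hyenademog.density import (
    density, fit_kud, impute_wet_area, isopleth_area, MIN_POINTS,
)
from hyenademog.encounters import (
    EncounterHistory, build_cjs_history, build_occasion_grid,
    build_seasonal_histories,
)
from hyenademog.synthetic_data import SimConfig, simulate_population

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one full pipeline run.

    Provide either ``sim`` (a simulator configuration) or both CSV paths.
    MCMC settings apply to all model fits; occasions default to the
    2-month grid spanning the simulated/loaded study window.
    """

    sim: SimConfig | None = None
    individuals_csv: str | None = None
    sightings_csv: str | None = None
    grid_start: date | None = None
    grid_end: date | None = None
    width_months: int = 2
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    augmentation_factor: float = 3.0
    bandwidth: str | float = "reference"
    isopleth_level: float = 0.90
    closed_models: tuple = ("M0", "Mh")
    run_collaring_check: bool = True
    season_filter: tuple | None = None     # e.g. (("dry", 2015),)
    impute_wet_years: tuple = ()           # wet years to impute by the mean area
    min_window_individuals: int = 10
    outdir: str | None = None
    seed: int = 0

    def config_hash(self) -> str:
        def _jsonable(o):
            if isinstance(o, dict):
                return {str(k): _jsonable(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [_jsonable(v) for v in o]
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (str, int, float, bool)) or o is None:
                return o
            return str(o)
        blob = json.dumps(_jsonable(asdict(self)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Machine-readable results of one pipeline run."""

    survival_table: pd.DataFrame
    detection: dict
    density_table: pd.DataFrame
    ddic_table: pd.DataFrame
    cub_mortality: CubMortality
    collaring: CollaringReport | None
    cjs_fit: CjsFit
    closed_fits: dict              # (season, year) -> {model: ClosedFit}
    diagnostics_flags: dict
    events: list
    provenance: dict

    def save(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.survival_table.to_csv(out / "survival.csv", index=False)
        self.density_table.to_csv(out / "density.csv", index=False)
        self.ddic_table.to_csv(out / "ddic.csv", index=False)
        with open(out / "events.jsonl", "w") as fh:
            for e in self.events:
                fh.write(json.dumps(e) + "\n")
        summary = {
            "detection": self.detection,
            "cub_mortality": asdict(self.cub_mortality),
            "collaring": None if self.collaring is None else {
                "beta_mean": self.collaring.beta_mean,
                "beta_lo": self.collaring.beta_lo,
                "beta_hi": self.collaring.beta_hi,
                "no_effect": self.collaring.no_effect,
            },
            "diagnostics": self.diagnostics_flags,
            "provenance": self.provenance,
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1)
        try:
            self.save_figures(out)
        except Exception as e:   # figures are best-effort side outputs
            logger.warning("figure generation failed: %s", e)

    def save_figures(self, outdir) -> None:
        """Density time series and survival posterior densities (PNG).

        The underlying tables (density.csv, survival.csv) are always
        written alongside by :meth:`save`.
        """
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        out = Path(outdir)
        if len(self.density_table):
            fig, ax = plt.subplots(figsize=(7, 4))
            for season, g in self.density_table.groupby("season"):
                g = g.sort_values("year")
                ax.errorbar(g["year"], g["D_median"],
                            yerr=[g["D_median"] - g["D_lo"],
                                  g["D_hi"] - g["D_median"]],
                            marker="o", capsize=3, label=season)
            ax.set_xlabel("year")
            ax.set_ylabel("density (individuals / km$^2$)")
            ax.legend()
            fig.tight_layout()
            fig.savefig(out / "density_timeseries.png", dpi=150)
            plt.close(fig)

        fig, ax = plt.subplots(figsize=(7, 4))
        for (age, sex) in self.cjs_fit.cells:
            d = self.cjs_fit.phi_draws(age, sex)
            from hyenademog.cjs import annualize
            ax.hist(annualize(d, age), bins=60, histtype="step",
                    density=True, label=f"{age} {sex}")
        ax.set_xlabel("annual apparent survival")
        ax.set_ylabel("posterior density")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / "survival_posteriors.png", dpi=150)
        plt.close(fig)


def _load_tables(config: RunConfig):
    if config.sim is not None:
        individuals, sightings, state = simulate_population(config.sim)
        return individuals, sightings, state
    for name in ("individuals_csv", "sightings_csv"):
        path = getattr(config, name)
        if path is None:
            raise ValueError("provide either sim= or both CSV paths")
        if not Path(path).exists():
            raise FileNotFoundError(f"{name}: no such file: {path}")
    individuals = pd.read_csv(config.individuals_csv)
    sightings = pd.read_csv(config.sightings_csv)
    return individuals, sightings, None


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full pipeline; see the module docstring for the stages.

    Any stage failure raises with the stage named; results computed so far
    are attached to the exception as ``partial_report`` (a dict).
    """
    events: list[dict] = []
    partial: dict = {}

    def log(stage: str, **kw):
        events.append({"stage": stage, **kw})
        logger.info("%s: %s", stage, kw)

    def _stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as e:
                e.partial_report = partial
                raise RuntimeError(f"pipeline stage '{name}' failed: {e}") from e
        return deco

    individuals, sightings, state = _stage("load")(lambda: _load_tables(config))
    log("load", n_individuals=len(individuals), n_sightings=len(sightings))

    start = config.grid_start or (state.grid.start if state is not None
                                  else pd.to_datetime(sightings["datetime"]).min().date().replace(day=1))
    end = config.grid_end or (state.grid.end if state is not None else None)
    if end is None:
        raise ValueError("grid_end required when loading from CSV")
    grid = build_occasion_grid(start, end, config.width_months)
    history = _stage("encounters")(
        lambda: build_cjs_history(sightings, individuals, grid))
    log("encounters", n_rows=history.n_individuals,
        n_occasions=history.n_occasions,
        n_excluded_known_deaths=history.n_dropped_deaths,
        n_dropped_sightings=history.n_dropped_sightings)
    partial["history"] = history

    cjs_fit = _stage("cjs")(lambda: fit_cjs(history, mcmc=config.mcmc))
    partial["cjs_fit"] = cjs_fit
    survival = cjs_fit.survival_table()
    detection = cjs_fit.detection_summary()
    log("cjs", converged=cjs_fit.converged, **detection)

    cub = _stage("cub_mortality")(lambda: approximate_cub_mortality(history))
    log("cub_mortality", **asdict(cub))

    collaring = None
    if config.run_collaring_check:
        col_any = history.collared.any(axis=1)
        if col_any.any() and not col_any.all():
            collaring = _stage("collaring")(
                lambda: collaring_effect(history, mcmc=config.mcmc))
            log("collaring", beta_mean=collaring.beta_mean,
                no_effect=collaring.no_effect)
        else:
            log("collaring", skipped="no usable collared/uncollared contrast")

    windows = _stage("seasonal")(lambda: build_seasonal_histories(sightings))
    if config.season_filter:
        keep = set(config.season_filter)
        windows = [w for w in windows if (w.season, w.year) in keep]
    windows = [w for w in windows
               if len(w.ids) >= config.min_window_individuals]
    log("seasonal", n_windows=len(windows))

    closed_fits: dict = {}
    ddic_rows = []
    areas_wet: dict[int, float] = {}
    area_by_window: dict = {}
    for w in windows:
        key = (w.season, w.year)
        fits = {}
        for model in config.closed_models:
            fits[model] = _stage(f"closed[{key}][{model}]")(
                lambda m=model: fit_closed(w, model=m, mcmc=config.mcmc,
                                           factor=config.augmentation_factor))
        closed_fits[key] = fits
        if len(fits) == 2:
            d0, dh = fits["M0"].dic, fits["Mh"].dic
            ddic_rows.append({"season": w.season, "year": w.year,
                              "dic_M0": d0, "dic_Mh": dh,
                              "delta_dic": d0 - dh,
                              "preferred": "Mh" if dh < d0 else "M0"})
        pts = np.column_stack([w.x, w.y]) if len(w.x) else np.empty((0, 2))
        impute = w.season == "wet" and w.year in config.impute_wet_years
        if len(pts) >= MIN_POINTS and not impute:
            surf = _stage(f"kud[{key}]")(
                lambda: fit_kud(pts, bandwidth=config.bandwidth))
            area = isopleth_area(surf, config.isopleth_level)
            area_by_window[key] = (area, "estimated")
            if w.season == "wet":
                areas_wet[w.year] = area
            log("kud", season=w.season, year=w.year, n_points=len(pts),
                bandwidth=surf.bandwidth, area_km2=area)
        else:
            area_by_window[key] = (None, "pending_imputation")
            log("kud", season=w.season, year=w.year, skipped=True)

    dens_rows = []
    for w in windows:
        key = (w.season, w.year)
        area, source = area_by_window[key]
        if area is None:
            if w.season == "wet" and areas_wet:
                ref_years = sorted(areas_wet)
                area = impute_wet_area(areas_wet, reference_years=ref_years)
                source = "imputed_mean_wet"
                log("impute_area", year=w.year, area_km2=area,
                    reference_years=ref_years)
            else:
                log("density", season=w.season, year=w.year,
                    skipped="no area available")
                continue
        model = "Mh" if "Mh" in closed_fits[key] else config.closed_models[0]
        est = density(closed_fits[key][model], area,
                      meta={"season": w.season, "year": w.year},
                      area_source=source)
        dens_rows.append(est.as_dict())

    flags = {
        "cjs_converged": cjs_fit.converged,
        "closed_converged": {f"{s}-{y}": {m: f.converged for m, f in d.items()}
                             for (s, y), d in closed_fits.items()},
        "closed_pileup": {f"{s}-{y}": {m: f.pileup for m, f in d.items()}
                          for (s, y), d in closed_fits.items()},
    }
    from importlib.metadata import version as _pkg_version
    try:
        _version = _pkg_version("hyenademog")
    except Exception:
        _version = "unknown"
    provenance = {"seed": config.seed, "config_hash": config.config_hash(),
                  "package_version": _version,
                  "mcmc": {"n_chains": config.mcmc.n_chains,
                           "n_iter": config.mcmc.n_iter,
                           "n_burnin": config.mcmc.n_burnin}}
    report = RunReport(
        survival_table=survival, detection=detection,
        density_table=pd.DataFrame(dens_rows),
        ddic_table=pd.DataFrame(ddic_rows),
        cub_mortality=cub, collaring=collaring, cjs_fit=cjs_fit,
        closed_fits=closed_fits, diagnostics_flags=flags, events=events,
        provenance=provenance)
    if config.outdir:
        report.save(config.outdir)
    return report


def fit_sex_specific_p(history: EncounterHistory,
                       mcmc: McmcConfig | None = None) -> pd.DataFrame:
    """CJS variant with sex-level fixed effects on detection (no individual
    random effect); returns per-sex bi-monthly p with 95% credible interval.
    """
    present = set(map(str, history.sex))
    fit = fit_cjs(history, mcmc=mcmc, p_model="sex")
    rows = []
    for s in ("F", "M", "U"):
        if s not in present:
            raise ValueError(f"sex level {s!r} absent from the data")
        d = fit.draws[f"p[{s}]"].ravel()
        rows.append({"sex": s, "p_mean": d.mean(),
                     "p_lo": np.percentile(d, 2.5),
                     "p_hi": np.percentile(d, 97.5)})
    return pd.DataFrame(rows)
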