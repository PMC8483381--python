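"""End-to-end orchestration: tracks → classification → metrics → winter → fidelity.

`run_pipeline` strings the stages together with one configuration object and
writes the artifact bundle (CSV tables, the UD raster, area polygons, a run
log). Each stage is also callable on its own for interactive use.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import (ClassifierConfig, MovementClassification,
                       SeasonalBoundaries, classify_year,
                       population_median_seasons, wilson_ci)
from .fidelity import build_sequences, transition_matrix
from .fpt import DEFAULT_RADIUS_M, compute_fpt, log_profile
from .metrics import kruskal_wallis_mc, metrics_table, migration_distances, \
    paired_season_test
from .nsd import compute_nsd
from .segmentation import segment_series
from .simulate import SyntheticConfig, generate_population, ground_truth_frame
from .telemetry import CaribouYear, DegenerateTrajectoryError, qc_report, \
    resample_to_interval
from .winter import (RegionRule, WinterAssignment, assign_winter_area,
                     delineate_areas, fit_ud, select_bandwidth_adhoc,
                     write_ud_tiff)
from .projection import DEFAULT_PROJECTION

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "classify_years", "winter_fixes",
           "region_rule_from_centers", "write_report"]


@dataclass
class RunConfig:
    """All knobs of an end-to-end run (defaults match the module defaults)."""

    synthetic: SyntheticConfig | None = None
    telemetry_path: str | None = None
    out_dir: str = "out"
    seed: int = 0
    radius_m: float = DEFAULT_RADIUS_M
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    classify_interval_h: float | None = None  # None = native fix interval
    standard_interval_h: float = 12.0  # two fixes/day for distances & UDs
    lmin: int = 10
    kmax: int = 20
    rho: float = 0.75
    ud_cell_m: float = 2_000.0
    max_ud_points: int = 4_000
    region_rule: RegionRule | None = None
    n_years_total: int | None = None
    log_level: str = "INFO"


def region_rule_from_centers(cfg: SyntheticConfig) -> RegionRule:
    """Derive the coastal/Brooks divide and the W/E meridian from the
    generator's wintering-area centers (absolute plane coordinates)."""
    origin = np.array(DEFAULT_PROJECTION.forward(-153.5, 70.6), dtype=float)
    centers = {k: np.array(v) * 1000.0 + origin
               for k, v in cfg.range_centers_km.items() if k != "Summer"}
    coastal_y = [c[1] for k, c in centers.items() if "Coastal" in k]
    brooks_y = [c[1] for k, c in centers.items() if "Brooks" in k]
    divide = 0.5 * (min(coastal_y) + max(brooks_y))
    return RegionRule(divide_y=float(divide), meridian_x=float(origin[0]))


def classify_years(
    years: list[CaribouYear],
    radius_m: float = DEFAULT_RADIUS_M,
    cfg: ClassifierConfig = ClassifierConfig(),
    lmin: int = 10,
    kmax: int = 20,
    rho: float = 0.75,
    resample_h: float | None = None,
) -> list[MovementClassification]:
    """FPT → segmentation → NSD → rules, for every caribou-year."""
    out = []
    for cy in years:
        work = cy
        if resample_h is not None and resample_h > cy.nominal_interval_h:
            work = resample_to_interval(cy, resample_h)
        try:
            # segmentation and the high/low threshold work on log FPT
            lfpt = log_profile(compute_fpt(work, radius_m))
            seg = segment_series(lfpt, lmin=lmin, kmax=kmax, rho=rho)
            nsd = compute_nsd(work, 0)
            out.append(classify_year(work, seg, lfpt, nsd, cfg))
        except ValueError as exc:
            log.warning("%s %s: classification failed (%s); labeled other",
                        cy.animal_id, cy.year, exc)
            out.append(MovementClassification(
                animal_id=cy.animal_id, year=cy.year, label="other",
                rule_trace=f"degenerate:{exc}", winter_span=None))
    return out


def winter_fixes(
    cy: CaribouYear,
    mc: MovementClassification,
    pop_seasons: SeasonalBoundaries | None,
) -> np.ndarray:
    """Planar winter-period fixes for one (standardized) caribou-year.

    Migrants use their own boundaries; residents and others fall back to the
    population median winter dates.
    """
    if mc.label == "migrant" and mc.boundaries is not None:
        b = mc.boundaries
    elif pop_seasons is not None:
        b = pop_seasons
    else:
        raise ValueError("no boundaries available for a non-migrant year")
    days = (cy.df["t"] - cy.year_start).dt.total_seconds().to_numpy() / 86400.0
    sel = (days >= b.winter_start) & (days <= b.winter_end)
    return np.column_stack([cy.df["x"].to_numpy()[sel],
                            cy.df["y"].to_numpy()[sel]])


def _classification_frame(mcs, assignments=None):
    amap = {}
    if assignments:
        amap = {(a.animal_id, a.year): a for a in assignments}
    rows = []
    for m in mcs:
        b = m.boundaries
        a = amap.get((m.animal_id, m.year))
        rows.append({
            "animal_id": m.animal_id, "year": m.year, "label": m.label,
            "rule_trace": m.rule_trace,
            "fall_start_day": b.fall_start if b else np.nan,
            "fall_end_day": b.fall_end if b else np.nan,
            "winter_start_day": b.winter_start if b else np.nan,
            "winter_end_day": b.winter_end if b else np.nan,
            "spring_start_day": b.spring_start if b else np.nan,
            "spring_end_day": b.spring_end if b else np.nan,
            "fine_area": a.fine_label if a else None,
            "coarse_area": a.coarse_label if a else None,
            "assignment_method": a.method if a else None,
        })
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and return the artifact bundle (also on disk)."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=cfg.log_level)
    bundle: dict = {"config": cfg}

    # --- inputs -----------------------------------------------------------
    if cfg.synthetic is not None:
        years, truths = generate_population(cfg.synthetic, cfg.n_years_total)
        bundle["ground_truth"] = ground_truth_frame(truths)
    elif cfg.telemetry_path is not None:
        from .telemetry import (FormatConfig, filter_implausible_fixes,
                                project_to_plane, read_telemetry,
                                split_analysis_years)
        years = []
        for traj in read_telemetry(cfg.telemetry_path, FormatConfig()):
            traj = project_to_plane(traj)
            try:
                traj = filter_implausible_fixes(traj)
            except DegenerateTrajectoryError:
                continue
            years.extend(split_analysis_years(traj))
        years = [cy for cy in years if cy.passed_qc]
    else:
        raise ValueError("RunConfig needs either synthetic or telemetry_path")
    bundle["years"] = years
    bundle["qc"] = qc_report(years)

    # --- classification ---------------------------------------------------
    mcs = classify_years(years, cfg.radius_m, cfg.classifier,
                         cfg.lmin, cfg.kmax, cfg.rho,
                         resample_h=cfg.classify_interval_h)
    bundle["classifications"] = mcs
    try:
        pop_seasons = population_median_seasons(mcs)
    except ValueError as exc:
        log.error("season medians unavailable: %s", exc)
        pop_seasons = None
    bundle["population_seasons"] = pop_seasons

    # --- standardized (≤2/day) tracks ------------------------------------
    std: dict[tuple[str, int], CaribouYear] = {}
    for cy in years:
        try:
            std[(cy.animal_id, cy.year)] = (
                resample_to_interval(cy, cfg.standard_interval_h)
                if cfg.standard_interval_h > cy.nominal_interval_h else cy)
        except DegenerateTrajectoryError:
            continue

    # --- migration metrics ------------------------------------------------
    metrics = []
    for m in mcs:
        if m.label != "migrant" or m.boundaries is None:
            continue
        cy = std.get((m.animal_id, m.year))
        if cy is None:
            continue
        for season in ("fall", "spring"):
            try:
                metrics.append(migration_distances(cy, m.boundaries, season))
            except ValueError as exc:
                log.info("metrics skipped: %s", exc)
    bundle["metrics"] = metrics

    # --- winter UDs, areas, assignment ------------------------------------
    assignments: list[WinterAssignment] = []
    area_set = None
    if pop_seasons is not None:
        per_year_pts = {}
        for m in mcs:
            cy = std.get((m.animal_id, m.year))
            if cy is None:
                continue
            pts = winter_fixes(cy, m, pop_seasons)
            if len(pts) >= 5:
                per_year_pts[(m.animal_id, m.year)] = pts
        pooled = (np.vstack(list(per_year_pts.values()))
                  if per_year_pts else np.empty((0, 2)))
        if len(pooled) >= 5:
            if len(pooled) > cfg.max_ud_points:
                stride = int(np.ceil(len(pooled) / cfg.max_ud_points))
                pooled = pooled[::stride]
            h_pop = select_bandwidth_adhoc(pooled, isopleth=0.95,
                                           cell_m=cfg.ud_cell_m)
            pop_ud = fit_ud(pooled, h_pop, cfg.ud_cell_m)
            rule = cfg.region_rule
            if rule is None and cfg.synthetic is not None:
                rule = region_rule_from_centers(cfg.synthetic)
            if rule is None:
                raise ValueError("region_rule is required for telemetry input")
            area_set = delineate_areas(pop_ud, rule)
            bundle["population_ud"] = pop_ud
            bundle["area_set"] = area_set
            for (aid, yr), pts in per_year_pts.items():
                try:
                    h_i = select_bandwidth_adhoc(pts, isopleth=0.95,
                                                 cell_m=min(cfg.ud_cell_m, 1000.0))
                    iud = fit_ud(pts, h_i, min(cfg.ud_cell_m, 1000.0))
                    assignments.append(assign_winter_area(aid, yr, iud, area_set))
                except ValueError as exc:
                    log.warning("%s %s: assignment failed (%s)", aid, yr, exc)
    bundle["assignments"] = assignments

    # --- fidelity ---------------------------------------------------------
    for scale in ("coarse", "fine"):
        seqs = build_sequences(assignments, scale)
        try:
            bundle[f"transitions_{scale}"] = transition_matrix(seqs, scale)
        except ValueError:
            bundle[f"transitions_{scale}"] = None

    write_report(bundle, out_dir)
    return bundle


def write_report(bundle: dict, out_dir: Path) -> None:
    """Write the artifact bundle as CSV/TIFF/GeoJSON report files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg: RunConfig = bundle["config"]
    mcs = bundle["classifications"]

    bundle["qc"].to_csv(out_dir / "qc_report.csv", index=False)
    cls_df = _classification_frame(mcs, bundle.get("assignments"))
    cls_df.to_csv(out_dir / "classification.csv", index=False)

    # class percentages and per-year migrant percentage with Wilson CIs
    n = len(mcs)
    counts = {lab: sum(m.label == lab for m in mcs)
              for lab in ("migrant", "resident", "other")}
    summary = {
        "n_years": n,
        **{f"n_{k}": v for k, v in counts.items()},
        **{f"pct_{k}": round(100.0 * v / n, 1) for k, v in counts.items()},
    }
    rows = []
    for yr in sorted({m.year for m in mcs}):
        sub = [m for m in mcs if m.year == yr]
        k = sum(m.label == "migrant" for m in sub)
        est = wilson_ci(k, len(sub))
        rows.append({"year": yr, "n": est.n, "migrants": est.k,
                     "pct_migrant": round(100 * est.p_hat, 1),
                     "ci_low_pct": round(100 * est.ci_low, 1),
                     "ci_high_pct": round(100 * est.ci_high, 1)})
    pd.DataFrame(rows).to_csv(out_dir / "migrant_percentage_by_year.csv",
                              index=False)

    ps = bundle.get("population_seasons")
    if ps is not None:
        # report non-overlapping calendar ranges (shared day advances)
        ref = pd.Timestamp(2004, 7, 1)

        def d(day, offset=0.0):
            return (ref + pd.Timedelta(days=float(day) + offset)).strftime("%b %d")

        season_tbl = pd.DataFrame([{
            "summer": f"Jul 01 - {d(ps.fall_start, -1)}",
            "fall_migration": f"{d(ps.fall_start)} - {d(ps.winter_start, -1)}",
            "winter": f"{d(ps.winter_start)} - {d(ps.winter_end, -1)}",
            "spring_migration": f"{d(ps.winter_end)} - {d(ps.spring_end)}",
        }])
        season_tbl.to_csv(out_dir / "season_table.csv", index=False)
    else:
        (out_dir / "season_table.MISSING.txt").write_text(
            "no migrant years: season medians unavailable\n")

    metrics = bundle.get("metrics") or []
    if metrics:
        mt = metrics_table(metrics)
        amap = {(a.animal_id, a.year): a for a in bundle.get("assignments", [])}
        mt["fine_area"] = [getattr(amap.get((r.animal_id, r.year)), "fine_label",
                                   None) for r in mt.itertuples()]
        mt["coarse_area"] = [getattr(amap.get((r.animal_id, r.year)),
                                     "coarse_label", None)
                             for r in mt.itertuples()]
        mt.to_csv(out_dir / "migration_metrics.csv", index=False)
        stats_rows = []
        for season in ("fall", "spring"):
            sub = mt[mt.season == season].dropna(subset=["coarse_area"])
            for metric in ("path_km", "euclid_km", "duration_days",
                           "directedness"):
                for scale in ("coarse_area", "fine_area"):
                    groups = {k: g[metric].to_numpy()
                              for k, g in sub.groupby(scale) if len(g) > 0}
                    if len(groups) >= 2:
                        H, p, sig = kruskal_wallis_mc(groups)
                        stats_rows.append({
                            "season": season, "metric": metric, "scale": scale,
                            "H": round(H, 3), "p": p,
                            "significant_pairs": "; ".join(
                                f"{a}|{b}" for a, b in sorted(sig))})
        fall = mt[mt.season == "fall"].set_index(["animal_id", "year"])
        spring = mt[mt.season == "spring"].set_index(["animal_id", "year"])
        common = fall.index.intersection(spring.index)
        for metric in ("duration_days", "directedness"):
            if len(common) >= 2:
                try:
                    stat, p = paired_season_test(
                        fall.loc[common, metric].to_numpy(),
                        spring.loc[common, metric].to_numpy(),
                        list(common))
                    stats_rows.append({"season": "fall_vs_spring",
                                       "metric": metric, "scale": "paired",
                                       "H": round(stat, 3), "p": p,
                                       "significant_pairs": ""})
                except ValueError:
                    pass
        pd.DataFrame(stats_rows).to_csv(out_dir / "metric_tests.csv",
                                        index=False)

    if bundle.get("population_ud") is not None:
        write_ud_tiff(bundle["population_ud"], str(out_dir / "winter_ud.tif"),
                      crs=DEFAULT_PROJECTION.name)
    if bundle.get("area_set") is not None:
        feats = []
        for a in bundle["area_set"].areas:
            feats.append({
                "type": "Feature",
                "properties": {"label": a.label,
                               "isopleth_level": a.isopleth_level},
                "geometry": a.polygon.__geo_interface__,
            })
        (out_dir / "wintering_areas.geojson").write_text(
            json.dumps({"type": "FeatureCollection", "features": feats}))

    for scale in ("coarse", "fine"):
        tm = bundle.get(f"transitions_{scale}")
        if tm is not None:
            tm.to_frame().to_csv(out_dir / f"transitions_{scale}.csv")

    (out_dir / "run_log.json").write_text(json.dumps({
        "package_version": __version__,
        "seed": cfg.seed,
        "radius_m": cfg.radius_m,
        "n_years": n,
        "summary": summary,
    }, indent=2, default=str))
    bundle["summary"] = summary
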