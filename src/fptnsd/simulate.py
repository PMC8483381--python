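"""Synthetic multi-year caribou trajectories with known ground truth.

The generator emulates the movement structure of a partially migratory
barren-ground caribou herd: a shared summer range on the coastal plain,
four discrete wintering areas (two coastal, two in the Brooks Range far to
the south), a tortuous fall migration and a more directed spring return,
year-to-year wintering-area choice following a Markov chain, and collar
realism — mixed fix schedules (2/3/8/12 h), positional noise, outages and
truncated years.

Movement kernels:

* within a seasonal range — a discrete mean-reverting (Ornstein–Uhlenbeck
  style) wander around the range center, which produces the long first
  passage times the classifier keys on;
* migration — a start→target bridge with correlated meander whose
  amplitude is set by a per-season ``persistence`` in (0, 1]: the expected
  straightness index of the leg approximately equals the persistence, so
  fall (default 0.46) comes out more tortuous than spring (default 0.72);
* "other" years — half nomadic drift (a slowly turning drifting range
  center, no stable winter range), half one-way shifts (fall migration
  without the return leg).

Every generated caribou-year carries a ground-truth record (class, true
season boundary days, true wintering area, fix interval) so downstream
stages can be scored for recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .projection import DEFAULT_PROJECTION
from .telemetry import CaribouYear, _make_year

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "sample_winter_sequence",
    "simulate_year_track",
    "generate_population",
    "to_telemetry_csv",
    "ground_truth_frame",
]

#: Observed herd proportions used as default mixture weights.
DEFAULT_CLASS_MIX = {"migrant": 129 / 164, "resident": 19 / 164, "other": 16 / 164}

#: Per-year fix-interval mixture (hours -> probability), collar-fleet realism.
DEFAULT_FIX_MIX = {2: 120 / 164, 3: 17 / 164, 8: 10 / 164, 12: 17 / 164}

#: Fine-scale wintering-area transition probabilities (renormalized from the
#: herd summaries reported at 2 dp) and first-year area frequencies.
DEFAULT_WINTER_TRANSITION = np.array(
    [
        [0.57, 0.22, 0.00, 0.22],
        [0.43, 0.29, 0.00, 0.29],
        [0.88, 0.12, 0.00, 0.00],
        [0.32, 0.26, 0.11, 0.32],
    ]
)
DEFAULT_WINTER_TRANSITION /= DEFAULT_WINTER_TRANSITION.sum(axis=1, keepdims=True)
DEFAULT_WINTER_INITIAL = np.array([71, 43, 10, 40], dtype=float) / 164.0

AREA_LABELS = ("W Coastal", "E Coastal", "W Brooks", "E Brooks")

#: Wintering-area centers (km, planar, summer range at the origin).
#: Coastal areas sit near the summer range; Brooks areas several hundred km
#: south, so Brooks migrations are much longer than coastal ones.
DEFAULT_RANGE_CENTERS_KM = {
    "Summer": (0.0, 0.0),
    "W Coastal": (-120.0, -60.0),
    "E Coastal": (100.0, -80.0),
    "W Brooks": (-250.0, -450.0),
    "E Brooks": (200.0, -480.0),
}

#: Median season boundary days (days since Jul 1): fall Sep 28 – Nov 10,
#: winter through May 1, spring May 2 – Jun 1.
DEFAULT_SEASON_TIMING = {
    "fall_start": (89.0, 8.0),
    "fall_end": (132.0, 8.0),
    "spring_start": (305.0, 6.0),
    "spring_end": (335.0, 4.0),
}

#: Distribution of collar-years per individual (mean ~2.2, ~51% multi-year).
DEFAULT_YEARS_PER_INDIVIDUAL = {
    1: 0.49, 2: 0.20, 3: 0.12, 4: 0.08, 5: 0.05, 6: 0.03, 7: 0.02, 8: 0.01,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition knobs of the generator (defaults = herd conditions)."""

    n_individuals: int = 60
    years_per_individual: dict = field(
        default_factory=lambda: dict(DEFAULT_YEARS_PER_INDIVIDUAL))
    class_mix: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    range_centers_km: dict = field(
        default_factory=lambda: dict(DEFAULT_RANGE_CENTERS_KM))
    winter_transition: np.ndarray = field(
        default_factory=lambda: DEFAULT_WINTER_TRANSITION.copy())
    winter_initial: np.ndarray = field(
        default_factory=lambda: DEFAULT_WINTER_INITIAL.copy())
    season_timing: dict = field(
        default_factory=lambda: dict(DEFAULT_SEASON_TIMING))
    fall_persistence: float = 0.46
    spring_persistence: float = 0.72
    # per-axis SD of the within-range wander: a ~24 km 95% range span, small
    # enough that a resident's summer and winter activity centers stay well
    # inside the residency displacement cap
    range_sd_km: float = 6.0
    range_tau_h: float = 480.0  # OU decorrelation time within a range (20 d):
    # in-range daily drift ~2.5 km/day, so a 9-km circle takes days to cross
    # while migration crosses it in hours — the FPT contrast of real tracks
    fix_mix: dict = field(default_factory=lambda: dict(DEFAULT_FIX_MIX))
    noise_sd_m: float = 30.0
    gap_prob: float = 0.3
    gap_max_days: float = 10.0
    truncate_prob: float = 0.1
    nomad_speed_km_day: float = 2.5
    other_one_way_frac: float = 0.5
    first_year: int = 2004
    tz: str = "America/Anchorage"
    seed: int = 0

    def __post_init__(self):
        mix = np.array(list(self.class_mix.values()), dtype=float)
        if not np.isclose(mix.sum(), 1.0, atol=1e-6):
            raise ValueError("class_mix must sum to 1")
        wt = np.asarray(self.winter_transition, dtype=float)
        if not np.allclose(wt.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("winter_transition rows must sum to 1")
        if not self.fall_persistence < self.spring_persistence:
            raise ValueError("fall persistence must be below spring persistence")


@dataclass
class GroundTruth:
    """True generating state for one synthetic caribou-year."""

    animal_id: str
    year: int
    true_class: str
    true_subclass: str
    fall_start: float
    fall_end: float
    spring_start: float
    spring_end: float
    true_area: str | None
    interval_h: float


def sample_winter_sequence(
    cfg: SyntheticConfig, n_years: int, rng: np.random.Generator,
    initial: np.ndarray | None = None,
) -> list[str]:
    """Markov chain of wintering-area labels across an individual's years."""
    P = np.asarray(cfg.winter_transition, dtype=float)
    p0 = np.asarray(initial if initial is not None else cfg.winter_initial,
                    dtype=float)
    p0 = p0 / p0.sum()
    states = [int(rng.choice(4, p=p0))]
    for _ in range(n_years - 1):
        states.append(int(rng.choice(4, p=P[states[-1]])))
    return [AREA_LABELS[s] for s in states]


def _ou_wander(n: int, start: np.ndarray, center: np.ndarray, sd_m: float,
               phi: float, rng: np.random.Generator) -> np.ndarray:
    """Discrete mean-reverting wander; returns n positions after ``start``."""
    out = np.empty((n, 2))
    p = start.astype(float).copy()
    step_sd = sd_m * np.sqrt(max(1.0 - phi * phi, 1e-12))
    for i in range(n):
        p = center + phi * (p - center) + rng.normal(0.0, step_sd, 2)
        out[i] = p
    return out


def _migration_bridge(n: int, start: np.ndarray, target: np.ndarray,
                      persistence: float, rng: np.random.Generator) -> np.ndarray:
    """Start→target leg with correlated meander; directedness ≈ persistence."""
    if n < 1:
        return np.empty((0, 2))
    base = np.linspace(start, target, n + 1)[1:]
    d0 = np.linalg.norm(target - start) / n
    p = float(np.clip(persistence, 0.05, 1.0))
    sd_step = d0 * np.sqrt(max(1.0 / (p * p) - 1.0, 0.0) / 2.0)
    phi = 0.5  # meander smoothness; diff of AR(1) then has sd ~ sd_step
    e = np.zeros((n + 1, 2))
    # AR(1) meander whose step-to-step increments have sd ~ sd_step
    sd_e = sd_step / np.sqrt(2.0 * (1.0 - phi))
    innov_sd = sd_e * np.sqrt(1.0 - phi * phi)
    for i in range(1, n + 1):
        e[i] = phi * e[i - 1] + rng.normal(0.0, innov_sd, 2)
    e -= np.outer(np.arange(n + 1) / n, e[-1])  # pin the bridge at the target
    return base + e[1:]


def _simulate_positions(cfg, rng, days, dt_h, cls, subclass, winter_center_m,
                        season_days):
    """Planar positions (meters) at each fix time for one caribou-year."""
    n = len(days)
    summer = np.array(cfg.range_centers_km["Summer"]) * 1000.0
    sd_m = cfg.range_sd_km * 1000.0
    phi = float(np.exp(-dt_h / cfg.range_tau_h))
    pos = np.empty((n, 2))
    if cls == "resident":
        pos[:] = _ou_wander(n, summer, summer, sd_m, phi, rng)
        return pos
    if cls == "other" and subclass == "nomadic":
        # drifting range center with a slowly turning heading
        heading = rng.uniform(0, 2 * np.pi)
        speed = cfg.nomad_speed_km_day * 1000.0 / 24.0  # m/h
        center = summer.astype(float).copy()
        p = summer.astype(float).copy()
        step_sd = 0.5 * sd_m * np.sqrt(max(1 - phi * phi, 1e-12))
        for i in range(n):
            heading += rng.normal(0.0, 0.15)
            center = center + speed * dt_h * np.array(
                [np.cos(heading), np.sin(heading)])
            p = center + phi * (p - center) + rng.normal(0.0, step_sd, 2)
            pos[i] = p
        return pos
    # migrant or one-way shift: summer -> fall leg -> winter [-> spring leg]
    fs, fe, ss, se = (season_days[k] for k in
                      ("fall_start", "fall_end", "spring_start", "spring_end"))
    ph_summer1 = days < fs
    ph_fall = (days >= fs) & (days < fe)
    ph_winter = (days >= fe) & (days < ss)
    ph_spring = (days >= ss) & (days < se)
    ph_summer2 = days >= se
    if cls == "other":  # one-way: no return leg, winter continues to year end
        ph_winter = days >= fe
        ph_spring = np.zeros(n, dtype=bool)
        ph_summer2 = np.zeros(n, dtype=bool)
    cursor = summer.astype(float)
    k = int(ph_summer1.sum())
    if k:
        seg = _ou_wander(k, cursor, summer, sd_m, phi, rng)
        pos[ph_summer1] = seg
        cursor = seg[-1]
    k = int(ph_fall.sum())
    if k:
        seg = _migration_bridge(k, cursor, winter_center_m,
                                cfg.fall_persistence, rng)
        pos[ph_fall] = seg
        cursor = seg[-1] if len(seg) else cursor
    k = int(ph_winter.sum())
    if k:
        seg = _ou_wander(k, cursor, winter_center_m, sd_m, phi, rng)
        pos[ph_winter] = seg
        cursor = seg[-1]
    k = int(ph_spring.sum())
    if k:
        seg = _migration_bridge(k, cursor, summer, cfg.spring_persistence, rng)
        pos[ph_spring] = seg
        cursor = seg[-1] if len(seg) else cursor
    k = int(ph_summer2.sum())
    if k:
        pos[ph_summer2] = _ou_wander(k, cursor, summer, sd_m, phi, rng)
    return pos


def _draw_season_days(cfg, rng) -> dict[str, float]:
    out = {}
    for key, (mu, sd) in cfg.season_timing.items():
        out[key] = float(rng.normal(mu, sd))
    # enforce ordering with sensible minimum leg/occupancy lengths
    out["fall_end"] = max(out["fall_end"], out["fall_start"] + 14.0)
    out["spring_start"] = min(
        max(out["spring_start"], out["fall_end"] + 45.0), 345.0)
    out["spring_end"] = min(max(out["spring_end"], out["spring_start"] + 10.0),
                            362.0)
    return out


def simulate_year_track(
    cfg: SyntheticConfig,
    animal_id: str,
    year: int,
    cls: str,
    winter_area: str,
    rng: np.random.Generator,
    origin_m: np.ndarray,
) -> tuple[CaribouYear, GroundTruth]:
    """One synthetic caribou-year plus its ground-truth record.

    ``origin_m`` places the synthetic summer range on the projection plane
    so that emitted lon/lat land in the study region.
    """
    dt_candidates = sorted(cfg.fix_mix)
    probs = np.array([cfg.fix_mix[k] for k in dt_candidates], dtype=float)
    dt_h = float(rng.choice(dt_candidates, p=probs / probs.sum()))
    year_start = pd.Timestamp(year=year, month=7, day=1, tz=cfg.tz)
    year_end = pd.Timestamp(year=year + 1, month=7, day=1, tz=cfg.tz)
    total_h = (year_end - year_start).total_seconds() / 3600.0
    hours = np.arange(0.0, total_h - dt_h / 2, dt_h)

    subclass = cls
    if cls == "other":
        subclass = ("one_way" if rng.random() < cfg.other_one_way_frac
                    else "nomadic")
    season = _draw_season_days(cfg, rng)
    wc = np.array(cfg.range_centers_km[winter_area]) * 1000.0
    days = hours / 24.0
    pos = _simulate_positions(cfg, rng, days, dt_h, cls, subclass, wc, season)
    pos = pos + rng.normal(0.0, cfg.noise_sd_m, pos.shape)

    keep = np.ones(len(hours), dtype=bool)
    if rng.random() < cfg.truncate_prob:
        cut = rng.uniform(295.0, 355.0)
        keep &= days <= cut
    if rng.random() < cfg.gap_prob:
        g0 = rng.uniform(10.0, 330.0)
        g1 = g0 + rng.uniform(1.0, cfg.gap_max_days)
        keep &= ~((days > g0) & (days < g1))
    hours, pos = hours[keep], pos[keep]

    t = year_start + pd.to_timedelta(hours, unit="h")
    xy = pos + origin_m
    lon, lat = DEFAULT_PROJECTION.inverse(xy[:, 0], xy[:, 1])
    df = pd.DataFrame({"t": t, "lon": lon, "lat": lat,
                       "x": xy[:, 0], "y": xy[:, 1]})
    cy = _make_year(animal_id, year_start, df, interval_h=dt_h)

    migratory = cls == "migrant" or subclass == "one_way"
    gt = GroundTruth(
        animal_id=animal_id, year=year, true_class=cls, true_subclass=subclass,
        fall_start=season["fall_start"] if migratory else np.nan,
        fall_end=season["fall_end"] if migratory else np.nan,
        spring_start=season["spring_start"] if cls == "migrant" else np.nan,
        spring_end=season["spring_end"] if cls == "migrant" else np.nan,
        true_area=winter_area if migratory else None,
        interval_h=dt_h,
    )
    return cy, gt


def generate_population(
    cfg: SyntheticConfig,
    n_years_total: int | None = None,
) -> tuple[list[CaribouYear], list[GroundTruth]]:
    """A reproducible multi-individual, multi-year synthetic population.

    Individuals get 1–8 consecutive analysis-years; wintering areas follow
    the Markov chain; classes are drawn per year from the class mixture.
    ``n_years_total`` optionally caps the total number of caribou-years
    (individuals are added until the cap is reached).
    """
    rng = np.random.default_rng(cfg.seed)
    origin = np.array(DEFAULT_PROJECTION.forward(-153.5, 70.6), dtype=float)
    ypi_keys = sorted(cfg.years_per_individual)
    ypi_p = np.array([cfg.years_per_individual[k] for k in ypi_keys], float)
    ypi_p /= ypi_p.sum()
    cls_keys = list(cfg.class_mix)
    cls_p = np.array([cfg.class_mix[k] for k in cls_keys], float)
    cls_p /= cls_p.sum()

    years: list[CaribouYear] = []
    truths: list[GroundTruth] = []
    i = 0
    while True:
        if n_years_total is None:
            if i >= cfg.n_individuals:
                break
        elif len(years) >= n_years_total:
            break
        i += 1
        animal_id = f"SIM{i:04d}"
        ny = int(rng.choice(ypi_keys, p=ypi_p))
        if n_years_total is not None:
            ny = min(ny, n_years_total - len(years))
            if ny == 0:
                break
        y0 = int(rng.integers(cfg.first_year, cfg.first_year + 9))
        areas = sample_winter_sequence(cfg, ny, rng)
        for j in range(ny):
            cls = str(rng.choice(cls_keys, p=cls_p))
            cy, gt = simulate_year_track(
                cfg, animal_id, y0 + j, cls, areas[j], rng, origin)
            years.append(cy)
            truths.append(gt)
    return years, truths


def ground_truth_frame(truths: list[GroundTruth]) -> pd.DataFrame:
    return pd.DataFrame([t.__dict__ for t in truths])


def to_telemetry_csv(years: list[CaribouYear], path) -> None:
    """Emit the telemetry CSV dialect that the ingest module reads."""
    frames = []
    for cy in years:
        frames.append(pd.DataFrame({
            "animal_id": cy.animal_id,
            "timestamp": cy.df["t"].dt.tz_convert("UTC").dt.strftime(
                "%Y-%m-%dT%H:%M:%SZ"),
            "lon": cy.df["lon"].round(6),
            "lat": cy.df["lat"].round(6),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
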