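"""Ingest, clean, split and standardize GPS telemetry.

Raw collar files arrive as delimited text with one relocation per row.
This module turns them into analysis-ready objects:

* :func:`read_telemetry` — parse, sort, de-duplicate into per-animal
  :class:`Trajectory` objects;
* :func:`project_to_plane` — fill planar equal-area coordinates;
* :func:`filter_implausible_fixes` — drop out-and-back positional spikes
  flagged by the combination of speed and turning angle;
* :func:`split_analysis_years` — partition each animal's record into
  analysis-years running July 1 → June 30 and apply the completeness
  screens (≥290 days of data, no gap longer than two weeks);
* :func:`resample_to_interval` — thin a year to a coarser nominal fix
  interval on a midnight-anchored grid (e.g. at most two fixes per day
  for a 12-hour grid).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .projection import DEFAULT_PROJECTION, AlbersEqualArea

log = logging.getLogger(__name__)

__all__ = [
    "FormatConfig",
    "Trajectory",
    "CaribouYear",
    "FormatError",
    "DegenerateTrajectoryError",
    "read_telemetry",
    "project_to_plane",
    "filter_implausible_fixes",
    "split_analysis_years",
    "resample_to_interval",
    "qc_report",
    "apply_exclusions",
]

#: Quality screens for an analysis-year.
MIN_DURATION_DAYS = 290.0
MAX_GAP_DAYS = 14.0

#: Fix intervals (hours) that collars in this study are programmed at.
KNOWN_INTERVALS_H = (2, 3, 8, 12)


class FormatError(ValueError):
    """Input file does not match the declared column layout."""


class DegenerateTrajectoryError(ValueError):
    """A filter reduced a trajectory below two usable fixes."""


@dataclass(frozen=True)
class FormatConfig:
    """Column mapping and parsing options for telemetry text files.

    Defaults follow Movebank-style exports (ISO-8601 timestamps,
    ``individual-local-identifier`` shortened to ``animal_id``).
    """

    id_col: str = "animal_id"
    time_col: str = "timestamp"
    lon_col: str = "lon"
    lat_col: str = "lat"
    sep: str = ","
    tz: str = "UTC"  # assumed zone for naive timestamps


@dataclass
class Trajectory:
    """Time-ordered relocations for a single animal.

    ``df`` has columns ``t`` (timezone-aware), ``lon``, ``lat`` and — once
    :func:`project_to_plane` has run — ``x``, ``y`` in meters. ``dropped``
    accumulates removed rows with a ``reason`` column (``duplicate``,
    ``implausible``).
    """

    animal_id: str
    df: pd.DataFrame
    crs: str | None = None
    dropped: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if len(self.df) < 2:
            raise DegenerateTrajectoryError(
                f"trajectory for {self.animal_id!r} has <2 fixes"
            )
        t = self.df["t"]
        if not t.is_monotonic_increasing or t.duplicated().any():
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class CaribouYear:
    """One animal's relocations clipped to a July 1 → June 30 analysis-year."""

    animal_id: str
    year_start: pd.Timestamp  # local July 1
    df: pd.DataFrame
    nominal_interval_h: float
    duration_days: float
    max_gap_days: float
    passed_qc: bool

    @property
    def year(self) -> int:
        """Calendar year in which the analysis-year starts."""
        return int(self.year_start.year)

    def day_of_year(self, t: pd.Timestamp) -> float:
        """Days elapsed since the July 1 that opens this analysis-year."""
        return (t - self.year_start).total_seconds() / 86400.0

    def __len__(self) -> int:
        return len(self.df)


def read_telemetry(path, fmt: FormatConfig | None = None) -> list[Trajectory]:
    """Parse a delimited telemetry file into per-animal trajectories.

    Rows with identical (animal id, timestamp) are collapsed to the first
    occurrence; the rest are recorded as duplicates. Unparseable timestamps
    raise with the offending line number.
    """
    fmt = fmt or FormatConfig()
    raw = pd.read_csv(path, sep=fmt.sep)
    required = [fmt.id_col, fmt.time_col, fmt.lon_col, fmt.lat_col]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise FormatError(f"missing required column(s): {missing}")

    ts = pd.to_datetime(raw[fmt.time_col], errors="coerce", utc=False, format="ISO8601")
    bad = ts.isna() & raw[fmt.time_col].notna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        raise FormatError(
            f"unparseable timestamp {raw[fmt.time_col][bad].iloc[0]!r} at line {line}"
        )
    if ts.dt.tz is None:
        ts = ts.dt.tz_localize(fmt.tz)

    df = pd.DataFrame(
        {
            "animal_id": raw[fmt.id_col].astype(str),
            "t": ts,
            "lon": raw[fmt.lon_col].astype(float),
            "lat": raw[fmt.lat_col].astype(float),
        }
    )
    out: list[Trajectory] = []
    for animal_id, g in df.groupby("animal_id", sort=True):
        g = g.sort_values("t", kind="mergesort").reset_index(drop=True)
        dup = g["t"].duplicated(keep="first")
        dropped = g[dup].assign(reason="duplicate")
        g = g[~dup].reset_index(drop=True)
        if len(g) < 2:
            log.warning("animal %s has <2 unique fixes; skipped", animal_id)
            continue
        out.append(
            Trajectory(animal_id=str(animal_id), df=g.drop(columns="animal_id"),
                       dropped=dropped.drop(columns="animal_id"))
        )
    return out


def project_to_plane(
    traj: Trajectory, proj: AlbersEqualArea = DEFAULT_PROJECTION
) -> Trajectory:
    """Fill planar x/y (meters) from lon/lat on an equal-area plane."""
    df = traj.df.copy()
    x, y = proj.forward(df["lon"].to_numpy(), df["lat"].to_numpy())
    df["x"], df["y"] = x, y
    return replace(traj, df=df, crs=proj.name)


def _leg_speeds_kmh(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-leg speed (km/h) and per-vertex cosine of the turning angle."""
    x = df["x"].to_numpy()
    y = df["y"].to_numpy()
    th = df["t"].astype("int64").to_numpy() / 3.6e12  # hours
    dx, dy, dt = np.diff(x), np.diff(y), np.diff(th)
    step_km = np.hypot(dx, dy) / 1000.0
    speed = step_km / np.maximum(dt, 1e-9)
    dot = dx[:-1] * dx[1:] + dy[:-1] * dy[1:]
    norm = np.hypot(dx[:-1], dy[:-1]) * np.hypot(dx[1:], dy[1:])
    cos = np.where(norm > 0, dot / np.maximum(norm, 1e-12), 1.0)
    return speed, cos


def filter_implausible_fixes(
    traj: Trajectory,
    rate_max_kmh: float = 15.0,
    spike_cos_max: float = -0.97,
) -> Trajectory:
    """Iteratively remove out-and-back positional spikes.

    A fix is implausible when the implied speed on *both* adjacent legs
    exceeds ``rate_max_kmh`` and the path nearly reverses there (cosine of
    the turning angle below ``spike_cos_max``). The worst offender (highest
    adjacent speed) is removed first and the screen re-evaluated until
    stable, so consecutive spikes are peeled off one by one.
    """
    if "x" not in traj.df.columns:
        raise ValueError("projected coordinates required; run project_to_plane first")
    df = traj.df.reset_index(drop=True)
    removed = []
    while True:
        if len(df) < 2:
            raise DegenerateTrajectoryError(
                f"{traj.animal_id!r}: spike filter left <2 fixes"
            )
        speed, cos = _leg_speeds_kmh(df)
        v_in, v_out = speed[:-1], speed[1:]
        bad = (v_in > rate_max_kmh) & (v_out > rate_max_kmh) & (cos < spike_cos_max)
        if not bad.any():
            break
        worst = np.maximum(v_in, v_out)
        worst[~bad] = -np.inf
        idx = int(np.argmax(worst)) + 1  # vertex index in df
        removed.append(df.iloc[idx])
        df = df.drop(df.index[idx]).reset_index(drop=True)
    dropped = traj.dropped
    if removed:
        extra = pd.DataFrame(removed).assign(reason="implausible")
        dropped = pd.concat([dropped, extra], ignore_index=True)
    return replace(traj, df=df, dropped=dropped)


def _analysis_year_start(t: pd.Timestamp) -> pd.Timestamp:
    y = t.year if (t.month, t.day) >= (7, 1) else t.year - 1
    return pd.Timestamp(year=y, month=7, day=1, tz=t.tz)


def _infer_interval_h(th: np.ndarray) -> float:
    if len(th) < 2:
        return float("nan")
    med = float(np.median(np.diff(th)))
    return float(min(KNOWN_INTERVALS_H, key=lambda k: abs(k - med)))


def _make_year(animal_id: str, year_start: pd.Timestamp, g: pd.DataFrame,
               interval_h: float | None = None) -> CaribouYear:
    th = g["t"].astype("int64").to_numpy() / 3.6e12
    duration = (th[-1] - th[0]) / 24.0
    max_gap = float(np.max(np.diff(th)) / 24.0) if len(th) > 1 else np.inf
    return CaribouYear(
        animal_id=animal_id,
        year_start=year_start,
        df=g.reset_index(drop=True),
        nominal_interval_h=interval_h if interval_h is not None else _infer_interval_h(th),
        duration_days=float(duration),
        max_gap_days=max_gap,
        passed_qc=bool(duration >= MIN_DURATION_DAYS and max_gap <= MAX_GAP_DAYS),
    )


def split_analysis_years(
    traj: Trajectory, tz: str = "America/Anchorage"
) -> list[CaribouYear]:
    """Partition a trajectory at local July 1 boundaries.

    Each resulting year records its data duration, worst gap and whether it
    passes the completeness screens. Years with fewer than two fixes are
    omitted (logged).
    """
    df = traj.df.copy()
    df["t"] = df["t"].dt.tz_convert(tz)
    starts = df["t"].map(_analysis_year_start)
    out: list[CaribouYear] = []
    for ys, g in df.groupby(starts, sort=True):
        if len(g) < 2:
            log.info("animal %s year %s has <2 fixes; omitted", traj.animal_id, ys.year)
            continue
        out.append(_make_year(traj.animal_id, ys, g))
    return out


def resample_to_interval(
    cy: CaribouYear,
    target_interval_h: float,
    tolerance_h: float | None = None,
) -> CaribouYear:
    """Thin a year to a coarser fix interval on a midnight-anchored grid.

    Grid times run every ``target_interval_h`` hours from local midnight
    (a 12-h grid yields 00:00 and 12:00, i.e. at most two fixes per day);
    each grid slot takes the nearest fix within ``tolerance_h`` (default
    half the target interval) and a fix can serve only one slot.
    """
    if target_interval_h < cy.nominal_interval_h:
        log.warning(
            "target interval %.1f h finer than nominal %.1f h; result will be sparse",
            target_interval_h, cy.nominal_interval_h,
        )
    tol = target_interval_h / 2.0 if tolerance_h is None else tolerance_h
    df = cy.df
    t = df["t"]
    day0 = t.iloc[0].normalize()
    day1 = t.iloc[-1].normalize() + pd.Timedelta(days=1)
    grid = pd.date_range(day0, day1, freq=pd.Timedelta(hours=target_interval_h))
    grid = grid[(grid >= t.iloc[0]) & (grid <= t.iloc[-1])]
    th = t.astype("int64").to_numpy() / 3.6e12
    gh = grid.astype("int64").to_numpy() / 3.6e12

    pos = np.searchsorted(th, gh)
    left = np.clip(pos - 1, 0, len(th) - 1)
    right = np.clip(pos, 0, len(th) - 1)
    pick = np.where(np.abs(th[left] - gh) <= np.abs(th[right] - gh), left, right)
    dist = np.abs(th[pick] - gh)
    ok = dist <= tol
    pick, dist = pick[ok], dist[ok]
    # One slot per fix: keep the closest grid assignment for each fix.
    order = np.argsort(dist, kind="stable")
    seen: dict[int, bool] = {}
    keep = []
    for j in order:
        if pick[j] not in seen:
            seen[pick[j]] = True
            keep.append(pick[j])
    idx = np.sort(np.asarray(keep, dtype=int))
    g = df.iloc[idx]
    if len(g) < 2:
        raise DegenerateTrajectoryError(
            f"{cy.animal_id!r} {cy.year}: resampling left <2 fixes"
        )
    return _make_year(cy.animal_id, cy.year_start, g, interval_h=float(target_interval_h))


def qc_report(years: list[CaribouYear]) -> pd.DataFrame:
    """One row per caribou-year: duration, worst gap, fix interval, QC flag."""
    return pd.DataFrame(
        {
            "animal_id": [cy.animal_id for cy in years],
            "year": [cy.year for cy in years],
            "n_fixes": [len(cy) for cy in years],
            "nominal_interval_h": [cy.nominal_interval_h for cy in years],
            "duration_days": [round(cy.duration_days, 2) for cy in years],
            "max_gap_days": [round(cy.max_gap_days, 2) for cy in years],
            "passed_qc": [cy.passed_qc for cy in years],
        }
    )


def apply_exclusions(
    years: list[CaribouYear], exclusions: set[tuple[str, int]]
) -> list[CaribouYear]:
    """Drop curated (animal_id, year) pairs, e.g. herd-switching years."""
    return [cy for cy in years if (cy.animal_id, cy.year) not in exclusions]
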