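"""Migration distance, directedness, timing and group comparisons.

Path distance sums consecutive planar steps over the migratory period on a
track standardized to at most two fixes per day (path length grows with
sampling rate, so all years must contribute at the same rate); Euclidean
distance is the straight line from the first to the last fix of the season.
Directedness (the straightness index) is their ratio — 1 for a perfectly
straight migration, near 0 for a looping one.

Group differences across wintering areas use the Kruskal-Wallis rank sum
test with a Siegel–Castellan style multiple comparison on mean ranks;
fall-vs-spring contrasts within individuals use the Wilcoxon signed-rank
test (the paired analogue of the Mann-Whitney test).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .classify import SeasonalBoundaries
from .telemetry import CaribouYear

__all__ = [
    "MigrationMetrics",
    "migration_distances",
    "kruskal_wallis_mc",
    "paired_season_test",
]


@dataclass
class MigrationMetrics:
    """Distance and timing summary for one migrant season."""

    animal_id: str
    year: int
    season: str  # fall | spring
    start_day: float
    end_day: float
    duration_days: float
    path_km: float
    euclid_km: float
    directedness: float


def migration_distances(
    cy: CaribouYear,
    boundaries: SeasonalBoundaries,
    season: str,
) -> MigrationMetrics:
    """Path/Euclidean distance and directedness for one migration season.

    ``cy`` should already be standardized to at most two fixes per day
    (12-hour resampling); the function operates on whatever fixes it is
    given.
    """
    if season == "fall":
        d0, d1 = boundaries.fall_start, boundaries.fall_end
    elif season == "spring":
        d0, d1 = boundaries.spring_start, boundaries.spring_end
    else:
        raise ValueError(f"unknown season {season!r}")
    days = (cy.df["t"] - cy.year_start).dt.total_seconds().to_numpy() / 86400.0
    sel = (days >= d0) & (days <= d1)
    if sel.sum() < 2:
        raise ValueError(
            f"{cy.animal_id} {cy.year} {season}: fewer than 2 fixes in season"
        )
    x = cy.df["x"].to_numpy(float)[sel] / 1000.0
    y = cy.df["y"].to_numpy(float)[sel] / 1000.0
    path = float(np.sum(np.hypot(np.diff(x), np.diff(y))))
    euclid = float(np.hypot(x[-1] - x[0], y[-1] - y[0]))
    directedness = euclid / path if path > 0 else 1.0
    ds = days[sel]
    return MigrationMetrics(
        animal_id=cy.animal_id, year=cy.year, season=season,
        start_day=float(ds[0]), end_day=float(ds[-1]),
        duration_days=float(ds[-1] - ds[0]),
        path_km=path, euclid_km=euclid, directedness=directedness,
    )


def kruskal_wallis_mc(
    groups: dict[str, np.ndarray],
    alpha: float = 0.05,
) -> tuple[float, float, set[tuple[str, str]]]:
    """Kruskal-Wallis test plus a mean-rank multiple comparison.

    Returns the tie-corrected H statistic, its chi-square p-value, and the
    set of group pairs whose mean-rank difference exceeds the
    Siegel–Castellan critical value at family-wise level ``alpha``:

        |R̄_i − R̄_j| ≥ z(α / (g(g−1))) · sqrt(N(N+1)/12 · (1/n_i + 1/n_j))
    """
    labels = sorted(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    vals = [np.asarray(groups[g], dtype=float) for g in labels]
    for g, v in zip(labels, vals):
        if len(v) == 0:
            raise ValueError(f"group {g!r} is empty")
    pooled = np.concatenate(vals)
    if np.ptp(pooled) == 0:  # scipy refuses all-identical input
        H, p = 0.0, 1.0
    else:
        H, p = stats.kruskal(*vals)
    ranks = stats.rankdata(pooled)
    N = len(pooled)
    mean_ranks = {}
    start = 0
    for g, v in zip(labels, vals):
        mean_ranks[g] = float(np.mean(ranks[start : start + len(v)]))
        start += len(v)
    g_count = len(labels)
    z = stats.norm.ppf(1.0 - alpha / (g_count * (g_count - 1)))
    sig: set[tuple[str, str]] = set()
    for a, b in combinations(labels, 2):
        crit = z * np.sqrt(N * (N + 1) / 12.0 * (1.0 / len(groups[a]) + 1.0 / len(groups[b])))
        if abs(mean_ranks[a] - mean_ranks[b]) >= crit:
            sig.add((a, b))
    return float(H), float(p), sig


def paired_season_test(
    fall_values: np.ndarray,
    spring_values: np.ndarray,
    pairing_keys: list | None = None,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired fall/spring values.

    Values are paired by caribou-year (``pairing_keys`` documents the
    pairing; lengths must agree). Zero differences are dropped, ties get
    mid-ranks, and the exact null distribution is used for n ≤ 25.
    ``alternative='less'`` tests fall < spring.
    """
    f = np.asarray(fall_values, dtype=float)
    s = np.asarray(spring_values, dtype=float)
    if len(f) != len(s):
        raise ValueError("fall and spring values must pair one-to-one")
    if pairing_keys is not None and len(pairing_keys) != len(f):
        raise ValueError("pairing_keys length mismatch")
    d = s - f
    nz = d[d != 0]
    if len(nz) < 1:
        raise ValueError("no nonzero paired differences")
    method = "exact" if len(nz) <= 25 else "approx"
    res = stats.wilcoxon(f, s, zero_method="wilcox", method=method,
                         alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def metrics_table(metrics: list[MigrationMetrics]) -> pd.DataFrame:
    """Flat per-season table (one row per migrant-season)."""
    return pd.DataFrame([m.__dict__ for m in metrics])
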