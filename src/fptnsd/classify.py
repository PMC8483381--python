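"""Migrant / resident / other classification from segments and NSD.

A year counts as migration when it shows discrete summer and winter ranges
and a there-and-back return movement; residency when the winter-period
range stays on (or next to) the summer range; anything else — nomadic
drift, one-way shifts — is "other". No minimum migration distance is
imposed. The rules below are explicit, configurable surrogates for what is
often done by expert review of FPT segment plots and NSD curves:

1. no sedentary (high-FPT) winter period of at least ``d_min_days`` days
   whose timing falls in the winter window → other (nomadic);
2. winter and summer ranges (convex hulls buffered ``buffer_m``) overlap by
   at least ``theta_overlap`` of the smaller range and their centroids sit
   within ``delta_res_km`` → resident;
3. otherwise, the year-start NSD over the final two weeks must fall below
   ``theta_return`` times its winter mean (the animal came back) → migrant;
   if not → other (one-way shift).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint
from statsmodels.stats.proportion import proportion_confint

from .fpt import FptProfile
from .segmentation import Segmentation
from .telemetry import CaribouYear

__all__ = [
    "ClassifierConfig",
    "SeasonalBoundaries",
    "MovementClassification",
    "ProportionEstimate",
    "detect_winter_range",
    "classify_year",
    "derive_seasons",
    "population_median_seasons",
    "wilson_ci",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """Rule constants of the classifier (all surrogates for expert review)."""

    d_min_days: float = 30.0        # minimum sedentary winter duration
    window_start_day: float = 92.0  # Oct 1 as days since Jul 1
    window_end_day: float = 318.0   # May 15
    theta_overlap: float = 0.05     # range-overlap fraction for residency
    delta_res_km: float = 15.0      # centroid displacement cap for residency
    theta_return: float = 0.25      # return criterion on year-start NSD
    buffer_m: float = 2_000.0       # hull buffer for seasonal range polygons
    summer_end_day: float = 76.0    # Sep 15: summer-range fixes are Jul 1..here
    # high/low segment split: segment means (log FPT) are clustered into
    # two groups; only a between-cluster gap of at least this many log
    # units marks the year as containing transit, otherwise every segment
    # counts as range use (within-range means wander ~1 log unit on their
    # own, while even slow coastal migration sits >1 log unit below range)
    high_spread_min: float = 1.0
    return_window_days: float = 14.0
    # truncated records (collar failure/mortality after the 290-day screen):
    # a return merely underway still counts if the post-winter NSD dropped
    # clearly below its winter level; within-range wander alone rarely dips
    # below ~0.75 of the winter mean, so 0.7 separates the two
    truncated_end_day: float = 360.0
    theta_partial_return: float = 0.7


class SeasonalBoundaries:
    """Season boundaries as days since the July 1 opening the analysis-year.

    Adjacent seasons share an instant internally (``fall_end ==
    winter_start``); reports print non-overlapping calendar ranges by
    advancing the shared day. ``source`` records whether the boundaries are
    the individual's own or population medians.
    """

    def __init__(self, fall_start, winter_start, winter_end, spring_end,
                 source="individual"):
        if not (fall_start < winter_start <= winter_end < spring_end):
            raise ValueError(
                "seasons must be ordered: fall_start < winter_start <= "
                "winter_end < spring_end"
            )
        self.fall_start = float(fall_start)
        self.winter_start = float(winter_start)
        self.winter_end = float(winter_end)
        self.spring_end = float(spring_end)
        self.source = source

    fall_end = property(lambda self: self.winter_start)
    spring_start = property(lambda self: self.winter_end)

    def date(self, day: float, year_start: pd.Timestamp) -> pd.Timestamp:
        return year_start + pd.Timedelta(days=float(day))

    def as_days(self) -> tuple[float, float, float, float]:
        return (self.fall_start, self.winter_start, self.winter_end,
                self.spring_end)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"SeasonalBoundaries(fall {self.fall_start:.1f}-{self.fall_end:.1f}, "
            f"winter -{self.winter_end:.1f}, spring -{self.spring_end:.1f}, "
            f"{self.source})"
        )


@dataclass
class MovementClassification:
    """Label and supporting evidence for one caribou-year."""

    animal_id: str
    year: int
    label: str  # migrant | resident | other
    rule_trace: str
    winter_span: tuple[int, int] | None  # fix-index span [start, end]
    boundaries: SeasonalBoundaries | None = None
    summer_range_poly: object = None
    winter_range_poly: object = None
    overlap_fraction: float = np.nan
    centroid_km: float = np.nan
    extras: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ProportionEstimate:
    """A proportion with its Wilson score interval."""

    k: int
    n: int
    p_hat: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05


def wilson_ci(k: int, n: int, alpha: float = 0.05) -> ProportionEstimate:
    """Wilson score interval for a binomial proportion."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must satisfy 0 <= k <= n")
    lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
    return ProportionEstimate(k=int(k), n=int(n), p_hat=k / n,
                              ci_low=float(lo), ci_high=float(hi), alpha=alpha)


def _segment_times(cy: CaribouYear, seg: Segmentation) -> np.ndarray:
    """Temporal bounds of each segment as days since year start."""
    t = cy.df["t"]
    days = (t - cy.year_start).dt.total_seconds().to_numpy() / 86400.0
    fb = np.clip(seg.fix_bounds(), 0, len(days) - 1)
    return days[fb]


def _high_segments(seg: Segmentation, cfg: ClassifierConfig) -> np.ndarray:
    """Which segments reflect sedentary range use (vs transit).

    Segment means (log FPT) are split into two groups by exact 1-D 2-means;
    the split is accepted as a transit/range division only when the two
    cluster means sit at least ``high_spread_min`` log units apart.
    Otherwise the year contains no transit and every segment is range use.
    """
    means = seg.segment_means
    if seg.K < 2:
        return np.ones(seg.K, dtype=bool)
    order = np.argsort(means)
    srt = means[order]
    best = None
    for cut in range(1, seg.K):  # exact 2-means on sorted values
        lo, hi = srt[:cut], srt[cut:]
        wss = np.sum((lo - lo.mean()) ** 2) + np.sum((hi - hi.mean()) ** 2)
        if best is None or wss < best[0]:
            best = (wss, float(hi.mean() - lo.mean()), float(srt[cut - 1]))
    _, gap, cut_value = best
    if gap < cfg.high_spread_min:
        return np.ones(seg.K, dtype=bool)
    return means > cut_value


def detect_winter_range(
    seg: Segmentation,
    fpt: FptProfile,
    cy: CaribouYear,
    cfg: ClassifierConfig = ClassifierConfig(),
) -> tuple[int, int] | None:
    """Locate the sedentary winter period, if any.

    Maximal runs of consecutive high-FPT (range-use) segments whose
    temporal midpoints fall in the winter window (Oct 1 – May 15 by
    default) are candidates; the longest run lasting at least
    ``d_min_days`` is returned as a fix-index span, or None.
    """
    high = _high_segments(seg, cfg)
    tb = _segment_times(cy, seg)  # segment bounds in days, len K+1
    mids = 0.5 * (tb[:-1] + tb[1:])
    candidate = high & (mids >= cfg.window_start_day) & (mids <= cfg.window_end_day)
    runs: list[tuple[int, int]] = []
    i = 0
    while i < seg.K:
        if candidate[i]:
            j = i
            while j + 1 < seg.K and candidate[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    best = None
    best_dur = -1.0
    for i, j in runs:
        dur = tb[j + 1] - tb[i]
        if dur >= cfg.d_min_days and dur > best_dur:
            best_dur = dur
            best = (i, j)
    if best is None:
        return None
    fb = seg.fix_bounds()
    return int(fb[best[0]]), int(min(fb[best[1] + 1] - 1, len(cy) - 1))


def _range_polygon(df: pd.DataFrame, idx: np.ndarray, buffer_m: float):
    pts = MultiPoint(list(zip(df["x"].to_numpy()[idx], df["y"].to_numpy()[idx])))
    return pts.convex_hull.buffer(buffer_m)


def classify_year(
    cy: CaribouYear,
    seg: Segmentation,
    fpt: FptProfile,
    nsd_year: np.ndarray,
    cfg: ClassifierConfig = ClassifierConfig(),
) -> MovementClassification:
    """Apply the migrant/resident/other rules to one caribou-year."""
    days = (cy.df["t"] - cy.year_start).dt.total_seconds().to_numpy() / 86400.0
    span = detect_winter_range(seg, fpt, cy, cfg)
    base = dict(animal_id=cy.animal_id, year=cy.year)
    if span is None:
        return MovementClassification(
            label="other", rule_trace="no-winter-range:nomadic",
            winter_span=None, **base,
        )
    ws, we = span
    summer_idx = np.flatnonzero(days <= cfg.summer_end_day)
    if len(summer_idx) < 3:
        summer_idx = np.arange(min(10, len(cy)))
    winter_idx = np.arange(ws, we + 1)
    sp = _range_polygon(cy.df, summer_idx, cfg.buffer_m)
    wp = _range_polygon(cy.df, winter_idx, cfg.buffer_m)
    inter = sp.intersection(wp).area
    denom = min(sp.area, wp.area)
    overlap = inter / denom if denom > 0 else 0.0
    c_s, c_w = sp.centroid, wp.centroid
    centroid_km = np.hypot(c_s.x - c_w.x, c_s.y - c_w.y) / 1000.0
    common = dict(
        winter_span=span, summer_range_poly=sp, winter_range_poly=wp,
        overlap_fraction=float(overlap), centroid_km=float(centroid_km),
    )
    if overlap >= cfg.theta_overlap and centroid_km < cfg.delta_res_km:
        return MovementClassification(
            label="resident", rule_trace="winter-overlaps-summer:resident",
            **common, **base,
        )
    # discrete ranges: did the animal come back?
    last_day = days[-1]
    tail = nsd_year[days >= last_day - cfg.return_window_days]
    winter_mean = float(np.mean(nsd_year[winter_idx]))
    tail_mean = float(np.mean(tail)) if len(tail) else np.inf
    if winter_mean > 0 and tail_mean < cfg.theta_return * winter_mean:
        mc = MovementClassification(
            label="migrant", rule_trace="discrete-ranges+return:migrant",
            **common, **base,
        )
        mc.boundaries = derive_seasons(mc, seg, fpt, cy, cfg)
        return mc
    # truncated record: the return leg may be underway when the collar dies
    post = nsd_year[we + 1 :]
    if (
        last_day < cfg.truncated_end_day
        and len(post)
        and winter_mean > 0
        and float(np.min(post)) < cfg.theta_partial_return * winter_mean
    ):
        mc = MovementClassification(
            label="migrant", rule_trace="truncated-return-underway:migrant",
            **common, **base,
        )
        mc.boundaries = derive_seasons(mc, seg, fpt, cy, cfg)
        return mc
    return MovementClassification(
        label="other", rule_trace="discrete-ranges-no-return:one-way",
        **common, **base,
    )


def derive_seasons(
    mc: MovementClassification,
    seg: Segmentation,
    fpt: FptProfile,
    cy: CaribouYear,
    cfg: ClassifierConfig = ClassifierConfig(),
) -> SeasonalBoundaries:
    """Season boundaries for a migrant year from its segments.

    Fall migration runs from the end of the last sedentary summer segment to
    the first winter fix; spring runs from the last winter fix to the start
    of the first sedentary post-winter segment (or the record end for
    truncated years).
    """
    if mc.label != "migrant":
        raise ValueError("seasons are derived only for migrant years; "
                         "use population medians otherwise")
    ws, we = mc.winter_span
    days = (cy.df["t"] - cy.year_start).dt.total_seconds().to_numpy() / 86400.0
    high = _high_segments(seg, cfg)
    fb = seg.fix_bounds()
    winter_start_d = days[ws]
    winter_end_d = days[min(we, len(days) - 1)]

    # last high segment ending at or before the winter span
    fall_start_d = days[0]
    for k in range(seg.K):
        if high[k] and fb[k + 1] - 1 <= ws and fb[k + 1] - 1 < len(days):
            end_idx = min(int(fb[k + 1]), len(days) - 1)
            if days[end_idx] < winter_start_d:
                fall_start_d = days[end_idx]
    # first high segment starting after the winter span
    spring_end_d = None
    for k in range(seg.K):
        if high[k] and fb[k] > we:
            spring_end_d = days[min(int(fb[k]), len(days) - 1)]
            break
    if spring_end_d is None or spring_end_d <= winter_end_d:
        jun2 = 336.0  # Jun 2 as days since Jul 1 (non-leap)
        before = days[days < jun2]
        spring_end_d = float(before[-1]) if len(before) else float(days[-1])
    if spring_end_d <= winter_end_d:
        spring_end_d = winter_end_d + 1.0
    if fall_start_d >= winter_start_d:
        fall_start_d = max(days[0], winter_start_d - 1.0)
    return SeasonalBoundaries(fall_start_d, winter_start_d, winter_end_d,
                              spring_end_d, source="individual")


def population_median_seasons(
    mcs: list[MovementClassification],
) -> SeasonalBoundaries:
    """Element-wise median season boundaries over migrant years.

    These medians define winter for residents and other non-migratory years,
    whose own records carry no usable breakpoints.
    """
    mig = [m for m in mcs if m.label == "migrant" and m.boundaries is not None]
    if not mig:
        raise ValueError("no migrant years: population medians undefined")
    arr = np.array([m.boundaries.as_days() for m in mig])
    med = np.median(arr, axis=0)
    if not (med[0] < med[1] <= med[2] < med[3]):  # pathological mixtures
        med = np.sort(med)
        med[1] = max(med[0] + 0.5, med[1])
        med[3] = max(med[2] + 0.5, med[3])
    return SeasonalBoundaries(*med, source="population_median")
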