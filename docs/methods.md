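# Methods

This note documents the models and procedures implemented in `fptnsd`, the
defaults and why they sit where they do, and the limits of what the test
suite establishes.

## Data model and screening

A *caribou-year* is one animal's relocations from July 1 through June 30
(boundaries evaluated in a configurable timezone, default
America/Anchorage; the convention starts the year just after calving).
Screens follow standard practice for this system: duplicate id+timestamp
records collapse to the first occurrence; out-and-back positional spikes
are removed iteratively when both adjacent implied speeds exceed
`rate_max_kmh` (default 15 km/h) and the turning-angle cosine falls below
`spike_cos_max` (default −0.97) — filters of this kind are
described in the literature only by citation, so both constants are config-exposed; a year is
retained only with ≥ 290 days of data and no gap over 14 days. Mixed
collar schedules are standardized by nearest-fix resampling onto a
midnight-anchored grid (a 12-h grid keeps at most two fixes per day, near
00:00 and 12:00 local; tolerance defaults to half the target interval).
Known herd-switching years are an input-curation exclusion list, not a
computed filter.

All geometry runs in meters on an Albers equal-area plane. The default is
a study-area Albers (standard parallels 66.5° and 71°N, origin 69°N
153.5°W, GRS80): with the statewide parallels (55°/65°) north–south
distances at 70°N are distorted by >1%, while the study-area parallels
keep planar distances within a few tenths of a percent of geodesics. The
statewide parameter set remains available as `ALASKA_ALBERS` for working
with statewide rasters.

## FPT, scale selection, segmentation

FPT is symmetric (backward + forward passage), with the crossing instant
solved exactly on the straddling segment under constant within-segment
speed; it is undefined where the record ends inside the circle. The
analysis radius maximizes the population mean variance of ln FPT over a
1–30 km grid (ties to the smaller radius; radii with no defined FPT are
dropped). For this system the conventional radius is 9 km, which
`DEFAULT_RADIUS_M` encodes; `select_scale` recomputes it when wanted.

Segmentation uses a piecewise-constant-mean model fitted by exact dynamic
programming under a minimum segment length (`Lmin` = 10 fixes, `Kmax` =
20). Two deliberate choices:

* **Log scale.** The DP runs on ln FPT. Passage times within ranges are
  strongly right-skewed (hundreds of hours with e-fold fluctuation);
  on the raw scale that variance swamps the migration/range contrast and
  the model underfits K. The log scale is also the scale on which the
  radius-selection variance is defined.
* **Choice of K.** A Lavielle-style elbow on the normalized contrast
  (second difference > ρ, default 0.75) plus a support condition: a
  candidate K must reduce the contrast by at least
  `support_factor · σ̂² · ln n` (default factor 3, σ̂² the residual
  variance at Kmax). Without the support condition, shallow pure-noise
  contrast curves get inflated by the normalization and trip the elbow;
  with it, i.i.d. noise yields K = 1 in ≥ 90% of simulations while real
  season structure (contrast drops orders of magnitude larger) is
  unaffected. Ends of the series with undefined FPT are trimmed (an
  offset maps back to fix indices); interior gaps are bridged linearly
  for the contrast only.

## Classification rules

Classifications of this kind conventionally rest on expert review of FPT
segment plots and NSD curves. `fptnsd` replaces that review with explicit
rules whose constants live in `ClassifierConfig`, justified by recovery on
synthetic ground truth (94–97% label agreement at default noise, ≥ 95%
at zero noise):

1. **Winter range detection.** Segment means (log FPT) are split into two
   groups by exact 1-D 2-means; the split counts as a transit/range
   division only if the cluster gap is ≥ `high_spread_min` = 1 log unit
   (within-range segment means wander ~1 log unit on their own, while even
   the slowest coastal migration sits > 1 log unit below range use — a
   fixed threshold such as "above the year median" fails precisely when
   range occupancy dominates the year, because the median then falls in
   the middle of the range-FPT distribution). Runs of consecutive
   range-use segments whose midpoints fall in the Oct 1 – May 15 window
   qualify; the longest run ≥ 30 days is the winter span. No span →
   *other* (nomadic).
2. **Residency.** Summer (Jul 1 – Sep 15 fixes) and winter range polygons
   are buffered convex hulls (2 km). Overlap ≥ 5% of the smaller polygon
   *and* centroids within 15 km → *resident*.
3. **Return criterion.** Otherwise the year is migratory in shape; it is
   *migrant* if the year-start NSD over the final 14 days falls below
   0.25× its winter-span mean (the animal came back). A truncated record
   (ending before day 360; collar failure and mortality years ≥ 290 days
   are retained by design) still counts as migrant when the post-winter
   NSD minimum drops below 0.7× the winter mean — a return underway at
   collar death, which within-range wander alone (dips rarely below
   ~0.75×) does not mimic. Anything else → *other* (one-way). No distance
   threshold is imposed anywhere.

Season boundaries for migrants come from the segmentation (fall = end of
the last summer range segment to the first winter fix; spring = last
winter fix to the first post-winter range segment, falling back to the
record end for truncated years); residents and others inherit the
population median boundaries. Reports print adjacent seasons as
non-overlapping calendar ranges by advancing the shared day.

## Migration metrics and tests

Path and Euclidean distance are computed on the ≤ 2-fixes/day
standardized track, because path length grows with sampling rate;
directedness is their ratio. Kruskal–Wallis (tie-corrected H, chi-square
p) compares wintering-area groups, with pairwise mean-rank differences
against the Siegel–Castellan critical value at family α = 0.05 (the exact
multiple-comparison procedure in the source literature is not fully
specified; this is the standard reading, config-overridable). The paired
fall-vs-spring contrast is the Wilcoxon signed-rank test — the standard
paired analogue of the Mann–Whitney test — exact null for n ≤ 25.

## Winter UDs, areas, assignment, fidelity

The UD is an exact Gaussian kernel sum evaluated on a regular grid
(separable per-point products, chunked; unit mass by grid
renormalization; extent padded 3 bandwidths). h_ref = σ·n^(−1/6) with σ
the RMS coordinate SD. The ad hoc bandwidth rule steps h down by 5% of
h_ref and keeps the smallest h at which the chosen isopleth (default 95%)
neither fragments into more polygons than at h_ref nor develops interior
holes, flooring at 0.5·h_ref (the cited rule is described only by
citation; this operationalization is config-exposed). Isopleths are
density super-level sets holding the stated mass, polygonized by marching
squares (with a cell-union fallback for degenerate few-cell sets).

Wintering areas take the 50% contour north of the region divide and the
85% contour south of it, labeled W/E by centroid against the region
meridian; the divide and meridian are required configuration (synthetic
runs derive them from the generator's area centers). Assignment is by
greatest individual-UD mass inside an area polygon, else nearest area by
edge-to-edge distance from the individual's 95% contour. State sequences
count transitions only between strictly consecutive analysis-years
(a flag allows any-next-observed-year); coarse counts aggregate fine
counts exactly, and probabilities are reported at 2 dp with raw values
retained.

## The synthetic generator

The generator is the study-conditions stand-in: class mixture 129:19:16
(migrant:resident:other), fix-interval mixture 120:17:10:17 over
2/3/8/12 h, 1–8 consecutive years per individual (mean ≈ 2.2, ~51%
multi-year), season timing centered on the medians reported for this herd (fall
Sep 28 – Nov 10, winter to May 1, spring May 2 – Jun 1, SDs 4–8 days),
four wintering-area centers at 128–520 km from the summer range (Coastal
near, Brooks far), a wintering-area Markov chain with the herd's
reported two-decimal transition rows renormalized, 30 m positional noise, a 30%
chance of one 1–10 day outage, and a 10% chance of truncation to 295–355
days. Movement kernels: mean-reverting (discrete OU) wander within ranges
(per-axis SD 6 km — a ~24 km 95% range span, inside the residency
displacement cap — and 20-day decorrelation, i.e. ~2.5 km/day drift, so a
9-km circle takes days to cross in range but hours in transit);
migration legs are straight-line bridges plus AR(1) meander whose
amplitude is set so the leg's expected straightness ≈ the per-season
persistence (fall 0.46 < spring 0.72, the directedness means reported
for this herd).
"Other" splits 50/50 between nomadic drift (~2.5 km/day drifting center)
and one-way shifts.

What passing recovery tests shows: the pipeline's rules recover the
generating labels, seasons, areas and transition structure under
realistic noise, gaps, truncation and mixed schedules. What it does not
show: robustness to features the generator omits — habitat- or
snow-driven movement, mid-winter excursions between areas, collar duty
cycles that change within a season, spatial error bursts, or herds whose
range geometry differs from the four-center template.

## Problem sizes and numerical choices

Classifier-recovery runs use 300 caribou-years on a 12-hour fix schedule
(the coarsest interval in the study design, and the rate the distance
metrics standardize to); the CLI likewise classifies on the 12-h
standardized series by default, with native-resolution classification one
flag away. Population UDs default to 2-km cells with pooled winter fixes
thinned to ≤ 4000 points; individual UDs use 1-km cells. Assignment ties
break to the smaller edge distance, then lexicographic label; scale
selection ties break to the smaller radius; degenerate trajectories
(< 2 fixes after filtering) raise rather than propagate. Seeded runs are
byte-reproducible.

## Known limitations

* Rule constants approximate expert review; borderline years (e.g.
  truncated before any return movement is visible) are genuinely
  ambiguous and fall to *other*, which biases the migrant share downward
  by roughly 1–3 points in recovery runs — the same direction manual
  review would disagree with itself.
* The herd's 2-dp transition rows are renormalized for the generator's
  chain; the underlying integer counts are recovered exactly by
  exhaustive search in the tests, but third decimal places are not
  identifiable.
* The ad hoc bandwidth rule depends on grid resolution near the
  fragmentation point; very sparse individual winters (≈ 5–10 fixes) use
  the cell-union isopleth fallback.
* Season-boundary recovery is limited by segment granularity (`Lmin`
  fixes) and the fix interval; at 12-h data the fall start is typically
  recovered within ±4 days.
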