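# fptnsd

Movement classification and wintering-area fidelity analysis for partially
migratory ungulates tracked by GPS collars.

Arctic caribou herds mix strategies: most individuals migrate hundreds of
kilometers between a summer range on the coastal plain and one of several
discrete wintering areas, while others stay resident near the summer range
or wander without a stable winter range, and the same animal can switch
strategy between years. `fptnsd` implements the first passage time – net
squared displacement (FPT–NSD) pipeline that movement ecologists use to
turn multi-year collar files into annual strategy labels (migrant /
resident / other), migration metrics, wintering-area maps, and
between-year fidelity statistics. It is written for ecologists and
analysts working with Movebank-style telemetry CSVs.

## The method

For each *analysis-year* (July 1 → June 30 of one animal):

1. **First passage time.** FPT(i) is the time the path takes to leave a
   circle of radius *r* centered on relocation *i* (backward + forward,
   with the crossing instant interpolated on the straddling segment).
   Sedentary range use gives long passage times, directed transit short
   ones. The analysis radius *r\** maximizes the population mean variance
   of log FPT over a radius grid (9 km is the conventional default for
   this system); `select_scale` recomputes it from data.
2. **Segmentation.** The log-FPT series is partitioned into K
   homogeneous-mean segments by exact dynamic programming on the
   within-segment sum of squares, with K chosen by a Lavielle-style elbow
   on the normalized contrast (threshold ρ = 0.75) plus a noise-floor
   support condition.
3. **Net squared displacement.** NSD(i) = squared planar distance (km²)
   from the first fix of the year (and, in a second pass, from the first
   day of winter behavior). Plateaus mark range shifts; the return leg of
   a there-and-back migration brings the year-start NSD back down.
4. **Classification.** Explicit rules replace expert review: a sedentary
   winter period ≥ 30 days in the Oct 1 – May 15 window, seasonal range
   polygons (buffered convex hulls) that overlap → *resident*; discrete
   ranges with the year-start NSD returning below 0.25× its winter mean →
   *migrant*; everything else → *other*. No minimum migration distance is
   imposed.
5. **Migration metrics.** On tracks standardized to ≤ 2 fixes/day: path
   distance Σ|Δx|, Euclidean distance, duration, and directedness
   (straightness index) = Euclidean / path ∈ (0, 1]. Group contrasts use
   Kruskal–Wallis with a Siegel–Castellan mean-rank multiple comparison;
   fall-vs-spring contrasts use the Wilcoxon signed-rank test.
6. **Wintering areas and fidelity.** A population-level kernel utilization
   distribution (bivariate normal kernel, ad hoc bandwidth stepped down
   from h_ref = σ·n^(−1/6)) is cut at the 50% isopleth on the high-density
   coastal plain and the 85% isopleth in the Brooks Range; each
   caribou-year is assigned to the area holding the greatest share of its
   individual UD mass (edge-to-edge distance from its 95% contour as the
   fallback), and per-animal state sequences yield row-stochastic
   transition matrices at coarse (Coastal/Brooks) and fine (four-area)
   scales.

A calibrated synthetic trajectory generator (`fptnsd.simulate`) emulates
the herd's structure — mean-reverting range wander, bridge-with-meander
migration legs whose straightness tracks a per-season persistence
parameter, a Markov chain over wintering areas, mixed 2/3/8/12-h collar
schedules, outages, and truncated years — and emits ground truth for every
year, so the whole pipeline is testable end to end.

## Worked example

```bash
fptnsd run-all --seed 5 --n-individuals 40 --out demo/
```

prints (about 20 s on one CPU):

```
{'n_years': 77, 'n_migrant': 62, 'n_resident': 6, 'n_other': 9,
 'pct_migrant': 80.5, 'pct_resident': 7.8, 'pct_other': 11.7}
```

i.e. 40 simulated animals contributed 77 analysis-years that passed the
completeness screens (≥ 290 days of data, no gap over two weeks), of which
80.5% were classified as migration. `demo/` then contains the full
bundle: per-year labels and season dates (`classification.csv`), the
migrant percentage per year with Wilson 95% CIs, migration metrics and
their nonparametric tests, the winter UD raster (`winter_ud.tif` + world
file), wintering-area polygons (GeoJSON), and the transition tables. The
recovered population-median season table for this run,

```
summer          fall_migration   winter           spring_migration
Jul 01 - Sep 28  Sep 29 - Nov 07  Nov 08 - May 02  May 03 - Jun 01
```

and the coarse-scale fidelity matrix,

```
                  Coastal (n = 26)  Brooks (n = 11)
Coastal (n = 25)              0.72             0.28
Brooks (n = 12)               0.67             0.33
```

show the characteristic pattern: coastal-plain winterers tend to stay
coastal, Brooks Range winterers tend to switch north the following year.

The same stages run on real data:

```bash
fptnsd classify --telemetry fixes.csv --out classification.csv
fptnsd run-all --telemetry fixes.csv --out results/
```

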