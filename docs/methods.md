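# Methods

## The estimation problem

Half-moon SWC structures are expected to raise vegetation greenness inside
the intervened polygons from their construction year onward. With no
baseline survey and no designated controls, the evidence must come from
the satellite record itself, through two complementary designs:

* a **pre/post comparison** of each site's annual peak greenness around
  its own intervention year, with seasonal rainfall tracked as the main
  confounder; and
* a **BACI (Before-After-Control-Impact) contrast** over retrospective
  control pairs: two polygons of one site intervened years apart, the
  later one acting as an untreated control for the earlier one until its
  own construction.

## NDVI extraction

NDVI = (NIR − Red)/(NIR + Red), computed per pixel; pixels whose QA flag
is cloudy/shadow/fill (or unknown — masked conservatively with a warning)
are dropped. A pixel belongs to a polygon when its center falls inside the
geometry (deterministic, resolution-honest at 30 m given the ≥13 ha
polygons analyzed). Polygon means are taken over valid pixels only, and a
record with zero valid pixels is missing, never zero. No minimum
valid-pixel fraction is enforced at extraction; screening happens at
compositing so the threshold is a single knob (`min_valid_fraction`,
default 0.5).

Scenes live on one shared grid. Geotransforms follow the GDAL convention
(outer corner of pixel (0,0); half-open pixel intervals; north-up). The
CRS is carried as an identifier and validated for equality between scenes
and polygons; the package performs no reprojection — inputs must already
share a projected CRS. Reflectance is accepted as [0,1] floats.

## Temporal statistics

* **Monthly composite**: arithmetic mean of the scene-level polygon NDVI
  values in the calendar month that clear `min_valid_fraction`.
  Max-value compositing is deliberately not used; the downstream
  comparisons are defined on average greenness.
* **Annual peak**: the 95th percentile (linear interpolation between
  order statistics) of scene-level polygon-mean NDVI within the Aug–Oct
  window of each year. The percentile is taken over polygon means, not
  pooled pixels, matching the aggregate-then-analyze order of the rest of
  the pipeline; `annual_peak_pixelpool` provides the pixel-pooling
  variant for sensitivity checks. A high percentile rather than the
  maximum damps single-scene artifacts that survive QA masking.

## Pre/post analysis

For each polygon, "before" runs from the study start to the year
preceding its intervention and "after" from the following year to the
study end; the intervention year itself is excluded from both (construction
happens mid-season and would contaminate either side). Polygons intervened
in the final study year have no after-sample and are excluded. Site values
average polygon-year peaks with equal polygon weight (not area-weighted);
the cross-polygon standard error is reported alongside.

Percent differences are sign-preserving: 100·(after − before)/before.
Rainfall enters as the Jun–Aug pentad total (the two months preceding plus
the first month of the peak window), averaged over each period's years,
and as standardized annual anomalies (total − long-term mean)/long-term
SD. Significance uses a two-tailed Welch t-test on the annual peak samples
(the unequal-variance form is the safer default; the pooled-variance
variant is a parameter). The NDVI~rainfall relationship is ordinary least
squares with R² = squared Pearson correlation.

The bundled published site table reproduces to rounding error with one
caveat: one site's rainfall declined between periods, but the source
prints that cell unsigned; the sign-preserving recomputation therefore
gives a grand-mean rainfall change of 12.1% against the printed 12.3%.
The package reports the signed value.

## Control pairing and BACI

Pairs require: same site (shared weather and practices), same livelihood
zone (comparable vegetation), interventions ≥ 3 years apart, and both
areas ≥ 13 ha (≈150 Landsat pixels) for stable polygon means. Every
qualifying combination is emitted — the pair is the analysis unit — in a
deterministic order. Baseline period: study start through the experiment
member's intervention year (year-level granularity); experiment period:
the following year through the control member's intervention year; later
years are excluded. Period means use monthly composites over all calendar
months, so they sit well below peak values.

BACI contrast = (mean control change) − (mean experiment change) across
pairs; negative when the intervened member gains more. Relative contrast
divides by the experiment members' mean baseline NDVI. Uncertainty comes
from resampling pairs with replacement (default 50 iterations, fully
seeded) with a 2.5/97.5 percentile interval; the point estimate is always
the full-data contrast. Paired t-tests compare members within the
baseline (expected null) and experiment (expected signal) periods, and
the baseline-adjusted difference (experiment-period difference minus
baseline difference) is reported next to the raw one.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
on the study's scales:

| parameter | default | meaning |
|---|---|---|
| study span | 2010–2020 | 11 calendar years |
| revisit | 16 d | Landsat-7-like cadence, ~23 scenes/yr |
| grid | 128×128 px at 30 m | ~14.7 km² domain |
| sites × polygons | 4 × 3 | each polygon ≥ ~15 ha (≥150 px) |
| baseline NDVI | 0.12 | dry-season floor |
| seasonal amplitude | 0.22 | raised cosine peaking 1 Sep → peak ≈ 0.34 |
| rainfall mean, SD | 450, 70 mm/yr | truncated-normal annual totals |
| rain coupling | 3·10⁻⁴ NDVI/mm | interannual greenness variability |
| cloud probability | 0.26 | per-pixel Bernoulli; ~74% availability |
| noise SD | 0.02 NDVI | per-pixel, per-scene Gaussian |
| effect size | +0.10 NDVI | step, Jun–Dec months, from intervention year |

Rainfall follows a fixed unimodal monthly climatology placing 92% of the
annual total in Jun–Sept, split into 6 pentads/month by a Dirichlet draw.
Intervention years rotate (2013, 2018, 2015, …) within each site so every
site contains a ≥3-year-gap pair and nothing is intervened in the final
year. The effect is a uniform step across the polygon during
growing-season months (Jun–Dec) — the pre/post divergence appears in the
wet season and persists into the dry-down, while early-dry-season months
match, as observed at real sites. Reflectance is synthesized by fixing
red at 0.2 and inverting the target NDVI for NIR; any pair with the right
ratio is equivalent downstream. All randomness derives from one seed via
independent substreams (rainfall, clouds, noise), so identical configs
are bit-identical.

What the generator does **not** emulate — and what passing recovery tests
therefore cannot attest about real imagery: radiometric realism
(atmosphere, BRDF), SLC-off stripe geometry (cloud gaps are
pixel-independent), spatial autocorrelation of noise and clouds,
within-polygon heterogeneity of the greening (real half-moons occupy part
of a polygon), soil-background effects, and spatially varying rainfall
(the rainfall grid is uniform, so the site-level NDVI~rain regression
degenerates on synthetic data and is skipped there).

## Numerical and design notes

* Percentiles: NumPy's `linear` method everywhere, including the peak
  statistic and bootstrap intervals.
* Degenerate inputs: identical zero-variance t-test samples return
  p = 1 with a warning rather than NaN; zero-denominator NDVI pixels,
  empty polygons and fully masked records are missing values; a zero
  rainfall SD or zero regression variance raises.
* The expected scene count of a month is the number of acquisitions
  actually falling in it, so availability is well defined for partial
  months at the record edges.
* The pipeline-level BACI contrast on synthetic data is attenuated
  relative to the injected step: period means average all 12 months while
  the effect spans 7, and the control member is itself intervened in the
  final experiment-period year. Bootstrap-recovery checks of the BACI
  machinery are therefore run on constructed pair summaries, where the
  injected effect maps 1:1 onto the expected contrast.
* Known limitation: with as few pairs as a real study yields (~7), the
  percentile bootstrap interval undercovers — measured ≈83% at 50
  iterations (≈87% at 1000) against a nominal 95%, consistent with the
  t-approximation P(|t₆| ≤ 1.96·√(6/7)) ≈ 0.88. Near-nominal coverage is
  reached only from a few dozen pairs. Interpret the 7-pair interval as
  descriptive, not calibrated; a studentized or BCa interval would be the
  upgrade path.
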