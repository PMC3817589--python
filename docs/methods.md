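# Methods

This note documents the models, parameter choices and numerical conventions
behind `fjordsurvey`, and what the synthetic surveys do and do not emulate.

## Survey geometry

Frame footprints follow the pinhole model $w = 2d\tan(\theta_h/2)$,
$h = 2d\tan(\theta_v/2)$ with the substrate plane perpendicular to the
optical axis; the survey protocol adapts vehicle pitch to keep it so, and no
obliquity or lens-distortion correction is applied. The camera's angles of
view are required configuration, not constants: they are not published for
the camera model used in this class of surveys, and the defaults (60° x 40°,
1920x1080 px) are plausible HD-camera values, not calibrated ones.

Frames are placed in an analysis coordinate system with depth positive down
on the y axis and one vertical lane per (site, transect) on an arbitrary x
axis. Lanes are ordered along the fjord (sites in axis order, down transect
before up) and pitched at 1.5x the widest frame, which guarantees lane
disjointness — transects sit next to each other but never overlap. Worldfiles
use the raster convention (y-up, negative pixel y-size): map y is negated
depth, and C/F address the centre of the upper-left pixel. Parameters are
written in fixed decimal notation with 17 significant digits, enough for a
written file to re-parse to the identical double; zeros are written `0.0`.

**Overlap exclusion.** The field rule is only "exclude overlapping frames";
the implementation is a deterministic greedy pass in acquisition order: a
frame is retained iff its rectangle's intersection with the union of
previously retained rectangles in its lane is at most `overlap_tolerance_m2`
(default 0). Rectangle set operations use shapely. The greedy rule is
order-respecting and reproducible; whether the original workflow dropped
partially overlapping frames or only fully redundant ones is unknown, so the
tolerance is a knob.

## Quantification conventions

One annotation row per frame is one patch (the aggregation within a single
frame); disjoint clusters inside a frame are not subdivided. Banks are
maximal runs of at least three consecutive patch-bearing retained frames
within a lane; a single coral-free frame breaks a run (no bridging), and
adjacency is positional, not geometric. Corals counted but not measurable
contribute to abundance only; shape summaries cover the measured subset.

## Depth binning

Bins are half-open $[10k, 10(k+1))$ labelled by centre; boundary depths fall
in the deeper bin. Surfaces are summed, coral and CTD parameters averaged.
Two abundance denominators are supported: mean count per retained frame
(default; area-stable and it preserves the zero-inflation of the raw data)
and mean count per patch-bearing frame. Substrate usage per bin is computed
from the summed areas, `100 * sum(cover) / sum(available)`, which is the
"fraction of settleable rock colonised" reading and is guaranteed to lie in
[0, 100]; the mean patch size is reported separately. 0/0 usage is missing,
cover on zero substrate is a data error. CTD values are joined to frames by
nearest depth within the same site and transect before averaging — the
choice of join is ours; profiles are smooth at the metre scale, so any
reasonable join is equivalent.

## Statistical layer

*Break split.* A bin whose interval contains the break depth (default 275 m,
the centre of the 270–280 m band) counts as "above"; otherwise bins split by
centre. Either side empty is an error.

*Wilcoxon rank-sum.* Midranks for ties; W is the rank sum of the above
group. Exact null distribution by full enumeration of the
$\binom{n}{n_a}$ rank assignments when the pooled $n \le 12$ with no ties;
otherwise the normal approximation with the standard tie correction, no
continuity correction (this matches the large-sample rank-sum statistic in
scipy, which the tests use as an independent cross-check). Two-sided p as
twice the smaller tail, capped at 1.

*Permutation test.* Statistic: difference of group means; default
alternative one-sided (above > below) because the scientific hypothesis is
directional. B random relabellings preserving group sizes;
$p = (1 + \#\{\text{perm} \ge \text{obs}\})/(B+1)$, which cannot return 0
and is slightly conservative by construction. Ties with the observed
statistic count as extreme (with a $10^{-12}$-scale tolerance so that exact
ties of a degenerate configuration are not lost to rounding). Seeded and
vectorised.

*Regressions.* Ordinary least squares via statsmodels, one predictor per fit
for the reporting table (a joint multiple fit is available through the same
function), adjusted $r^2$ from the closed form. Rows with missing response
or predictor drop pairwise, so a site with a dead salinity sensor simply
contributes no salinity rows. Surface-layer exclusion is depth-based (bin
centre shallower than the halocline depth, default 10 m) rather than
salinity-based, so it also works where salinity is missing.

## The synthetic fjord

The generator emulates the *structure* of the field data — seven sites with
the observed maximum depths, down+up vertical transects, frames on a regular
cadence, co-registered CTD casts, a four-layer water column, and a step drop
in coral density below a break depth — with every random draw governed by a
single seed.

Water column: four presets tiling the column — a brackish surface layer
(upper 7 m, lowest salinity, warm, high pH and oxygen), a subsurface pH and
oxygen dip below the halocline, near-uniform intermediate oceanic water, and
deep basin water below 300 m with the highest salinity and the column's pH
and oxygen minima (about 7.71 and 91 µmol/l at the bottom). Values are layer
mean plus within-layer linear gradient plus Gaussian noise (default SDs:
salinity 0.15, temperature 0.10 °C, pH 0.02, oxygen 3 µmol/l). A
`salinity_na_sites` option blanks a site's salinity to exercise
missing-value handling downstream.

Frames sit on a depth grid (`frames_per_metre`, default 1): the 10-s frame
cadence maps to depth through an assumed constant winch speed of about
0.1 m/s, which is simpler than a time grid and equivalent for testing.
Echo-sounder range is truncated-normal, 1.0 ± 0.2 m (free parameters; survey
range is not published).

Substrate: the fraction of a frame that is settleable rock is drawn **per
site x 10-m depth cell** (shared by both transects) from a Beta with mean
0.3 and concentration 0.35 — a strongly bimodal rock-or-sediment pattern.
The cell-level (rather than frame-level) draw is deliberate: rock patchiness
operates at scales larger than a single frame, and it is what makes
available substrate statistically unrelated to surface analysed (the
representativeness property of the survey design, bin-level $r^2 < 0.05$).
With per-frame fractions the two would share the footprint factor and
correlate strongly.

Corals: expected count per frame is `density x available substrate`, with
density 100 individuals per m² of rock above the break (dense-patch scale;
field reports reach 1500/m² on vertical walls) and density/`drop_factor`
below it (default drop 5). Counts are zero-inflated negative binomial:
occupancy 0.6 is the probability a frame holds corals at all, and occupied
frames draw NB counts (dispersion k = 2) whose mean is inflated by
1/occupancy so the unconditional mean is unchanged — field aggregation is
patchy, and no count distribution is prescribed by the study design. Cover
is `count x 0.002 m² x lognormal(0, 0.3)`, clipped at the available
substrate. About 30% of corals (capped at 30 per frame) carry length/width
measurements, lognormal length (median 6 cm) and lognormal shape ratio
(median 3).

Ground truth records the break depth, densities, and the exact expected
per-bin abundance given the deterministic frame depth grid; a Monte-Carlo
test over 200 seeds checks the generated data against it within 3 standard
errors.

**What the generator does not emulate:** imagery pixels, navigation error,
tides and currents, within-transect spatial autocorrelation of corals beyond
the substrate cells, species mixtures, or any causal link between the
environmental parameters and coral density (the break is a step in depth, not
in pH or oxygen). Passing tests therefore demonstrate that the pipeline
recovers known structure from data shaped like the field tables — not that
the field inference itself is re-derived.

## Calibration facts the tests rely on

- The permutation test's type-I error at α = 0.05 is slightly conservative
  (add-one estimator) and sits inside the binomial 95% band over 1000 null
  datasets at B = 500.
- With a five-fold drop below 275 m and at least 8 bins per side, the
  B = 10,000 permutation test rejects at α = 0.05 in ≥ 95% of 200 seeded
  surveys. The rank-sum test is noticeably weaker in this regime: the patchy
  substrate puts zero-abundance bins on both sides of the break, and
  midranked zeros carry no signal — one reason a permutation test on the mean
  difference is the right confirmation when the deep stations are few.
- The per-bin substrate-usage expectation has the closed form
  `density x footprint x exp(σ²/2)`; the cover-clip makes the realised value
  fall below it in near-barren cells (a single coral footprint can exceed the
  rock area), so the generator cross-check conditions on non-scarce bins.

## Problem sizes

Default test and acceptance runs use the full 7-site survey (~3500 frames)
for single-pipeline checks, a 2-site survey at 0.5 frames/m for the
200-replicate power study, and a 1-site survey for Monte-Carlo
ground-truth consistency; these sizes give stable Monte-Carlo estimates
while keeping the whole suite in the minutes range on one core.
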