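# fjordsurvey

Quantification and statistical analysis of ROV video transects for mapping
cold-water coral abundance along depth and physico-chemical gradients in a
stratified fjord — with a seeded synthetic-survey generator so that every
stage of the pipeline is testable end to end without field data.

The intended users are benthic ecologists and imaging-survey engineers who
turn vertically flown ROV video into per-depth-interval coral and substrate
statistics: how much wall was surveyed, how much settleable rock it held, how
much of that rock corals occupy, and whether abundance changes at a
hypothesised break depth.

## What it computes

**Frame scaling (pinhole photogrammetry).** A video frame shot at
echo-sounder range $d$ with horizontal/vertical angles of view $\theta_h,
\theta_v$ covers

$$w = 2d\tan(\theta_h/2), \qquad h = 2d\tan(\theta_v/2)$$

metres of wall (optical axis perpendicular to the substrate). Frames are
placed with depth on the $y$ axis, one lane per (site, transect) on an
arbitrary along-fjord $x$ axis, written as standard six-parameter ESRI
worldfiles (`.pgw`), and de-duplicated by greedy in-order exclusion of frames
whose rectangle intersects the union of previously retained frames in the
same lane.

**Quantities per retained frame.** Surface analysed, available (non-sediment)
substrate, coral patch size (the aggregation within one frame), coral count,
and shape $L/W$ per measurable individual. Patch runs spanning $\ge 3$
consecutive frames are coral banks.

**Depth binning.** Per site within half-open 10-m intervals, surfaces are
summed and coral/CTD parameters averaged; substrate usage is
$\%\,\mathrm{used} = 100\cdot\text{coral cover}/\text{available substrate}$.

**Statistics.** Above/below-break comparison of per-bin abundance with a
two-sample Wilcoxon rank-sum test (exact by enumeration for pooled $n \le
12$ without ties, tie-corrected normal otherwise) and a Monte-Carlo
permutation test with $B = 10{,}000$ relabellings and the add-one estimator
$p = (1 + \#\{\text{perm} \ge \text{obs}\})/(B+1)$; per-predictor OLS
regressions of coral parameters on the environment reporting adjusted
$r^2 = 1-(1-r^2)\frac{n-1}{n-p-1}$, optionally excluding the brackish
surface layer.

## Worked example

`examples/05_depth_bins_and_break_test.py` generates the default synthetic
fjord (7 sites, down+up transects, five-fold abundance drop below 275 m),
bins it, and tests the break:

```
183 site x 10-m-bin rows
...
abundance above vs below 275 m (159 / 24 bins):
  mean difference   18.54 corals per frame
  Wilcoxon          W = 14946, p = 0.182
  permutation       p = 0.0009  (B = 10000)
```

Read: pooling the sites gives 159 depth bins above the 275-m break and 24
below; mean abundance is 18.5 corals per frame higher above. The permutation
test on the mean difference detects the configured five-fold density drop
decisively, while the rank-sum test — diluted by the many zero-abundance
bins that the patchy substrate produces on both sides of the break — does
not; this is exactly why a permutation test is the right tool when the deep
stations are few. The other scripts in `examples/` walk through generation,
CTD summaries, georeferencing, quantification and the regression table; the
full chain is also available as one reproducible run
(`fjordsurvey run-all --seed 42 --out run/` or
`fjordsurvey.pipeline.run_pipeline`).

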