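"""Per-predictor regressions of coral parameters on the environment.

One OLS per environmental predictor (the tabular layout used for reporting),
with adjusted r^2 = 1 - (1 - r^2)(n - 1)/(n - p - 1); optionally the brackish
surface layer (bins shallower than the halocline) is excluded. The
representativeness check regresses available substrate on surface analysed:
a near-zero r^2 means sampling effort did not drive the substrate estimates.
"""

import fjordsurvey as fs
from fjordsurvey import binning, stats

config = fs.FjordConfig(seed=42)
dataset = fs.generate_survey(config)
bins = binning.bin_frames(dataset.frames, dataset.annotations, ctd=dataset.ctd)

print("response   predictor        window          adj r^2      n")
for response in ("abundance", "pct_used"):
    for predictor in ("pH", "oxygen_umol_l", "temperature_C", "salinity"):
        for exclude in (False, True):
            r = stats.regress(bins, response, predictor, exclude_surface=exclude)
            window = "excl. surface" if exclude else "whole column"
            print(f"{response:<10} {predictor:<16} {window:<15} {r.adjusted_r2:7.3f} {r.n:6d}")

rep = stats.regress(bins, "available_substrate_m2", "surface_analysed_m2")
print(f"\nrepresentativeness: available substrate ~ surface analysed, "
      f"r^2 = {rep.r2:.3f} (n = {rep.n})")
# In the synthetic fjord no environmental parameter drives abundance directly
# (the break is a step in depth), so adjusted r^2 values stay modest; the
# representativeness r^2 stays below 0.05 by survey design.
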