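"""Patches, coral banks and shape metrics from annotated frames.

A patch is the coral aggregation within one retained frame; a bank is a patch
run spanning at least three consecutive frames of a transect; coral shape is
length / mid-length width of each individually measured coral (> 5: long and
thin, < 3: short and thick).
"""

import fjordsurvey as fs
from fjordsurvey import quantify

config = fs.FjordConfig(seed=42)
dataset = fs.generate_survey(config)
camera = fs.CameraModel(60.0, 40.0)
geo = fs.exclude_overlaps(fs.place_frames(dataset.frames, camera, list(config.site_codes)))

annotations = quantify.filter_to_retained(dataset.annotations, geo)
patches = quantify.collect_patches(annotations, geo)
banks = quantify.detect_banks(patches, geo)
shapes = quantify.shape_metrics(dataset.measured)

print(f"retained frames: {int(geo['retained'].sum())}")
print(f"patches:         {len(patches)} "
      f"(mean size {patches['area_m2'].mean():.3f} m2, "
      f"mean {patches['coral_count'].mean():.1f} corals per patch)")
print(f"banks:           {len(banks)} "
      f"(largest spans {banks['n_frames'].max()} consecutive frames)")

long_thin = (shapes["shape"] > 5).mean()
short_thick = (shapes["shape"] < 3).mean()
print(f"shapes:          {len(shapes)} measured corals, "
      f"{100*long_thin:.0f}% long/thin (L/W > 5), "
      f"{100*short_thick:.0f}% short/thick (L/W < 3)")
# Counts always include unmeasurable corals; shapes only the measured subset.
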