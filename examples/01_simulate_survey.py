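"""Generate a synthetic fjord survey and look at its ground truth.

The generator emulates an ROV video-transect study: seven sites along the
fjord, a down and an up transect each, frames on a regular depth grid with
echo-sounder ranges, per-frame substrate/coral annotations, and co-registered
CTD casts through a four-layer water column. Coral density drops five-fold
below 275 m by default.
"""

import fjordsurvey as fs

config = fs.FjordConfig(seed=42)
dataset = fs.generate_survey(config)

print(f"sites:        {', '.join(config.site_codes)}")
print(f"frames:       {len(dataset.frames)} (down+up transects)")
print(f"annotations:  {len(dataset.annotations)} rows, "
      f"{int(dataset.annotations['coral_count'].sum())} corals counted")
print(f"measured:     {len(dataset.measured)} individuals with length/width")
print(f"CTD records:  {len(dataset.ctd)}")

truth = dataset.ground_truth
print("\nground truth baked into the draw:")
print(f"  break depth        {truth['break_depth_m']} m")
print(f"  density above      {truth['density_above_per_m2']} corals per m2 rock")
print(f"  density below      {truth['density_below_per_m2']} corals per m2 rock")

paths = fs.write_survey(dataset, "scratch/example_survey")
print(f"\nwrote {len(paths)} files to scratch/example_survey/")
# The drop factor (above/below density ratio) is what the statistical layer
# must recover from the tables alone.
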