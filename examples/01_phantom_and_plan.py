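"""Generate a synthetic pelvic phantom and a 7-field plan.

The phantom emulates a cervical-cancer planning CT: an elliptical body,
a central spherical PTV and six normal structures, on a 2.5 mm dose grid.
"""

import dosekit as dk

params = dk.PhantomParams(seed=42)
phantom = dk.generate_phantom(params)
plan = dk.generate_plan(seed=42, beam_count=7, angle_policy="fixed", position="supine")

print(f"grid: {phantom.grid.shape} voxels at {phantom.grid.spacing} mm")
print(f"plan: {plan.beam_count} beams at {plan.angles} deg, "
      f"{plan.prescription_gy} Gy prescription, {plan.position}")
voxel_cc = phantom.grid.voxel_volume_mm3 / 1000.0
for name in dk.REQUIRED_ROIS:
    n = int(phantom.structures[name].sum())
    print(f"  {name:16s} {n:6d} voxels  ({n * voxel_cc:7.1f} cm^3)")
# Each ROI volume is the voxel count times the voxel volume; the PTV is a
# sphere of ~20 mm radius (~34 cm^3) and every ROI lies inside the body.
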