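"""Recover the radius of a digital cylinder from its binary mask.

Builds a 4 mm-radius tube on a 1 mm grid, runs the EDT -> skeleton ->
propagation pipeline and compares every voxel's assigned radius against
the known truth.
"""

import numpy as np

import vesselrad as vr

spec = vr.PhantomSpec(kind="cylinder", radius_mm=4.0, length_mm=100.0, spacing=(1, 1, 1))
mask, truth = vr.make_cylinder(spec)
print(f"phantom: {mask.foreground_count()} foreground voxels on grid {mask.shape}")

field = vr.radius_pipeline(mask, "artery")
fg = field.provenance > 0
rel_err = np.abs(field.radius[fg] - 4.0) / 4.0

print(f"voxels within 15% of the true 4.0 mm radius: {100 * (rel_err <= 0.15).mean():.1f}%")
print(f"median propagated radius: {np.median(field.radius[fg]):.3f} mm")
print(f"fallback-assigned voxels: {100 * field.fallback_fraction:.2f}%")
print()
print("The median exceeds 4.0 mm by a fraction of a voxel: the distance")
print("transform measures center-to-center distances, which overestimates the")
print("tube radius by up to half a voxel (a documented, correctable bias).")
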