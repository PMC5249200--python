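"""Volumetric wear recovery on a synthetic cup with known ground truth.

Builds a 32/50 mm polyethylene cup, wears it by pushing the 32 mm head
0.5 mm toward the pole, voxelizes both states into CT-like volumes
(0.3 mm voxels here, for speed), determines both surfaces, and compares
the measured volume difference with a brute-force integration of the
true removed material.
"""

import cupwear as cw

spec = cw.CupSpec()                       # 32 mm inner / 50 mm outer, 0.934 mg/mm^3
pattern = cw.WearPattern(0.5)             # 0.5 mm head penetration toward the pole

truth = cw.true_wear_volume(spec, pattern, method="grid", grid_step=0.04)

solid = cw.make_cup_geometry(spec)
worn = cw.apply_wear(solid, spec, pattern)
vol_before = cw.voxelize(solid, voxel_size=0.3)
vol_after = cw.voxelize(worn, voxel_size=0.3)

mesh_before = cw.extract_surface(vol_before)   # ISO-50 + adaptive refinement
mesh_after = cw.extract_surface(vol_after)

dv = cw.wear_volume(mesh_before, mesh_after)
mass = cw.mass_from_volume(dv, spec.density)

print(f"true wear volume      : {truth:8.2f} mm^3")
print(f"measured wear volume  : {dv:8.2f} mm^3  ({100*(dv-truth)/truth:+.2f}%)")
print(f"equivalent mass loss  : {mass:8.2f} mg at {spec.density} mg/mm^3")
print()
print("The measured volume difference should sit within a couple of percent")
print("of the ground truth at this resolution; the mass is volume x density.")
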