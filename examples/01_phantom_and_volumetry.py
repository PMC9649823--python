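"""Generate a synthetic canine CT phantom and check voxel-count volumetry.

Builds one post-contrast phantom (two ellipsoid kidneys in a soft-tissue
torso), measures each structure by counting labelled voxels, and compares
against the exact closed-form ellipsoid volumes. The printed fractional
errors are pure discretization error and should be well under 3% at the
default (1.5, 1.5, 2.0) mm spacing.
"""
import numpy as np

from renovol.phantom import PhantomSpec, generate_phantom, voxelized_volume_error
from renovol.postvolume import voxel_count_volume

vol, gt = generate_phantom(PhantomSpec(seed=7))
print(f"phantom grid {vol.shape} at spacing {vol.spacing} mm")
print(f"lung caudal margin at axial slice {gt.lung_caudal_index}")

measured = voxel_count_volume(gt.labels).volumes_cm3
errors = voxelized_volume_error(gt)
print(f"{'structure':<14}{'voxel-count cm3':>16}{'analytic cm3':>14}{'frac error':>12}")
for name, analytic in gt.analytic_volumes_cm3.items():
    m = measured.get(name if name != "total_kidney" else "total")
    print(f"{name:<14}{m:>16.3f}{analytic:>14.3f}{errors[name]:>12.4f}")
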