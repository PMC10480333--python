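"""Transfer a wall-shear-stress field onto micro-CT voxels via ICP.

The resected dome is scanned in an arbitrary scanner pose; ICP recovers
the rigid transform to the micro-CT surface, the same transform carries
the preoperative model (with its per-vertex WSS field, in Pa) into
micro-CT space, and every voxel takes the value of its nearest vertex.
"""

import numpy as np
import trimesh

from aneuwall import (
    VoxelGrid,
    apply_transform,
    assign_field_to_voxels,
    field_to_slice,
    icp_register,
)
from aneuwall.synthetic import generate_dome_phantom, generate_wss_field

phantom = generate_dome_phantom(seed=1)
wss = generate_wss_field(phantom.target, pattern="spot", seed=1)

# micro-CT pose: a known rigid offset of the dome
T_scan = trimesh.transformations.rotation_matrix(np.deg2rad(12), (0, 1, 0.2))
T_scan[:3, 3] = (1.0, -0.5, 0.8)
ct_surface = apply_transform(phantom.dome, T_scan)

icp = icp_register(phantom.dome, ct_surface)
print(f"ICP converged with RMS {icp.rms:.2e} mm "
      f"in {len(icp.rms_history) - 1} iterations")

model_ct = apply_transform(phantom.target, icp.transform)
lo = model_ct.vertices.min(axis=0) - 0.5
hi = model_ct.vertices.max(axis=0) + 0.5
grid = VoxelGrid.make(lo, (hi - lo) / 64, (64, 64, 64))
volume = assign_field_to_voxels(model_ct, wss, grid)
print(f"WSS volume: {volume.shape}, range "
      f"{volume.min():.2f}-{volume.max():.2f} Pa")

mid = lo[2] + (hi[2] - lo[2]) / 2
sl = field_to_slice(volume, grid, offset_mm=mid, axis_direction=(0, 0, 1))
print(f"slice at z={mid:.2f} mm: mean WSS {sl.mean():.2f} Pa")
# The voxel volume can now be overlaid slice by slice with the mapped
# histology and the calcification masks.
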