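"""Build the six-sphere IEC body phantom, rasterize it, and partition it
into VOI masks.

The background VOI is defined as the full body contour minus the sphere
VOIs, so with zero margins the three masks tile the body exactly.
"""

import nemaiq as nq

fill = nq.PhantomFill("99mTc", sphere_concentration=236.0,
                      background_concentration=23.7)
spec = nq.default_nema_spec(fill)
print(f"sphere diameters (mm): {spec.diameters}")
print(f"true sphere-to-background ratio A = {fill.true_ratio:.3f}  "
      "(computed from the fill, never assumed to be 10)")

grid = nq.VoxelGrid(shape=(48, 96, 96), spacing=(4.8, 4.8, 4.8))
truth = nq.voxelize(spec, grid, supersample=4)
print(f"\nrasterized on {grid.shape} voxels of {grid.spacing[0]} mm "
      f"({truth.total_activity_bq() / 1e6:.1f} MBq total)")

contour = nq.contour_mask(spec, grid)
spheres = nq.sphere_masks(spec, grid)
background = nq.background_mask(spec, grid)
n_sphere = sum(int(m.sum()) for m in spheres)
print(f"body contour: {int(contour.sum())} voxels = "
      f"{int(background.sum())} background + {n_sphere} sphere voxels")
print("-> the masks partition the body exactly; every VOI mean is a plain "
      "arithmetic mean over one of these binary masks")
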