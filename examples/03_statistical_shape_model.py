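"""Learn a statistical shape model from masks and sample new shapes.

Ten rough SH shapes are voxelized, radially resampled on a shared angular
grid, and fed to a PCA shape model; a new shape is then drawn as the mean
plus a random combination of the leading eigenmodes.
"""

import numpy as np

from synmicro import (AngularGrid, boundary_to_mask, fit_shape_model,
                      radial_resample, sample_shape, sample_sh_shape,
                      voxelize_star_convex)

grid = AngularGrid.fibonacci(162)
boundaries = []
for seed in range(10):
    shape = sample_sh_shape(r=9.0, gamma=2.0, l_max=4, seed=100 + seed)
    mask = voxelize_star_convex(shape.radius_fn, (16, 16, 16), (33, 33, 33))
    boundaries.append(radial_resample(mask, grid))

model = fit_shape_model(boundaries)
explained = model.variances[:3].sum() / model.variances.sum()
print(f"shape model: {model.n_train} training shapes, "
      f"{model.positive_modes()} positive-variance modes")
print(f"top-3 modes explain {100 * explained:.1f}% of the boundary variance")

new = sample_shape(model, n_modes=3, seed=7)
new_mask = boundary_to_mask(new, (33, 33, 33))
print(f"sampled shape -> {int(new_mask.data.sum())} foreground voxels "
      f"(mean-shape volume {int(boundary_to_mask(sample_shape(model, 1, b=np.zeros(1)), (33, 33, 33)).data.sum())})")
# The sampled mode weights are bounded by 3*lambda_j, so generated shapes
# stay inside the variance range seen in training.
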