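"""Positional conditioning: signed tanh of the distance to the organism boundary.

The map is positive inside the specimen, negative outside, zero at the
boundary, and saturates with depth at a rate set by alpha — the knob that
also selects the synthetic image quality level.
"""

import numpy as np

from synmicro import SHShape, positional_map, voxelize_star_convex

ball = voxelize_star_convex(SHShape(12.0, 5.0, 0, [12.0]).radius_fn,
                            (16, 16, 16), (33, 33, 33))
for alpha in (10.0, 100.0, 500.0):
    pm = positional_map(ball, alpha=alpha, beta=100.0)
    center = pm.values[16, 16, 16]
    print(f"alpha={alpha:5.0f}: value at organism center = {center:.4f}, "
          f"range = ({pm.values.min():.4f}, {pm.values.max():.4f})")
# Small alpha saturates quickly (deep voxels -> ~1: strong depth effect);
# large alpha keeps the map nearly linear in depth (mild depth effect).
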