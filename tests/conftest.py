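"""Shared fixtures: small simulated volumes reused across test modules."""

import numpy as np
import pytest

from synmicro import (
    RenderConfig,
    SHShape,
    SimulationConfig,
    classical_render,
    positional_map,
    simulate_annotation,
    substream_seed,
    voxelize_star_convex,
)


@pytest.fixture(scope="session")
def ball_mask_r10():
    """Voxelized ball of radius 10 centered in a 33^3 grid."""
    shape = SHShape(10.0, 5.0, 0, [10.0])
    return voxelize_star_convex(shape.radius_fn, (16, 16, 16), (33, 33, 33))


@pytest.fixture(scope="session")
def membrane_annotation():
    """One simulated membrane-mode annotation triple on a (32, 64, 64) grid."""
    cfg = SimulationConfig(grid_shape=(32, 64, 64), structure="membranes",
                           organism_radius=22.0, seed=11)
    return simulate_annotation(cfg)


@pytest.fixture(scope="session")
def training_triples(membrane_annotation):
    """Eight aligned (mask, positional, rendered-image) volumes of 64x64x32.

    These are the study conditions of the CPU-scale smoke training: masks
    from the simulator, surrogate images from the classical renderer.
    """
    triples = []
    for v in range(8):
        cfg = SimulationConfig(grid_shape=(32, 64, 64), structure="membranes",
                               organism_radius=22.0, seed=substream_seed(7, "sim", v))
        _, struct, fg = simulate_annotation(cfg)
        pos = positional_map(fg, 100.0, 100.0)
        img = classical_render(struct, fg, RenderConfig(seed=substream_seed(7, "render", v)))
        triples.append(((struct.data > 0).astype(np.float32), pos.values, img.data))
    return triples
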