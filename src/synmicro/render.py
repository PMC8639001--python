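"""Classical surrogate renderer: microscopy-like intensity volumes from masks.

The renderer turns a structure mask into an intensity volume with the four
dominant appearance traits of 3D fluorescence stacks: PSF-like Gaussian
blur, depth-dependent signal attenuation inside the specimen, a baseline
background level, and mixed Gaussian/Poisson noise. It is a deliberately
simple physics caricature — its purpose is to give the synthesis GAN a
self-contained target image domain for training and evaluation, not to
model real optics.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.ndimage import gaussian_filter

from .positional import boundary_distance
from .volumes import IntensityVolume, as_array

__all__ = ["RenderConfig", "classical_render"]


@dataclass
class RenderConfig:
    """Rendering parameters (all in voxel/intensity units).

    ``decay_alpha`` is the tanh scaling of the depth attenuation (larger
    values = slower saturation = better image quality at depth; 0 disables
    attenuation), reusing the positional-encoding distance transform.
    ``decay_strength`` is the maximum fraction of signal lost at saturation.
    """

    psf_sigma: tuple[float, float, float] = (1.0, 1.5, 1.5)
    decay_alpha: float = 30.0
    decay_strength: float = 0.8
    noise_gaussian_sd: float = 0.03
    noise_poisson_scale: float = 200.0
    background_level: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for name in ("decay_alpha", "decay_strength", "noise_gaussian_sd",
                     "noise_poisson_scale", "background_level"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["psf_sigma"] = list(np.atleast_1d(self.psf_sigma).astype(float))
        return d


def classical_render(structure_mask, foreground, cfg: RenderConfig) -> IntensityVolume:
    """Render one intensity volume from a structure mask and organism foreground.

    Pipeline: binary structure signal -> depth attenuation (tanh of the
    distance to the organism boundary, scaled by ``decay_alpha``) -> Gaussian
    PSF blur -> background offset -> Poisson and Gaussian noise -> clip to
    [0, 1]. Deterministic per ``cfg.seed``.
    """
    structure = (as_array(structure_mask) > 0).astype(np.float32)
    fg = as_array(foreground) > 0
    if structure.shape != fg.shape:
        raise ValueError("structure and foreground volumes must be aligned")
    signal = structure
    if cfg.decay_alpha > 0 and fg.any() and not fg.all():
        dist = boundary_distance(foreground)
        atten = np.where(fg, np.tanh(dist / cfg.decay_alpha), 0.0).astype(np.float32)
        signal = signal * (1.0 - cfg.decay_strength * atten)
    sigma = np.atleast_1d(np.asarray(cfg.psf_sigma, dtype=float))
    if np.any(sigma > 0):
        signal = gaussian_filter(signal, sigma=sigma if sigma.size == 3 else float(sigma))
    img = signal + cfg.background_level
    rng = np.random.default_rng(cfg.seed)
    if cfg.noise_poisson_scale > 0:
        img = rng.poisson(np.clip(img, 0, None) * cfg.noise_poisson_scale) / cfg.noise_poisson_scale
    if cfg.noise_gaussian_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_gaussian_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    return IntensityVolume(img, metadata={"render": cfg.to_dict()})
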