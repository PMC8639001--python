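"""End-to-end dataset generation: masks -> positional encoding -> images.

One pipeline run produces a fully-annotated dataset directory: for each
simulated volume an intensity image, the instance segmentation, the binary
structure mask (membranes or nuclei), the organism foreground and the
positional conditioning map, plus a single provenance record. Images come
either from the classical surrogate renderer (default, self-contained) or
from a trained GAN checkpoint applied patch-wise.

A quality sweep renders/synthesizes the *same* mask at several foreground
scalings alpha, mirroring the published multi-quality benchmark layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .masks import SimulationConfig, simulate_annotation
from .patches import PatchGridSpec, apply_patchwise
from .positional import positional_map
from .render import RenderConfig, classical_render
from .volumes import IntensityVolume, substream_seed
from .volio import Provenance, write_volume

__all__ = ["PipelineConfig", "run_pipeline", "synthesize_volume"]


@dataclass
class PipelineConfig:
    """Dataset-level configuration.

    ``alphas`` lists the positional foreground scalings of the quality sweep;
    each volume is written once per alpha. ``checkpoint`` optionally points
    to a trained GAN archive; without it the classical renderer supplies the
    images (its depth-decay scaling is tied to alpha so the sweep changes
    image quality the same way).
    """

    out_dir: str = "dataset"
    n_volumes: int = 2
    structure: str = "membranes"
    grid_shape: tuple[int, int, int] = (48, 64, 64)
    alphas: tuple[float, ...] = (100.0,)
    beta: float = 100.0
    seed: int = 0
    simulation: dict = field(default_factory=dict)   # overrides for SimulationConfig
    render: dict = field(default_factory=dict)       # overrides for RenderConfig
    checkpoint: str | None = None
    patch: dict = field(default_factory=dict)        # PatchGridSpec overrides for synthesis
    image_format: str = "tif"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**d)
        cfg.grid_shape = tuple(cfg.grid_shape)
        cfg.alphas = tuple(cfg.alphas)
        return cfg

    def to_dict(self) -> dict:
        return {
            "out_dir": self.out_dir, "n_volumes": self.n_volumes,
            "structure": self.structure, "grid_shape": list(self.grid_shape),
            "alphas": list(self.alphas), "beta": self.beta, "seed": self.seed,
            "simulation": self.simulation, "render": self.render,
            "checkpoint": self.checkpoint, "patch": self.patch,
            "image_format": self.image_format,
        }


def synthesize_volume(generator, mask, pos, spec: PatchGridSpec | None = None) -> IntensityVolume:
    """Apply a trained generator to a full-size mask + positional map.

    The volume is processed patch-wise on the spec's tiling grid and
    reassembled with concentric-weight overlap averaging.
    """
    from .gan import generator_forward

    spec = spec or PatchGridSpec()
    out = apply_patchwise(lambda m, p: generator_forward(m, p, generator),
                          [np.asarray(mask, np.float32) > 0, pos], spec)
    return IntensityVolume(np.clip(out, 0.0, 1.0).astype(np.float32))


def run_pipeline(config: PipelineConfig) -> Path:
    """Generate a fully-annotated synthetic dataset directory.

    Layout: ``images/volXX_alphaYY.tif``, ``labels/volXX.tif``,
    ``structure/volXX.tif``, ``foreground/volXX.tif``,
    ``positional/volXX_alphaYY.tif`` and one ``provenance.json``.
    Deterministic per master seed. Stage failures raise with the stage name.
    """
    out = Path(config.out_dir)
    prov = Provenance(master_seed=config.seed, config=config.to_dict())
    generator = None
    patch_spec = None
    if config.checkpoint:
        from .gan import load_checkpoint

        _, generator, _, _, _, _ = load_checkpoint(config.checkpoint)
        patch_spec = PatchGridSpec(**config.patch) if config.patch else PatchGridSpec()
    for v in range(config.n_volumes):
        sim_seed = substream_seed(config.seed, "simulate", v)
        prov.stage_seeds[f"simulate:{v}"] = sim_seed
        sim_kwargs = dict(grid_shape=config.grid_shape, structure=config.structure,
                          seed=sim_seed)
        sim_kwargs.update(config.simulation)
        try:
            instances, structure, foreground = simulate_annotation(SimulationConfig(**sim_kwargs))
        except Exception as e:
            raise RuntimeError(f"stage 'simulate-masks' failed on volume {v}: {e}") from e
        write_volume(instances, out / "labels" / f"vol{v:02d}.{config.image_format}")
        write_volume(structure, out / "structure" / f"vol{v:02d}.{config.image_format}")
        write_volume(foreground, out / "foreground" / f"vol{v:02d}.{config.image_format}")
        prov.add_checksum(f"labels:{v}", instances)
        prov.add_checksum(f"structure:{v}", structure)
        for alpha in config.alphas:
            try:
                pos = positional_map(foreground, alpha=alpha, beta=config.beta)
            except Exception as e:
                raise RuntimeError(f"stage 'encode-position' failed on volume {v}: {e}") from e
            pos_vol = IntensityVolume(pos.values)
            tag = f"vol{v:02d}_alpha{alpha:g}"
            write_volume(pos_vol, out / "positional" / f"{tag}.{config.image_format}")
            try:
                if generator is not None:
                    image = synthesize_volume(generator, structure, pos.values, patch_spec)
                else:
                    render_seed = substream_seed(config.seed, "render", v, alpha)
                    prov.stage_seeds[f"render:{v}:{alpha:g}"] = render_seed
                    render_kwargs = dict(decay_alpha=alpha, seed=render_seed)
                    render_kwargs.update(config.render)
                    image = classical_render(structure, foreground, RenderConfig(**render_kwargs))
            except Exception as e:
                stage = "synthesize" if generator is not None else "render"
                raise RuntimeError(f"stage '{stage}' failed on volume {v}: {e}") from e
            write_volume(image, out / "images" / f"{tag}.{config.image_format}")
            prov.add_checksum(f"images:{v}:{alpha:g}", image)
    prov.write(out / "provenance.json")
    return out


def check_dataset(path) -> dict:
    """Integrity check of a pipeline output directory.

    Verifies that every image has matching labels/structure/foreground with
    identical shapes and that the provenance record exists. Returns a summary
    dict (counts and shapes); raises on misalignment.
    """
    from .volio import read_volume

    path = Path(path)
    prov_file = path / "provenance.json"
    if not prov_file.exists():
        raise FileNotFoundError(f"no provenance record in {path}")
    images = sorted((path / "images").glob("vol*"))
    if not images:
        raise FileNotFoundError(f"no images in {path}")
    shapes = set()
    for img_path in images:
        vol_id = img_path.stem.split("_")[0]
        img = read_volume(img_path, kind="intensity")
        for sub in ("labels", "structure", "foreground"):
            match = list((path / sub).glob(f"{vol_id}.*"))
            if not match:
                raise FileNotFoundError(f"missing {sub} for {img_path.name}")
            lab = read_volume(match[0], kind="label")
            if lab.shape != img.shape:
                raise ValueError(f"shape mismatch: {img_path.name} vs {sub}/{match[0].name}")
        shapes.add(img.shape)
    return {"n_images": len(images), "shapes": sorted(shapes),
            "provenance": str(prov_file)}
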