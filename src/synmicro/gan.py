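"""Conditional GAN for mask-to-microscopy image synthesis.

A 3D U-Net generator receives a two-channel input — the binary structure
mask and the positional conditioning map — and emits an intensity patch. A
3D PatchGAN discriminator receives (image, mask, positional map) and scores
local patches. Least-squares adversarial objectives are used together with
an L1 identity loss (feeding the real image through the generator must
reproduce it), which anchors the intensity statistics.

Overfitting on small datasets is counteracted by adaptive discriminator
augmentation (ADA): a fixed set of five augmentations is applied to the
discriminator's image inputs, each independently with probability ``p_aug``,
and ``p_aug`` is controlled in closed loop from the fraction of real samples
the discriminator classifies as real (target 0.6, step 0.05 per epoch).

All randomness in training derives from the config seed through named
substreams (epoch, volume, role), so runs are bitwise reproducible and a
resumed run continues exactly where an uninterrupted one would be.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .nn import PatchGAN3D, RAdam, UNet3D
from .nn.autodiff import Tensor, abs_, mean, square, sub
from .patches import random_patch
from .volumes import as_array, substream_seed

__all__ = [
    "GANConfig",
    "ADAState",
    "generator_forward",
    "identity_loss",
    "adversarial_losses",
    "ada_observe_and_update",
    "apply_augmentations",
    "TrainResult",
    "train",
    "save_checkpoint",
    "load_checkpoint",
    "smoke_config",
]


@dataclass
class GANConfig:
    """Training configuration.

    Defaults mirror the reference setting (5000 epochs, 128x128x64 (x, y, z)
    patches, identity weight 5); ``smoke_config()`` returns a scaled-down
    variant for CPU-sized experiments. ``patch_size`` is (z, y, x).
    """

    patch_size: tuple[int, int, int] = (64, 128, 128)
    epochs: int = 5000
    depth: int = 4
    base_width: int = 16
    disc_base_width: int = 16
    disc_layers: int = 3
    shuffle: int = 2
    lambda_identity: float = 5.0
    lr: float = 2e-4
    betas: tuple[float, float] = (0.9, 0.999)
    ada_target: float = 0.6
    ada_step: float = 0.05
    ada_every: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.lambda_identity < 0:
            raise ValueError("loss weights must be non-negative")
        f = 2 ** self.depth
        if any(p % f for p in self.patch_size):
            raise ValueError(f"patch_size {self.patch_size} must be divisible by 2**depth = {f}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["patch_size"] = list(self.patch_size)
        d["betas"] = list(self.betas)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GANConfig":
        d = dict(d)
        d["patch_size"] = tuple(d["patch_size"])
        d["betas"] = tuple(d["betas"])
        return cls(**d)


def smoke_config(seed: int = 0) -> GANConfig:
    """Small CPU-scale configuration for smoke training and tests."""
    return GANConfig(patch_size=(16, 32, 32), epochs=20, depth=2, base_width=4,
                     disc_base_width=8, disc_layers=2, lr=1e-3, seed=seed)


# ---------------------------------------------------------------------------
# losses and forward helpers
# ---------------------------------------------------------------------------

def generator_forward(mask_patch, pos_patch, model: UNet3D) -> np.ndarray:
    """Evaluate the generator on one aligned (mask, positional) patch pair.

    Returns an intensity patch with the same spatial extents, values in
    (0, 1). Deterministic for fixed weights and inputs.
    """
    mask = np.asarray(as_array(mask_patch), dtype=np.float32)
    pos = np.asarray(as_array(pos_patch), dtype=np.float32)
    if mask.shape != pos.shape:
        raise ValueError("mask and positional patches must be aligned")
    x = np.stack([mask, pos])[None]  # (1, 2, D, H, W)
    return model(Tensor(x)).data[0, 0]


def identity_loss(real_patch, reconstructed) -> float:
    """Per-voxel-normalized L1 discrepancy ||i_real - G(i_real)||_1 / n."""
    a = np.asarray(as_array(real_patch), dtype=np.float64)
    b = np.asarray(as_array(reconstructed), dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"extent mismatch: {a.shape} vs {b.shape}")
    return float(np.mean(np.abs(a - b)))


def adversarial_losses(d_real, d_fake) -> tuple[float, float]:
    """Least-squares GAN objectives on discriminator score maps.

    ``d_loss = mean((d_real - 1)^2 + d_fake^2) / 2``;
    ``g_loss = mean((d_fake - 1)^2)``.
    """
    d_real = np.asarray(as_array(d_real), dtype=np.float64)
    d_fake = np.asarray(as_array(d_fake), dtype=np.float64)
    d_loss = float(np.mean((d_real - 1.0) ** 2 + d_fake ** 2) / 2.0)
    g_loss = float(np.mean((d_fake - 1.0) ** 2))
    return g_loss, d_loss


# ---------------------------------------------------------------------------
# adaptive discriminator augmentation
# ---------------------------------------------------------------------------

@dataclass
class ADAState:
    """Controller state for adaptive discriminator augmentation."""

    p_aug: float = 0.0
    target: float = 0.6
    delta: float = 0.05
    every: int = 1
    history: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"p_aug": self.p_aug, "target": self.target, "delta": self.delta,
                "every": self.every, "history": list(self.history)}

    @classmethod
    def from_dict(cls, d: dict) -> "ADAState":
        return cls(**d)


def ada_observe_and_update(state: ADAState, d_real_outputs, epoch: int,
                           center: float = 0.0) -> ADAState:
    """One controller step of the ADA feedback loop.

    ``r_ADA = mean(sign(scores - center))`` — with centered scores (default
    ``center=0``) a positive score means "classified real"; the training loop
    passes ``center=0.5`` for least-squares discriminator outputs. On epochs
    that are multiples of ``state.every`` the augmentation probability moves
    by ``delta`` towards the target: up when ``r_ADA > target`` (discriminator
    too confident, augment more), down when below, clamped to [0, 1].
    """
    scores = np.asarray(as_array(d_real_outputs), dtype=np.float64).ravel()
    if scores.size == 0:
        raise ValueError("need a non-empty batch of discriminator scores")
    r_ada = float(np.mean(np.sign(scores - center)))
    new = ADAState(p_aug=state.p_aug, target=state.target, delta=state.delta,
                   every=state.every, history=list(state.history) + [r_ada])
    if state.every > 0 and epoch % state.every == 0:
        new.p_aug = float(np.clip(state.p_aug + state.delta * np.sign(r_ada - state.target),
                                  0.0, 1.0))
    return new


# ---------------------------------------------------------------------------
# augmentations
# ---------------------------------------------------------------------------

_AUG_NAMES = ("intensity_scale", "gaussian_noise", "voxel_shuffle",
              "inpainting", "linear_reduction")


def _random_region(rng, shape, size):
    """Origin/extent of a random axis-aligned region, clipped to the patch."""
    ext = tuple(min(s, n) for s, n in zip(size, shape))
    origin = tuple(int(rng.integers(0, n - e + 1)) for n, e in zip(shape, ext))
    return tuple(slice(o, o + e) for o, e in zip(origin, ext))


def apply_augmentations(patch, p_aug: float, seed: int, return_info: bool = False):
    """ADA augmentation stack applied to one intensity patch.

    Five transforms fire independently, each with probability ``p_aug``, in
    this fixed order: (1) linear intensity scaling by U[0.6, 1.2]; (2)
    additive Gaussian noise N(0, 0.1); (3) voxel shuffling inside a random
    25^3 region; (4) zero inpainting of a random 15^3 region; (5) linear
    intensity reduction along one random axis (ramp from 1 down to a
    U[0.2, 0.8] endpoint). Regions larger than the patch are clipped.
    Deterministic per seed; ``p_aug = 0`` returns the input bitwise.
    """
    if not 0.0 <= p_aug <= 1.0:
        raise ValueError("p_aug must be in [0, 1]")
    out = np.array(as_array(patch), dtype=np.float32, copy=True)
    rng = np.random.default_rng(seed)
    applied = []
    # 1: linear intensity scaling
    if rng.uniform() < p_aug:
        out *= rng.uniform(0.6, 1.2)
        applied.append("intensity_scale")
    # 2: additive Gaussian noise
    if rng.uniform() < p_aug:
        out += rng.normal(0.0, 0.1, size=out.shape).astype(np.float32)
        applied.append("gaussian_noise")
    # 3: voxel shuffle in a random 25^3 region
    if rng.uniform() < p_aug:
        sl = _random_region(rng, out.shape, (25, 25, 25))
        region = out[sl]
        out[sl] = rng.permutation(region.ravel()).reshape(region.shape)
        applied.append("voxel_shuffle")
    # 4: zero inpainting of a random 15^3 region
    if rng.uniform() < p_aug:
        sl = _random_region(rng, out.shape, (15, 15, 15))
        out[sl] = 0.0
        applied.append("inpainting")
    # 5: linear intensity reduction along one random axis
    if rng.uniform() < p_aug:
        axis = int(rng.integers(0, 3))
        end = rng.uniform(0.2, 0.8)
        n = out.shape[axis]
        ramp = np.linspace(1.0, end, n, dtype=np.float32)
        shape = [1, 1, 1]
        shape[axis] = n
        out *= ramp.reshape(shape)
        applied.append("linear_reduction")
    if not applied:
        out = np.array(as_array(patch), dtype=np.float32, copy=True)
    return (out, applied) if return_info else out


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    generator: UNet3D
    discriminator: PatchGAN3D
    ada: ADAState
    log: list          # per-epoch dicts: epoch, g_loss, d_loss, r_ada, p_aug
    config: GANConfig
    opt_g: "RAdam | None" = None
    opt_d: "RAdam | None" = None


def _to_input(mask, pos) -> Tensor:
    return Tensor(np.stack([np.asarray(mask, np.float32),
                            np.asarray(pos, np.float32)])[None])


def _d_input(image_t: Tensor, mask, pos) -> Tensor:
    from .nn.autodiff import concat_channels
    cond = Tensor(np.stack([np.asarray(mask, np.float32),
                            np.asarray(pos, np.float32)])[None])
    return concat_channels(image_t, cond)


def train(config: GANConfig, dataset, out_log=None, start_epoch: int = 0,
          generator: UNet3D | None = None, discriminator: PatchGAN3D | None = None,
          ada: ADAState | None = None,
          opt_g_state: dict | None = None, opt_d_state: dict | None = None) -> TrainResult:
    """Adversarial training on aligned (mask, positional, real-image) volumes.

    Per epoch, one randomly located patch is extracted from each volume
    triple; the discriminator is updated on ADA-augmented real and fake
    patches, then the generator on the adversarial plus weighted identity
    objective. The ADA probability is updated after every ``ada_every``-th
    epoch from the signs of the discriminator's real-patch scores.

    ``start_epoch``/``generator``/... enable exact resumption: because all
    randomness is derived from ``(config.seed, epoch, volume, role)``, a
    resumed run reproduces the losses of an uninterrupted one.
    """
    if len(dataset) < 1:
        raise ValueError("need at least one (mask, positional, image) training volume")
    triples = [(as_array(m), as_array(p), as_array(r)) for m, p, r in dataset]
    G = generator or UNet3D(c_in=2, c_out=1, depth=config.depth, base=config.base_width,
                            shuffle=config.shuffle,
                            seed=substream_seed(config.seed, "init", "G"))
    D = discriminator or PatchGAN3D(c_in=3, base=config.disc_base_width,
                                    n_layers=config.disc_layers,
                                    seed=substream_seed(config.seed, "init", "D"))
    state = ada or ADAState(target=config.ada_target, delta=config.ada_step,
                            every=config.ada_every)
    opt_g = RAdam(G.parameters(), lr=config.lr, betas=config.betas)
    opt_d = RAdam(D.parameters(), lr=config.lr, betas=config.betas)
    if opt_g_state:
        opt_g.load_state(opt_g_state)
    if opt_d_state:
        opt_d.load_state(opt_d_state)
    log: list[dict] = []
    for epoch in range(start_epoch, config.epochs):
        g_losses, d_losses, real_scores = [], [], []
        for v, (mask_v, pos_v, real_v) in enumerate(triples):
            _, (mask, pos, real) = random_patch(
                [mask_v, pos_v, real_v], config.patch_size,
                seed=substream_seed(config.seed, "patch", epoch, v))
            # --- generator output for this step
            fake_t = G(_to_input(mask, pos))
            fake = fake_t.data[0, 0]
            # --- discriminator update on augmented real/fake
            real_aug = apply_augmentations(real, state.p_aug,
                                           substream_seed(config.seed, "aug-real", epoch, v))
            fake_aug = apply_augmentations(fake, state.p_aug,
                                           substream_seed(config.seed, "aug-fake", epoch, v))
            d_real = D(_d_input(Tensor(real_aug[None, None]), mask, pos))
            d_fake = D(_d_input(Tensor(fake_aug[None, None]), mask, pos))
            ones = np.ones_like(d_real.data)
            d_loss = mean(square(sub(d_real, Tensor(ones)))) + mean(square(d_fake))
            d_loss = mul_scalar(d_loss, 0.5)
            D.zero_grad()
            d_loss.backward()
            _check_finite(d_loss, "discriminator", epoch, v)
            opt_d.step()
            real_scores.append(float(d_real.data.mean()))
            # --- generator update: adversarial + identity
            d_fake_g = D(_d_input(fake_t, mask, pos))
            g_adv = mean(square(sub(d_fake_g, Tensor(np.ones_like(d_fake_g.data)))))
            rec_t = G(_to_input(real, pos))  # identity pass: real image replaces the mask channel
            g_id = mean(abs_(sub(rec_t, Tensor(real[None, None].astype(np.float32)))))
            g_total = g_adv + mul_scalar(g_id, config.lambda_identity)
            G.zero_grad()
            D.zero_grad()
            g_total.backward()
            _check_finite(g_total, "generator", epoch, v)
            opt_g.step()
            D.zero_grad()
            g_losses.append(float(g_total.data))
            d_losses.append(float(d_loss.data))
        state = ada_observe_and_update(state, np.asarray(real_scores), epoch, center=0.5)
        entry = {"epoch": epoch, "g_loss": float(np.mean(g_losses)),
                 "d_loss": float(np.mean(d_losses)),
                 "r_ada": state.history[-1], "p_aug": state.p_aug}
        log.append(entry)
        if out_log is not None:
            out_log.write(json.dumps(entry) + "\n")
            out_log.flush()
    return TrainResult(generator=G, discriminator=D, ada=state, log=log, config=config,
                       opt_g=opt_g, opt_d=opt_d)


def mul_scalar(t: Tensor, s: float) -> Tensor:
    from .nn.autodiff import mul
    return mul(t, Tensor(np.asarray(s, dtype=t.data.dtype)))


def _check_finite(loss: Tensor, which: str, epoch: int, volume: int) -> None:
    if not np.isfinite(loss.data).all():
        raise RuntimeError(
            f"non-finite {which} loss at epoch {epoch}, volume {volume}; "
            f"lower the learning rate or inspect the input volumes"
        )


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path, result: TrainResult, epoch: int | None = None,
                    opt_g: RAdam | None = None, opt_d: RAdam | None = None) -> None:
    """Single-file npz archive: weights, optimizer moments, config, ADA state, epoch."""
    opt_g = opt_g or result.opt_g
    opt_d = opt_d or result.opt_d
    arrays = {}
    for i, a in enumerate(result.generator.state_arrays()):
        arrays[f"G_{i}"] = a
    for i, a in enumerate(result.discriminator.state_arrays()):
        arrays[f"D_{i}"] = a
    if opt_g is not None:
        for i, a in enumerate(opt_g.m):
            arrays[f"OGm_{i}"] = a
        for i, a in enumerate(opt_g.v):
            arrays[f"OGv_{i}"] = a
        arrays["OGt"] = np.asarray(opt_g.t)
    if opt_d is not None:
        for i, a in enumerate(opt_d.m):
            arrays[f"ODm_{i}"] = a
        for i, a in enumerate(opt_d.v):
            arrays[f"ODv_{i}"] = a
        arrays["ODt"] = np.asarray(opt_d.t)
    meta = {"config": result.config.to_dict(), "ada": result.ada.to_dict(),
            "epoch": int(epoch if epoch is not None else len(result.log))}
    np.savez_compressed(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                        **arrays)


def load_checkpoint(path):
    """Load a checkpoint; returns (config, generator, discriminator, ada, epoch, opt_states)."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        config = GANConfig.from_dict(meta["config"])
        G = UNet3D(c_in=2, c_out=1, depth=config.depth, base=config.base_width,
                   shuffle=config.shuffle, seed=substream_seed(config.seed, "init", "G"))
        D = PatchGAN3D(c_in=3, base=config.disc_base_width, n_layers=config.disc_layers,
                       seed=substream_seed(config.seed, "init", "D"))
        G.load_state_arrays([z[f"G_{i}"] for i in range(len(G.parameters()))])
        D.load_state_arrays([z[f"D_{i}"] for i in range(len(D.parameters()))])
        ada = ADAState.from_dict(meta["ada"])
        opt_states = {}
        if "OGt" in z:
            n = len(G.parameters())
            opt_states["G"] = {"t": int(z["OGt"]),
                               "m": [z[f"OGm_{i}"] for i in range(n)],
                               "v": [z[f"OGv_{i}"] for i in range(n)]}
        if "ODt" in z:
            n = len(D.parameters())
            opt_states["D"] = {"t": int(z["ODt"]),
                               "m": [z[f"ODm_{i}"] for i in range(n)],
                               "v": [z[f"ODv_{i}"] for i in range(n)]}
        return config, G, D, ada, meta["epoch"], opt_states
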