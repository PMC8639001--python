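"""Network building blocks: 3D U-Net generator and 3D PatchGAN discriminator.

The generator is an encoder–decoder with skip connections; upsampling in the
decoding path uses 3D pixel shuffle (a convolution expands channels by s^3,
which are then rearranged into spatial resolution). The discriminator is a
fully-convolutional PatchGAN whose output is a map of local realism scores.
"""

from __future__ import annotations

import numpy as np

from .autodiff import (
    Tensor,
    concat_channels,
    conv3d,
    instance_norm,
    leaky_relu,
    pixel_shuffle3d,
    sigmoid,
)

__all__ = ["Module", "Conv3d", "InstanceNorm3d", "UNet3D", "PatchGAN3D"]


class Module:
    """Parameter container with recursive discovery (list of Tensors)."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch: {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=p.data.dtype)


class Conv3d(Module):
    """3x3x3 (configurable) convolution with He-style seeded initialization."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.pad = (k // 2) if pad is None else pad
        scale = np.sqrt(2.0 / (c_in * k ** 3))
        self.weight = Tensor(
            (rng.standard_normal((c_out, c_in, k, k, k)) * scale).astype(np.float32),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x) -> Tensor:
        return conv3d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class InstanceNorm3d(Module):
    def __init__(self, channels: int):
        self.gain = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)

    def __call__(self, x) -> Tensor:
        return instance_norm(x, self.gain, self.bias)


class _ConvBlock(Module):
    """conv -> instance norm -> leaky ReLU."""

    def __init__(self, c_in: int, c_out: int, rng, stride: int = 1):
        self.conv = Conv3d(c_in, c_out, stride=stride, rng=rng)
        self.norm = InstanceNorm3d(c_out)

    def __call__(self, x) -> Tensor:
        return leaky_relu(self.norm(self.conv(x)), 0.2)


class UNet3D(Module):
    """3D U-Net with pixel-shuffle upsampling and a sigmoid output head.

    ``depth`` is the number of 2x downsampling stages, so every spatial input
    extent must be divisible by ``2**depth``. Feature widths double per level
    starting from ``base``. Inputs are (N, C_in, D, H, W); the output has the
    same spatial extents (full convolutionality) with ``c_out`` channels in
    (0, 1).
    """

    def __init__(self, c_in: int = 2, c_out: int = 1, depth: int = 4,
                 base: int = 16, shuffle: int = 2, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.depth = depth
        self.shuffle = shuffle
        feats = [base * 2 ** i for i in range(depth + 1)]
        self.enc = [_ConvBlock(c_in if i == 0 else feats[i], feats[i], rng)
                    for i in range(depth)]
        self.down = [_ConvBlock(feats[i], feats[i + 1], rng, stride=2)
                     for i in range(depth)]
        self.bottleneck = _ConvBlock(feats[depth], feats[depth], rng)
        s3 = shuffle ** 3
        self.up = [Conv3d(feats[i + 1], feats[i] * s3, k=1, rng=rng)
                   for i in range(depth)]
        self.dec = [_ConvBlock(feats[i] * 2, feats[i], rng) for i in range(depth)]
        self.head = Conv3d(feats[0], c_out, k=1, rng=rng)

    def _check_extents(self, shape) -> None:
        f = 2 ** self.depth
        bad = [s for s in shape[2:] if s % f != 0]
        if bad:
            raise ValueError(
                f"spatial extents {tuple(shape[2:])} must be divisible by "
                f"2**depth = {f}; choose multiples of {f} per axis"
            )

    def __call__(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        self._check_extents(x.shape)
        skips = []
        h = x
        for i in range(self.depth):
            h = self.enc[i](h)
            skips.append(h)
            h = self.down[i](h)
        h = self.bottleneck(h)
        for i in reversed(range(self.depth)):
            h = pixel_shuffle3d(self.up[i](h), self.shuffle)
            h = concat_channels(h, skips[i])
            h = self.dec[i](h)
        return sigmoid(self.head(h))


class PatchGAN3D(Module):
    """Fully-convolutional local-realism classifier.

    ``n_layers`` strided conv blocks halve resolution; the final 1-channel
    convolution emits an unbounded score map (least-squares objectives are
    applied directly to it).
    """

    def __init__(self, c_in: int = 3, base: int = 16, n_layers: int = 3, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.blocks: list[Module] = []
        c = c_in
        width = base
        for i in range(n_layers):
            if i == 0:
                self.blocks.append(Conv3d(c, width, stride=2, rng=rng))
            else:
                self.blocks.append(_ConvBlock(c, width, rng, stride=2))
            c = width
            width = min(width * 2, base * 8)
        self.head = Conv3d(c, 1, rng=rng)

    def __call__(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        h = x
        for i, blk in enumerate(self.blocks):
            h = blk(h)
            if i == 0:
                from .autodiff import leaky_relu as _lr
                h = _lr(h, 0.2)
        return self.head(h)
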