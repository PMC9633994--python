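"""Six-level two-channel 3D encoder-decoder for new-lesion segmentation.

Contracting path: per resolution level, two 3x3x3 convolutions each followed
by instance normalization and LeakyReLU; the first convolution of every level
below the top is strided (2,2,2), except the transition into the lowest level
which is strided (2,1,2) — the axial axis is already coarse at that depth.
Expanding path: transposed convolutions (kernel == stride) mirror the
transitions, skip features are concatenated, and two convolutions refine.
A final 1x1x1 convolution maps to K voxelwise class scores; output spatial
shape equals input spatial shape.

Feature width at level l is min(base_features * 2^l, max_features):
32, 64, 128, 256, 320, 320 at the defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import Conv3d, ConvTranspose3d, InstanceNorm3d, LeakyReLU, Param, Triple


@dataclass(frozen=True)
class NetworkConfig:
    n_levels: int = 6
    base_features: int = 32
    max_features: int = 320
    in_channels: int = 2
    n_classes: int = 2
    lowest_level_stride: Triple = (2, 1, 2)
    other_strides: Triple = (2, 2, 2)
    leaky_slope: float = 0.01

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")

    @property
    def feature_widths(self) -> list[int]:
        return [min(self.base_features * 2**l, self.max_features) for l in range(self.n_levels)]

    def transition_stride(self, level: int) -> Triple:
        """Stride of the transition into ``level`` (1-indexed from the top)."""
        if level == self.n_levels - 1:
            return self.lowest_level_stride
        return self.other_strides

    @property
    def cumulative_strides(self) -> Triple:
        cum = np.ones(3, dtype=int)
        for level in range(1, self.n_levels):
            cum *= np.array(self.transition_stride(level))
        return tuple(int(c) for c in cum)  # type: ignore[return-value]

    def validate_patch_shape(self, shape: tuple[int, int, int]) -> None:
        for axis, (s, c) in enumerate(zip(shape, self.cumulative_strides)):
            if s % c != 0:
                raise ValueError(
                    f"patch axis {axis} has extent {s}, not divisible by the "
                    f"cumulative stride {c} of a {self.n_levels}-level network"
                )


class _ConvBlock:
    """conv -> instance norm -> LeakyReLU, twice; the first conv may be strided."""

    def __init__(self, in_ch: int, out_ch: int, first_stride: Triple, slope: float,
                 rng: np.random.Generator, name: str):
        self.ops = [
            Conv3d(in_ch, out_ch, 3, first_stride, rng, f"{name}.conv0"),
            InstanceNorm3d(out_ch, name=f"{name}.norm0"),
            LeakyReLU(slope),
            Conv3d(out_ch, out_ch, 3, (1, 1, 1), rng, f"{name}.conv1"),
            InstanceNorm3d(out_ch, name=f"{name}.norm1"),
            LeakyReLU(slope),
        ]

    def params(self) -> list[Param]:
        return [p for op in self.ops for p in op.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for op in self.ops:
            x = op.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for op in reversed(self.ops):
            grad = op.backward(grad)
        return grad


class UNet3D:
    """Encoder-decoder with skip connections; built from a :class:`NetworkConfig`."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        widths = cfg.feature_widths
        slope = cfg.leaky_slope

        self.encoder: list[_ConvBlock] = []
        for level in range(cfg.n_levels):
            in_ch = cfg.in_channels if level == 0 else widths[level - 1]
            stride = (1, 1, 1) if level == 0 else cfg.transition_stride(level)
            self.encoder.append(
                _ConvBlock(in_ch, widths[level], stride, slope, rng, f"enc{level}")
            )

        self.upsamples: list[ConvTranspose3d] = []
        self.decoder: list[_ConvBlock] = []
        for level in range(cfg.n_levels - 2, -1, -1):
            stride = cfg.transition_stride(level + 1)
            self.upsamples.append(
                ConvTranspose3d(widths[level + 1], widths[level], stride, rng, f"up{level}")
            )
            self.decoder.append(
                _ConvBlock(2 * widths[level], widths[level], (1, 1, 1), slope, rng,
                           f"dec{level}")
            )

        self.head = Conv3d(widths[0], cfg.n_classes, 1, (1, 1, 1), rng, "head")
        self._skip_channels: list[int] = []

    def params(self) -> list[Param]:
        out: list[Param] = []
        for block in self.encoder:
            out += block.params()
        for up, block in zip(self.upsamples, self.decoder):
            out += up.params()
            out += block.params()
        out += self.head.params()
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Map (N, in_channels, D, H, W) to (N, n_classes, D, H, W) scores."""
        if x.ndim != 5 or x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels}-channel input of shape "
                f"(N, {self.cfg.in_channels}, D, H, W), got {x.shape}"
            )
        self.cfg.validate_patch_shape(x.shape[2:])
        skips = []
        h = x.astype(np.float32)
        for block in self.encoder:
            h = block.forward(h)
            skips.append(h)
        self._skip_channels = [s.shape[1] for s in skips]
        for i, (up, block) in enumerate(zip(self.upsamples, self.decoder)):
            skip = skips[-(i + 2)]
            h = up.forward(h)
            h = np.concatenate([skip, h], axis=1)
            h = block.forward(h)
        return self.head.forward(h)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = self.head.backward(grad)
        skip_grads: list[np.ndarray | None] = [None] * len(self.encoder)
        for i in range(len(self.decoder) - 1, -1, -1):
            grad = self.decoder[i].backward(grad)
            c = self._skip_channels[len(self.encoder) - 2 - i]
            skip_grad, grad = grad[:, :c], grad[:, c:]
            grad = self.upsamples[i].backward(np.ascontiguousarray(grad))
            skip_grads[len(self.encoder) - 2 - i] = np.ascontiguousarray(skip_grad)
        for level in range(len(self.encoder) - 1, -1, -1):
            extra = skip_grads[level]
            if extra is not None and level != len(self.encoder) - 1:
                grad = grad + extra
            elif extra is not None:
                grad = extra
            grad = self.encoder[level].backward(grad)
        return grad

    # --- weight de/serialisation -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.value.copy() for p in self.params()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params():
            if p.name not in state:
                raise KeyError(f"missing parameter {p.name} in checkpoint")
            if state[p.name].shape != p.value.shape:
                raise ValueError(
                    f"shape mismatch for {p.name}: checkpoint {state[p.name].shape} "
                    f"vs network {p.value.shape}"
                )
            p.value = state[p.name].astype(np.float32).copy()
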