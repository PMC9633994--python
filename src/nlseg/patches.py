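"""Fixed-size 3D patch extraction with lesion-region oversampling.

Training patches are drawn randomly from the volume with probability
1 - foreground_probability and forced to contain the lesion region with
probability foreground_probability (default 1/3), countering the extreme
class imbalance of new-lesion segmentation. Inference uses overlapping
sliding windows whose per-voxel probabilities are averaged before
thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .volumes import LongitudinalCase


@dataclass(frozen=True)
class PatchSpec:
    patch_shape: tuple[int, int, int] = (128, 112, 160)
    foreground_probability: float = 1.0 / 3.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(p < 1 for p in self.patch_shape):
            raise ValueError(f"patch_shape components must be >= 1, got {self.patch_shape}")
        if not (0 <= self.foreground_probability <= 1):
            raise ValueError("foreground_probability must be in [0, 1]")


def case_to_channels(case: LongitudinalCase, normalize: bool = True) -> np.ndarray:
    """Stack baseline and follow-up as a (2, D, H, W) float32 array.

    By default each channel is z-scored over the whole volume (the standard
    intensity normalisation for FLAIR segmentation networks); training and
    inference both go through this path so the statistics always match.
    """
    channels = np.stack(
        [case.baseline.data.astype(np.float32), case.follow_up.data.astype(np.float32)]
    )
    if normalize:
        for c in range(channels.shape[0]):
            std = channels[c].std()
            channels[c] = (channels[c] - channels[c].mean()) / (std if std > 0 else 1.0)
    return channels


def pad_to_shape(
    image: np.ndarray, label: np.ndarray | None, target: Sequence[int]
) -> tuple[np.ndarray, np.ndarray | None, tuple[int, int, int]]:
    """Zero-pad (symmetrically) the trailing 3 axes up to ``target``; label padded with 0.

    Returns the padded arrays and the per-axis left-pad offsets, so callers
    can crop predictions back onto the original grid.
    """
    spatial = image.shape[-3:]
    pads = []
    for s, t in zip(spatial, target):
        extra = max(t - s, 0)
        pads.append((extra // 2, extra - extra // 2))
    img_pad = [(0, 0)] * (image.ndim - 3) + pads
    image_p = np.pad(image, img_pad) if any(p != (0, 0) for p in pads) else image
    label_p = None
    if label is not None:
        label_p = np.pad(label, pads) if any(p != (0, 0) for p in pads) else label
    return image_p, label_p, tuple(p[0] for p in pads)  # type: ignore[return-value]


def sample_patch(
    case: LongitudinalCase, spec: PatchSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, tuple[int, int, int]]:
    """Draw one training patch: (2-channel image, label patch, origin).

    With probability ``foreground_probability`` (and a non-empty label) the
    patch is centred on a uniformly chosen lesion voxel, shifted inward at
    boundaries; otherwise the origin is uniform over valid positions. Cases
    with empty labels always take the random branch. Images smaller than the
    patch are zero-padded symmetrically first.
    """
    image = case_to_channels(case)
    label = (
        case.new_lesion_label.data
        if case.new_lesion_label is not None
        else np.zeros(case.shape, dtype=np.uint8)
    )
    image, label, _ = pad_to_shape(image, label, spec.patch_shape)
    shape = image.shape[-3:]
    patch = spec.patch_shape
    max_origin = [s - p for s, p in zip(shape, patch)]

    fg_voxels = np.argwhere(label > 0)
    take_fg = len(fg_voxels) > 0 and rng.uniform() < spec.foreground_probability
    if take_fg:
        center = fg_voxels[rng.integers(len(fg_voxels))]
        origin = tuple(
            int(np.clip(c - p // 2, 0, m)) for c, p, m in zip(center, patch, max_origin)
        )
    else:
        origin = tuple(int(rng.integers(0, m + 1)) for m in max_origin)

    sl = tuple(slice(o, o + p) for o, p in zip(origin, patch))
    return image[(slice(None),) + sl].copy(), label[sl].copy(), origin


def sliding_window_origins(
    image_shape: Sequence[int], patch_shape: Sequence[int], overlap: float = 0.5
) -> list[tuple[int, int, int]]:
    """Origins of a covering set of windows with the requested fractional overlap."""
    origins_per_axis = []
    for size, patch in zip(image_shape, patch_shape):
        if patch > size:
            raise ValueError(f"patch {patch} exceeds image extent {size}; pad first")
        step = max(int(round(patch * (1 - overlap))), 1)
        starts = list(range(0, size - patch + 1, step))
        if starts[-1] != size - patch:
            starts.append(size - patch)
        origins_per_axis.append(starts)
    return [
        (a, b, c)
        for a in origins_per_axis[0]
        for b in origins_per_axis[1]
        for c in origins_per_axis[2]
    ]


def reassemble(
    patches: Iterable[np.ndarray],
    origins: Iterable[tuple[int, int, int]],
    image_shape: Sequence[int],
) -> np.ndarray:
    """Fuse overlapping probability patches into one map by per-voxel averaging.

    Every voxel must be covered by at least one patch; uncovered voxels are an
    error.
    """
    acc = np.zeros(tuple(image_shape), dtype=np.float64)
    count = np.zeros(tuple(image_shape), dtype=np.int32)
    for patch, origin in zip(patches, origins):
        sl = tuple(slice(o, o + s) for o, s in zip(origin, patch.shape))
        acc[sl] += patch
        count[sl] += 1
    if (count == 0).any():
        raise ValueError(f"{int((count == 0).sum())} voxels not covered by any patch")
    return (acc / count).astype(np.float32)
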