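"""Imaging-aware and lesion-aware augmentations over longitudinal cases.

Two augmentations carry the scientific content:

* **Axial subsampling** — a 1 x 1 x n median filter (n in {2, 3, 4}) along the
  axial slice-normal axis (axis 2), simulating thick-slice acquisition: the
  through-plane resolution drops while in-plane values see no cross-talk.
* **CarveMix** — a lesion-aware mix: a region of interest is carved from a
  donor case by thresholding the signed Euclidean distance transform of its
  new-lesion label at a random level, and image + label are fused into a
  recipient case by voxelwise selection,
  ``X = X_donor * M + X_recipient * (1 - M)`` (and identically for Y).

A minimal standard set (mirroring, gamma, additive Gaussian noise) is
provided as plumbing. All transforms are deterministic given an rng state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes import LabelMask, LongitudinalCase, Volume

_ALLOWED_N = (2, 3, 4)


@dataclass(frozen=True)
class AxialSubsampleParams:
    """Median-filter extent choices along the slice-normal axis and how often to apply."""

    n_choices: tuple[int, ...] = (2, 3, 4)
    apply_probability: float = 0.25

    def __post_init__(self) -> None:
        if any(n not in _ALLOWED_N for n in self.n_choices):
            raise ValueError(f"n must be in {_ALLOWED_N}, got {self.n_choices}")
        if not (0 <= self.apply_probability <= 1):
            raise ValueError("apply_probability must be in [0, 1]")


@dataclass(frozen=True)
class CarveParams:
    """CarveMix policy: how often to mix, and an optional fixed threshold for testing."""

    mix_probability: float = 0.5
    lambda_threshold: float | None = None  # None: sample per mix
    rng_seed: int = 0


@dataclass(frozen=True)
class StandardAugmentParams:
    mirror_probability: float = 0.5  # per mirrorable axis
    mirror_axes: tuple[int, ...] = (0, 1, 2)
    gamma_probability: float = 0.3
    gamma_range: tuple[float, float] = (0.7, 1.5)
    noise_probability: float = 0.15
    noise_sigma: float = 0.05


def median_filter_axis2(data: np.ndarray, n: int) -> np.ndarray:
    """Sliding median of extent ``n`` along the last axis of a 3D array.

    Window covers offsets ceil(-(n-1)/2) .. floor(n/2); boundaries use
    edge-inclusive reflect padding; for even ``n`` the lower of the two middle
    values is taken, so outputs stay in the input value set.
    """
    if n not in _ALLOWED_N:
        raise ValueError(f"median filter extent must be in {_ALLOWED_N}, got {n}")
    left = (n - 1) // 2  # -ceil(-(n-1)/2)
    right = n // 2
    pad = [(0, 0)] * (data.ndim - 1) + [(left, right)]
    padded = np.pad(data, pad, mode="symmetric")
    windows = np.lib.stride_tricks.sliding_window_view(padded, n, axis=-1)
    return np.sort(windows, axis=-1)[..., (n - 1) // 2]


def axial_subsample(vol: Volume, n: int) -> Volume:
    """Simulate thick-slice axial acquisition with a 1 x 1 x n median filter."""
    return Volume(median_filter_axis2(vol.data, n), vol.spacing, affine=vol.affine)


def signed_distance(label: LabelMask) -> np.ndarray:
    """Signed Euclidean distance to the lesion set, in mm.

    Negative inside the lesion (depth below the boundary), positive outside
    (distance to the nearest lesion voxel). An empty label gives +inf
    everywhere.
    """
    fg = label.data.astype(bool)
    if not fg.any():
        return np.full(label.shape, np.inf, dtype=np.float32)
    d_out = ndimage.distance_transform_edt(~fg, sampling=label.spacing)
    d_in = ndimage.distance_transform_edt(fg, sampling=label.spacing)
    return (d_out - d_in).astype(np.float32)


def carve_mask(label: LabelMask, lam: float) -> LabelMask:
    """Threshold the signed distance transform: M = {v : D(v) <= lam}.

    lam above the largest outside distance gives the whole grid; lam below the
    deepest inside distance gives an empty mask. Larger lam always gives a
    superset mask.
    """
    d = signed_distance(label)
    return LabelMask((d <= lam).astype(np.uint8), label.spacing, affine=label.affine)


def sample_lambda(label: LabelMask, rng: np.random.Generator) -> float:
    """Random carve threshold: half the time a sub-lesion carve, half a dilation.

    With probability 1/2, lam = -|D_min| * u (an inner subregion); otherwise
    lam = (|D_min| / 2) * u (the lesion plus a bounded dilation), with
    u ~ Uniform(0, 1] and D_min the most-negative signed distance.
    """
    if not label.data.any():
        raise ValueError("sample_lambda requires a non-empty label")
    d = signed_distance(label)
    depth = float(-d.min())  # |D_min| > 0 for non-empty labels
    u = 1.0 - rng.uniform(0.0, 1.0)  # in (0, 1]
    if rng.uniform() < 0.5:
        return -depth * u
    return 0.5 * depth * u


def carvemix(
    donor: LongitudinalCase, recipient: LongitudinalCase, lam: float
) -> LongitudinalCase:
    """Fuse the donor's lesion region into the recipient by voxel selection.

    The carve mask M comes from the donor's new-lesion label; the same M is
    applied to both time-point channels and to the label:
    out = donor * M + recipient * (1 - M).
    """
    if donor.new_lesion_label is None or not donor.new_lesion_label.data.any():
        raise ValueError("carvemix donor must have a non-empty new-lesion label")
    if recipient.new_lesion_label is None:
        raise ValueError("carvemix recipient must carry a label (may be empty)")
    if donor.shape != recipient.shape or not np.allclose(donor.spacing, recipient.spacing):
        raise ValueError("carvemix donor and recipient must share grid shape and spacing")

    m = carve_mask(donor.new_lesion_label, lam).data.astype(bool)

    def mix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return np.where(m, a, b)

    spacing = recipient.spacing
    return LongitudinalCase(
        baseline=Volume(mix(donor.baseline.data, recipient.baseline.data), spacing),
        follow_up=Volume(mix(donor.follow_up.data, recipient.follow_up.data), spacing),
        new_lesion_label=LabelMask(
            mix(donor.new_lesion_label.data, recipient.new_lesion_label.data), spacing
        ),
        case_id=f"{donor.case_id}+{recipient.case_id}",
    )


def _gamma_transform(data: np.ndarray, gamma: float) -> np.ndarray:
    lo, hi = float(data.min()), float(data.max())
    if hi <= lo:
        return data.copy()
    norm = (data - lo) / (hi - lo)
    return (norm**gamma * (hi - lo) + lo).astype(data.dtype)


def standard_augment(
    case: LongitudinalCase, params: StandardAugmentParams, rng: np.random.Generator
) -> LongitudinalCase:
    """Mirroring, gamma and additive Gaussian noise, each with its probability.

    Mirroring flips label and both channels identically; gamma and noise touch
    intensities only, so the label stays binary throughout.
    """
    base = case.baseline.data.copy()
    follow = case.follow_up.data.copy()
    label = None if case.new_lesion_label is None else case.new_lesion_label.data.copy()

    for axis in params.mirror_axes:
        if rng.uniform() < params.mirror_probability:
            base = np.flip(base, axis)
            follow = np.flip(follow, axis)
            if label is not None:
                label = np.flip(label, axis)

    if rng.uniform() < params.gamma_probability:
        gamma = rng.uniform(*params.gamma_range)
        base = _gamma_transform(base, gamma)
        follow = _gamma_transform(follow, gamma)

    if rng.uniform() < params.noise_probability:
        base = base + rng.normal(0, params.noise_sigma, base.shape).astype(np.float32)
        follow = follow + rng.normal(0, params.noise_sigma, follow.shape).astype(np.float32)

    spacing = case.spacing
    return LongitudinalCase(
        baseline=Volume(np.ascontiguousarray(base), spacing),
        follow_up=Volume(np.ascontiguousarray(follow), spacing),
        new_lesion_label=None
        if label is None
        else LabelMask(np.ascontiguousarray(label), spacing),
        case_id=case.case_id,
    )
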