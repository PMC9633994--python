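"""Volumetric data model: scalar volumes, binary label masks, longitudinal cases.

All grids are 3D with axis order (sagittal, coronal, axial); axis 2 is the
axial slice-normal direction by convention. Coordinates are 0-based and shapes
half-open. NIfTI affines are carried through on I/O but never used to reorient:
the toolkit assumes pre-registered, consistently oriented inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

Spacing = tuple[float, float, float]


def _validate_spacing(spacing: Sequence[float]) -> Spacing:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise ValueError(f"spacing must have 3 components, got {len(spacing)}")
    if not all(np.isfinite(s) and s > 0 for s in spacing):
        raise ValueError(f"spacing components must be strictly positive and finite, got {spacing}")
    return spacing


@dataclass
class Volume:
    """A 3D scalar image with voxel spacing in mm.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Real-valued intensities; NaN is rejected.
    spacing : (sx, sy, sz)
        Voxel edge lengths in mm, each strictly positive.
    affine : ndarray (4, 4), optional
        NIfTI affine carried through untouched; purely metadata here.
    """

    data: np.ndarray
    spacing: Spacing
    affine: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D")
        if np.issubdtype(self.data.dtype, np.integer):
            self.data = self.data.astype(np.float32)
        if np.isnan(self.data).any():
            raise ValueError("volume data contains NaN")
        self.spacing = _validate_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        """Physical volume of one voxel, sx*sy*sz in mm^3."""
        return float(np.prod(self.spacing))

    def same_grid(self, other: "Volume | LabelMask") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


@dataclass
class LabelMask:
    """A binary 3D mask on the same grid contract as :class:`Volume`."""

    data: np.ndarray
    spacing: Spacing
    affine: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D mask, got {self.data.ndim}D")
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask values must be exactly 0 or 1, found {vals[:10]}")
        self.data = self.data.astype(np.uint8)
        self.spacing = _validate_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other: "Volume | LabelMask") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


@dataclass
class LongitudinalCase:
    """Aligned (baseline, follow-up, new-lesion label) triplet for one patient.

    The label marks voxels that are lesion at follow-up but not at baseline
    ("new" lesions); it is optional for inference-only cases. All members must
    share one grid shape and spacing.
    """

    baseline: Volume
    follow_up: Volume
    new_lesion_label: Optional[LabelMask] = None
    case_id: str = ""

    def __post_init__(self) -> None:
        if not self.baseline.same_grid(self.follow_up):
            raise ValueError(f"case {self.case_id!r}: baseline and follow-up grids differ")
        if self.new_lesion_label is not None and not self.baseline.same_grid(self.new_lesion_label):
            raise ValueError(f"case {self.case_id!r}: label grid differs from images")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.baseline.shape

    @property
    def spacing(self) -> Spacing:
        return self.baseline.spacing

    @property
    def has_new_lesions(self) -> bool:
        return self.new_lesion_label is not None and bool(self.new_lesion_label.data.any())


def read_nifti(path: str | Path, as_mask: bool = False) -> Volume | LabelMask:
    """Read a NIfTI-1/2 file into a :class:`Volume` (or :class:`LabelMask`).

    Spacing is taken from the header zooms; integer-typed files are promoted
    to float32 for volumes. Non-3D images and non-positive spacings fail with
    a descriptive error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"NIfTI file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D in {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if not all(np.isfinite(s) and s > 0 for s in spacing):
        raise ValueError(f"non-positive voxel spacing {spacing} in {path}")
    if as_mask:
        return LabelMask((np.asarray(data) > 0.5).astype(np.uint8), spacing, affine=img.affine)
    return Volume(np.asarray(data, dtype=np.float32), spacing, affine=img.affine)


def write_nifti(vol: Volume | LabelMask, path: str | Path) -> None:
    """Write a volume or mask as NIfTI; masks are stored as uint8, images float32.

    Round trip through :func:`read_nifti` is bit-exact for masks and within
    float32 precision for volumes.
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    if isinstance(vol, LabelMask):
        data = vol.data.astype(np.uint8)
    else:
        data = vol.data.astype(np.float32)
    affine = vol.affine
    if affine is None:
        affine = np.diag(list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def resample(vol: Volume | LabelMask, target_spacing: Sequence[float]) -> Volume | LabelMask:
    """Resample to ``target_spacing`` (mm).

    Output shape is round(shape * spacing / target) with a minimum of 1 per
    axis. Images use trilinear interpolation; masks use nearest-neighbour so
    outputs stay binary and small components keep their topology.
    """
    target = _validate_spacing(target_spacing)
    in_shape = np.array(vol.shape, dtype=float)
    in_spacing = np.array(vol.spacing, dtype=float)
    out_shape = np.maximum(np.round(in_shape * in_spacing / np.array(target)), 1).astype(int)

    if tuple(out_shape) == vol.shape and np.allclose(vol.spacing, target):
        cls = LabelMask if isinstance(vol, LabelMask) else Volume
        return cls(vol.data.copy(), target, affine=vol.affine)

    # Map output voxel centres onto input voxel index space.
    zoom = in_shape / out_shape
    coords = np.meshgrid(
        *[(np.arange(n) + 0.5) * z - 0.5 for n, z in zip(out_shape, zoom)], indexing="ij"
    )
    is_label = isinstance(vol, LabelMask)
    order = 0 if is_label else 1
    out = ndimage.map_coordinates(
        vol.data.astype(np.float32), np.stack(coords), order=order, mode="nearest"
    )
    if is_label:
        return LabelMask((out > 0.5).astype(np.uint8), target, affine=vol.affine)
    return Volume(out.astype(np.float32), target, affine=vol.affine)


def resample_case(case: LongitudinalCase, target_spacing: Sequence[float]) -> LongitudinalCase:
    """Resample every member of a longitudinal case to a common spacing."""
    label = None
    if case.new_lesion_label is not None:
        label = resample(case.new_lesion_label, target_spacing)
    return LongitudinalCase(
        baseline=resample(case.baseline, target_spacing),
        follow_up=resample(case.follow_up, target_spacing),
        new_lesion_label=label,
        case_id=case.case_id,
    )


def median_spacing(volumes: Sequence[Volume | LabelMask | LongitudinalCase]) -> Spacing:
    """Per-axis median spacing of a collection.

    For an even count the lower of the two middle values is taken, so the
    result is always a spacing actually observed in the cohort.
    """
    if len(volumes) == 0:
        raise ValueError("median_spacing of an empty collection")
    spacings = np.array([v.spacing for v in volumes], dtype=float)
    result = []
    for axis in range(3):
        vals = np.sort(spacings[:, axis])
        n = len(vals)
        # lower middle: works for both odd (true median) and even counts
        result.append(float(vals[(n - 1) // 2]))
    return tuple(result)  # type: ignore[return-value]
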