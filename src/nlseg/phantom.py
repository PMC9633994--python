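"""Longitudinal brain phantoms with known new-lesion ground truth.

The generator emulates, at desk scale, a longitudinal FLAIR cohort: a
skull-stripped brain-like ellipsoid with slowly varying tissue intensity,
hyperintense blob lesions of which some exist at both time points (and may
have grown by follow-up) and some appear only at follow-up. Only the
newly-appeared lesions are marked in the ground-truth label — existing and
grown lesions are deliberately left unannotated, reproducing the confound
that a segmenter must ignore pre-existing and growing lesions.

Lesions are axis-aligned ellipsoids so each one has an analytic volume
(4/3 pi ra rb rc) usable as an oracle for the voxel-counting metrics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .volumes import LabelMask, LongitudinalCase, Spacing, Volume, write_nifti

#: fraction of the field of view occupied by the brain semi-axes
_BRAIN_FRACTION = 0.42
#: Gaussian edge width of the lesion intensity profile, in units of lesion radius
_EDGE_WIDTH = 0.25
#: amplitude of the smooth tissue intensity variation (tissue mean is 1.0)
_TISSUE_VARIATION = 0.08


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic longitudinal case.

    Defaults emulate the study conditions: anisotropic spacing near the
    cohort median (0.977 x 0.977 x 0.530 mm), a handful of small
    hyperintense lesions, mild noise.
    """

    shape: tuple[int, int, int] = (48, 48, 64)
    spacing: Spacing = (0.977, 0.977, 0.530)
    n_new_lesions: int = 3
    n_existing_lesions: int = 2
    lesion_radius_range_mm: tuple[float, float] = (1.5, 4.0)
    lesion_contrast: float = 0.6
    growth_fraction: float = 0.3
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.lesion_radius_range_mm
        if not (0 < lo <= hi):
            raise ValueError(f"invalid lesion radius range {self.lesion_radius_range_mm}")
        if self.n_new_lesions < 0 or self.n_existing_lesions < 0:
            raise ValueError("lesion counts must be non-negative")
        if not (0 <= self.growth_fraction < 1):
            raise ValueError("growth_fraction must be in [0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")

    def replace(self, **kwargs) -> "PhantomSpec":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class _Lesion:
    center_mm: tuple[float, float, float]  # relative to volume corner
    radii_mm: tuple[float, float, float]

    @property
    def analytic_volume_mm3(self) -> float:
        return float(4.0 / 3.0 * np.pi * np.prod(self.radii_mm))

    def scaled(self, factor: float) -> "_Lesion":
        return _Lesion(self.center_mm, tuple(r * factor for r in self.radii_mm))


def _mm_grids(shape: Sequence[int], spacing: Spacing) -> list[np.ndarray]:
    """Per-axis voxel-centre coordinates in mm (open grids for broadcasting)."""
    axes = [(np.arange(n, dtype=np.float32) + 0.5) * s for n, s in zip(shape, spacing)]
    return list(np.ix_(*axes))


def _normalized_radius(grids, lesion: _Lesion) -> np.ndarray:
    rho2 = sum(
        ((g - c) / r) ** 2 for g, c, r in zip(grids, lesion.center_mm, lesion.radii_mm)
    )
    return np.sqrt(rho2)


def _lesion_bump(grids, lesion: _Lesion, contrast: float) -> np.ndarray:
    """Intensity bump: full contrast inside the ellipsoid, Gaussian falloff outside."""
    rho = _normalized_radius(grids, lesion)
    excess = np.maximum(rho - 1.0, 0.0)
    return (contrast * np.exp(-(excess**2) / (2 * _EDGE_WIDTH**2))).astype(np.float32)


def lesion_mask(shape, spacing, lesion: _Lesion) -> np.ndarray:
    """Binary membership of the lesion ellipsoid (rho <= 1)."""
    grids = _mm_grids(shape, spacing)
    return (_normalized_radius(grids, lesion) <= 1.0).astype(np.uint8)


def _place_lesions(
    spec: PhantomSpec, rng: np.random.Generator, n_existing: int, n_new: int
) -> tuple[list[_Lesion], list[_Lesion]]:
    """Sample non-overlapping lesions that fit inside the brain ellipsoid.

    Existing lesions reserve room for their grown (follow-up) extent, so the
    new-lesion label can never touch a grown rim.
    """
    extent = np.array(spec.shape) * np.array(spec.spacing)
    center = extent / 2.0
    brain_semi = extent * _BRAIN_FRACTION
    grow = 1.0 + spec.growth_fraction

    placed: list[tuple[_Lesion, float]] = []  # (lesion, effective max radius incl. growth)
    existing: list[_Lesion] = []
    new: list[_Lesion] = []
    lo, hi = spec.lesion_radius_range_mm

    for kind, count in (("existing", n_existing), ("new", n_new)):
        for _ in range(count):
            for _attempt in range(300):
                radii = tuple(rng.uniform(lo, hi, size=3))
                eff = max(radii) * (grow if kind == "existing" else 1.0)
                # uniform direction, biased-inward radius keeps placements central
                u = rng.uniform(-1.0, 1.0, size=3)
                c = tuple(center + u * (brain_semi * 0.75 - eff).clip(min=0.0))
                # containment: lesion (incl. growth) inside the brain ellipsoid
                margin = np.sqrt(sum(((ci - cc) / a) ** 2 for ci, cc, a in zip(c, center, brain_semi)))
                if margin + eff / min(brain_semi) > 0.92:
                    continue
                les = _Lesion(c, radii)
                gap_ok = all(
                    np.linalg.norm(np.array(c) - np.array(o.center_mm))
                    > eff + o_eff + 1.0
                    for o, o_eff in placed
                )
                if not gap_ok:
                    continue
                placed.append((les, eff))
                (existing if kind == "existing" else new).append(les)
                break
            else:
                raise RuntimeError(
                    f"could not place {kind} lesion after bounded retries; "
                    f"reduce lesion count or radii for shape {spec.shape}"
                )
    return existing, new


def generate_case(spec: PhantomSpec, case_id: str = "phantom_0") -> LongitudinalCase:
    """Generate one aligned longitudinal phantom case.

    The baseline holds brain + existing lesions + noise; the follow-up shares
    the anatomy, grows the existing lesions by ``growth_fraction`` (radius
    scaling), adds ``n_new_lesions`` fresh hyperintense blobs, and draws
    independent noise. The returned label marks exactly the new blobs.
    Identical spec (including seed) gives bit-identical voxel data.
    """
    rng = np.random.default_rng(spec.seed)
    grids = _mm_grids(spec.shape, spec.spacing)
    extent = np.array(spec.shape) * np.array(spec.spacing)
    center = extent / 2.0
    brain_semi = extent * _BRAIN_FRACTION

    brain = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, brain_semi)) <= 1.0
    brain = brain.astype(np.float32)

    # smooth low-frequency tissue variation
    field = rng.standard_normal(spec.shape).astype(np.float32)
    field = ndimage.gaussian_filter(field, sigma=6.0)
    std = field.std()
    if std > 0:
        field *= _TISSUE_VARIATION / std
    tissue = (1.0 + field) * brain

    existing, new = _place_lesions(spec, rng, spec.n_existing_lesions, spec.n_new_lesions)

    base = tissue.copy()
    for les in existing:
        base += _lesion_bump(grids, les, spec.lesion_contrast) * brain

    follow = tissue.copy()
    for les in existing:
        follow += _lesion_bump(grids, les.scaled(1.0 + spec.growth_fraction),
                               spec.lesion_contrast) * brain
    label = np.zeros(spec.shape, dtype=np.uint8)
    for les in new:
        follow += _lesion_bump(grids, les, spec.lesion_contrast) * brain
        label |= lesion_mask(spec.shape, spec.spacing, les)

    if spec.noise_sigma > 0:
        base = base + rng.normal(0.0, spec.noise_sigma, spec.shape).astype(np.float32)
        follow = follow + rng.normal(0.0, spec.noise_sigma, spec.shape).astype(np.float32)

    return LongitudinalCase(
        baseline=Volume(base.astype(np.float32), spec.spacing),
        follow_up=Volume(follow.astype(np.float32), spec.spacing),
        new_lesion_label=LabelMask(label, spec.spacing),
        case_id=case_id,
    )


def case_geometry(spec: PhantomSpec) -> tuple[list[_Lesion], list[_Lesion]]:
    """(existing, new) lesion ellipsoids the seeded spec will generate.

    Replays the generator's random stream, so the returned geometry matches
    :func:`generate_case` for the same spec exactly.
    """
    rng = np.random.default_rng(spec.seed)
    # consume the tissue field draw exactly as generate_case does
    rng.standard_normal(spec.shape)
    return _place_lesions(spec, rng, spec.n_existing_lesions, spec.n_new_lesions)


def analytic_lesion_volumes(spec: PhantomSpec) -> list[float]:
    """Analytic mm^3 volumes of the new lesions the seeded spec will generate."""
    _, new = case_geometry(spec)
    return [les.analytic_volume_mm3 for les in new]


def generate_cohort(
    spec_template: PhantomSpec,
    n_cases: int,
    fraction_no_new: float = 0.0,
    seed: int = 0,
) -> list[LongitudinalCase]:
    """Generate a cohort; round(fraction_no_new * n_cases) cases get no new lesions.

    Per-case seeds and the choice of no-new cases derive deterministically
    from ``seed``, so two calls with the same arguments give identical cohorts.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    if not (0 <= fraction_no_new <= 1):
        raise ValueError("fraction_no_new must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_empty = int(round(fraction_no_new * n_cases))
    empty_idx = set(rng.permutation(n_cases)[:n_empty].tolist())
    case_seeds = rng.integers(0, 2**31 - 1, size=n_cases)
    cohort = []
    for i in range(n_cases):
        n_new = 0 if i in empty_idx else spec_template.n_new_lesions
        spec = spec_template.replace(seed=int(case_seeds[i]), n_new_lesions=n_new)
        cohort.append(generate_case(spec, case_id=f"case_{i:03d}"))
    return cohort


def export_cohort(cases: Sequence[LongitudinalCase], directory: str | Path) -> list[Path]:
    """Write a cohort as NIfTI triplets, ``case_<id>/{baseline,followup,label}.nii.gz``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = []
    for case in cases:
        case_dir = directory / case.case_id
        case_dir.mkdir(exist_ok=True)
        write_nifti(case.baseline, case_dir / "baseline.nii.gz")
        write_nifti(case.follow_up, case_dir / "followup.nii.gz")
        if case.new_lesion_label is not None:
            write_nifti(case.new_lesion_label, case_dir / "label.nii.gz")
        out.append(case_dir)
    return out
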