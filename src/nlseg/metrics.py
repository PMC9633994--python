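"""Lesion-wise evaluation of new-lesion segmentations.

A "lesion" is a connected component of a binary mask (26-connectivity by
default) whose physical volume (voxel count x voxel volume) is at least
3 mm^3; smaller components are excluded before any counting, on both the
ground-truth and predicted side.

Detection follows the 10%/70% rule: a ground-truth lesion g is detected if
the union P_g of predicted components touching it covers at least 10% of g's
volume and does not go outside g by more than 70% (of the detected union's
volume, by default; the denominator is configurable to the ground-truth
volume reading). Lesion-wise F1 is the harmonic mean of detection
sensitivity S_L = n_TP / (n_TP + n_FN) and precision P_L = matched / total
predicted components. DSC is the usual voxel-overlap 2|A∩G| / (|A|+|G|).

Cohorts are reported separately for cases with and without new lesions: the
first subset gets mean DSC, F1 and lesion counts; the second gets mean
false-positive count and false-positive lesion volume V_FP.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import LabelMask

DEFAULT_MIN_VOLUME_MM3 = 3.0

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass(frozen=True)
class LesionComponent:
    """One connected lesion: its voxels, voxel count and physical volume."""

    voxel_indices: frozenset[tuple[int, int, int]]
    volume_mm3: float

    @property
    def voxel_count(self) -> int:
        return len(self.voxel_indices)


@dataclass(frozen=True)
class DetectionTable:
    n_tp: int
    n_fn: int
    n_fp: int
    matched_pred: int
    total_pred: int
    detected_gt: tuple[bool, ...]
    unmatched_pred: tuple[LesionComponent, ...]


@dataclass(frozen=True)
class LesionCaseReport:
    case_id: str
    dsc: float
    f1: float | None
    n_tp: int
    n_fp: int
    n_fn: int
    v_fp_mm3: float
    has_new_lesions_gt: bool
    predicted_new_lesions: bool

    def to_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "dsc": self.dsc,
            "f1": self.f1,
            "n_tp": self.n_tp,
            "n_fp": self.n_fp,
            "n_fn": self.n_fn,
            "v_fp_mm3": self.v_fp_mm3,
            "has_new_lesions_gt": self.has_new_lesions_gt,
            "predicted_new_lesions": self.predicted_new_lesions,
        }


@dataclass(frozen=True)
class CohortReport:
    n_cases: int
    n_new_lesion_cases: int
    n_no_new_lesion_cases: int
    mean_dsc: float
    mean_f1: float
    mean_n_tp: float
    mean_n_fp: float
    mean_n_fn: float
    no_new_mean_n_fp: float
    no_new_mean_v_fp_mm3: float
    correctly_identified_new: int
    correctly_identified_no_new: int
    per_case: pd.DataFrame = field(repr=False, compare=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("new-lesion cases", "DSC", self.mean_dsc),
            ("new-lesion cases", "F1", self.mean_f1),
            ("new-lesion cases", "n_TP", self.mean_n_tp),
            ("new-lesion cases", "n_FP", self.mean_n_fp),
            ("new-lesion cases", "n_FN", self.mean_n_fn),
            ("no-new-lesion cases", "n_FP", self.no_new_mean_n_fp),
            ("no-new-lesion cases", "V_FP_mm3", self.no_new_mean_v_fp_mm3),
        ]
        return pd.DataFrame(rows, columns=["subset", "metric", "mean"])


def extract_lesions(
    mask: LabelMask,
    min_volume_mm3: float = DEFAULT_MIN_VOLUME_MM3,
    connectivity: Literal[6, 18, 26] = 26,
) -> list[LesionComponent]:
    """Connected components above the minimum physical volume."""
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}")
    labelled, n = ndimage.label(mask.data, structure=_STRUCTURES[connectivity])
    vv = mask.voxel_volume_mm3
    out = []
    for idx, sl in enumerate(ndimage.find_objects(labelled), start=1):
        coords = np.argwhere(labelled[sl] == idx) + np.array([s.start for s in sl])
        volume = len(coords) * vv
        if volume < min_volume_mm3:
            continue
        out.append(
            LesionComponent(
                voxel_indices=frozenset(map(tuple, coords.tolist())),
                volume_mm3=volume,
            )
        )
    return out


def match_lesions(
    gt: Sequence[LesionComponent],
    pred: Sequence[LesionComponent],
    min_overlap_fraction: float = 0.10,
    max_outside_fraction: float = 0.70,
    outside_denominator: Literal["pred", "gt"] = "pred",
) -> DetectionTable:
    """Apply the 10%/70% detection rule and count TP/FP/FN lesions.

    For each ground-truth lesion g, P_g is the union of predicted components
    intersecting g. g is detected iff |P_g ∩ g| >= 0.10 |g| and the part of
    P_g outside g is at most 0.70 of |P_g| (or of |g| when
    ``outside_denominator="gt"``). A predicted component is matched iff it
    intersects at least one detected ground-truth lesion; unmatched predicted
    components are the false positives.
    """
    detected = []
    for g in gt:
        touching = [p for p in pred if p.voxel_indices & g.voxel_indices]
        union: set = set()
        for p in touching:
            union |= p.voxel_indices
        inter = len(union & g.voxel_indices)
        outside = len(union - g.voxel_indices)
        denom = len(union) if outside_denominator == "pred" else len(g.voxel_indices)
        ok = (
            len(union) > 0
            and inter >= min_overlap_fraction * len(g.voxel_indices)
            and outside <= max_outside_fraction * denom
        )
        detected.append(ok)

    matched_flags = []
    for p in pred:
        matched_flags.append(
            any(d and (p.voxel_indices & g.voxel_indices) for g, d in zip(gt, detected))
        )
    unmatched = tuple(p for p, m in zip(pred, matched_flags) if not m)
    n_tp = sum(detected)
    return DetectionTable(
        n_tp=n_tp,
        n_fn=len(gt) - n_tp,
        n_fp=len(unmatched),
        matched_pred=sum(matched_flags),
        total_pred=len(pred),
        detected_gt=tuple(detected),
        unmatched_pred=unmatched,
    )


def dsc(pred: LabelMask, gt: LabelMask) -> float:
    """Dice similarity 2|A∩G|/(|A|+|G|); both masks empty -> 1 by convention."""
    if pred.shape != gt.shape:
        raise ValueError(f"grid mismatch: {pred.shape} vs {gt.shape}")
    a = pred.data.astype(bool)
    g = gt.data.astype(bool)
    denom = int(a.sum()) + int(g.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & g).sum()) / denom


def lesion_f1(table: DetectionTable) -> float | None:
    """Lesion-wise F1 = 2 S_L P_L / (S_L + P_L); None when undefined.

    Undefined only when there are neither ground-truth lesions nor
    predictions. No ground truth but predictions present -> 0; ground truth
    present but nothing detected -> 0.
    """
    n_gt = table.n_tp + table.n_fn
    if n_gt == 0 and table.total_pred == 0:
        return None
    if n_gt == 0 or table.total_pred == 0:
        return 0.0
    s_l = table.n_tp / n_gt
    p_l = table.matched_pred / table.total_pred
    if s_l + p_l == 0:
        return 0.0
    return 2.0 * s_l * p_l / (s_l + p_l)


def false_positive_volume(unmatched: Sequence[LesionComponent]) -> float:
    """Total physical volume (mm^3) of false-positive lesion components."""
    return float(sum(c.volume_mm3 for c in unmatched))


def evaluate_case(
    pred: LabelMask,
    gt: LabelMask,
    case_id: str = "",
    min_volume_mm3: float = DEFAULT_MIN_VOLUME_MM3,
    connectivity: Literal[6, 18, 26] = 26,
    outside_denominator: Literal["pred", "gt"] = "pred",
) -> LesionCaseReport:
    """Full lesion-wise report for one case.

    DSC is computed on the raw voxel masks; the minimum-volume exclusion
    applies to the lesion-wise detection metrics on both sides, matching the
    behaviour of the standard challenge evaluation tool.
    """
    if pred.shape != gt.shape:
        raise ValueError(f"grid mismatch for case {case_id!r}: {pred.shape} vs {gt.shape}")
    gt_comp = extract_lesions(gt, min_volume_mm3, connectivity)
    pred_comp = extract_lesions(pred, min_volume_mm3, connectivity)
    table = match_lesions(gt_comp, pred_comp, outside_denominator=outside_denominator)
    has_gt = len(gt_comp) > 0
    # for no-new-lesion cases every retained prediction is a false positive
    v_fp = false_positive_volume(pred_comp if not has_gt else table.unmatched_pred)
    return LesionCaseReport(
        case_id=case_id,
        dsc=dsc(pred, gt),
        f1=lesion_f1(table),
        n_tp=table.n_tp,
        n_fp=table.n_fp,
        n_fn=table.n_fn,
        v_fp_mm3=v_fp,
        has_new_lesions_gt=has_gt,
        predicted_new_lesions=len(pred_comp) > 0,
    )


def cohort_evaluate(
    cases: Sequence[tuple[LabelMask, LabelMask]] | Sequence[LesionCaseReport],
    case_ids: Sequence[str] | None = None,
    min_volume_mm3: float = DEFAULT_MIN_VOLUME_MM3,
    connectivity: Literal[6, 18, 26] = 26,
    outside_denominator: Literal["pred", "gt"] = "pred",
) -> CohortReport:
    """Average per-case metrics separately over the new-lesion and
    no-new-lesion subsets.

    ``cases`` is either a list of (prediction, ground-truth) mask pairs or a
    list of precomputed :class:`LesionCaseReport`. A new-lesion case counts as
    correctly identified when its F1 is non-zero; a no-new-lesion case when it
    has zero retained predictions.
    """
    if len(cases) == 0:
        raise ValueError("cohort_evaluate needs at least one case")
    if isinstance(cases[0], LesionCaseReport):
        reports = list(cases)  # type: ignore[arg-type]
    else:
        ids = case_ids or [f"case_{i:03d}" for i in range(len(cases))]
        reports = [
            evaluate_case(p, g, cid, min_volume_mm3, connectivity, outside_denominator)
            for (p, g), cid in zip(cases, ids)
        ]

    new = [r for r in reports if r.has_new_lesions_gt]
    no_new = [r for r in reports if not r.has_new_lesions_gt]

    def mean(vals):
        vals = [v for v in vals if v is not None]
        return float(np.mean(vals)) if vals else float("nan")

    per_case = pd.DataFrame([r.to_dict() for r in reports])
    return CohortReport(
        n_cases=len(reports),
        n_new_lesion_cases=len(new),
        n_no_new_lesion_cases=len(no_new),
        mean_dsc=mean([r.dsc for r in new]),
        mean_f1=mean([r.f1 for r in new]),
        mean_n_tp=mean([r.n_tp for r in new]),
        mean_n_fp=mean([r.n_fp for r in new]),
        mean_n_fn=mean([r.n_fn for r in new]),
        no_new_mean_n_fp=mean([r.n_fp for r in no_new]),
        no_new_mean_v_fp_mm3=mean([r.v_fp_mm3 for r in no_new]),
        correctly_identified_new=sum(1 for r in new if r.f1 not in (None, 0.0) and r.f1 > 0),
        correctly_identified_no_new=sum(1 for r in no_new if not r.predicted_new_lesions),
        per_case=per_case,
    )
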