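"""Model/Results interface over the segmentation pipeline.

:class:`NewLesionModel` is constructed from a cohort of longitudinal cases
plus the network, training, patch and augmentation configurations; ``fit()``
runs the fold cross-validation training and returns a
:class:`NewLesionResults` carrying the fold checkpoints, the per-epoch
training history, ensembled prediction, lesion-wise evaluation and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path
from typing import Sequence

import pandas as pd

from .metrics import CohortReport, cohort_evaluate, evaluate_case
from .patches import PatchSpec
from .nn import NetworkConfig
from .training import (
    AugmentConfig,
    FoldResult,
    TrainConfig,
    ensemble_predict,
    load_checkpoint,
    save_checkpoint,
    train_fold,
)
from .volumes import LabelMask, LongitudinalCase


class NewLesionModel:
    """Patch-trained encoder-decoder for new-lesion segmentation of aligned
    longitudinal scan pairs.

    Parameters
    ----------
    cases : sequence of LongitudinalCase
        Training cohort; each case needs a new-lesion label.
    network, training, patches, augmentation : configuration dataclasses
        Defaults are the full-scale recipe; desk-scale work passes reduced
        values (fewer levels, smaller patches, fewer epochs).
    exclude_no_new_lesion_cases : bool
        Drop label-empty cases from the training cohort before fitting
        (they carry no positive voxels for the loss to learn from).
    """

    def __init__(
        self,
        cases: Sequence[LongitudinalCase],
        network: NetworkConfig | None = None,
        training: TrainConfig | None = None,
        patches: PatchSpec | None = None,
        augmentation: AugmentConfig | None = None,
        exclude_no_new_lesion_cases: bool = True,
    ):
        all_cases = list(cases)
        if exclude_no_new_lesion_cases:
            self.cases = [c for c in all_cases if c.has_new_lesions]
        else:
            self.cases = all_cases
        self.n_excluded = len(all_cases) - len(self.cases)
        if not self.cases:
            raise ValueError("no training cases left after exclusion")
        for c in self.cases:
            if c.new_lesion_label is None:
                raise ValueError(f"training case {c.case_id!r} lacks a label")
        self.network = network or NetworkConfig()
        self.training = training or TrainConfig()
        self.patches = patches or PatchSpec()
        self.augmentation = augmentation or AugmentConfig()

    def fit(self, folds: Sequence[int] | None = None) -> "NewLesionResults":
        """Train the requested folds (all by default) and bundle the results."""
        folds = list(folds) if folds is not None else list(range(self.training.n_folds))
        results = [
            train_fold(
                self.cases, fold, self.training, self.network,
                self.augmentation, self.patches,
            )
            for fold in folds
        ]
        return NewLesionResults(self, results)


class NewLesionResults:
    """Fitted fold models with ensembled prediction and evaluation."""

    def __init__(self, model: NewLesionModel, fold_results: Sequence[FoldResult]):
        self.model = model
        self.fold_results = list(fold_results)

    @property
    def history(self) -> pd.DataFrame:
        """Per-epoch loss terms and validation Dice, stacked over folds."""
        frames = []
        for fr in self.fold_results:
            h = fr.history.copy()
            h.insert(0, "fold", fr.fold_index)
            frames.append(h)
        return pd.concat(frames, ignore_index=True)

    def predict(self, case: LongitudinalCase) -> LabelMask:
        """Ensembled (mean softmax, threshold 0.5) new-lesion mask for one case."""
        return ensemble_predict(self.fold_results, case, self.model.patches)

    def evaluate(self, cases: Sequence[LongitudinalCase]) -> CohortReport:
        """Predict every case and report lesion-wise cohort metrics."""
        pairs = []
        ids = []
        for case in cases:
            if case.new_lesion_label is None:
                raise ValueError(f"case {case.case_id!r} has no ground truth to evaluate")
            pairs.append((self.predict(case), case.new_lesion_label))
            ids.append(case.case_id)
        return cohort_evaluate(pairs, case_ids=ids)

    def summary(self) -> str:
        lines = [
            "New-lesion segmentation fit",
            "=" * 60,
            f"training cases: {len(self.model.cases)} "
            f"(excluded without new lesions: {self.model.n_excluded})",
            f"network: {self.model.network.n_levels} levels, "
            f"features {self.model.network.feature_widths}",
            f"patch shape: {self.model.patches.patch_shape}, "
            f"foreground p={self.model.patches.foreground_probability:.3f}",
            f"schedule: lr {self.model.training.initial_lr}, "
            f"momentum {self.model.training.momentum}, "
            f"batch {self.model.training.batch_size}, "
            f"{self.model.training.epochs} epochs x "
            f"{self.model.training.steps_per_epoch} steps",
            "-" * 60,
            f"{'fold':>4} {'best epoch':>10} {'best val DSC':>13} "
            f"{'train/val cases':>16}",
        ]
        for fr in self.fold_results:
            lines.append(
                f"{fr.fold_index:>4} {fr.best_epoch:>10} {fr.best_val_dice:>13.4f} "
                f"{len(fr.train_ids):>8}/{len(fr.val_ids)}"
            )
        return "\n".join(lines)

    def save(self, directory: str | Path) -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for fr in self.fold_results:
            p = directory / f"fold_{fr.fold_index}.npz"
            save_checkpoint(fr, p)
            paths.append(p)
        return paths

    @classmethod
    def load(
        cls, model: NewLesionModel, directory: str | Path
    ) -> "NewLesionResults":
        directory = Path(directory)
        paths = sorted(directory.glob("fold_*.npz"))
        if not paths:
            raise FileNotFoundError(f"no fold checkpoints under {directory}")
        return cls(model, [load_checkpoint(p) for p in paths])
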