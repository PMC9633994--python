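"""Patch-based training with fold cross-validation and ensembled inference.

Each fold trains on its complement, validates whole-volume Dice after every
epoch, and keeps the argmax-Dice checkpoint (ties -> earliest epoch).
Inference averages per-voxel softmax probabilities over the fold models and
thresholds at 0.5; no morphological post-processing is applied.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .augment import (
    AxialSubsampleParams,
    CarveParams,
    StandardAugmentParams,
    axial_subsample,
    carvemix,
    sample_lambda,
    standard_augment,
)
from .metrics import dsc
from .patches import (
    PatchSpec,
    case_to_channels,
    pad_to_shape,
    reassemble,
    sample_patch,
    sliding_window_origins,
)
from .nn import NetworkConfig, SGDNesterov, UNet3D, clip_grad_norm, loss_and_grad, one_hot, softmax_channels
from .volumes import LabelMask, LongitudinalCase


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation schedule; the defaults mirror the full-scale recipe.

    Tests and desk-scale runs override epochs/steps_per_epoch downward; the
    optimiser itself (SGD, Nesterov momentum 0.99, initial lr 0.01, polynomial
    decay, batch size 2) is the published configuration.
    """

    initial_lr: float = 0.01
    momentum: float = 0.99
    lr_power: float = 0.9
    batch_size: int = 2
    epochs: int = 1000
    steps_per_epoch: int = 250
    n_folds: int = 5
    grad_clip: float = 12.0
    ce_reduction: str = "sum"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.steps_per_epoch < 1 or self.batch_size < 1:
            raise ValueError("epochs, steps_per_epoch and batch_size must be >= 1")
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be positive")


@dataclass(frozen=True)
class AugmentConfig:
    standard: StandardAugmentParams = field(default_factory=StandardAugmentParams)
    axial: AxialSubsampleParams = field(default_factory=AxialSubsampleParams)
    carve: CarveParams = field(default_factory=CarveParams)
    enabled: bool = True


@dataclass
class FoldResult:
    fold_index: int
    state_dict: dict[str, np.ndarray]
    best_epoch: int
    best_val_dice: float
    history: pd.DataFrame
    train_ids: list[str]
    val_ids: list[str]
    net_config: NetworkConfig


def argmax_earliest(values: Sequence[float]) -> int:
    """Index of the maximum; ties resolve to the earliest occurrence."""
    if len(values) == 0:
        raise ValueError("empty sequence")
    best = 0
    for i, v in enumerate(values):
        if v > values[best]:
            best = i
    return best


def fold_split(
    case_ids: Sequence[str], n_folds: int, seed: int
) -> list[tuple[list[str], list[str]]]:
    """Deterministic shuffled split into ``n_folds`` (train_ids, val_ids) pairs."""
    if len(case_ids) < n_folds:
        raise ValueError(f"need at least {n_folds} cases for {n_folds}-fold CV, got {len(case_ids)}")
    rng = np.random.default_rng(seed)
    order = [case_ids[i] for i in rng.permutation(len(case_ids))]
    chunks = [list(c) for c in np.array_split(np.array(order, dtype=object), n_folds)]
    splits = []
    for i in range(n_folds):
        val = [str(x) for x in chunks[i]]
        train = [str(x) for c in chunks[:i] + chunks[i + 1 :] for x in c]
        splits.append((train, val))
    return splits


def _augmented_case(
    case: LongitudinalCase,
    train_cases: Sequence[LongitudinalCase],
    aug: AugmentConfig,
    rng: np.random.Generator,
) -> LongitudinalCase:
    if not aug.enabled:
        return case
    # lesion-aware mixing: carve a random donor's lesions into this case
    if rng.uniform() < aug.carve.mix_probability:
        donors = [c for c in train_cases if c.has_new_lesions and c.case_id != case.case_id]
        if donors:
            donor = donors[rng.integers(len(donors))]
            if donor.shape == case.shape:
                lam = (
                    aug.carve.lambda_threshold
                    if aug.carve.lambda_threshold is not None
                    else sample_lambda(donor.new_lesion_label, rng)
                )
                case = carvemix(donor, case, lam)
    case = standard_augment(case, aug.standard, rng)
    if rng.uniform() < aug.axial.apply_probability:
        n = int(aug.axial.n_choices[rng.integers(len(aug.axial.n_choices))])
        case = LongitudinalCase(
            baseline=axial_subsample(case.baseline, n),
            follow_up=axial_subsample(case.follow_up, n),
            new_lesion_label=case.new_lesion_label,
            case_id=case.case_id,
        )
    return case


def predict_probability(
    net: UNet3D, case: LongitudinalCase, patch_spec: PatchSpec, overlap: float = 0.5
) -> np.ndarray:
    """Foreground probability map via sliding-window inference (mean fusion)."""
    image = case_to_channels(case)
    image, _, offsets = pad_to_shape(image, None, patch_spec.patch_shape)
    shape = image.shape[-3:]
    origins = sliding_window_origins(shape, patch_spec.patch_shape, overlap)
    probs = []
    for origin in origins:
        sl = tuple(slice(o, o + p) for o, p in zip(origin, patch_spec.patch_shape))
        logits = net.forward(image[(slice(None),) + sl][None])
        probs.append(softmax_channels(logits)[0, 1])
    fused = reassemble(probs, origins, shape)
    crop = tuple(slice(o, o + s) for o, s in zip(offsets, case.shape))
    return fused[crop]


def train_fold(
    cases: Sequence[LongitudinalCase],
    fold_index: int,
    train_cfg: TrainConfig,
    net_cfg: NetworkConfig,
    augment_cfg: AugmentConfig | None = None,
    patch_spec: PatchSpec | None = None,
) -> FoldResult:
    """Train one cross-validation fold and return its best checkpoint.

    The fold split, initial weights, augmentation draws and patch draws are all
    derived from ``train_cfg.seed``, so a rerun reproduces the run exactly.
    """
    augment_cfg = augment_cfg or AugmentConfig()
    patch_spec = patch_spec or PatchSpec()
    net_cfg.validate_patch_shape(patch_spec.patch_shape)

    splits = fold_split([c.case_id for c in cases], train_cfg.n_folds, train_cfg.seed)
    train_ids, val_ids = splits[fold_index]
    by_id = {c.case_id: c for c in cases}
    train_cases = [by_id[i] for i in train_ids]
    val_cases = [by_id[i] for i in val_ids]

    net = UNet3D(net_cfg, seed=(train_cfg.seed * 1000 + fold_index) % 2**31)
    opt = SGDNesterov(net.params(), lr=train_cfg.initial_lr, momentum=train_cfg.momentum)
    rng = np.random.default_rng([train_cfg.seed, fold_index, 17])

    total_steps = train_cfg.epochs * train_cfg.steps_per_epoch
    from .nn import poly_lr  # local import avoids a cycle at module load

    rows = []
    best: tuple[float, int, dict[str, np.ndarray]] | None = None
    step = 0
    for epoch in range(train_cfg.epochs):
        ep_dice, ep_ce = 0.0, 0.0
        for _ in range(train_cfg.steps_per_epoch):
            opt.lr = poly_lr(train_cfg.initial_lr, step, total_steps, train_cfg.lr_power)
            net.zero_grad()
            batch_imgs, batch_labels = [], []
            for _b in range(train_cfg.batch_size):
                case = train_cases[rng.integers(len(train_cases))]
                case = _augmented_case(case, train_cases, augment_cfg, rng)
                img, lab, _ = sample_patch(case, patch_spec, rng)
                batch_imgs.append(img)
                batch_labels.append(lab)
            x = np.stack(batch_imgs)
            logits = net.forward(x)
            grads = np.zeros_like(logits)
            for b in range(train_cfg.batch_size):
                terms, g = loss_and_grad(
                    logits[b], one_hot(batch_labels[b], net_cfg.n_classes),
                    ce_reduction=train_cfg.ce_reduction,
                )
                grads[b] = g / train_cfg.batch_size
                ep_dice += terms.dice_term / train_cfg.batch_size
                ep_ce += terms.ce_term / train_cfg.batch_size
            net.backward(grads)
            clip_grad_norm(net.params(), train_cfg.grad_clip)
            opt.step()
            step += 1

        val_dice = float(
            np.mean([_whole_volume_dice(net, c, patch_spec) for c in val_cases])
        ) if val_cases else float("nan")
        n = train_cfg.steps_per_epoch
        rows.append(
            {
                "epoch": epoch,
                "dice_term": ep_dice / n,
                "ce_term": ep_ce / n,
                "total": (ep_dice + ep_ce) / n,
                "val_dsc": val_dice,
            }
        )
        if val_cases and (best is None or val_dice > best[0]):
            best = (val_dice, epoch, net.state_dict())

    if best is None:  # no validation cases: keep the final weights
        best = (float("nan"), train_cfg.epochs - 1, net.state_dict())

    return FoldResult(
        fold_index=fold_index,
        state_dict=best[2],
        best_epoch=best[1],
        best_val_dice=best[0],
        history=pd.DataFrame(rows),
        train_ids=train_ids,
        val_ids=val_ids,
        net_config=net_cfg,
    )


def _whole_volume_dice(net: UNet3D, case: LongitudinalCase, patch_spec: PatchSpec) -> float:
    prob = predict_probability(net, case, patch_spec)
    pred = LabelMask((prob >= 0.5).astype(np.uint8), case.spacing)
    return dsc(pred, case.new_lesion_label)


def ensemble_predict(
    fold_results: Sequence[FoldResult],
    case: LongitudinalCase,
    patch_spec: PatchSpec,
    threshold: float = 0.5,
) -> LabelMask:
    """Average fold-model foreground probabilities, then threshold.

    For K = 2 the argmax of the mean softmax equals mean foreground
    probability >= 0.5. All checkpoints must share one network configuration.
    """
    if not fold_results:
        raise ValueError("ensemble_predict needs at least one fold model")
    cfg = fold_results[0].net_config
    for fr in fold_results[1:]:
        if fr.net_config != cfg:
            raise ValueError("fold checkpoints disagree on network configuration")
    acc = np.zeros(case.shape, dtype=np.float64)
    for fr in fold_results:
        net = UNet3D(cfg, seed=0)
        net.load_state_dict(fr.state_dict)
        acc += predict_probability(net, case, patch_spec)
    mean_prob = acc / len(fold_results)
    return LabelMask((mean_prob >= threshold).astype(np.uint8), case.spacing)


# --- checkpoint I/O ---------------------------------------------------------------


def save_checkpoint(result: FoldResult, path: str | Path) -> None:
    """Persist weights + network config + fold metadata as an .npz archive."""
    path = Path(path)
    meta = {
        "fold_index": result.fold_index,
        "best_epoch": result.best_epoch,
        "best_val_dice": result.best_val_dice,
        "train_ids": result.train_ids,
        "val_ids": result.val_ids,
        "net_config": asdict(result.net_config),
        "history": result.history.to_dict(orient="list"),
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **result.state_dict)


def load_checkpoint(path: str | Path) -> FoldResult:
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    cfg_dict = meta["net_config"]
    for key in ("lowest_level_stride", "other_strides"):
        cfg_dict[key] = tuple(cfg_dict[key])
    return FoldResult(
        fold_index=meta["fold_index"],
        state_dict=state,
        best_epoch=meta["best_epoch"],
        best_val_dice=meta["best_val_dice"],
        history=pd.DataFrame(meta["history"]),
        train_ids=meta["train_ids"],
        val_ids=meta["val_ids"],
        net_config=NetworkConfig(**cfg_dict),
    )
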