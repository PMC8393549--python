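"""Training protocol and loss-comparison benchmark for phantom datasets.

The harness trains the 2D U-Net slice-wise (axial slices, including
slices without foreground, preserving the class imbalance), sweeping a
learning-rate grid and checkpointing at an epoch grid.  The study-scale
defaults are Adam (beta1=0.9, beta2=0.999, eps=1e-7), batch size 5,
learning rates {1e-3, 1e-4, 1e-5} and epoch checkpoints {10, 20, 30};
:meth:`TrainConfig.desk_scale` is a reduced profile for CPU runs on
small phantoms.  The checkpoint with the highest mean foreground DSC on
the validation cases is selected (ties break to the lowest learning
rate, then the fewest epochs), used to predict the test volumes
slice-by-slice, and scored with the four-metric battery; the per-case
metric table feeds the Wilcoxon rank-scoring engine.

Class-frequency weights (inverse/median) are computed once over the full
training subset; distance weight maps (dtm/dpt) are computed per slice
from the ground truth, in voxel units, and cached before training.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import losses as losses_mod
from .distance_maps import class_weight_maps
from .metrics import dsc, evaluate_case, records_to_frame
from .ranking import RankReport, rank_benchmark
from .synthetic import PhantomCase

logger = logging.getLogger(__name__)

__all__ = [
    "UNetSpec",
    "TrainConfig",
    "SelectedModel",
    "ExperimentResult",
    "TrainingDivergedError",
    "build_unet",
    "train",
    "select_best",
    "predict_volume",
    "run_benchmark",
]


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class UNetSpec:
    """Architecture description (see :class:`segweight.unet.UNet2D`)."""

    in_channels: int = 1
    n_classes: int = 2
    base: int = 8
    depth: int = 2
    norm: bool = True


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation grid and constants.

    The defaults are the study-scale protocol; ``desk_scale`` shrinks the
    grid for CPU-sized experiments.
    """

    lr_grid: tuple = (1e-3, 1e-4, 1e-5)
    epoch_grid: tuple = (10, 20, 30)
    batch_size: int = 5
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-7
    seed: int = 0

    def __post_init__(self):
        if not self.lr_grid or not self.epoch_grid:
            raise ValueError("learning-rate and epoch grids must be nonempty")

    @classmethod
    def desk_scale(cls, seed: int = 0) -> "TrainConfig":
        return cls(lr_grid=(1e-3, 1e-4), epoch_grid=(3, 6), seed=seed)


@dataclass
class SelectedModel:
    """The checkpoint chosen on the validation set."""

    loss_name: str
    lr: float
    epochs: int
    val_score: float
    state: list = field(repr=False, default=None)


@dataclass
class ExperimentResult:
    selected: dict
    metric_table: pd.DataFrame
    rank_report: Optional[RankReport]
    logs: dict


def build_unet(spec: UNetSpec, seed: int = 0):
    """Instantiate the network; identical (spec, seed) gives identical
    initial parameters."""
    from .unet import UNet2D

    return UNet2D(spec.in_channels, spec.n_classes, base=spec.base,
                  depth=spec.depth, norm=spec.norm, seed=seed)


# ---------------------------------------------------------------------------
# data plumbing
# ---------------------------------------------------------------------------

def stack_slices(cases: Sequence[PhantomCase]):
    """All axial slices of a case list: X (S, C, H, W), Y (S, H, W)."""
    xs, ys = [], []
    for case in cases:
        for k in range(case.labels.shape[-1]):
            xs.append(case.image[:, :, :, k])
            ys.append(case.labels[:, :, k])
    return np.asarray(xs, dtype=np.float64), np.asarray(ys)


def _one_hot(y, n_classes):
    return np.eye(n_classes)[y]  # (..., C)


def _flatten_maps(maps):
    # (B, C, H, W) weight maps -> (B*H*W, C), matching flattened labels
    return np.ascontiguousarray(np.moveaxis(maps, 1, -1)).reshape(
        -1, maps.shape[1])


# ---------------------------------------------------------------------------
# training / selection / prediction
# ---------------------------------------------------------------------------

def train(net_spec: UNetSpec, train_cases: Sequence[PhantomCase],
          loss_name: str, config: TrainConfig):
    """Train the network for every learning rate in the grid.

    Returns ``(checkpoints, logs)``: parameter states keyed by
    ``(lr, epoch)`` for each epoch checkpoint, and per-lr lists of mean
    epoch losses.  Raises :class:`TrainingDivergedError` on a non-finite
    loss.
    """
    from .unet import Adam

    if loss_name not in losses_mod.LOSS_NAMES:
        raise ValueError(f"unknown loss {loss_name!r}")
    if not train_cases:
        raise ValueError("empty training set")
    x_all, y_all = stack_slices(train_cases)
    n_classes = net_spec.n_classes
    class_counts = np.bincount(y_all.ravel(), minlength=n_classes).astype(float)
    objective = losses_mod.make_loss(loss_name, class_counts=class_counts)
    scheme = objective.config.weighting
    weight_maps = None
    if scheme in ("dtm", "dpt"):
        weight_maps = np.stack([class_weight_maps(y, n_classes, scheme)
                                for y in y_all])
    g_all = _one_hot(y_all, n_classes)

    checkpoints, logs = {}, {}
    n_slices = x_all.shape[0]
    max_epoch = max(config.epoch_grid)
    for lr_idx, lr in enumerate(config.lr_grid):
        model = build_unet(net_spec, seed=config.seed)
        opt = Adam(model.params(), lr=lr, beta1=config.beta1,
                   beta2=config.beta2, eps=config.eps)
        rng = np.random.default_rng([config.seed, lr_idx])
        history = []
        for epoch in range(1, max_epoch + 1):
            order = rng.permutation(n_slices)
            epoch_losses = []
            for start in range(0, n_slices, config.batch_size):
                sel = order[start:start + config.batch_size]
                logits = model.forward(x_all[sel], train=True)
                zflat = np.moveaxis(logits, 1, -1).reshape(-1, n_classes)
                gflat = g_all[sel].reshape(-1, n_classes)
                wflat = (None if weight_maps is None
                         else _flatten_maps(weight_maps[sel]))
                value, dz = objective.value_and_grad(gflat, zflat,
                                                     weight_maps=wflat)
                if not np.isfinite(value):
                    raise TrainingDivergedError(
                        f"{loss_name}: non-finite loss at lr={lr}, "
                        f"epoch {epoch}")
                dlogits = np.moveaxis(
                    dz.reshape(logits.shape[0], logits.shape[2],
                               logits.shape[3], n_classes), -1, 1)
                model.zero_grad()
                model.backward(dlogits)
                opt.step()
                epoch_losses.append(value)
            history.append(float(np.mean(epoch_losses)))
            if epoch in config.epoch_grid:
                checkpoints[(lr, epoch)] = model.get_state()
        logs[lr] = history
        logger.info("%s lr=%g: loss %0.4f -> %0.4f", loss_name, lr,
                    history[0], history[-1])
    return checkpoints, logs


def predict_volume(model, image: np.ndarray) -> np.ndarray:
    """Slice-wise forward passes and per-voxel argmax, restacked to 3D.

    ``image`` has shape ``(in_channels, nx, ny, nz)``; returns integer
    labels of shape ``(nx, ny, nz)``.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 4 or image.shape[0] != model.in_channels:
        raise ValueError(f"expected ({model.in_channels}, nx, ny, nz) "
                         f"image, got {image.shape}")
    x = np.moveaxis(image, -1, 0)  # (nz, C, nx, ny)
    logits = model.forward(x, train=False)
    labels = logits.argmax(axis=1)  # (nz, nx, ny)
    return np.moveaxis(labels, 0, -1).astype(np.uint8)


def _mean_foreground_dsc(model, cases, n_classes) -> float:
    vals = []
    for case in cases:
        pred = predict_volume(model, case.image)
        for c in range(1, n_classes):
            vals.append(dsc(case.labels == c, pred == c))
    return float(np.mean(vals))


def select_best(checkpoints: dict, val_cases: Sequence[PhantomCase],
                net_spec: UNetSpec, config: TrainConfig,
                loss_name: str = "") -> SelectedModel:
    """Checkpoint maximising mean foreground DSC on the validation set.

    Ties (and the single-checkpoint case) resolve to the lowest learning
    rate, then the fewest epochs.
    """
    if not checkpoints:
        raise ValueError("no checkpoints to select from")
    if not val_cases:
        raise ValueError("empty validation set")
    model = build_unet(net_spec, seed=config.seed)
    best = None
    for (lr, epoch) in sorted(checkpoints):
        model.set_state(checkpoints[(lr, epoch)])
        score = _mean_foreground_dsc(model, val_cases, net_spec.n_classes)
        if not np.isfinite(score):
            continue
        if best is None or score > best.val_score:
            best = SelectedModel(loss_name=loss_name, lr=lr, epochs=epoch,
                                 val_score=score,
                                 state=checkpoints[(lr, epoch)])
    if best is None:
        raise TrainingDivergedError("every checkpoint scored non-finite")
    return best


# ---------------------------------------------------------------------------
# benchmark orchestration
# ---------------------------------------------------------------------------

def run_benchmark(dataset: dict, loss_names: Sequence[str],
                  net_spec: UNetSpec, config: TrainConfig,
                  spacing=None, tau: float = 1.0,
                  out_dir=None, rank: bool = True) -> ExperimentResult:
    """Full loss comparison: train, select, predict, evaluate, rank.

    ``dataset`` maps split names (train/val/test) to PhantomCase lists.
    With ``rank=True`` (needs >= 2 losses) the metric table is passed to
    the Wilcoxon rank-scoring engine.  When ``out_dir`` is given, the
    metric table, rank report, predictions and a run manifest are
    persisted.
    """
    loss_names = list(loss_names)
    if rank and len(loss_names) < 2:
        raise ValueError("ranking needs at least 2 losses")
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    selected, logs, records = {}, {}, []
    model = build_unet(net_spec, seed=config.seed)
    for loss_name in loss_names:
        checkpoints, logs[loss_name] = train(net_spec, dataset["train"],
                                             loss_name, config)
        best = select_best(checkpoints, dataset["val"], net_spec, config,
                           loss_name=loss_name)
        selected[loss_name] = best
        model.set_state(best.state)
        for case in dataset["test"]:
            pred = predict_volume(model, case.image)
            records += evaluate_case(case.labels, pred, spacing=spacing,
                                     classes=range(net_spec.n_classes),
                                     tau=tau, case_id=case.case_id,
                                     loss_id=loss_name)
            if out is not None:
                import nibabel as nib

                affine = np.diag(list(spacing or (1, 1, 1)) + [1.0])
                safe = loss_name.replace("/", "_")
                nib.save(nib.Nifti1Image(pred, affine),
                         out / f"pred_{safe}_{case.case_id}.nii.gz")
    table = records_to_frame(records)
    report = rank_benchmark(table) if rank else None
    if out is not None:
        table.to_csv(out / "metrics.csv", index=False)
        if report is not None:
            report.scores.to_csv(out / "rank.csv")
        manifest = {
            "losses": loss_names,
            "net_spec": dataclasses.asdict(net_spec),
            "train_config": dataclasses.asdict(config),
            "selected": {k: {"lr": v.lr, "epochs": v.epochs,
                             "val_score": v.val_score}
                         for k, v in selected.items()},
        }
        with open(out / "run.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return ExperimentResult(selected=selected, metric_table=table,
                            rank_report=report, logs=logs)
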