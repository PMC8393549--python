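"""Weighted cross-entropy and Dice losses for class-imbalanced segmentation.

Twelve objectives are provided: the plain cross-entropy (CE) and Dice
losses, each combined with five weighting strategies addressed by string
key ``"<base>/<weighting>"``:

==========  =================================================================
weighting   effect
==========  =================================================================
none        the base loss
inverse     per-class weight ``W_c = (sum_i g_ic)^-alpha`` (inverse class
            frequency; ``alpha=2`` with the Dice base gives the generalized
            Dice loss)
median      per-class weight ``W_c = median(F)/F_c`` with ``F_c`` the
            normalised class frequency
focal       per-voxel weight ``W_ic = (1 - p_ic)^gamma`` down-weighting
            confidently classified voxels
dtm         per-voxel weight ``1 + DTM_c`` (distance to the class boundary),
            emphasising errors far from the ground-truth boundary
dpt         per-voxel weight ``1 + DPT_c`` (bounded inverse of the DTM),
            emphasising errors near the boundary
==========  =================================================================

Class weights (inverse/median) multiply the per-class voxel sums; per-voxel
weights (focal/dtm/dpt) multiply each term of the double sum over classes
and voxels.  With the Dice base, inverse/median/focal weights enter both the
numerator and the denominator (generalised-Dice style), while dtm/dpt
weights multiply only the false-positive ``(1-g)p`` and false-negative
``g(1-p)`` denominator terms, leaving the overlap numerator unweighted.

All losses operate on flattened fields of shape ``(N, C)``: ``g`` one-hot
ground truth, ``p`` a per-voxel probability simplex.  Class frequencies are
meant to be accumulated over the full training set, not per batch.  Focal
weights are treated as a constant modulation per step: gradients do not
flow through the weight field.

Numerical conventions: probabilities are clipped to ``[eps, 1-eps]``
before logarithms, and Dice ratios carry ``eps`` in numerator and
denominator, so every loss is exactly/near zero at a perfect one-hot
prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "LossConfig",
    "WeightedLoss",
    "LOSS_NAMES",
    "cross_entropy",
    "dice_loss",
    "inverse_frequency_weights",
    "median_frequency_weights",
    "focal_weight_field",
    "weighted_cross_entropy",
    "weighted_dice",
    "make_loss",
    "softmax",
]

BASES = ("ce", "dice")
WEIGHTINGS = ("none", "inverse", "median", "focal", "dtm", "dpt")
#: the twelve named objectives, ``"<base>/<weighting>"``
LOSS_NAMES = tuple(f"{b}/{w}" for b in BASES for w in WEIGHTINGS)

_DEFAULT_ALPHA = {"ce": 1.0, "dice": 2.0}
_DEFAULT_GAMMA = {"ce": 2.0, "dice": 1.0}
_EPS = 1e-7


@dataclass(frozen=True)
class LossConfig:
    """Configuration of one weighted loss.

    ``alpha`` (inverse-frequency power) and ``gamma`` (focal focusing
    parameter) default per base loss: alpha 1 for CE / 2 for Dice, gamma
    2 for CE / 1 for Dice.
    """

    base: str = "ce"
    weighting: str = "none"
    alpha: Optional[float] = None
    gamma: Optional[float] = None
    epsilon: float = _EPS

    def __post_init__(self):
        if self.base not in BASES:
            raise ValueError(f"unknown base loss {self.base!r}")
        if self.weighting not in WEIGHTINGS:
            raise ValueError(f"unknown weighting {self.weighting!r}")
        if self.gamma is not None and self.gamma < 0:
            raise ValueError("focusing parameter gamma must be >= 0")

    @property
    def name(self) -> str:
        return f"{self.base}/{self.weighting}"

    @property
    def alpha_(self) -> float:
        return _DEFAULT_ALPHA[self.base] if self.alpha is None else self.alpha

    @property
    def gamma_(self) -> float:
        return _DEFAULT_GAMMA[self.base] if self.gamma is None else self.gamma


def _flatten(a) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        raise ValueError("fields must carry a trailing class axis")
    return a.reshape(-1, a.shape[-1])


def _validate_pair(g: np.ndarray, p: np.ndarray) -> None:
    if g.shape != p.shape:
        raise ValueError(f"shape mismatch: g {g.shape} vs p {p.shape}")
    if g.shape[-1] < 2:
        raise ValueError("need at least 2 classes (background included)")
    if not np.isin(g, (0.0, 1.0)).all() or not np.allclose(g.sum(axis=-1), 1.0):
        raise ValueError("g must be one-hot (binary, one 1 per voxel)")
    if (p < 0).any() or (p > 1).any() or not np.allclose(p.sum(axis=-1), 1.0, atol=1e-6):
        raise ValueError("p must be a per-voxel probability simplex")


def softmax(z) -> np.ndarray:
    """Channelwise softmax over the trailing axis, numerically stable."""
    z = np.asarray(z, dtype=float)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# class / voxel weight constructors
# ---------------------------------------------------------------------------

def _class_counts(g_or_counts) -> np.ndarray:
    a = np.asarray(g_or_counts, dtype=float)
    if a.ndim == 1:  # already a counts vector
        return a
    return _flatten(a).sum(axis=0)


def inverse_frequency_weights(g_or_counts, alpha: float = 1.0,
                              epsilon: float = _EPS) -> np.ndarray:
    """Per-class weights ``(sum_i g_ic)^-alpha``.

    Accepts a one-hot field or a precomputed per-class voxel-count vector
    (counts should span the whole training set).  Absent classes would get
    an infinite weight; their count is floored at ``epsilon`` and a warning
    is logged.
    """
    counts = _class_counts(g_or_counts)
    if (counts == 0).any():
        logger.warning("absent class(es) %s: epsilon-guarded inverse weights",
                       np.flatnonzero(counts == 0).tolist())
        counts = np.maximum(counts, epsilon)
    return counts ** (-float(alpha))


def median_frequency_weights(g_or_counts, epsilon: float = _EPS) -> np.ndarray:
    """Per-class weights ``median(F) / F_c``, ``F_c`` the normalised frequency."""
    counts = _class_counts(g_or_counts)
    freq = counts / counts.sum()
    if (freq == 0).any():
        logger.warning("absent class(es) %s: epsilon-guarded median weights",
                       np.flatnonzero(freq == 0).tolist())
        freq = np.maximum(freq, epsilon)
    return np.median(freq) / freq


def focal_weight_field(p, gamma: float) -> np.ndarray:
    """Per-voxel focal weights ``(1 - p_ic)^gamma``; gamma=0 gives all ones."""
    if gamma < 0:
        raise ValueError("focusing parameter gamma must be >= 0")
    p = np.asarray(p, dtype=float)
    return (1.0 - p) ** float(gamma)


# ---------------------------------------------------------------------------
# loss cores: value and gradient w.r.t. p
# ---------------------------------------------------------------------------

def _ce_core(g, p, voxel_w, class_w, eps, want_grad):
    n = g.shape[0]
    pc = np.clip(p, eps, 1.0 - eps)
    w = np.ones_like(g)
    if voxel_w is not None:
        w = w * voxel_w
    if class_w is not None:
        w = w * class_w  # broadcasts (C,) over voxels
    value = -(w * g * np.log(pc)).sum() / n
    if not want_grad:
        return value, None
    grad = -(w * g) / pc / n
    grad *= (p > eps) & (p < 1.0 - eps)  # clip region has zero derivative
    return value, grad


def _dice_core(g, p, voxel_w, class_w, distance_w, eps, want_grad):
    """Generic Dice ratio; exactly one weighting family may be active.

    voxel_w/class_w weight numerator and denominator (generalised-Dice
    style); distance_w weights only the FP and FN denominator terms.
    """
    if distance_w is not None:
        overlap = (g * p).sum()
        num = 2.0 * overlap + eps
        den = (2.0 * overlap
               + (distance_w * (1.0 - g) * p).sum()
               + (distance_w * g * (1.0 - p)).sum() + eps)
        if want_grad:
            dnum = 2.0 * g
            dden = 2.0 * g + distance_w * (1.0 - g) - distance_w * g
    else:
        w = np.ones_like(g)
        if voxel_w is not None:
            w = w * voxel_w
        if class_w is not None:
            w = w * class_w
        num = 2.0 * (w * g * p).sum() + eps
        den = (w * (g + p)).sum() + eps
        if want_grad:
            dnum = 2.0 * w * g
            dden = w
    value = 1.0 - num / den
    if not want_grad:
        return value, None
    grad = -(dnum * den - num * dden) / den ** 2
    return value, grad


# ---------------------------------------------------------------------------
# public loss functions
# ---------------------------------------------------------------------------

def cross_entropy(g, p, epsilon: float = _EPS) -> float:
    """Plain multi-class cross-entropy: mean over voxels of -log p(true class)."""
    g, p = _flatten(g), _flatten(p)
    _validate_pair(g, p)
    value, _ = _ce_core(g, p, None, None, epsilon, False)
    return float(value)


def dice_loss(g, p, epsilon: float = _EPS) -> float:
    """Plain Dice loss: one all-classes-pooled ratio, ``1 - 2*sum(gp)/(sum g + sum p)``."""
    g, p = _flatten(g), _flatten(p)
    _validate_pair(g, p)
    value, _ = _dice_core(g, p, None, None, None, epsilon, False)
    return float(value)


def _resolve_aux(config: LossConfig, g, p, class_weights, weight_maps,
                 focal_weights):
    """Return (voxel_w, class_w, distance_w) for the configured weighting."""
    w = config.weighting
    if w == "none":
        return None, None, None
    if w in ("inverse", "median"):
        if class_weights is None:
            class_weights = (inverse_frequency_weights(g, config.alpha_, config.epsilon)
                             if w == "inverse" else
                             median_frequency_weights(g, config.epsilon))
        class_weights = np.asarray(class_weights, dtype=float)
        if class_weights.shape != (g.shape[-1],):
            raise ValueError("class weight vector has wrong length")
        return None, class_weights, None
    if w == "focal":
        if focal_weights is None:
            focal_weights = focal_weight_field(p, config.gamma_)
        return np.asarray(focal_weights, dtype=float), None, None
    # dtm / dpt
    if weight_maps is None:
        raise ValueError(f"weighting {w!r} requires per-voxel weight maps")
    weight_maps = _flatten(weight_maps)
    if weight_maps.shape != g.shape:
        raise ValueError("weight maps must match the label field shape")
    return None, None, weight_maps


def weighted_cross_entropy(g, p, config: LossConfig, class_weights=None,
                           weight_maps=None, focal_weights=None) -> float:
    """Cross-entropy under ``config.weighting``; ``"none"`` reproduces
    :func:`cross_entropy`.

    ``class_weights`` (inverse/median) is a per-class vector, normally
    precomputed from training-set counts; ``weight_maps`` (dtm/dpt) are
    per-voxel per-class fields shaped like ``g``; ``focal_weights`` may be
    passed to freeze the focal modulation, otherwise it is computed from
    ``p``.
    """
    if config.base != "ce":
        raise ValueError("config.base must be 'ce'")
    g, p = _flatten(g), _flatten(p)
    _validate_pair(g, p)
    vw, cw, dw = _resolve_aux(config, g, p, class_weights, weight_maps,
                              focal_weights)
    if dw is not None:  # distance weights enter CE per voxel, like focal
        vw, dw = dw, None
    value, _ = _ce_core(g, p, vw, cw, config.epsilon, False)
    return float(value)


def weighted_dice(g, p, config: LossConfig, class_weights=None,
                  weight_maps=None, focal_weights=None) -> float:
    """Dice loss under ``config.weighting`` (see :func:`weighted_cross_entropy`)."""
    if config.base != "dice":
        raise ValueError("config.base must be 'dice'")
    g, p = _flatten(g), _flatten(p)
    _validate_pair(g, p)
    vw, cw, dw = _resolve_aux(config, g, p, class_weights, weight_maps,
                              focal_weights)
    value, _ = _dice_core(g, p, vw, cw, dw, config.epsilon, False)
    return float(value)


# ---------------------------------------------------------------------------
# the registry objective
# ---------------------------------------------------------------------------

class WeightedLoss:
    """A named differentiable objective closing over precomputed class weights.

    Evaluate with :meth:`value` on probabilities, or with
    :meth:`value_and_grad` on unnormalised logits (softmax applied
    internally) to obtain the analytic gradient used for optimisation.
    """

    def __init__(self, config: LossConfig, class_weights=None):
        self.config = config
        if config.weighting in ("inverse", "median") and class_weights is None:
            raise ValueError(
                f"{config.name}: training-set class counts/weights required")
        self.class_weights = (None if class_weights is None
                              else np.asarray(class_weights, dtype=float))

    @property
    def name(self) -> str:
        return self.config.name

    def __repr__(self):
        return f"WeightedLoss({self.name!r})"

    def value(self, g, p, weight_maps=None, focal_weights=None) -> float:
        fn = weighted_cross_entropy if self.config.base == "ce" else weighted_dice
        return fn(g, p, self.config, class_weights=self.class_weights,
                  weight_maps=weight_maps, focal_weights=focal_weights)

    def value_and_grad(self, g, logits, weight_maps=None):
        """Loss and its gradient w.r.t. ``logits``.

        The focal modulation, when active, is computed from the current
        probabilities and then held constant (no gradient through the
        weight field).
        """
        g = _flatten(g)
        z = _flatten(logits)
        if g.shape != z.shape:
            raise ValueError(f"shape mismatch: g {g.shape} vs logits {z.shape}")
        p = softmax(z)
        cfg = self.config
        vw, cw, dw = _resolve_aux(cfg, g, p, self.class_weights, weight_maps,
                                  None)
        if cfg.base == "ce":
            if dw is not None:
                vw, dw = dw, None
            value, dp = _ce_core(g, p, vw, cw, cfg.epsilon, True)
        else:
            value, dp = _dice_core(g, p, vw, cw, dw, cfg.epsilon, True)
        # chain rule through the softmax: dz = p * (dp - <dp, p>)
        dz = p * (dp - (dp * p).sum(axis=-1, keepdims=True))
        return float(value), dz.reshape(np.asarray(logits).shape)


def make_loss(name_or_config, class_counts=None, alpha=None, gamma=None,
              epsilon: float = _EPS) -> WeightedLoss:
    """Build one of the twelve named objectives.

    Parameters
    ----------
    name_or_config : str or LossConfig
        E.g. ``"dice/inverse"``; see :data:`LOSS_NAMES`.
    class_counts : array-like, optional
        Per-class voxel counts over the full training set; required for
        the inverse and median weightings.
    """
    if isinstance(name_or_config, LossConfig):
        config = name_or_config
    else:
        try:
            base, weighting = str(name_or_config).split("/")
        except ValueError:
            raise ValueError(f"loss name must look like 'ce/focal', got "
                             f"{name_or_config!r}") from None
        config = LossConfig(base=base, weighting=weighting, alpha=alpha,
                            gamma=gamma, epsilon=epsilon)
    class_weights = None
    if config.weighting == "inverse":
        if class_counts is None:
            raise ValueError(f"{config.name}: class_counts required")
        class_weights = inverse_frequency_weights(class_counts, config.alpha_,
                                                  config.epsilon)
    elif config.weighting == "median":
        if class_counts is None:
            raise ValueError(f"{config.name}: class_counts required")
        class_weights = median_frequency_weights(class_counts, config.epsilon)
    return WeightedLoss(config, class_weights=class_weights)
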