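"""Composite segmentation loss: weighted cross-entropy + soft Dice.

Class weights are *prior statistics*: pixel proportions of the five
classes are counted once over the training fold, and each class weight is
``1 - N_c / (H*W*D)`` with an extra ``-0.2`` offset for the two large
muscle regions (Rectus Abdominis, class 1, and Paravertebral, class 4),
so that the scarce psoas classes (2, 3) are up-weighted relative to
equally-proportioned large regions.  The background (class 0) uses the
no-offset branch: it is the largest region and naturally receives the
smallest weight.

Both loss terms are written as sums over the pixels of one axial image
and all five classes, then averaged over the 8 slices of the batch so the
magnitude does not depend on slab depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np

from .ioprep import N_CLASSES
from .nn.core import log_softmax, softmax

#: Per-class weight offsets: classes 1 and 4 (the large muscle regions)
#: are offset by 0.2; background and psoas classes are not.
DEFAULT_OFFSETS = (0.0, 0.2, 0.0, 0.0, 0.2)

DICE_EPS = 1e-5


@dataclass(frozen=True)
class ClassWeights:
    """Prior class weights ``omega_c`` for c in {0,...,4}."""

    omega: tuple[float, ...]
    counts: tuple[int, ...]
    total: int

    def __post_init__(self) -> None:
        if len(self.omega) != N_CLASSES:
            raise ValueError("need one weight per class")
        if not all(np.isfinite(self.omega)):
            raise ValueError("non-finite class weight")

    @classmethod
    def uniform(cls) -> "ClassWeights":
        return cls(omega=(1.0,) * N_CLASSES, counts=(0,) * N_CLASSES, total=0)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.omega, dtype=np.float64)


def compute_class_weights(training_labels, offsets=DEFAULT_OFFSETS) -> ClassWeights:
    """Pooled prior weights ``omega_c = 1 - N_c / (H*W*D*n_volumes) - offset_c``.

    ``training_labels`` is a sequence of label volumes (objects with a
    ``labels`` array or plain integer arrays).  Raises when any weight is
    non-positive (a class occupying more than ``1 - offset`` of all pixels
    is incompatible with the offset scheme).
    """
    arrays = [np.asarray(getattr(v, "labels", v)) for v in training_labels]
    if not arrays:
        raise ValueError("need at least one training label volume")
    counts = np.zeros(N_CLASSES, dtype=np.int64)
    total = 0
    for a in arrays:
        counts += np.bincount(a.ravel(), minlength=N_CLASSES)[:N_CLASSES]
        total += a.size
    omega = 1.0 - counts / total - np.asarray(offsets, dtype=np.float64)
    if np.any(omega <= 0):
        bad = np.nonzero(omega <= 0)[0].tolist()
        raise ValueError(
            f"non-positive weight for class(es) {bad}: class proportion "
            "exceeds 1 - offset"
        )
    return ClassWeights(
        omega=tuple(float(w) for w in omega),
        counts=tuple(int(c) for c in counts),
        total=int(total),
    )


@dataclass(frozen=True)
class LossValue:
    total: float
    ce_term: float
    dice_term: float


def _check_onehot(target) -> None:
    t = np.asarray(target)
    if t.ndim != 4:
        raise ValueError("target must be (B, C, H, W) one-hot")
    if not np.all((t == 0) | (t == 1)) or not np.all(t.sum(axis=1) == 1):
        raise ValueError("target is not one-hot")


def _weight_vector(weights: ClassWeights | None, use_weights: bool, like=None):
    if weights is None or not use_weights:
        w = np.ones(N_CLASSES)
    else:
        w = weights.as_array()
    # match the target dtype so float32 training stays float32 end to end
    if like is not None and np.asarray(like).dtype == np.float32:
        w = w.astype(np.float32)
    return w


def cross_entropy_loss(pred_logits, target, weights: ClassWeights | None = None,
                       use_weights: bool = True):
    """Class-weighted multi-class cross-entropy.

    Softmax over the class axis, ``-sum_i sum_c omega_c y_ic log p_ic``
    per image, averaged over the batch axis.  ``target`` must be one-hot
    with the same (B, C, H, W) shape as the logits.
    """
    _check_onehot(target)
    if tuple(np.shape(pred_logits)) != np.asarray(target).shape:
        raise ValueError("logit / target shape mismatch")
    w = _weight_vector(weights, use_weights, like=target).reshape(1, -1, 1, 1)
    logp = log_softmax(pred_logits, axis=1)
    per_image = -anp.sum(w * target * logp, axis=(1, 2, 3))
    return anp.mean(per_image)


def dice_loss(pred_probs, target, weights: ClassWeights | None = None,
              use_weights: bool = True, eps: float = DICE_EPS):
    """Class-weighted soft Dice complement.

    Per image and class: ``1 - (2 sum y*p + eps) / (sum y^2 + sum p^2 + eps)``,
    weighted by ``omega_c``, summed over classes and averaged over the
    batch.  The epsilon in numerator and denominator makes the term vanish
    when a class is absent from both prediction and target.
    """
    _check_onehot(target)
    if isinstance(pred_probs, np.ndarray):
        if pred_probs.min() < -1e-6 or pred_probs.max() > 1 + 1e-6:
            raise ValueError("predicted probabilities outside [0, 1]")
    w = _weight_vector(weights, use_weights, like=target).reshape(1, -1)
    inter = anp.sum(pred_probs * target, axis=(2, 3))
    denom = anp.sum(pred_probs**2, axis=(2, 3)) + anp.sum(target**2, axis=(2, 3))
    per_class = 1.0 - (2.0 * inter + eps) / (denom + eps)  # (B, C)
    return anp.mean(anp.sum(w * per_class, axis=1))


def combined_loss(pred_logits, target, weights: ClassWeights | None = None,
                  use_weights: bool = True) -> LossValue:
    """Total loss = cross-entropy + Dice, reported with both terms."""
    ce = cross_entropy_loss(pred_logits, target, weights, use_weights)
    dc = dice_loss(softmax(pred_logits, axis=1), target, weights, use_weights)
    return LossValue(total=float(ce + dc), ce_term=float(ce), dice_term=float(dc))


def combined_loss_scalar(pred_logits, target, weights: ClassWeights | None = None,
                         use_weights: bool = True):
    """Differentiable scalar total (for the training loop)."""
    ce = cross_entropy_loss(pred_logits, target, weights, use_weights)
    dc = dice_loss(softmax(pred_logits, axis=1), target, weights, use_weights)
    return ce + dc


def one_hot(labels: np.ndarray, n_classes: int = N_CLASSES) -> np.ndarray:
    """(B, H, W) integer labels -> (B, C, H, W) one-hot float array."""
    lab = np.asarray(labels)
    out = np.zeros((lab.shape[0], n_classes) + lab.shape[1:], dtype=np.float32)
    for c in range(n_classes):
        out[:, c] = lab == c
    return out
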