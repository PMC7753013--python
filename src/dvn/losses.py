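"""Loss functions for extremely class-imbalanced binary voxel labelling.

Four variants are exposed, selectable by name in the training config:

``cross_entropy``
    Mean negative log-likelihood (1/N scaling).
``balanced``
    Class-weighted sums with ``beta = |Y-|/|Y|`` on positives and
    ``1 - beta`` on negatives. Deliberately NOT mean-scaled: its value
    grows linearly with batch size, which is the numerical-instability
    failure mode the stable variants fix.
``l1_only``
    Per-class means: each class contributes its own mean log-loss. Scale
    stable while preserving the beta/(1-beta) weighting ratio.
``deepvesselnet``
    ``l1_only`` plus a false-prediction correction term whose weights
    gamma1, gamma2 in [0.5, 1] grow with the mean confidence of the wrong
    predictions (distance of their probabilities from the 0.5 center).

Probabilities are clipped to [eps, 1-eps] before any logarithm. Set
membership and the gamma weights are recomputed per batch but treated as
constants under differentiation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EPS",
    "PredictionBatch",
    "BatchPartition",
    "LossTerms",
    "cross_entropy",
    "balanced_cross_entropy",
    "partition_batch",
    "loss_l1",
    "loss_l2",
    "l1_only_loss",
    "deepvesselnet_loss",
    "loss_gradient",
    "get_loss",
    "LOSS_NAMES",
]

EPS = 1e-7


@dataclass
class PredictionBatch:
    """Paired per-example probabilities of label 1 and binary labels."""

    p: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=np.float64).ravel()
        self.y = np.asarray(self.y).ravel()
        if self.p.shape != self.y.shape:
            raise ValueError(
                f"p and y must have the same length, got {self.p.size} vs {self.y.size}"
            )
        if self.p.size < 1:
            raise ValueError("empty batch")
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
        uniq = np.unique(self.y)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"labels must be binary, got values {uniq}")
        self.y = self.y.astype(np.int8)

    @property
    def N(self) -> int:
        return self.p.size


@dataclass
class BatchPartition:
    """Index sets Y+, Y-, Yf+, Yf- at a probability threshold.

    Predicted label is positive iff p > threshold, so an example with
    p == threshold and y == 1 counts as a false negative.
    """

    Y_plus: np.ndarray
    Y_minus: np.ndarray
    Yf_plus: np.ndarray
    Yf_minus: np.ndarray
    threshold: float = 0.5


@dataclass
class LossTerms:
    """Decomposition of a loss value.

    ``gamma1``/``gamma2`` are None when undefined (no false predictions of
    the corresponding kind, or a loss without the correction term).
    """

    L: float
    L1: float
    L2: float = 0.0
    beta: float | None = None
    gamma1: float | None = None
    gamma2: float | None = None


def _clip(p: np.ndarray) -> np.ndarray:
    return np.clip(p, EPS, 1.0 - EPS)


def cross_entropy(batch: PredictionBatch) -> LossTerms:
    """Standard mean cross entropy with 1/N scaling."""
    p = _clip(batch.p)
    y = batch.y
    ll = y * np.log(p) + (1 - y) * np.log1p(-p)
    L = float(-np.mean(ll))
    return LossTerms(L=L, L1=L)


def balanced_cross_entropy(batch: PredictionBatch) -> LossTerms:
    """Class-balanced cross entropy: weighted sums, no mean scaling.

    beta = |Y-|/|Y| multiplies the positive-class sum, (1-beta) the
    negative-class sum. The value scales linearly under batch duplication.
    """
    p = _clip(batch.p)
    y = batch.y
    pos = y == 1
    neg = ~pos
    beta = float(np.count_nonzero(neg)) / batch.N
    L = float(-beta * np.sum(np.log(p[pos])) - (1.0 - beta) * np.sum(np.log1p(-p[neg])))
    return LossTerms(L=L, L1=L, beta=beta)


def partition_batch(batch: PredictionBatch, threshold: float = 0.5) -> BatchPartition:
    """Split a batch into true-class and false-prediction index sets."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    y = batch.y
    p = batch.p
    idx = np.arange(batch.N)
    pos = y == 1
    Y_plus = idx[pos]
    Y_minus = idx[~pos]
    Yf_plus = idx[~pos & (p > threshold)]
    Yf_minus = idx[pos & (p <= threshold)]
    return BatchPartition(Y_plus, Y_minus, Yf_plus, Yf_minus, threshold)


def loss_l1(batch: PredictionBatch, partition: BatchPartition) -> float:
    """Stable class-balanced term: per-class mean log-losses.

    A class absent from the batch contributes 0 (its normalizer would be
    0/0 otherwise; box-sampled batches can legitimately be all-background).
    """
    p = _clip(batch.p)
    L1 = 0.0
    if partition.Y_plus.size:
        L1 -= float(np.mean(np.log(p[partition.Y_plus])))
    if partition.Y_minus.size:
        L1 -= float(np.mean(np.log1p(-p[partition.Y_minus])))
    return L1


def loss_l2(
    batch: PredictionBatch,
    partition: BatchPartition,
    center: float = 0.5,
) -> tuple[float, float | None, float | None]:
    """False-prediction correction term and its confidence weights.

    gamma1 = center + mean over false positives of |(1-p) - center|;
    gamma2 = center + mean over false negatives of |p - center|. Note the
    asymmetric normalizers: the false-positive sum is divided by |Y+| and
    the false-negative sum by |Y-|. An empty false set contributes 0 and
    leaves its gamma undefined.
    """
    p = _clip(batch.p)
    n_plus = partition.Y_plus.size
    n_minus = partition.Y_minus.size
    gamma1: float | None = None
    gamma2: float | None = None
    L2 = 0.0
    if partition.Yf_plus.size and n_plus:
        q = 1.0 - p[partition.Yf_plus]  # P(y=0) for wrongly-positive examples
        gamma1 = center + float(np.mean(np.abs(q - center)))
        L2 -= gamma1 / n_plus * float(np.sum(np.log(q)))
    elif partition.Yf_plus.size:
        q = 1.0 - p[partition.Yf_plus]
        gamma1 = center + float(np.mean(np.abs(q - center)))
    if partition.Yf_minus.size and n_minus:
        q = p[partition.Yf_minus]  # P(y=1) for wrongly-negative examples
        gamma2 = center + float(np.mean(np.abs(q - center)))
        L2 -= gamma2 / n_minus * float(np.sum(np.log(q)))
    elif partition.Yf_minus.size:
        q = p[partition.Yf_minus]
        gamma2 = center + float(np.mean(np.abs(q - center)))
    return L2, gamma1, gamma2


def l1_only_loss(batch: PredictionBatch, threshold: float = 0.5) -> LossTerms:
    """The stable balanced term alone (ablation without FP-rate correction)."""
    part = partition_batch(batch, threshold)
    L1 = loss_l1(batch, part)
    beta = part.Y_minus.size / batch.N
    return LossTerms(L=L1, L1=L1, beta=beta)


def deepvesselnet_loss(
    batch: PredictionBatch, threshold: float = 0.5, center: float = 0.5
) -> LossTerms:
    """Stable balanced term plus false-prediction-rate correction."""
    part = partition_batch(batch, threshold)
    L1 = loss_l1(batch, part)
    L2, gamma1, gamma2 = loss_l2(batch, part, center)
    beta = part.Y_minus.size / batch.N
    return LossTerms(L=L1 + L2, L1=L1, L2=L2, beta=beta, gamma1=gamma1, gamma2=gamma2)


# ---------------------------------------------------------------------------
# Gradients (w.r.t. the probabilities; partition sets and gammas are
# constants under differentiation)
# ---------------------------------------------------------------------------


def _grad_cross_entropy(batch: PredictionBatch) -> np.ndarray:
    p = _clip(batch.p)
    y = batch.y
    return (-(y / p) + (1 - y) / (1.0 - p)) / batch.N


def _grad_balanced(batch: PredictionBatch) -> np.ndarray:
    p = _clip(batch.p)
    y = batch.y
    pos = y == 1
    beta = float(np.count_nonzero(~pos)) / batch.N
    g = np.zeros_like(p)
    g[pos] = -beta / p[pos]
    g[~pos] = (1.0 - beta) / (1.0 - p[~pos])
    return g


def _grad_l1(batch: PredictionBatch, part: BatchPartition) -> np.ndarray:
    p = _clip(batch.p)
    g = np.zeros_like(p)
    if part.Y_plus.size:
        g[part.Y_plus] = -1.0 / (part.Y_plus.size * p[part.Y_plus])
    if part.Y_minus.size:
        g[part.Y_minus] = 1.0 / (part.Y_minus.size * (1.0 - p[part.Y_minus]))
    return g


def _grad_l2(batch: PredictionBatch, part: BatchPartition, center: float) -> np.ndarray:
    p = _clip(batch.p)
    g = np.zeros_like(p)
    _, gamma1, gamma2 = loss_l2(batch, part, center)
    if part.Yf_plus.size and part.Y_plus.size and gamma1 is not None:
        g[part.Yf_plus] += gamma1 / (part.Y_plus.size * (1.0 - p[part.Yf_plus]))
    if part.Yf_minus.size and part.Y_minus.size and gamma2 is not None:
        g[part.Yf_minus] += -gamma2 / (part.Y_minus.size * p[part.Yf_minus])
    return g


def loss_gradient(
    name: str,
    batch: PredictionBatch,
    threshold: float = 0.5,
    center: float = 0.5,
) -> np.ndarray:
    """dL/dp for the named loss, elementwise over the batch."""
    if name == "cross_entropy":
        return _grad_cross_entropy(batch)
    if name == "balanced":
        return _grad_balanced(batch)
    part = partition_batch(batch, threshold)
    if name == "l1_only":
        return _grad_l1(batch, part)
    if name == "deepvesselnet":
        return _grad_l1(batch, part) + _grad_l2(batch, part, center)
    raise KeyError(f"unknown loss {name!r}")


def get_loss(name: str):
    """Look up a loss function by its config name."""
    try:
        return LOSS_NAMES[name]
    except KeyError:
        raise KeyError(
            f"unknown loss {name!r}; choose from {sorted(LOSS_NAMES)}"
        ) from None


LOSS_NAMES = {
    "cross_entropy": cross_entropy,
    "balanced": balanced_cross_entropy,
    "l1_only": l1_only_loss,
    "deepvesselnet": deepvesselnet_loss,
}
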