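"""Training loop, inference, and evaluation protocols.

Training follows plain stochastic gradient descent — no momentum, no
regularization — on one box per step, with the learning rate decayed by a
fixed factor every fixed number of iterations. Volumes are tiled into
non-overlapping boxes at training time only; inference runs on full
volumes.

Evaluation covers voxel-wise precision/recall/Dice for segmentation and
centerline tasks, and a hit-or-miss protocol for bifurcation detection: a
ground-truth point counts as detected when the odd-sided cube centered on
it overlaps any predicted positive voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .losses import LOSS_NAMES, PredictionBatch, get_loss, loss_gradient
from .models import FCN
from .volume import Volume3D

__all__ = [
    "TrainConfig",
    "SegMetrics",
    "BifurcationEval",
    "PRTrace",
    "TrainResult",
    "extract_boxes",
    "lr_schedule",
    "train",
    "predict",
    "seg_metrics",
    "evaluate_bifurcations",
    "preprocess_intensity",
]


@dataclass
class TrainConfig:
    learning_rate: float = 0.01  # 0.001 for finetuning
    decay: float = 0.99
    decay_every: int = 200
    iterations: int = 1000
    box_size: int = 64
    loss: str = "deepvesselnet"
    metric_interval: int = 5
    threshold: float = 0.5
    center: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 < self.decay <= 1.0:
            raise ValueError(f"decay must lie in (0, 1], got {self.decay}")
        if self.decay_every < 1:
            raise ValueError("decay_every must be >= 1")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if self.box_size < 1:
            raise ValueError("box_size must be >= 1")
        if self.loss not in LOSS_NAMES:
            raise ValueError(f"unknown loss {self.loss!r}; choose from {sorted(LOSS_NAMES)}")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if self.metric_interval < 1:
            raise ValueError("metric_interval must be >= 1")


@dataclass
class SegMetrics:
    precision: float
    recall: float
    dice: float

    def as_dict(self) -> dict:
        return {"precision": self.precision, "recall": self.recall, "dice": self.dice}


@dataclass
class BifurcationEval:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    detection_rate: float
    mean_err: float
    err_std: float

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "detection_rate": self.detection_rate,
            "mean_err": self.mean_err,
            "err_std": self.err_std,
        }


@dataclass
class PRTrace:
    """Precision/recall ratio recorded at fixed iteration intervals."""

    iterations: list[int] = field(default_factory=list)
    ratios: list[float] = field(default_factory=list)

    def record(self, iteration: int, precision: float, recall: float) -> None:
        if recall > 0:
            ratio = precision / recall
        elif precision > 0:
            ratio = float("inf")
        else:
            ratio = float("nan")
        self.iterations.append(iteration)
        self.ratios.append(ratio)

    def mean_abs_deviation(self) -> float:
        """Mean |ratio - 1| over the finite entries of the trace."""
        arr = np.asarray(self.ratios, dtype=np.float64)
        finite = np.isfinite(arr)
        if not np.any(finite):
            return float("nan")
        return float(np.mean(np.abs(arr[finite] - 1.0)))


@dataclass
class TrainResult:
    model: FCN
    trace: PRTrace
    losses: list[float]
    lrs: list[float]


def _as_array(v) -> np.ndarray:
    return np.asarray(v.data if isinstance(v, Volume3D) else v, dtype=np.float64)


def extract_boxes(volume, labels, size: int = 64):
    """Tile a volume and its labels into aligned non-overlapping boxes.

    The grid is regular with stride ``size``; boundary remainders are
    zero-padded up to a full box. The image may carry a leading channel
    axis; labels are 3-D.
    """
    if size < 1:
        raise ValueError("box size must be >= 1")
    x = _as_array(volume)
    y = _as_array(labels)
    if x.ndim == 3:
        x = x[np.newaxis]
    if x.shape[1:] != y.shape:
        raise ValueError(f"image {x.shape[1:]} and labels {y.shape} spatial shapes differ")
    spatial = y.shape
    counts = [int(np.ceil(n / size)) for n in spatial]
    boxes = []
    for bi in range(counts[0]):
        for bj in range(counts[1]):
            for bk in range(counts[2]):
                lo = (bi * size, bj * size, bk * size)
                hi = tuple(min(l + size, n) for l, n in zip(lo, spatial))
                xs = x[:, lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
                ys = y[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
                pad = [(0, size - (h - l)) for l, h in zip(lo, hi)]
                if any(p[1] for p in pad):
                    xs = np.pad(xs, [(0, 0)] + pad)
                    ys = np.pad(ys, pad)
                boxes.append((xs, ys))
    return boxes


def lr_schedule(step: int, config: TrainConfig) -> float:
    """Stepped exponential decay: lr0 * decay ** floor(step / decay_every)."""
    if step < 0:
        raise ValueError("step must be >= 0")
    return config.learning_rate * config.decay ** (step // config.decay_every)


def _counts(pred: np.ndarray, gt: np.ndarray) -> tuple[int, int, int]:
    tp = int(np.count_nonzero(pred & gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    return tp, fp, fn


def train(model: FCN, dataset, config: TrainConfig) -> TrainResult:
    """SGD over shuffled boxes, one box per step.

    ``dataset`` is a sequence of ``(image, labels)`` pairs (arrays or
    :class:`Volume3D`); images may have a leading channel axis. The
    precision/recall ratio on the current box is recorded every
    ``metric_interval`` iterations. Fully reproducible for a fixed seed.
    """
    if not dataset:
        raise ValueError("empty dataset")
    boxes = []
    for image, labels in dataset:
        boxes.extend(extract_boxes(image, labels, config.box_size))
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(boxes))
    cursor = 0

    trace = PRTrace()
    losses: list[float] = []
    lrs: list[float] = []
    loss_fn = get_loss(config.loss)
    for step in range(config.iterations):
        if cursor == len(order):
            order = rng.permutation(len(boxes))
            cursor = 0
        x, y = boxes[order[cursor]]
        cursor += 1

        prob, cache = model.forward_cache(x)
        batch = PredictionBatch(prob.ravel(), (y > 0).astype(np.int8).ravel())
        terms = loss_fn(batch)
        if not np.isfinite(terms.L):
            raise FloatingPointError(
                f"non-finite loss {terms.L} at iteration {step} (loss={config.loss})"
            )
        dprob = loss_gradient(
            config.loss, batch, threshold=config.threshold, center=config.center
        ).reshape(prob.shape)
        grads = model.backward(dprob, cache)
        lr = lr_schedule(step, config)
        model.sgd_step(grads, lr)

        losses.append(terms.L)
        lrs.append(lr)
        if (step + 1) % config.metric_interval == 0:
            pred = prob > config.threshold
            gt = y > 0
            tp, fp, fn = _counts(pred, gt)
            precision = tp / (tp + fp) if tp + fp else 0.0
            recall = tp / (tp + fn) if tp + fn else 0.0
            trace.record(step + 1, precision, recall)
    return TrainResult(model=model, trace=trace, losses=losses, lrs=lrs)


def predict(model: FCN, volume) -> np.ndarray:
    """Full-volume probability map (no tiling needed at test time)."""
    return model.forward(_as_array(volume))


def seg_metrics(prob, gt, threshold: float = 0.5) -> SegMetrics:
    """Voxel-wise precision, recall, and Dice as percentages.

    Conventions for empty denominators: a perfect all-background prediction
    scores 100 everywhere; an empty prediction against a nonempty ground
    truth scores 0 precision/recall/Dice.
    """
    p = _as_array(prob)
    g = _as_array(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    pred = p > threshold
    gt_mask = g > 0
    tp, fp, fn = _counts(pred, gt_mask)
    if tp + fp + fn == 0:
        return SegMetrics(100.0, 100.0, 100.0)
    precision = 100.0 * tp / (tp + fp) if tp + fp else (100.0 if fn == 0 else 0.0)
    recall = 100.0 * tp / (tp + fn) if tp + fn else 100.0
    dice = 100.0 * 2 * tp / (2 * tp + fp + fn)
    return SegMetrics(precision, recall, dice)


def evaluate_bifurcations(pred_mask, gt_points, cube: int = 5) -> BifurcationEval:
    """Hit-or-miss scoring of point detections against a predicted mask.

    A ground-truth point is a hit (TP) when the cube of side ``cube``
    centered on it contains at least one predicted positive voxel, a miss
    (FN) otherwise. Predicted positives are grouped into 26-connected
    components; a component whose voxels' cubes contain no ground-truth
    point counts as one FP. Localization error is the Euclidean distance
    from each hit point to its nearest predicted voxel.
    """
    if cube < 1 or cube % 2 == 0:
        raise ValueError(f"cube side must be odd and >= 1, got {cube}")
    half = cube // 2
    mask = _as_array(pred_mask) > 0
    points = np.atleast_2d(np.asarray(gt_points, dtype=np.float64))
    if points.size == 0:
        points = points.reshape(0, 3)
    if points.shape[1] != 3:
        raise ValueError("gt_points must be (n, 3)")
    n_gt = points.shape[0]

    coords = np.argwhere(mask).astype(np.float64)
    if coords.shape[0] == 0:
        return BifurcationEval(
            tp=0,
            fp=0,
            fn=n_gt,
            precision=100.0 if n_gt == 0 else 0.0,
            recall=100.0 if n_gt == 0 else 0.0,
            detection_rate=100.0 if n_gt == 0 else 0.0,
            mean_err=float("nan"),
            err_std=float("nan"),
        )

    pred_tree = cKDTree(coords)
    errors = []
    tp = 0
    for pt in points:
        center = np.rint(pt)
        cheb, _ = pred_tree.query(center, p=np.inf)
        if cheb <= half:
            tp += 1
            eucl, _ = pred_tree.query(pt, p=2)
            errors.append(eucl)
    fn = n_gt - tp

    # one FP per wrong 26-connected predicted component
    labeled, n_comp = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    fp = 0
    if n_gt:
        gt_tree = cKDTree(np.rint(points))
        for comp in range(1, n_comp + 1):
            comp_coords = np.argwhere(labeled == comp).astype(np.float64)
            dists, _ = gt_tree.query(comp_coords, p=np.inf)
            if np.min(dists) > half:
                fp += 1
    else:
        fp = n_comp

    precision = 100.0 * tp / (tp + fp) if tp + fp else (100.0 if n_gt == 0 else 0.0)
    detection = 100.0 * tp / (tp + fn) if tp + fn else 100.0
    mean_err = float(np.mean(errors)) if errors else float("nan")
    err_std = float(np.std(errors)) if errors else float("nan")
    return BifurcationEval(
        tp=tp,
        fp=fp,
        fn=fn,
        precision=precision,
        recall=detection,
        detection_rate=detection,
        mean_err=mean_err,
        err_std=err_std,
    )


def preprocess_intensity(volume, percentile: float = 99.9):
    """Quadratic bright-structure enhancement with high-intensity clipping.

    Clips at the given percentile, squares the normalized intensities, and
    rescales to [0, 255]. Constant volumes map to zeros.
    """
    arr = _as_array(volume)
    spacing = volume.spacing if isinstance(volume, Volume3D) else None
    hi = np.percentile(arr, percentile)
    arr = np.clip(arr, 0.0, hi if hi > 0 else None)
    vmax = arr.max()
    if vmax <= arr.min() or vmax <= 0:
        out = np.zeros_like(arr)
    else:
        out = (arr / vmax) ** 2 * 255.0
    return Volume3D(out, spacing) if spacing is not None else out
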