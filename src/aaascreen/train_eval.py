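"""Stratified cross-validation, the training loop, and threshold metrics.

Evaluation follows the screening convention: a case is called positive
when its AAA probability reaches the discrimination threshold (default
0.5, ties positive). Five metrics are derived from the confusion counts —
accuracy A, precision P, true-positive rate TPR, false-positive rate FPR
and F1 — plus the ROC curve and its area. Ratios with a zero denominator
are reported as NaN with a warning, never silently as 0, so that pooled
aggregation cannot be corrupted.

Cross-validation is stratified 5-fold: five disjoint test sets covering
all cases with class proportions preserved to within one case, and a
small stratified validation set drawn from the non-test cases of each
fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from . import nn
from .models3d import Model
from .preprocess import AnchorPoint, AugmentParams, Patch, augment, extract_patch, sample_augment_params


# --------------------------------------------------------------------------
# fold splitting
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldSplit:
    """One cross-validation fold: pairwise-disjoint id sets."""

    k: int
    train_ids: tuple
    val_ids: tuple
    test_ids: tuple

    def __post_init__(self):
        train, val, test = set(self.train_ids), set(self.val_ids), set(self.test_ids)
        if train & val or train & test or val & test:
            raise ValueError(f"fold {self.k}: train/val/test sets overlap")


def stratified_kfold(labels, k: int = 5, n_val: int = 6, seed: int = 0) -> list[FoldSplit]:
    """Split cases into k disjoint stratified test sets with a stratified
    validation subset per fold.

    ``labels`` maps position -> class; case ids are the positions. For each
    fold the test set is one of the k stratified partitions, ``n_val``
    validation cases are drawn stratified from the remaining cases, and
    everything else trains. Deterministic given ``seed``.
    """
    labels = np.asarray(labels, dtype=int)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"need at least {k} cases per class for {k}-fold stratification, "
            f"got counts {dict(zip(classes.tolist(), counts.tolist()))}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rng = np.random.default_rng(seed)
    folds = []
    for i, (rest_idx, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        rest_idx = np.asarray(rest_idx)
        # stratified validation draw: allocate n_val across classes
        # proportionally to their share among the non-test cases
        val_ids: list[int] = []
        remaining = n_val
        for j, cls in enumerate(classes):
            pool = rest_idx[labels[rest_idx] == cls]
            if j == len(classes) - 1:
                take = remaining
            else:
                take = int(round(n_val * len(pool) / len(rest_idx)))
                take = min(take, remaining)
            val_ids.extend(rng.choice(pool, size=min(take, len(pool)), replace=False))
            remaining -= min(take, len(pool))
        val_set = set(int(v) for v in val_ids)
        train_ids = tuple(int(r) for r in rest_idx if int(r) not in val_set)
        folds.append(
            FoldSplit(
                k=i,
                train_ids=train_ids,
                val_ids=tuple(sorted(val_set)),
                test_ids=tuple(int(t) for t in test_idx),
            )
        )
    return folds


# --------------------------------------------------------------------------
# confusion counts and derived metrics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


@dataclass(frozen=True)
class MetricsReport:
    """The five screening metrics at a fixed discrimination threshold.

    Undefined ratios (zero denominator) are NaN.
    """

    accuracy: float
    precision: float
    tpr: float
    fpr: float
    f1: float
    threshold: float = 0.5

    def as_dict(self) -> dict:
        return {
            "A": self.accuracy,
            "P": self.precision,
            "TPR": self.tpr,
            "FPR": self.fpr,
            "F1": self.f1,
            "DT": self.threshold,
        }


def confusion(labels, probabilities, dt: float = 0.5) -> ConfusionMatrix:
    """Threshold probabilities at ``dt`` (ties positive) and count outcomes."""
    labels = np.asarray(labels, dtype=int)
    probs = np.asarray(probabilities, dtype=float)
    if labels.shape != probs.shape:
        raise ValueError(f"length mismatch: {labels.shape} labels vs {probs.shape} probabilities")
    if labels.size and (probs.min() < 0 or probs.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    pred = probs >= dt
    pos = labels == 1
    return ConfusionMatrix(
        tp=int(np.sum(pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN", stacklevel=3)
        return float("nan")
    return num / den


def metrics(cm: ConfusionMatrix, dt: float = 0.5) -> MetricsReport:
    """Derive A, P, TPR, FPR and F1 from confusion counts."""
    if cm.total == 0:
        raise ValueError("cannot compute metrics of an empty confusion matrix")
    a = (cm.tp + cm.tn) / cm.total
    p = _ratio(cm.tp, cm.tp + cm.fp, "precision")
    tpr = _ratio(cm.tp, cm.tp + cm.fn, "TPR")
    fpr = _ratio(cm.fp, cm.fp + cm.tn, "FPR")
    if np.isnan(p) or np.isnan(tpr) or (p + tpr) == 0:
        f1 = float("nan")
        if not (np.isnan(p) or np.isnan(tpr)):
            warnings.warn("F1 undefined (P + TPR = 0); reporting NaN", stacklevel=2)
    else:
        f1 = 2 * p * tpr / (p + tpr)
    return MetricsReport(a, p, tpr, fpr, f1, dt)


def roc_auc(labels, probabilities):
    """ROC over all distinct thresholds and trapezoidal AUC.

    The trapezoidal area equals the probability that a random positive
    outscores a random negative, with ties counting one half.

    Returns
    -------
    (fpr, tpr, thresholds), auc
    """
    labels = np.asarray(labels, dtype=int)
    probs = np.asarray(probabilities, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thr = _sk_roc_curve(labels, probs)
    return (fpr, tpr, thr), float(_sk_auc(fpr, tpr))


# --------------------------------------------------------------------------
# likert records (storage + averaging only; the scoring itself is a manual
# radiologist reading)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LikertRecord:
    case_id: str
    score: int
    rater_id: str = ""
    note: str = ""

    def __post_init__(self):
        if self.score not in (1, 2, 3, 4, 5):
            raise ValueError(f"Likert score must be in 1..5, got {self.score}")


def mean_likert(records) -> float:
    if not records:
        raise ValueError("no Likert records to average")
    return float(np.mean([r.score for r in records]))


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

@dataclass
class Case:
    """One dataset entry: a preprocessed (windowed + resampled) volume, its
    anchor and its label."""

    case_id: str
    volume: object  # CTVolume, windowed to [-1, 1] at the working spacing
    anchor: AnchorPoint
    label: int


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 8
    lr: float = 1e-4
    lr_final: float | None = None  # cosine decay to this value; None = constant
    weight_decay: float = 0.0
    patience: int = 15  # early stopping on validation loss; <=0 disables
    augment: bool = True
    #: voxel-unit shift/offset bounds; scale these down on grids coarser
    #: than the 0.9/1.5 mm reference so physical jitter stays comparable
    augment_bounds: dict = field(
        default_factory=lambda: {"max_shift": 10, "max_center_offset": 32}
    )
    patch_shape: tuple = (64, 64, 64)
    seed: int = 0


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_accuracy: list = field(default_factory=list)
    best_epoch: int = -1


def _patch_stack(cases, shape, rng=None, do_augment=False, bounds=None):
    out = np.empty((len(cases), 1) + tuple(shape), dtype=np.float32)
    for i, case in enumerate(cases):
        if do_augment:
            params = sample_augment_params(rng, **(bounds or {}))
            patch = augment(case.volume, case.anchor, params, shape, volume_id=case.case_id)
        else:
            patch = extract_patch(case.volume, case.anchor, shape, volume_id=case.case_id)
        out[i, 0] = patch.data
    return out


def _eval_loss(model: Model, cases, shape):
    """Validation loss/accuracy on unaugmented patches."""
    model.set_train(False)
    x = _patch_stack(cases, shape)
    labels = np.array([c.label for c in cases])
    logits = model.forward(x)
    loss, _ = nn.cross_entropy(logits, labels)
    probs = nn.softmax(logits.astype(np.float64))[:, 1]
    acc = float(np.mean((probs >= 0.5).astype(int) == labels))
    return loss, acc, probs


def _calibrate(model, train_cases, config, rng, max_cases: int = 32):
    cases = train_cases
    if len(cases) > max_cases:
        idx = rng.choice(len(cases), size=max_cases, replace=False)
        cases = [cases[i] for i in idx]

    def batches():
        for start in range(0, len(cases), config.batch_size):
            yield _patch_stack(cases[start : start + config.batch_size], config.patch_shape)

    nn.calibrate_batchnorm(model.net, batches())


def train(model: Model, dataset, split: FoldSplit, config: TrainConfig):
    """Train on a fold's training cases with per-epoch validation.

    ``dataset`` maps case id -> :class:`Case`. Training patches are drawn
    with fresh augmentation parameters every epoch (when enabled);
    validation always uses plain anchor-centred patches. The parameters of
    the epoch with the lowest validation loss are restored at the end.

    Raises
    ------
    ValueError
        On an empty training set or unresolvable ids.
    FloatingPointError
        If the loss becomes non-finite (with the offending epoch named).
    """
    if not split.train_ids:
        raise ValueError("empty training set")
    try:
        train_cases = [dataset[i] for i in split.train_ids]
        val_cases = [dataset[i] for i in split.val_ids]
    except KeyError as e:  # pragma: no cover - defensive
        raise ValueError(f"case id {e} in split not resolvable in dataset") from e

    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.net, lr=config.lr, weight_decay=config.weight_decay)
    labels_all = np.array([c.label for c in train_cases])
    history = TrainHistory()
    best_state, best_val, best_epoch = None, np.inf, -1
    since_best = 0

    for epoch in range(config.epochs):
        if config.lr_final is not None and config.epochs > 1:
            frac = epoch / (config.epochs - 1)
            opt.lr = config.lr_final + 0.5 * (config.lr - config.lr_final) * (
                1 + np.cos(np.pi * frac)
            )
        model.set_train(True)
        order = rng.permutation(len(train_cases))
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            x = _patch_stack(
                [train_cases[i] for i in idx],
                config.patch_shape,
                rng,
                config.augment,
                config.augment_bounds,
            )
            nn.zero_grads(model.net)
            logits = model.forward(x)
            loss, dlogits = nn.cross_entropy(logits, labels_all[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            model.net.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(idx)
        history.train_loss.append(epoch_loss / len(order))

        if val_cases:
            # refresh BN inference statistics for the current weights before
            # eval-mode use; running estimates trail badly on short runs
            _calibrate(model, train_cases, config, rng)
            val_loss, val_acc, _ = _eval_loss(model, val_cases, config.patch_shape)
            history.val_loss.append(val_loss)
            history.val_accuracy.append(val_acc)
            if val_loss < best_val:
                best_val, best_epoch = val_loss, epoch
                best_state = nn.get_state(model.net)
                since_best = 0
            else:
                since_best += 1
                if config.patience > 0 and since_best >= config.patience:
                    break

    if best_state is not None:
        nn.set_state(model.net, best_state)
        history.best_epoch = best_epoch
    else:
        # without validation the final weights are returned; give them
        # freshly calibrated inference statistics
        _calibrate(model, train_cases, config, rng)
    model.set_train(False)
    return model, history


def evaluate(model: Model, dataset, ids, patch_shape) -> tuple[np.ndarray, np.ndarray]:
    """AAA probabilities for the given case ids (unaugmented patches)."""
    cases = [dataset[i] for i in ids]
    model.set_train(False)
    labels = np.array([c.label for c in cases])
    probs = np.empty(len(cases))
    batch = 8
    for start in range(0, len(cases), batch):
        x = _patch_stack(cases[start : start + batch], patch_shape)
        logits = model.forward(x)
        probs[start : start + batch] = nn.softmax(logits.astype(np.float64))[:, 1]
    return labels, probs
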