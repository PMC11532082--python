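"""Training protocol, stratified cross-validation and evaluation metrics.

Follows the study protocol: Adam at 1e-3 with cosine learning-rate decay,
mini-batches of 16, stratified k-fold cross-validation, and per-fold
accuracy / precision / recall / F1 / one-vs-rest AUC / confusion matrix.
Feature standardization statistics are computed on each training fold only
and applied to its test fold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import IO, Sequence

import numpy as np
from sklearn.metrics import (
    confusion_matrix as sk_confusion,
    precision_recall_fscore_support,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold

from .morphometrics import compute_feature_vector
from .net import FusionConfig, FusionNet, TrainConfig, cross_entropy
from .nn import Adam, cosine_lr
from .nn.tensor import Tensor
from .projection import project
from .swc import NeuronTree

__all__ = [
    "FoldReport",
    "prepare_arrays",
    "stratified_folds",
    "fit",
    "evaluate",
    "cross_validate",
]


# --------------------------------------------------------------------------
# dataset preparation
# --------------------------------------------------------------------------

def prepare_arrays(
    trees: Sequence[NeuronTree],
    labels: Sequence[str] | None = None,
    resolution: int = 32,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Extract (morphometrics, projection stacks, encoded labels, class names).

    Labels default to each tree's ``class_label``.
    """
    if labels is None:
        labels = [t.class_label or "" for t in trees]
    feats = np.stack([compute_feature_vector(t).values for t in trees])
    imgs = np.stack([project(t, resolution=resolution).pixels for t in trees])
    classes = sorted(set(labels))
    lut = {c: i for i, c in enumerate(classes)}
    y = np.array([lut[l] for l in labels], dtype=int)
    return feats, imgs, y, classes


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (test - mu) / sd


def _onehot(y: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros((len(y), k))
    out[np.arange(len(y)), y] = 1.0
    return out


def _augment_images(imgs: np.ndarray, rng: np.random.Generator, max_shift: int) -> np.ndarray:
    """Random horizontal/vertical flips plus integer shifts, per sample."""
    out = imgs.copy()
    n = len(out)
    flip_h = rng.random(n) < 0.5
    flip_v = rng.random(n) < 0.5
    out[flip_h] = out[flip_h, :, :, ::-1]
    out[flip_v] = out[flip_v, :, ::-1, :]
    if max_shift > 0:
        shifts = rng.integers(-max_shift, max_shift + 1, size=(n, 2))
        for i, (dy, dx) in enumerate(shifts):
            if dy or dx:
                out[i] = np.roll(out[i], (dy, dx), axis=(1, 2))
    return out


# --------------------------------------------------------------------------
# folds
# --------------------------------------------------------------------------

def stratified_folds(labels: Sequence, k: int, seed: int) -> list[np.ndarray]:
    """k disjoint, label-stratified test-index sets covering all samples."""
    y = np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    if k > counts.min():
        raise ValueError(
            f"k={k} exceeds the smallest class count ({counts.min()})"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(y)), y)]


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

@dataclass
class FoldReport:
    """Per-fold evaluation: rates in [0, 1], counts in the confusion matrix."""

    fold_index: int
    accuracy: float
    precision: np.ndarray  # per class
    recall: np.ndarray
    f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    auc: np.ndarray  # per class, one-vs-rest
    confusion_matrix: np.ndarray
    n_test: int = 0
    history: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "fold_index": self.fold_index,
            "accuracy": self.accuracy,
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1": self.f1.tolist(),
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "auc": self.auc.tolist(),
            "confusion_matrix": self.confusion_matrix.tolist(),
            "n_test": self.n_test,
        }


def evaluate(
    model: FusionNet,
    x_feat: np.ndarray,
    x_img: np.ndarray,
    y: np.ndarray,
    fold_index: int = 0,
    batch_size: int = 64,
) -> FoldReport:
    """Score a trained model on a held-out set."""
    k = model.config.n_classes
    probs = predict_proba_batched(model, x_feat, x_img, batch_size)
    pred = probs.argmax(axis=1)
    labels = np.arange(k)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y, pred, labels=labels, zero_division=0
    )
    cm = sk_confusion(y, pred, labels=labels)
    auc = np.zeros(k)
    for c in range(k):
        pos = y == c
        if pos.any() and (~pos).any():
            auc[c] = roc_auc_score(pos.astype(int), probs[:, c])
        else:
            auc[c] = np.nan
    return FoldReport(
        fold_index=fold_index,
        accuracy=float((pred == y).mean()),
        precision=prec,
        recall=rec,
        f1=f1,
        macro_precision=float(prec.mean()),
        macro_recall=float(rec.mean()),
        macro_f1=float(f1.mean()),
        auc=auc,
        confusion_matrix=cm,
        n_test=len(y),
    )


def predict_proba_batched(
    model: FusionNet, x_feat: np.ndarray, x_img: np.ndarray, batch_size: int = 64
) -> np.ndarray:
    out = []
    for i in range(0, len(x_feat), batch_size):
        out.append(
            model.predict_proba(
                x_feat[i : i + batch_size], x_img[i : i + batch_size]
            )
        )
    return np.concatenate(out, axis=0)


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

def fit(
    config: FusionConfig,
    x_feat: np.ndarray,
    x_img: np.ndarray,
    y: np.ndarray,
    train_config: TrainConfig | None = None,
    val: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    log_stream: IO[str] | None = None,
) -> tuple[FusionNet, list[dict]]:
    """Train a fusion network; returns the model and the per-epoch log.

    Inputs are assumed already standardized where desired.  The per-epoch
    log records train loss/accuracy (and validation metrics when ``val`` is
    given); ``log_stream`` additionally receives it as JSON lines.
    """
    if len(y) == 0:
        raise ValueError("empty training set")
    tc = train_config or TrainConfig()
    rng = np.random.default_rng(tc.seed)
    model = FusionNet(config, seed=tc.seed)
    opt = Adam(model.parameters(), lr=tc.learning_rate)
    n = len(y)
    k = config.n_classes
    history: list[dict] = []
    best_val, patience_left = -np.inf, tc.patience
    for epoch in range(tc.epochs):
        if tc.cosine_decay:
            opt.lr = cosine_lr(tc.learning_rate, epoch, tc.epochs)
        model.train()
        order = rng.permutation(n)
        losses, correct = [], 0
        for i in range(0, n, tc.batch_size):
            idx = order[i : i + tc.batch_size]
            xb_f = Tensor(x_feat[idx])
            batch_img = x_img[idx]
            if tc.augment:
                batch_img = _augment_images(batch_img, rng, tc.max_shift)
            xb_i = Tensor(batch_img)
            logits = model.forward(xb_f, xb_i)
            loss = cross_entropy(logits, _onehot(y[idx], k))
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            correct += int((logits.data.argmax(axis=1) == y[idx]).sum())
        entry = {
            "epoch": epoch,
            "lr": opt.lr,
            "train_loss": float(np.mean(losses)),
            "train_accuracy": correct / n,
        }
        if val is not None:
            vf, vi, vy = val
            vp = predict_proba_batched(model, vf, vi)
            entry["val_accuracy"] = float((vp.argmax(axis=1) == vy).mean())
            entry["val_loss"] = float(
                -np.mean(
                    np.log(np.clip(vp[np.arange(len(vy)), vy], 1e-12, None))
                )
            )
        history.append(entry)
        if log_stream is not None:
            log_stream.write(json.dumps(entry) + "\n")
        if tc.early_stopping and val is not None:
            if entry["val_accuracy"] > best_val:
                best_val, patience_left = entry["val_accuracy"], tc.patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break
    return model, history


def cross_validate(
    config: FusionConfig,
    x_feat: np.ndarray,
    x_img: np.ndarray,
    y: np.ndarray,
    k: int = 10,
    seed: int = 0,
    train_config: TrainConfig | None = None,
) -> dict:
    """Stratified k-fold cross-validation; returns per-fold reports and
    mean/sd aggregates of every metric."""
    tc = train_config or TrainConfig()
    folds = stratified_folds(y, k, seed)
    all_idx = np.arange(len(y))
    reports: list[FoldReport] = []
    for fi, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        xf_tr, xf_te = x_feat[train_idx], x_feat[test_idx]
        if config.standardize_features:
            xf_tr, xf_te = _standardize(xf_tr, xf_te)
        fold_tc = TrainConfig(**{**tc.to_dict(), "seed": tc.seed + fi})
        model, history = fit(
            config, xf_tr, x_img[train_idx], y[train_idx], fold_tc
        )
        report = evaluate(model, xf_te, x_img[test_idx], y[test_idx], fold_index=fi)
        report.history = history
        reports.append(report)
    accs = np.array([r.accuracy for r in reports])
    return {
        "fold_reports": reports,
        "accuracy_mean": float(accs.mean()),
        "accuracy_sd": float(accs.std()),
        "macro_f1_mean": float(np.mean([r.macro_f1 for r in reports])),
        "macro_precision_mean": float(np.mean([r.macro_precision for r in reports])),
        "macro_recall_mean": float(np.mean([r.macro_recall for r in reports])),
        "auc_mean": float(
            np.nanmean(np.concatenate([r.auc for r in reports]))
        ),
        "k": k,
    }
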