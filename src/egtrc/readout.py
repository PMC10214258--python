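"""Trained linear readout over reservoir states and its evaluation.

The readout is the only trained part of the system: a fully connected map
from the (standardized) reservoir states to the four gait classes.  The
default is multinomial softmax regression (cross-entropy minimisation,
mild L2); a ridge-regularised least-squares fit onto one-hot targets is
available as an alternative mode.  Includes the confusion-matrix report,
the accuracy-vs-readout-size sweep (uniform temporal downsampling of the
states by default) and a label-permutation null.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

logger = logging.getLogger(__name__)

__all__ = [
    "ReadoutModel",
    "EvalReport",
    "train_readout",
    "predict",
    "evaluate",
    "single_run",
    "size_sweep",
    "uniform_downsample_indices",
    "permutation_null",
    "stratified_split_indices",
    "model_to_json",
    "model_from_json",
]


@dataclass
class ReadoutModel:
    """Weights/intercepts of the trained readout plus its feature scaling.

    ``weights`` has shape (n_states_used, n_classes); dropped (constant)
    features keep a zero row so the model applies to full-width inputs.
    """

    weights: np.ndarray
    intercepts: np.ndarray
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    classes: np.ndarray
    training_seed: int
    n_states_used: int
    mode: str = "softmax"
    dropped_features: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.weights.shape != (self.n_states_used, len(self.classes)):
            raise ValueError("weight matrix shape mismatch")
        if not (
            np.all(np.isfinite(self.feature_mean))
            and np.all(np.isfinite(self.feature_scale))
        ):
            raise ValueError("scaling constants must be finite")


@dataclass(frozen=True)
class EvalReport:
    """Confusion counts (rows = truth), overall and per-class accuracy."""

    confusion: np.ndarray
    accuracy: float
    per_class_accuracy: np.ndarray
    classes: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.confusion,
            index=[f"true_{c}" for c in self.classes],
            columns=[f"pred_{c}" for c in self.classes],
        )


def _standardize_fit(states: np.ndarray) -> tuple[np.ndarray, np.ndarray, list[int]]:
    mean = states.mean(axis=0)
    scale = states.std(axis=0)
    dropped = [int(k) for k in np.flatnonzero(scale == 0.0)]
    if dropped:
        logger.warning(
            "dropping %d constant reservoir-state feature(s): %s",
            len(dropped),
            dropped,
        )
        scale = scale.copy()
        scale[dropped] = 1.0
    return mean, scale, dropped


def train_readout(
    states: np.ndarray,
    labels: Sequence[str],
    seed: int = 0,
    mode: str = "softmax",
    l2: float = 1.0,
) -> ReadoutModel:
    """Fit the fully connected readout on centred/scaled states.

    mode="softmax": multinomial logistic regression (lbfgs, inverse
    regularisation strength C = 1/l2 on standardized features).
    mode="ridge": closed-form ridge regression onto one-hot targets.
    Deterministic given (states, labels, seed).
    """
    states = np.asarray(states, dtype=float)
    labels = np.asarray(labels)
    if states.ndim != 2 or states.shape[0] != len(labels):
        raise ValueError("states must be (n_samples, n_features) matching labels")
    if not np.all(np.isfinite(states)):
        raise ValueError("states contain non-finite values")
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least two classes to train")

    mean, scale, dropped = _standardize_fit(states)
    z = (states - mean) / scale
    if dropped:
        z[:, dropped] = 0.0

    n_features = states.shape[1]
    n_classes = len(classes)
    if mode == "softmax":
        clf = LogisticRegression(
            C=1.0 / l2, max_iter=5000, random_state=seed, solver="lbfgs"
        )
        clf.fit(z, labels)
        weights = clf.coef_.T.copy()  # (n_features, n_classes)
        intercepts = clf.intercept_.copy()
        if n_classes == 2:  # sklearn stores one column for the binary case
            weights = np.column_stack([-weights[:, 0], weights[:, 0]]) / 2.0
            intercepts = np.array([-intercepts[0], intercepts[0]]) / 2.0
        classes = clf.classes_
    elif mode == "ridge":
        onehot = (labels[:, None] == classes[None, :]).astype(float)
        zc = np.column_stack([z, np.ones(len(z))])
        gram = zc.T @ zc + l2 * np.eye(n_features + 1)
        gram[-1, -1] -= l2  # no penalty on the intercept
        coef = np.linalg.solve(gram, zc.T @ onehot)
        weights, intercepts = coef[:-1], coef[-1]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if dropped:
        weights[dropped, :] = 0.0
    return ReadoutModel(
        weights=weights,
        intercepts=intercepts,
        feature_mean=mean,
        feature_scale=scale,
        classes=np.asarray(classes),
        training_seed=seed,
        n_states_used=n_features,
        mode=mode,
        dropped_features=tuple(dropped),
    )


def predict(
    model: ReadoutModel, states: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Labels and row-normalised class probabilities (softmax of scores).

    Ties break toward the lower class index (argmax order).
    """
    states = np.asarray(states, dtype=float)
    if states.ndim == 1:
        states = states[None, :]
    if states.shape[1] != model.n_states_used:
        raise ValueError(
            f"expected {model.n_states_used} features, got {states.shape[1]}"
        )
    z = (states - model.feature_mean) / model.feature_scale
    if model.dropped_features:
        z[:, list(model.dropped_features)] = 0.0
    scores = z @ model.weights + model.intercepts
    scores -= scores.max(axis=1, keepdims=True)
    probs = np.exp(scores)
    probs /= probs.sum(axis=1, keepdims=True)
    return model.classes[np.argmax(probs, axis=1)], probs


def evaluate(
    model: ReadoutModel, states: np.ndarray, labels: Sequence[str]
) -> EvalReport:
    """Confusion matrix and accuracy of the model on a labelled set."""
    labels = np.asarray(labels)
    unseen = set(labels) - set(model.classes)
    if unseen:
        raise ValueError(f"labels not seen in training: {sorted(unseen)}")
    pred, _ = predict(model, states)
    n = len(model.classes)
    index = {c: k for k, c in enumerate(model.classes)}
    confusion = np.zeros((n, n), dtype=int)
    for truth, guess in zip(labels, pred):
        confusion[index[truth], index[guess]] += 1
    row_sums = confusion.sum(axis=1)
    per_class = np.divide(
        np.diag(confusion), row_sums,
        out=np.zeros(n), where=row_sums > 0,
    )
    accuracy = float(np.trace(confusion)) / float(len(labels))
    return EvalReport(
        confusion=confusion,
        accuracy=accuracy,
        per_class_accuracy=per_class,
        classes=model.classes.copy(),
    )


# ---------------------------------------------------------------------------
# Protocol helpers: splits, size sweep, permutation null
# ---------------------------------------------------------------------------


def stratified_split_indices(
    labels: Sequence[str], train_fraction: float = 0.5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified shuffle-split index pair over an already-built matrix."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        order = rng.permutation(len(members))
        n_train = int(np.clip(round(len(members) * train_fraction), 1,
                              len(members) - 1))
        train_idx.extend(members[order[:n_train]])
        test_idx.extend(members[order[n_train:]])
    return np.array(train_idx), np.array(test_idx)


def single_run(
    states: np.ndarray,
    labels: Sequence[str],
    split_seed: int = 0,
    train_fraction: float = 0.5,
    mode: str = "softmax",
    feature_indices: np.ndarray | None = None,
) -> tuple[float, EvalReport]:
    """One stratified split -> train -> evaluate pass; returns test accuracy."""
    labels = np.asarray(labels)
    x = np.asarray(states, dtype=float)
    if feature_indices is not None:
        x = x[:, feature_indices]
    tr, te = stratified_split_indices(labels, train_fraction, split_seed)
    model = train_readout(x[tr], labels[tr], seed=split_seed, mode=mode)
    report = evaluate(model, x[te], labels[te])
    return report.accuracy, report


def uniform_downsample_indices(n_states: int, size: int) -> np.ndarray:
    """Keep every floor(n_states/size)-th state (whole-horizon coverage)."""
    if size > n_states:
        raise ValueError("size exceeds the number of states")
    stride = n_states // size
    return np.arange(0, n_states, stride)[:size]


def size_sweep(
    states: np.ndarray,
    labels: Sequence[str],
    sizes: Sequence[int],
    reduction: str = "uniform_downsample",
    seed: int = 0,
    repeats: int = 10,
    mode: str = "softmax",
) -> pd.DataFrame:
    """Accuracy vs readout size, averaged over repeated stratified splits."""
    states = np.asarray(states, dtype=float)
    labels = np.asarray(labels)
    n_states = states.shape[1]
    n_classes = len(np.unique(labels))
    rows = []
    for size in sizes:
        if size < n_classes:
            raise ValueError(
                f"readout size {size} below the number of classes {n_classes}"
            )
        if reduction == "uniform_downsample":
            idx = uniform_downsample_indices(n_states, size)
        elif reduction == "first_k":
            idx = np.arange(size)
        else:
            raise ValueError(f"unknown reduction {reduction!r}")
        accs = [
            single_run(states, labels, split_seed=seed + r, mode=mode,
                       feature_indices=idx)[0]
            for r in range(repeats)
        ]
        rows.append(
            {
                "size": size,
                "mean_accuracy": float(np.mean(accs)),
                "sd": float(np.std(accs, ddof=1)) if repeats > 1 else 0.0,
                "repeats": repeats,
            }
        )
    return pd.DataFrame(rows)


def permutation_null(
    states: np.ndarray,
    labels: Sequence[str],
    n_shuffles: int = 20,
    seed: int = 0,
    mode: str = "softmax",
) -> np.ndarray:
    """Test accuracies after shuffling labels — the no-signal baseline."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    accs = []
    for k in range(n_shuffles):
        shuffled = labels[rng.permutation(len(labels))]
        acc, _ = single_run(states, shuffled, split_seed=seed + k, mode=mode)
        accs.append(acc)
    return np.array(accs)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------


def model_to_json(model: ReadoutModel, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "weights": model.weights.tolist(),
                "intercepts": model.intercepts.tolist(),
                "feature_mean": model.feature_mean.tolist(),
                "feature_scale": model.feature_scale.tolist(),
                "classes": [str(c) for c in model.classes],
                "training_seed": model.training_seed,
                "n_states_used": model.n_states_used,
                "mode": model.mode,
                "dropped_features": list(model.dropped_features),
            },
            indent=2,
        )
    )


def model_from_json(path: str | Path) -> ReadoutModel:
    d = json.loads(Path(path).read_text())
    return ReadoutModel(
        weights=np.array(d["weights"]),
        intercepts=np.array(d["intercepts"]),
        feature_mean=np.array(d["feature_mean"]),
        feature_scale=np.array(d["feature_scale"]),
        classes=np.array(d["classes"]),
        training_seed=d["training_seed"],
        n_states_used=d["n_states_used"],
        mode=d["mode"],
        dropped_features=tuple(d["dropped_features"]),
    )
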