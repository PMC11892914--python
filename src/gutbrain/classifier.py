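"""MLP dementia classifier with permutation-based feature contributions.

Features are standardized species abundances plus clinical parameters;
subjects are split 60/20/20 into stratified shuffled train/validation/test
sets, scaling fit on the training set only.  The network is a small
feed-forward perceptron (one 16-unit ReLU hidden layer by default, logistic
output) trained by adaptive-moment gradient descent with early stopping on
validation log-loss.

Feature contributions are model-agnostic: the mean test-accuracy drop when a
feature's column is permuted, floored at zero and normalized to percentages
summing to 100.  This reproduces the artifact of a per-feature percentage
contribution chart without the game-theoretic attribution machinery.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, log_loss
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)

__all__ = ["FeatureSplits", "prepare_features", "train_mlp", "feature_contributions"]


@dataclass
class FeatureSplits:
    X_train: np.ndarray
    X_val: np.ndarray
    X_test: np.ndarray
    y_train: np.ndarray
    y_val: np.ndarray
    y_test: np.ndarray
    feature_names: list[str]
    dropped: list[str] = field(default_factory=list)
    scaler: StandardScaler | None = None


def prepare_features(
    features: pd.DataFrame,
    labels,
    val_frac: float = 0.2,
    test_frac: float = 0.2,
    seed: int = 0,
) -> FeatureSplits:
    """Stratified shuffled 60/20/20 split with train-only standardization.

    Constant feature columns (zero variance on the training set) are dropped
    with a warning.  Labels are binarized 0=control, 1=dementia (or taken
    as-is when already 0/1).
    """
    y = np.asarray(labels)
    if y.dtype.kind not in "biu":
        y = (y == "dementia").astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    if counts.min() < 10:
        raise ValueError("need >= 10 subjects per class for the default split")
    x = features.to_numpy(float)
    idx = np.arange(len(y))
    idx_tmp, idx_test = train_test_split(
        idx, test_size=test_frac, stratify=y, random_state=seed, shuffle=True
    )
    idx_train, idx_val = train_test_split(
        idx_tmp, test_size=val_frac / (1 - test_frac), stratify=y[idx_tmp],
        random_state=seed, shuffle=True,
    )
    keep = x[idx_train].std(axis=0) > 0
    dropped = [n for n, k in zip(features.columns, keep) if not k]
    if dropped:
        logger.warning("dropping constant feature column(s): %s", dropped)
    names = [n for n, k in zip(features.columns, keep) if k]
    scaler = StandardScaler().fit(x[np.ix_(idx_train, np.flatnonzero(keep))])
    tf = lambda rows: scaler.transform(x[np.ix_(rows, np.flatnonzero(keep))])
    return FeatureSplits(
        X_train=tf(idx_train), X_val=tf(idx_val), X_test=tf(idx_test),
        y_train=y[idx_train], y_val=y[idx_val], y_test=y[idx_test],
        feature_names=names, dropped=dropped, scaler=scaler,
    )


def train_mlp(
    splits: FeatureSplits,
    hidden_sizes: tuple[int, ...] = (16,),
    max_epochs: int = 400,
    patience: int = 30,
    learning_rate: float = 1e-3,
    seed: int = 0,
) -> tuple[MLPClassifier, dict]:
    """Train the perceptron with early stopping on validation log-loss.

    Returns the model (restored to its best-validation epoch) and a metrics
    dict with train/validation/test accuracy and the stopping epoch.
    """
    if len(splits.X_train) == 0:
        raise ValueError("empty training set")
    if len(np.unique(splits.y_train)) < 2:
        raise ValueError("training set must contain both classes")
    clf = MLPClassifier(
        hidden_layer_sizes=hidden_sizes,
        activation="relu",
        solver="adam",
        learning_rate_init=learning_rate,
        random_state=seed,
    )
    classes = np.array([0, 1])
    best_loss, best_state, best_epoch, stale = np.inf, None, 0, 0
    for epoch in range(max_epochs):
        clf.partial_fit(splits.X_train, splits.y_train, classes=classes)
        val_loss = log_loss(splits.y_val, clf.predict_proba(splits.X_val),
                            labels=classes)
        if val_loss < best_loss - 1e-6:
            best_loss, best_epoch, stale = val_loss, epoch, 0
            best_state = (copy.deepcopy(clf.coefs_), copy.deepcopy(clf.intercepts_))
        else:
            stale += 1
            if stale >= patience:
                break
    if best_state is not None:
        clf.coefs_, clf.intercepts_ = best_state
    metrics = {
        "train_accuracy": float(accuracy_score(splits.y_train, clf.predict(splits.X_train))),
        "val_accuracy": float(accuracy_score(splits.y_val, clf.predict(splits.X_val))),
        "test_accuracy": float(accuracy_score(splits.y_test, clf.predict(splits.X_test))),
        "best_epoch": int(best_epoch),
        "val_log_loss": float(best_loss),
    }
    return clf, metrics


def feature_contributions(
    model,
    X_test: np.ndarray,
    y_test: np.ndarray,
    feature_names: list[str],
    n_repeats: int = 50,
    seed: int = 0,
) -> pd.Series:
    """Percent contribution per feature from permutation accuracy drop.

    Per feature: permute its test column n_repeats times, average the drop in
    test accuracy, floor at 0, and normalize so contributions sum to 100%.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rng = np.random.default_rng(seed)
    base = accuracy_score(y_test, model.predict(X_test))
    drops = np.zeros(X_test.shape[1])
    for j in range(X_test.shape[1]):
        acc = 0.0
        for _ in range(n_repeats):
            xp = X_test.copy()
            xp[:, j] = rng.permutation(xp[:, j])
            acc += accuracy_score(y_test, model.predict(xp))
        drops[j] = base - acc / n_repeats
    drops = np.clip(drops, 0.0, None)
    total = drops.sum()
    if total == 0:
        logger.warning("no feature permutation changed accuracy; uniform contributions")
        pct = np.full(len(drops), 100.0 / len(drops))
    else:
        pct = 100.0 * drops / total
    return pd.Series(pct, index=feature_names, name="contribution_pct").sort_values(
        ascending=False
    )
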