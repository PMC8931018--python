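"""Evaluation harness and application modes.

Covers the experimental protocol around the classifier: confusion analysis
with per-class accuracy summaries, the small-sample sweep comparing the
prototype and softmax heads as the training set shrinks, 2-D feature-space
separability, open-set identity verification by prototype distance, and the
mapping from recognised words to device command tokens.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .model import DilatedGRUClassifier


class MappingError(KeyError):
    """Label outside the configured command set."""


@dataclass
class EvalReport:
    """Row-normalised confusion matrix plus summary accuracies."""

    counts: np.ndarray           # (K, K) raw counts, rows = true class
    matrix: np.ndarray           # row-normalised
    accuracy: float
    per_class: np.ndarray        # diagonal of the normalised matrix
    frac_perfect: float          # fraction of classes at 100% accuracy
    frac_above_90: float
    frac_above_80: float
    labels: list = field(default_factory=list)


def confusion(y_true, y_pred, labels=None) -> EvalReport:
    """Build an :class:`EvalReport` from true and predicted labels."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty test set")
    classes = np.unique(y_true) if labels is None else np.asarray(labels)
    counts = _sk_confusion(y_true, y_pred, labels=classes)
    row_sums = counts.sum(axis=1, keepdims=True)
    if np.any(row_sums == 0):
        raise ValueError("every class needs at least one test sample")
    matrix = counts / row_sums
    per_class = np.diag(matrix)
    return EvalReport(
        counts=counts, matrix=matrix,
        accuracy=float(np.trace(counts) / counts.sum()),
        per_class=per_class,
        frac_perfect=float(np.mean(per_class == 1.0)),
        frac_above_90=float(np.mean(per_class > 0.9)),
        frac_above_80=float(np.mean(per_class > 0.8)),
        labels=[str(c) for c in classes])


def evaluate_model(clf: DilatedGRUClassifier, X_test, y_test) -> EvalReport:
    return confusion(y_test, clf.predict(X_test), labels=clf.classes_)


def small_sample_sweep(X_train, y_train, X_test, y_test,
                       fractions=(1.0, 0.8, 0.6, 0.4, 0.2),
                       heads=("prototype", "softmax"), n_seeds: int = 3,
                       base_seed: int = 0, **clf_kwargs) -> pd.DataFrame:
    """Retrain with stratified subsets of the training split.

    For each fraction the training split is subsampled per class (seeded),
    both heads are trained from scratch, and accuracy is measured on the
    untouched test split.  Returns a tidy frame with one row per
    (fraction, head, seed); medians over seeds are the headline numbers.
    """
    X_train = np.asarray(X_train)
    y_train = np.asarray(y_train)
    classes = np.unique(y_train)
    rows = []
    for frac in fractions:
        if not (0 < frac <= 1):
            raise ValueError("fractions must lie in (0, 1]")
        for seed in range(n_seeds):
            rng = np.random.default_rng(base_seed + 1000 * seed)
            keep = []
            for c in classes:
                idx = np.flatnonzero(y_train == c)
                m = int(round(frac * idx.size))
                if m < 1:
                    raise ValueError("fraction leaves a class empty")
                keep.append(rng.choice(idx, size=m, replace=False))
            keep = np.concatenate(keep)
            for head in heads:
                clf = DilatedGRUClassifier(head=head,
                                           random_state=base_seed + seed,
                                           **clf_kwargs)
                clf.fit(X_train[keep], y_train[keep])
                acc = float(clf.score(np.asarray(X_test), np.asarray(y_test)))
                rows.append({"fraction": frac, "head": head, "seed": seed,
                             "accuracy": acc, "n_train": int(keep.size)})
    return pd.DataFrame(rows)


def separability_ratio(features: np.ndarray, y) -> float:
    """Mean between-class over mean within-class pairwise feature distance.

    A ratio well above 1 indicates interclass separability with intraclass
    compactness; around 1 is the null behaviour of an untrained extractor.
    Raises on a single class, where "between" is undefined.
    """
    from scipy.spatial.distance import pdist, squareform
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("separability undefined for a single class")
    D = squareform(pdist(np.asarray(features)))
    same = (y[:, None] == y[None, :])
    iu = np.triu_indices_from(D, k=1)
    within = D[iu][same[iu]]
    between = D[iu][~same[iu]]
    return float(between.mean() / within.mean())


def feature_map_2d(clf: DilatedGRUClassifier, X, y):
    """2-D feature coordinates and their separability statistic.

    The classifier must have been trained with ``feature_dim=2``; the
    returned scatter data reproduce the feature-space visualisation, and the
    ratio summarises it as a single number.
    """
    feats = clf.transform(X)
    if feats.shape[1] != 2:
        raise ValueError("feature_map_2d requires feature_dim=2")
    return feats, separability_ratio(feats, y)


# ---------------------------------------------------------------------------
# identity verification (open set)

@dataclass
class VerificationPolicy:
    """Enrolled prototype and accept/reject distance threshold."""

    speaker: str
    prototype: np.ndarray
    tau: float

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("threshold tau must be positive")


def enroll(features: np.ndarray, speaker: str = "host",
           quantile: float = 0.95) -> VerificationPolicy:
    """Enroll a speaker from genuine utterance features.

    The prototype is the mean feature vector; the threshold is the given
    quantile of the genuine distances to that prototype (so ~95% of genuine
    attempts fall inside by construction).
    """
    F = np.atleast_2d(np.asarray(features, dtype=float))
    proto = F.mean(axis=0)
    dists = np.linalg.norm(F - proto, axis=1)
    tau = float(np.quantile(dists, quantile))
    return VerificationPolicy(speaker=speaker, prototype=proto,
                              tau=max(tau, 1e-12))


def verify_identity(feature: np.ndarray, policy: VerificationPolicy) -> bool:
    """Accept iff the feature lies within ``tau`` of the enrolled prototype."""
    if policy is None:
        raise ValueError("no enrollment available")
    d = float(np.linalg.norm(np.asarray(feature) - policy.prototype))
    return d <= policy.tau


# ---------------------------------------------------------------------------
# command mapping

COMMANDS = {
    "Go forwards": "FORWARD",
    "Go backwards": "BACKWARD",
    "Left": "LEFT",
    "Right": "RIGHT",
}
_INVERSE_COMMANDS = {v: k for k, v in COMMANDS.items()}


def command_map(label: str) -> str:
    """Map a recognised instruction word to its action token."""
    try:
        return COMMANDS[label]
    except KeyError:
        raise MappingError(f"unknown instruction {label!r}") from None


def inverse_command_map(action: str) -> str:
    try:
        return _INVERSE_COMMANDS[action]
    except KeyError:
        raise MappingError(f"unknown action {action!r}") from None
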