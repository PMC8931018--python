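"""Scikit-learn estimator for lip-motion sequence classification.

:class:`DilatedGRUClassifier` composes the dilated GRU feature extractor
with either the prototype-learning head or a softmax baseline, exposing the
usual ``fit`` / ``predict`` / ``predict_proba`` / ``transform`` surface so
it plugs into sklearn pipelines and model selection.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.exceptions import NotFittedError
from sklearn.utils.validation import check_is_fitted

from . import nn


class DilatedGRUClassifier(TransformerMixin, ClassifierMixin, BaseEstimator):
    """Dilated GRU feature extractor + prototype or softmax classification.

    Parameters
    ----------
    n_layers, hidden_size : int
        Depth and width of the recurrent feature extractor (defaults 4 and
        50, the configuration used for the 20-word task).
    dilations : tuple of int or None
        Skip distance per layer; ``None`` selects the exponential schedule
        ``(1, 2, 4, ..., 2**(n_layers-1))``.
    feature_dim : int
        Dimension of the deep feature space (2 for visualisation).
    head : {"prototype", "softmax"}
        Prototype matching by Euclidean distance, or a linear softmax layer.
    gamma : float
        Distance scale of the prototype head: p(k|f) is proportional to
        ``exp(-gamma * ||f - m_k||^2)``.
    prototype_loss_weight : float
        Weight ``lambda`` of the pull term ``||f - m_y||^2``.
    epochs, batch_size, learning_rate : training schedule (Adam).
    lr_schedule : {"cosine", "constant"}
        Learning-rate annealing; cosine decays to zero over the run.
    random_state : int or None
        Seed for initialisation and batch shuffling; fixed seeds give
        bit-reproducible training on a fixed BLAS configuration.

    Attributes
    ----------
    classes_ : ndarray of class labels.
    params_ : dict of weight arrays (prototypes under key ``"M"``).
    history_ : DataFrame with per-epoch ``train_acc`` (running accuracy on
        the shuffled training batches) and ``test_acc`` when validation data
        were supplied to :meth:`fit`.
    """

    def __init__(self, n_layers: int = 4, hidden_size: int = 50,
                 dilations=None, feature_dim: int = 32,
                 head: str = "prototype", gamma: float = 3.0,
                 prototype_loss_weight: float = 0.1, epochs: int = 500,
                 batch_size: int = 32, learning_rate: float = 3e-3,
                 lr_schedule: str = "cosine", shuffle: bool = True,
                 random_state=None):
        self.n_layers = n_layers
        self.hidden_size = hidden_size
        self.dilations = dilations
        self.feature_dim = feature_dim
        self.head = head
        self.gamma = gamma
        self.prototype_loss_weight = prototype_loss_weight
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.lr_schedule = lr_schedule
        self.shuffle = shuffle
        self.random_state = random_state

    # -- helpers ----------------------------------------------------------

    def _validate_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, :, None]
        if X.ndim != 3:
            raise ValueError("X must be (n_samples, seq_len) or (n, T, channels)")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        return X

    def _resolved_dilations(self):
        if self.dilations is not None:
            dil = tuple(int(d) for d in self.dilations)
            if len(dil) != self.n_layers:
                raise ValueError("need one dilation per layer")
            if any(d < 1 for d in dil):
                raise ValueError("dilations must be >= 1")
            return dil
        return tuple(2 ** l for l in range(self.n_layers))

    def _features_batched(self, X: np.ndarray, batch: int = 256) -> np.ndarray:
        X = X.astype(self.params_["Wf"].dtype, copy=False)
        out = [nn.dilated_forward(X[i:i + batch], self.params_, self.dilations_)
               for i in range(0, X.shape[0], batch)]
        return np.concatenate(out, axis=0)

    # -- sklearn surface --------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None):
        """Train the extractor and head end to end with Adam.

        ``X_val``/``y_val`` are optional held-out data evaluated once per
        epoch into ``history_`` (they never influence the optimisation).
        """
        X = self._validate_X(X)
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        if X.shape[0] == 0:
            raise ValueError("empty training set")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n_classes = self.classes_.size
        self.dilations_ = self._resolved_dilations()
        self.n_features_in_ = X.shape[1]
        rng = np.random.default_rng(self.random_state)
        params = nn.init_params(X.shape[2], self.hidden_size, self.n_layers,
                                self.feature_dim, n_classes, self.head, rng)
        # single precision for the training loop: the recurrent pass is
        # BLAS-bound and float32 halves its cost at ample precision for SGD
        X = X.astype(np.float32)
        params = {k: v.astype(np.float32) for k, v in params.items()}
        self.params_ = params

        if self.head == "prototype":
            # initialise each prototype at its class mean in the initial
            # (untrained) feature space: one forward pass over the data
            f0 = self._features_batched(X)
            for k in range(n_classes):
                params["M"][k] = f0[y_idx == k].mean(axis=0)

        opt = nn.Adam(params, lr=self.learning_rate)
        n = X.shape[0]
        has_val = X_val is not None and y_val is not None
        if has_val:
            X_val = self._validate_X(X_val)
            val_idx = np.searchsorted(self.classes_, np.asarray(y_val))
        rows = []
        for epoch in range(self.epochs):
            if self.lr_schedule == "cosine":
                # anneal to zero over the run; settles near the late optimum
                opt.lr = self.learning_rate * 0.5 * (
                    1.0 + np.cos(np.pi * epoch / max(1, self.epochs - 1)))
            elif self.lr_schedule != "constant":
                raise ValueError("lr_schedule must be 'cosine' or 'constant'")
            order = rng.permutation(n) if self.shuffle else np.arange(n)
            correct = 0
            losses = []
            for i in range(0, n, self.batch_size):
                bi = order[i:i + self.batch_size]
                f, cache = nn.dilated_forward(X[bi], params, self.dilations_,
                                              return_cache=True)
                loss, df, hgrads = nn.loss_and_grads(
                    f, y_idx[bi], params, self.head, self.gamma,
                    self.prototype_loss_weight)
                probs, _ = nn.head_forward(f, params, self.head, self.gamma)
                correct += int((probs.argmax(axis=1) == y_idx[bi]).sum())
                losses.append(loss)
                grads = nn.dilated_backward(df, cache, params, self.dilations_)
                grads.update(hgrads)
                opt.step(params, grads)
            row = {"epoch": epoch + 1, "loss": float(np.mean(losses)),
                   "train_acc": correct / n}
            if has_val:
                pv = self._proba_from_params(X_val)
                row["test_acc"] = float((pv.argmax(axis=1) == val_idx).mean())
            rows.append(row)
        self.history_ = pd.DataFrame(rows)
        return self

    def _proba_from_params(self, X: np.ndarray) -> np.ndarray:
        f = self._features_batched(X)
        probs, _ = nn.head_forward(f, self.params_, self.head, self.gamma)
        return probs

    def transform(self, X) -> np.ndarray:
        """Map sequences to their deep feature vectors."""
        check_is_fitted(self, "params_")
        return self._features_batched(self._validate_X(X))

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        return self._proba_from_params(self._validate_X(X))

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        f = self.transform(X)
        _, logits = nn.head_forward(f, self.params_, self.head, self.gamma)
        return logits

    def predict(self, X, reject_distance: float | None = None):
        """Predict labels; ties break toward the lowest class index.

        With the prototype head, ``reject_distance`` enables an open-set
        decision: samples whose nearest prototype lies farther than the
        threshold (in Euclidean distance) are labelled ``None``.
        """
        check_is_fitted(self, "params_")
        X = self._validate_X(X)
        f = self._features_batched(X)
        probs, _ = nn.head_forward(f, self.params_, self.head, self.gamma)
        idx = probs.argmax(axis=1)
        labels = self.classes_[idx]
        if reject_distance is not None:
            if self.head != "prototype":
                raise ValueError("open-set rejection requires the prototype head")
            _, d2 = nn.prototype_logits(f, self.params_["M"], self.gamma)
            dmin = np.sqrt(d2.min(axis=1))
            labels = np.array([lab if d <= reject_distance else None
                               for lab, d in zip(labels, dmin)], dtype=object)
        return labels

    # -- persistence ------------------------------------------------------

    def save(self, path) -> Path:
        """Write weights (``.npz``) plus a JSON metadata sidecar."""
        check_is_fitted(self, "params_")
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(".npz")
        np.savez(path, __classes__=self.classes_, **self.params_)
        meta = {"hyperparameters": self.get_params(),
                "classes": [str(c) for c in self.classes_],
                "dilations": list(self.dilations_)}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1, default=str))
        return path

    @classmethod
    def load(cls, path) -> "DilatedGRUClassifier":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        hp = meta["hyperparameters"]
        if hp.get("dilations") is not None:
            hp["dilations"] = tuple(hp["dilations"])
        est = cls(**hp)
        with np.load(path.with_suffix(".npz")) as z:
            est.params_ = {k: z[k] for k in z.files if k != "__classes__"}
            est.classes_ = z["__classes__"]
        est.dilations_ = tuple(meta["dilations"])
        est.history_ = pd.DataFrame()
        return est


def train(X_train, y_train, X_test=None, y_test=None, head: str = "prototype",
          epochs: int = 500, seed: int | None = 0, **kwargs):
    """Thin functional wrapper: fit a classifier, return it with its curves.

    Returns ``(clf, history)`` where ``history`` has per-epoch train (and,
    when test data are given, test) accuracy.
    """
    clf = DilatedGRUClassifier(head=head, epochs=epochs, random_state=seed,
                               **kwargs)
    clf.fit(X_train, y_train, X_val=X_test, y_val=y_test)
    return clf, clf.history_


def predict_utterance(clf: DilatedGRUClassifier, x):
    """Classify one preprocessed sequence; returns (label, prob, feature)."""
    if not hasattr(clf, "params_"):
        raise NotFittedError("classifier is not trained")
    x = np.asarray(x, dtype=float)[None, :]
    f = clf.transform(x)[0]
    probs = clf.predict_proba(x)[0]
    k = int(probs.argmax())
    return clf.classes_[k], float(probs[k]), f
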