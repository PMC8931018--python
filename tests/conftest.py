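import numpy as np
import pytest

import liplang as ll


@pytest.fixture(scope="session")
def small_dataset():
    """A 5-class x 12-sample dataset, cheap enough for unit tests."""
    return ll.make_dataset(n_classes=5, n_per_class=12, base_seed=11)


@pytest.fixture(scope="session")
def small_arrays(small_dataset):
    return ll.dataset_to_arrays(small_dataset)


@pytest.fixture(scope="session")
def separable_sequences():
    """Three trivially separable synthetic sequence classes."""
    rng = np.random.default_rng(5)
    n, T = 30, 40
    X, y = [], []
    t = np.linspace(0, 1, T)
    protos = [np.sin(2 * np.pi * 1 * t), np.sin(2 * np.pi * 3 * t),
              t * 2 - 1]
    for c, p in enumerate(protos):
        for _ in range(n):
            X.append(p + 0.05 * rng.standard_normal(T))
            y.append(c)
    return np.asarray(X), np.asarray(y)


@pytest.fixture(scope="session")
def trained_small_clf(small_arrays):
    """Prototype-head classifier trained on the small dataset."""
    Xtr, ytr, Xte, yte, _ = small_arrays
    # 50 training samples need a longer schedule for enough Adam updates
    clf = ll.DilatedGRUClassifier(epochs=150, random_state=0)
    clf.fit(Xtr, ytr, X_val=Xte, y_val=yte)
    return clf
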