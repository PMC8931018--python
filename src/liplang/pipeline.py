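"""End-to-end glue: dataset -> conditioned fixed-length sequences -> model.

The classifier consumes 50 Hz sequences: after the 20 Hz low-pass the lip
signal carries no energy above the decimated Nyquist frequency, so the
polyphase decimation from the 1 kHz acquisition rate is lossless for
classification while cutting the recurrent computation by the same factor.
The default window of 75 samples (1.5 s) covers every single-word utterance
the generator produces.
"""

from __future__ import annotations

import numpy as np

from . import preprocess as pp
from .synth import LipDataset, make_dataset
from .waveform import Waveform

MODEL_RATE = 50.0
MODEL_LEN = 75


def condition_waveform(w: Waveform, lowpass_hz: float = 20.0,
                       model_rate: float = MODEL_RATE,
                       target_len: int = MODEL_LEN) -> np.ndarray:
    """Low-pass, normalise, decimate and fix the length of one waveform."""
    w = pp.lowpass(w, pp.FilterSpec(cutoff_hz=lowpass_hz))
    w = pp.normalize(w)
    if model_rate != w.rate:
        w = pp.resample_waveform(w, model_rate)
    return pp.to_model_input(w, target_len=target_len)


def dataset_to_arrays(ds: LipDataset, lowpass_hz: float = 20.0,
                      model_rate: float = MODEL_RATE,
                      target_len: int = MODEL_LEN):
    """Condition every utterance and split into train/test arrays.

    Returns ``(X_train, y_train, X_test, y_test, labels)`` with X of shape
    (n, target_len).
    """
    X = np.stack([
        condition_waveform(u.lip, lowpass_hz, model_rate, target_len)
        for u in ds.utterances])
    tr = ds.indices("train")
    te = ds.indices("test")
    return X[tr], ds.y[tr], X[te], ds.y[te], list(ds.labels)


def default_dataset(base_seed: int = 0, n_classes: int = 20,
                    n_per_class: int = 100, **kwargs) -> LipDataset:
    """The study-protocol dataset: 20 classes x 100 samples, 80/20 split."""
    return make_dataset(n_classes=n_classes, n_per_class=n_per_class,
                        base_seed=base_seed, **kwargs)
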