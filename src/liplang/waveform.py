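"""Uniformly sampled waveform container and plain-text I/O.

Waveforms are stored on disk as a two-column CSV (``time_s,value``) next to a
JSON sidecar carrying units, sampling rate and provenance metadata.  The CSV
dialect is deliberately simple: every artifact is inspectable with a text
editor and small enough (a 20 s recording at 1 kHz is tens of kilobytes) that
binary containers buy nothing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

SCHEMA_VERSION = 1

#: units accepted in sidecar metadata
VALID_UNITS = ("V", "nA", "normalized")


class FormatError(ValueError):
    """Malformed waveform file (missing sidecar, bad columns...)."""


class GridError(ValueError):
    """Time column is not a uniform, monotone grid."""


class ChannelError(ValueError):
    """Audio input has an unsupported channel layout."""


@dataclass
class Waveform:
    """A uniformly sampled signal.

    Parameters
    ----------
    samples : ndarray
        1-D float array of sample values.
    rate : float
        Sampling rate in Hz.
    kind : str
        Signal kind, e.g. ``"voc"`` (open-circuit voltage), ``"isc"``
        (short-circuit current), ``"lip"`` or ``"envelope"``.
    units : str
        One of ``"V"``, ``"nA"``, ``"normalized"``.
    meta : dict
        Free-form provenance (generator parameters, seed, sensor spec).
    """

    samples: np.ndarray
    rate: float
    kind: str = "voc"
    units: str = "V"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform samples must be finite")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.units not in VALID_UNITS:
            raise ValueError(f"units must be one of {VALID_UNITS}, got {self.units!r}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Length of the signal in seconds."""
        return self.samples.size / self.rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.rate

    def copy(self, **overrides) -> "Waveform":
        kw = dict(samples=self.samples.copy(), rate=self.rate, kind=self.kind,
                  units=self.units, meta=dict(self.meta))
        kw.update(overrides)
        return Waveform(**kw)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_waveform(w: Waveform, path) -> Path:
    """Write ``path`` (CSV ``time_s,value``) plus a JSON sidecar.

    Returns the CSV path.  Values are printed with 17 significant digits so a
    round-trip reproduces them to double precision.
    """
    path = Path(path)
    if path.suffix != ".csv":
        path = path.with_suffix(".csv")
    t = w.times
    with open(path, "w") as fh:
        fh.write("time_s,value\n")
        for ti, vi in zip(t, w.samples):
            fh.write(f"{ti:.9f},{vi:.17g}\n")
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "kind": w.kind,
        "units": w.units,
        "sampling_rate_hz": w.rate,
        "n_samples": int(w.samples.size),
        "meta": w.meta,
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=1, default=str)
    return path


def read_waveform(path) -> Waveform:
    """Read a CSV + sidecar pair written by :func:`write_waveform`."""
    path = Path(path)
    sc_path = _sidecar_path(path)
    if not sc_path.exists():
        raise FormatError(f"missing JSON sidecar for {path}")
    with open(sc_path) as fh:
        sc = json.load(fh)
    if "schema_version" not in sc:
        raise FormatError("sidecar lacks schema_version")
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if data.shape[1] != 2:
        raise FormatError("expected two columns time_s,value")
    t, v = data[:, 0], data[:, 1]
    if t.size > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise GridError("time column must be strictly increasing")
        if np.ptp(dt) > 1e-6 * np.median(dt) + 1e-12:
            raise GridError("time column is not a uniform grid")
    return Waveform(samples=v, rate=float(sc["sampling_rate_hz"]),
                    kind=sc.get("kind", "voc"), units=sc.get("units", "V"),
                    meta=sc.get("meta", {}))


def write_wav_envelope(w: Waveform, path, wav_rate: int = 8000) -> "Path":
    """Render an envelope (or any waveform) to a mono 16-bit WAV file.

    The signal is resampled to ``wav_rate`` and scaled to 90% full scale;
    useful for auditioning sound envelopes next to their lip waveforms.
    """
    path = Path(path)
    frac = Fraction(int(wav_rate), int(round(w.rate))).limit_denominator(10000)
    y = resample_poly(w.samples, frac.numerator, frac.denominator)
    peak = np.abs(y).max()
    if peak > 0:
        y = y / peak * 0.9
    wavfile.write(path, int(wav_rate), (y * 32767).astype(np.int16))
    return path


def read_wav_envelope(path, target_rate: float = 1000.0,
                      smooth_ms: float = 10.0) -> Waveform:
    """Load a mono WAV file and return its amplitude envelope.

    The audio is rectified, smoothed with a causal moving average of
    ``smooth_ms`` and resampled (polyphase, anti-aliased) to ``target_rate``
    so that it can be compared sample-by-sample with a lip-motion waveform.
    A causal window keeps the envelope onset within a fraction of the window
    of the true burst start instead of smearing it earlier in time.
    """
    sr, x = wavfile.read(path)
    x = np.asarray(x)
    if x.ndim != 1:
        raise ChannelError("expected a mono WAV file")
    was_int = np.issubdtype(x.dtype, np.integer)
    x = x.astype(float)
    if was_int:
        # scale integer PCM into [-1, 1]
        x = x / max(1.0, np.abs(x).max())
    env = np.abs(x)
    n_win = max(1, int(round(smooth_ms * 1e-3 * sr)))
    if n_win > 1:
        kernel = np.ones(n_win) / n_win
        env = np.convolve(env, kernel)[: env.size]
    frac = Fraction(int(round(target_rate)), int(sr)).limit_denominator(10000)
    env = resample_poly(env, frac.numerator, frac.denominator)
    env = np.clip(env, 0.0, None)
    return Waveform(samples=env, rate=float(target_rate), kind="envelope",
                    units="normalized", meta={"source": str(path), "wav_rate": int(sr)})
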