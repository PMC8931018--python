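"""Signal conditioning and timing analysis for lip-motion waveforms.

The conditioning chain mirrors the acquisition pipeline of the decoding
system: a zero-phase low-pass filter at 20 Hz removes power-line (50 Hz)
interference, per-utterance max-absolute normalization removes amplitude
interference, and threshold-with-hysteresis segmentation locates word
onsets.  On top of segmentation sit the timing statistics used to compare
lip motion with sound: duration efficiency of continuous versus separate
pronunciation, the sound/lip duration fraction, the lip-before-sound onset
advance, and the raw data-volume ratio.  A short-time Fourier transform and
a fixed-length resampler feed the downstream classifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .waveform import Waveform


class SpecError(ValueError):
    """Invalid filter or transform specification."""


class NormalizationError(ValueError):
    """Normalization of an all-zero waveform."""


class DetectionError(ValueError):
    """Required onset could not be detected."""


@dataclass
class FilterSpec:
    """Low-pass filter specification (Butterworth)."""

    cutoff_hz: float = 20.0
    order: int = 4
    zero_phase: bool = True


@dataclass
class Segment:
    """A labelled time interval within a waveform."""

    start_s: float
    end_s: float
    label: str | None = None

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s


@dataclass
class Spectrogram:
    """Magnitude STFT with its time/frequency axes."""

    magnitude: np.ndarray  # (n_freqs, n_frames)
    freqs_hz: np.ndarray
    times_s: np.ndarray
    window_len: int
    hop: int


def lowpass(w: Waveform, spec: FilterSpec | None = None) -> Waveform:
    """Low-pass filter a waveform (default: 4th-order, 20 Hz, zero-phase).

    The default attenuates a 50 Hz power-line tone by more than 60 dB while
    leaving the sub-10 Hz lip-motion band essentially untouched; the
    forward-backward pass has exactly zero phase shift, so onsets do not
    move.
    """
    spec = spec or FilterSpec()
    nyq = w.rate / 2.0
    if not (0 < spec.cutoff_hz < nyq):
        raise SpecError(f"cutoff must lie in (0, {nyq}) Hz")
    sos = sps.butter(spec.order, spec.cutoff_hz, btype="low", fs=w.rate, output="sos")
    if spec.zero_phase:
        # even edge extension: an odd extension turns a signal that starts
        # mid-oscillation (power-line pickup) into a low-frequency edge bump
        # that would survive the low-pass and fake an onset at t=0
        y = sps.sosfiltfilt(sos, w.samples, padtype="even")
    else:
        y = sps.sosfilt(sos, w.samples)
    return w.copy(samples=y)


def normalize(w: Waveform) -> Waveform:
    """Divide by the maximum absolute value (sign preserved).

    After normalization the peak magnitude is exactly 1 and every relative
    sub-peak keeps its ratio to the maximum, which is the convention implied
    by reporting sub-peak values as fractions of the largest peak.
    Idempotent.
    """
    peak = float(np.max(np.abs(w.samples))) if len(w) else 0.0
    if peak == 0.0:
        raise NormalizationError("cannot normalize an all-zero waveform")
    return w.copy(samples=w.samples / peak, units="normalized")


def detect_onsets(w: Waveform, threshold_frac: float = 0.05,
                  min_gap_s: float = 0.15, hysteresis_s: float = 0.05) -> list[Segment]:
    """Segment a waveform into active (word) regions.

    A sample is active when ``|x|`` exceeds ``threshold_frac`` of the global
    peak.  Active runs shorter than ``hysteresis_s`` are discarded as noise
    spikes, and runs separated by silent gaps shorter than ``min_gap_s`` are
    merged, so each returned segment corresponds to one word-scale event.
    Returns an empty list when nothing crosses the threshold.
    """
    if not len(w):
        return []
    env = np.abs(w.samples)
    peak = env.max()
    if peak == 0.0:
        return []
    thr = threshold_frac * peak
    above = env > thr
    if not above.any():
        return []
    # run-length encode the boolean mask: starts/ends of True runs
    padded = np.concatenate([[False], above, [False]])
    diff = np.diff(padded.astype(np.int8))
    run_starts = np.flatnonzero(diff == 1)
    run_ends = np.flatnonzero(diff == -1)
    runs = list(zip(run_starts.tolist(), run_ends.tolist()))
    # merge runs separated by short gaps
    min_gap = int(round(min_gap_s * w.rate))
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] < min_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    # drop merged runs shorter than the hysteresis time
    min_len = int(round(hysteresis_s * w.rate))
    merged = [(s, e) for s, e in merged if e - s >= min_len]
    return [Segment(start_s=s / w.rate, end_s=e / w.rate) for s, e in merged]


def onset_advance(lip: Waveform, sound: Waveform,
                  threshold_frac: float = 0.05) -> float:
    """Time (ms) by which the lip-motion onset precedes the sound onset.

    Positive when the lip leads, which is the physiological direction: the
    mouth opens before the sound is produced.
    """
    if lip.rate != sound.rate:
        raise ValueError("lip and sound must share a sampling rate")
    lip_segs = detect_onsets(lip, threshold_frac)
    sound_segs = detect_onsets(sound, threshold_frac)
    if not lip_segs or not sound_segs:
        raise DetectionError("no onset found in lip and/or sound signal")
    return (sound_segs[0].start_s - lip_segs[0].start_s) * 1e3


def efficiency(separate_durations, continuous_duration: float) -> float:
    """Duration efficiency (%) of continuous over separate pronunciation.

    ``100 * (sum(separate) - continuous) / sum(separate)``: the fraction of
    speaking time saved by pronouncing a phrase continuously instead of word
    by word.
    """
    sep = [float(d) for d in np.atleast_1d(separate_durations)]
    if any(d <= 0 for d in sep) or continuous_duration <= 0:
        raise ValueError("durations must be positive")
    total = sum(sep)
    if continuous_duration > total:
        raise ValueError("continuous duration exceeds the summed separate durations")
    return 100.0 * (total - continuous_duration) / total


def duration_fraction(sound_seg, lip_seg) -> float:
    """Sound duration as a percentage of the lip-motion duration.

    Accepts :class:`Segment` instances or plain durations in seconds.
    """
    s = sound_seg.duration if isinstance(sound_seg, Segment) else float(sound_seg)
    l = lip_seg.duration if isinstance(lip_seg, Segment) else float(lip_seg)
    if l <= 0:
        raise ValueError("lip duration must be positive")
    return 100.0 * s / l


def data_volume_ratio(lip_bytes: float, sound_bytes: float) -> float:
    """Ratio of lip-motion data volume to sound data volume."""
    if lip_bytes <= 0 or sound_bytes <= 0:
        raise ValueError("byte counts must be positive")
    return lip_bytes / sound_bytes


def stft(w: Waveform, window_len: int = 256, hop: int = 64,
         window: str = "hann") -> Spectrogram:
    """Magnitude short-time Fourier transform of a waveform."""
    if hop <= 0:
        raise SpecError("hop must be positive")
    if window_len > len(w):
        raise SpecError("window longer than the signal")
    win = sps.get_window(window, window_len, fftbins=True)
    sft = sps.ShortTimeFFT(win, hop=hop, fs=w.rate, scale_to=None)
    S = sft.stft(w.samples)
    times = sft.t(len(w))
    return Spectrogram(magnitude=np.abs(S), freqs_hz=sft.f, times_s=times,
                       window_len=window_len, hop=hop)


def resample_waveform(w: Waveform, new_rate: float) -> Waveform:
    """Anti-aliased polyphase resampling to a new sampling rate."""
    frac = Fraction(new_rate / w.rate).limit_denominator(10000)
    y = sps.resample_poly(w.samples, frac.numerator, frac.denominator)
    return w.copy(samples=y, rate=new_rate)


def to_model_input(x, target_len: int = 1000) -> np.ndarray:
    """Deterministically map a waveform to a fixed-length sequence.

    Inputs longer than ``target_len`` are resampled down (polyphase,
    anti-aliased) to exactly ``target_len`` samples; shorter inputs are
    zero-padded symmetrically so the original signal sits centred.
    """
    x = x.samples if isinstance(x, Waveform) else np.asarray(x, dtype=float)
    n = x.size
    if n == target_len:
        return x.copy()
    if n > target_len:
        frac = Fraction(target_len, n)
        y = sps.resample_poly(x, frac.numerator, frac.denominator)
        if y.size > target_len:
            y = y[:target_len]
        elif y.size < target_len:
            y = np.pad(y, (0, target_len - y.size))
        return y
    pad = target_len - n
    left = pad // 2
    return np.pad(x, (left, pad - left))
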