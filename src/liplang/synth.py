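"""Seeded generator of synthetic lip-motion utterances and sound envelopes.

The study's raw lip-motion recordings are not available in machine-readable
form, so this module emulates their statistical structure.  One mouth
open-close event produces a biphasic pulse: a positive raised-cosine lobe
while the opening mouth presses the sensor and a negative lobe while it
releases.  A word is an alternation of closed / opening / closing states; a
phrase concatenates words with the inter-word pauses removed and each word
compressed, reflecting how continuous speech omits parts of the isolated
pronunciations.  Speaker style enters through a speed factor, optional
leading troughs, and amplitude jitter; acquisition artifacts enter as 50 Hz
power-line interference plus white noise (amplitudes as fractions of the
clean peak).  The paired sound channel is represented as an amplitude
envelope that starts a configurable advance *after* the lip signal, because
the mouth opens before sound is produced (observed advances ~18-417 ms).

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import Segment
from .waveform import Waveform

DEFAULT_RATE = 1000.0
#: onset ground truth uses the same 5%-of-peak criterion as the detector
ONSET_THRESHOLD_FRAC = 0.05

#: amplitude of additive 50 Hz power-line interference, fraction of clean peak
NOISE_50HZ_FRAC = 0.10
#: standard deviation of additive white noise, fraction of clean peak
NOISE_WHITE_FRAC = 0.02


class TemplateError(ValueError):
    """Invalid word-template state alternation."""


class ManifestError(ValueError):
    """Inconsistent dataset manifest (duplicate labels, bad counts...)."""


@dataclass(frozen=True)
class WordTemplate:
    """A word as an ordered list of mouth states.

    ``segments`` holds ``(state, duration_s, peak_amplitude)`` triples where
    state is ``"closed"``, ``"opening"`` or ``"closing"``.  A valid template
    starts and ends closed; opening lobes are rendered positive, closing
    lobes negative, closed states are silent.
    """

    label: str
    segments: tuple

    def __post_init__(self) -> None:
        if not self.segments:
            raise TemplateError("template needs at least one segment")
        states = [s[0] for s in self.segments]
        if states[0] != "closed" or states[-1] != "closed":
            raise TemplateError("template must start and end in the closed state")
        for state, dur, amp in self.segments:
            if state not in ("closed", "opening", "closing"):
                raise TemplateError(f"unknown state {state!r}")
            if dur <= 0:
                raise TemplateError("segment durations must be positive")
            if state != "closed" and not (0 < amp <= 1):
                raise TemplateError("peak amplitudes must lie in (0, 1]")

    @property
    def duration(self) -> float:
        return sum(s[1] for s in self.segments)


@dataclass(frozen=True)
class SpeakerProfile:
    """Per-speaker articulation style.

    ``speed_factor`` > 1 means faster speech (shorter durations).  Speakers
    with ``initial_trough`` produce a slight downward dip just before the
    first opening of each word, a style feature observed between
    participants.  Jitter magnitudes are coefficients of variation applied
    per sample; ``onset_advance_ms_range`` bounds the lip-before-sound lead.
    """

    name: str = "speaker0"
    speed_factor: float = 1.0
    initial_trough: bool = False
    trough_depth: float = 0.08
    amplitude_jitter_cv: float = 0.10
    duration_jitter_cv: float = 0.05
    speed_jitter_sd: float = 0.08
    onset_advance_ms_range: tuple = (18.0, 417.0)

    def __post_init__(self) -> None:
        if self.speed_factor <= 0:
            raise ValueError("speed factor must be positive")
        lo, hi = self.onset_advance_ms_range
        if not (0 <= lo <= hi <= 1000):
            raise ValueError("onset advance range must lie within [0, 1000] ms")


@dataclass
class Utterance:
    """One synthetic lip-motion recording with ground truth attached."""

    lip: Waveform
    label: str
    speaker: str
    seed: int
    clean: np.ndarray
    word_spans: list  # list[Segment] with word labels (geometric boundaries)
    onset_s: float    # first 5%-of-peak crossing of the clean signal
    sound: Waveform | None = None

    def __post_init__(self) -> None:
        if self.sound is not None:
            s_on = _first_crossing(self.sound.samples, ONSET_THRESHOLD_FRAC)
            l_on = _first_crossing(self.clean, ONSET_THRESHOLD_FRAC)
            # tolerance: envelope smoothing may spread the foot ~10 ms early
            tol = int(round(0.010 * self.lip.rate))
            if s_on is not None and l_on is not None and s_on < l_on - tol:
                raise ValueError("lip onset must precede the sound onset")


def _first_crossing(x: np.ndarray, frac: float) -> int | None:
    peak = np.max(np.abs(x)) if x.size else 0.0
    if peak == 0:
        return None
    idx = np.flatnonzero(np.abs(x) > frac * peak)
    return int(idx[0]) if idx.size else None


def _render_lobe(n: int, amp: float) -> np.ndarray:
    """Raised-cosine lobe, zero at both ends, peak ``amp`` at the centre."""
    tau = np.arange(n) / n
    return amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * tau))


def _render_template(template: WordTemplate, rate: float, speed: float,
                     rng: np.random.Generator | None,
                     amp_cv: float, dur_cv: float,
                     trough_depth: float = 0.0):
    """Render one template to a clean waveform; returns (samples, spans).

    ``spans`` is a list of (state, start_idx, end_idx) at the given rate.
    """
    chunks, spans = [], []
    pos = 0
    for k, (state, dur, amp) in enumerate(template.segments):
        d = dur / speed
        a = amp
        if rng is not None:
            d *= float(np.exp(rng.normal(0.0, dur_cv)))
            a = max(0.05, a * (1.0 + float(rng.normal(0.0, amp_cv))))
        n = max(1, int(round(d * rate)))
        if state == "closed":
            chunk = np.zeros(n)
            if trough_depth > 0 and k == 0:
                # leading-trough style: small negative dip before the first
                # opening, carved into the tail of the leading silence
                nt = min(n, max(4, int(round(0.08 / speed * rate))))
                chunk[n - nt:] = -_render_lobe(nt, trough_depth)
        elif state == "opening":
            chunk = _render_lobe(n, a)
        else:
            chunk = -_render_lobe(n, a)
        chunks.append(chunk)
        spans.append((state, pos, pos + n))
        pos += n
    return np.concatenate(chunks), spans


def _add_noise(clean: np.ndarray, rate: float, rng: np.random.Generator,
               noise_50hz_frac: float, noise_white_frac: float) -> np.ndarray:
    peak = np.max(np.abs(clean))
    if peak == 0:
        return clean.copy()
    t = np.arange(clean.size) / rate
    phase = rng.uniform(0, 2 * np.pi)
    mains = noise_50hz_frac * peak * np.sin(2 * np.pi * 50.0 * t + phase)
    white = noise_white_frac * peak * rng.standard_normal(clean.size)
    return clean + mains + white


def synth_word(template: WordTemplate, profile: SpeakerProfile | None = None,
               seed: int = 0, rate: float = DEFAULT_RATE,
               noise_50hz_frac: float = NOISE_50HZ_FRAC,
               noise_white_frac: float = NOISE_WHITE_FRAC,
               jitter: bool = True) -> Utterance:
    """Synthesize one word utterance for a speaker.

    With ``jitter=False`` and zero noise fractions the rendering is the
    deterministic template shape (peak equal to the largest template
    amplitude, durations scaled by ``1/speed_factor``).
    """
    profile = profile or SpeakerProfile()
    rng = np.random.default_rng(seed)
    speed = profile.speed_factor
    jrng = None
    if jitter:
        speed *= float(np.exp(rng.normal(0.0, profile.speed_jitter_sd)))
        jrng = rng
    clean, spans = _render_template(
        template, rate, speed, jrng,
        profile.amplitude_jitter_cv, profile.duration_jitter_cv,
        trough_depth=profile.trough_depth if profile.initial_trough else 0.0)
    noisy = _add_noise(clean, rate, rng, noise_50hz_frac, noise_white_frac)
    onset_idx = _first_crossing(clean, ONSET_THRESHOLD_FRAC)
    lip = Waveform(samples=noisy, rate=rate, kind="lip", units="normalized",
                   meta={"label": template.label, "speaker": profile.name,
                         "seed": int(seed), "speed": speed})
    span = Segment(start_s=0.0, end_s=clean.size / rate, label=template.label)
    return Utterance(lip=lip, label=template.label, speaker=profile.name,
                     seed=int(seed), clean=clean, word_spans=[span],
                     onset_s=(onset_idx or 0) / rate)


def synth_phrase(templates: list, compression: float = 0.0,
                 profile: SpeakerProfile | None = None, seed: int = 0,
                 rate: float = DEFAULT_RATE, gap_s: float = 0.0,
                 noise_50hz_frac: float = NOISE_50HZ_FRAC,
                 noise_white_frac: float = NOISE_WHITE_FRAC,
                 jitter: bool = True) -> Utterance:
    """Concatenate word templates into one continuous phrase.

    Inter-word closed pauses are removed (replaced by ``gap_s``) and every
    word's durations are multiplied by ``1 - compression``, emulating the
    omission of parts of the pronunciation in fluent speech.  The total
    active duration is therefore strictly shorter than the sum of the
    isolated word durations whenever ``compression > 0``.
    """
    if not templates:
        raise ValueError("need at least one word template")
    if not (0 <= compression < 1):
        raise ValueError("compression must lie in [0, 1)")
    profile = profile or SpeakerProfile()
    rng = np.random.default_rng(seed)
    speed = profile.speed_factor
    jrng = None
    if jitter:
        speed *= float(np.exp(rng.normal(0.0, profile.speed_jitter_sd)))
        jrng = rng

    scale = 1.0 - compression
    chunks, word_spans = [], []
    lead = max(1, int(round(0.12 * rate)))
    gap = int(round(gap_s * rate))
    chunks.append(np.zeros(lead))
    pos = lead
    labels = []
    for i, tpl in enumerate(templates):
        labels.append(tpl.label)
        # strip the template's own leading/trailing silence only (interior
        # closed gaps between syllables belong to the word); compress cores
        states = [st for st, _, _ in tpl.segments]
        first = next(i for i, st in enumerate(states) if st != "closed")
        last = len(states) - 1 - next(
            i for i, st in enumerate(reversed(states)) if st != "closed")
        core = tuple((st, d * scale, a)
                     for st, d, a in tpl.segments[first:last + 1])
        core_tpl = WordTemplate(label=tpl.label, segments=(
            ("closed", 1e-9, 0.0),) + core + (("closed", 1e-9, 0.0),))
        samples, _ = _render_template(
            core_tpl, rate, speed, jrng,
            profile.amplitude_jitter_cv, profile.duration_jitter_cv)
        word_spans.append(Segment(start_s=pos / rate,
                                  end_s=(pos + samples.size) / rate,
                                  label=tpl.label))
        chunks.append(samples)
        pos += samples.size
        if i < len(templates) - 1 and gap > 0:
            chunks.append(np.zeros(gap))
            pos += gap
    chunks.append(np.zeros(lead))
    clean = np.concatenate(chunks)
    noisy = _add_noise(clean, rate, rng, noise_50hz_frac, noise_white_frac)
    onset_idx = _first_crossing(clean, ONSET_THRESHOLD_FRAC)
    label = " ".join(labels)
    lip = Waveform(samples=noisy, rate=rate, kind="lip", units="normalized",
                   meta={"label": label, "speaker": profile.name,
                         "seed": int(seed), "compression": compression})
    return Utterance(lip=lip, label=label, speaker=profile.name, seed=int(seed),
                     clean=clean, word_spans=word_spans,
                     onset_s=(onset_idx or 0) / rate)


def synth_sound_envelope(utt: Utterance, advance_ms: float | None = None,
                         per_word_advances: list | None = None,
                         duration_frac: float | None = None,
                         smooth_ms: float = 10.0) -> Utterance:
    """Attach a synthetic sound envelope to an utterance.

    The envelope is the rectified, lightly smoothed clean lip waveform
    delayed by the requested advance (the lip leads the sound).  With
    ``per_word_advances`` each word span is delayed individually.  With
    ``duration_frac`` each word's envelope is tapered so the sound occupies
    only that fraction of the lip-motion duration, matching the observation
    that sound durations cover roughly 61-85% of the lip durations.
    """
    rate = utt.lip.rate
    env = np.abs(utt.clean)
    n_win = max(1, int(round(smooth_ms * 1e-3 * rate)))
    if n_win > 1:
        kernel = np.ones(n_win) / n_win
        env = np.convolve(env, kernel, mode="same")

    if per_word_advances is not None:
        if len(per_word_advances) != len(utt.word_spans):
            raise ValueError("need one advance per word span")
        advances = [float(a) for a in per_word_advances]
    else:
        advances = [float(advance_ms or 0.0)] * len(utt.word_spans)
    if any(a < 0 for a in advances):
        raise ValueError("advances must be >= 0")

    margin = n_win  # smoothing spreads energy by up to one window
    out = np.zeros_like(env)
    for seg, adv in zip(utt.word_spans, advances):
        shift = int(round(adv * 1e-3 * rate))
        if shift >= env.size:
            raise ValueError("advance longer than the utterance")
        i0 = max(0, int(round(seg.start_s * rate)) - margin)
        i1 = min(env.size, int(round(seg.end_s * rate)) + margin)
        chunk = env[i0:i1]
        if duration_frac is not None:
            chunk = _taper_duration(chunk, duration_frac, rate)
        j0, j1 = i0 + shift, min(out.size, i1 + shift)
        out[j0:j1] = np.maximum(out[j0:j1], chunk[: j1 - j0])
    sound = Waveform(samples=out, rate=rate, kind="envelope", units="normalized",
                     meta={"advances_ms": advances, "duration_frac": duration_frac})
    return replace(utt, sound=sound)


def _taper_duration(chunk: np.ndarray, frac: float, rate: float) -> np.ndarray:
    """Taper a word envelope so its active span is ``frac`` of the original."""
    on = _first_crossing(chunk, ONSET_THRESHOLD_FRAC)
    if on is None:
        return chunk
    idx = np.flatnonzero(np.abs(chunk) > ONSET_THRESHOLD_FRAC * np.abs(chunk).max())
    off = int(idx[-1])
    keep = int(round(frac * (off - on)))
    cut = on + keep
    out = chunk.copy()
    n_t = min(max(4, int(round(0.03 * rate))), max(1, out.size - cut))
    if cut < out.size:
        ramp = 0.5 * (1.0 + np.cos(np.linspace(0, np.pi, n_t)))
        out[cut:cut + n_t] *= ramp
        out[cut + n_t:] = 0.0
    return out


# ---------------------------------------------------------------------------
# dataset generation

#: hand-authored per-word mouth-motion structure: syllables as
#: (opening peak, opening duration s, closing peak, closing duration s).
#: "berry" and "olive" are deliberately close in structure, emulating the
#: observation that some word pairs produce similar waveforms.
FRUIT_SYLLABLES: dict = {
    "apple":    [(0.90, 0.17, 0.60, 0.13), (0.45, 0.12, 0.35, 0.10)],
    "banana":   [(0.55, 0.12, 0.40, 0.10), (0.95, 0.15, 0.70, 0.12), (0.50, 0.12, 0.35, 0.10)],
    "cherry":   [(0.75, 0.14, 0.30, 0.12), (0.45, 0.11, 0.60, 0.10)],
    "date":     [(0.88, 0.20, 0.66, 0.16)],
    "fig":      [(0.62, 0.12, 0.50, 0.09)],
    "grape":    [(0.97, 0.22, 0.45, 0.18)],
    "kiwi":     [(0.60, 0.12, 0.30, 0.10), (0.80, 0.14, 0.40, 0.12)],
    "lemon":    [(0.82, 0.14, 0.55, 0.11), (0.38, 0.13, 0.52, 0.11)],
    "mango":    [(0.90, 0.16, 0.42, 0.13), (0.66, 0.14, 0.58, 0.12)],
    "melon":    [(0.74, 0.13, 0.62, 0.12), (0.40, 0.14, 0.30, 0.12)],
    "olive":    [(0.72, 0.15, 0.50, 0.12), (0.50, 0.12, 0.38, 0.10)],
    "berry":    [(0.68, 0.14, 0.47, 0.11), (0.47, 0.11, 0.36, 0.10)],
    "peach":    [(0.92, 0.15, 0.80, 0.13)],
    "pear":     [(0.76, 0.18, 0.36, 0.10)],
    "plum":     [(0.64, 0.13, 0.58, 0.15)],
    "apricot":  [(0.86, 0.13, 0.50, 0.10), (0.48, 0.11, 0.40, 0.09), (0.70, 0.13, 0.52, 0.11)],
    "papaya":   [(0.68, 0.12, 0.44, 0.10), (0.92, 0.15, 0.60, 0.12), (0.55, 0.12, 0.40, 0.10)],
    "guava":    [(0.85, 0.15, 0.70, 0.13), (0.72, 0.14, 0.44, 0.12)],
    "lime":     [(0.70, 0.24, 0.58, 0.19)],
    "coconut":  [(0.76, 0.12, 0.52, 0.10), (0.52, 0.11, 0.40, 0.09), (0.82, 0.13, 0.62, 0.11)],
}

FRUIT_WORDS = tuple(FRUIT_SYLLABLES)


def fruit_template(label: str, lead_s: float = 0.12,
                   gap_s: float = 0.06) -> WordTemplate:
    """Build the :class:`WordTemplate` for one of the built-in words."""
    syllables = FRUIT_SYLLABLES[label]
    segs: list = [("closed", lead_s, 0.0)]
    for i, (ao, do, ac, dc) in enumerate(syllables):
        if i:
            segs.append(("closed", gap_s, 0.0))
        segs.append(("opening", do, ao))
        segs.append(("closing", dc, ac))
    segs.append(("closed", lead_s, 0.0))
    return WordTemplate(label=label, segments=tuple(segs))


def default_templates(n_classes: int = 20) -> list:
    if n_classes > len(FRUIT_WORDS):
        raise ValueError(f"at most {len(FRUIT_WORDS)} built-in classes")
    return [fruit_template(w) for w in FRUIT_WORDS[:n_classes]]


def _blend_templates(templates: list, similarity: float) -> list:
    """Morph odd-indexed templates toward their predecessor.

    Only pairs with identical segment structure are blended; ``similarity``
    in [0, 1) interpolates durations and amplitudes, creating confusable
    class pairs on demand.
    """
    if similarity <= 0:
        return templates
    out = list(templates)
    for i in range(1, len(out), 2):
        a, b = out[i - 1], out[i]
        if len(a.segments) != len(b.segments):
            continue
        segs = tuple(
            (sb, db + similarity * (da - db), ab + similarity * (aa - ab)
             if sb != "closed" else ab)
            for (sa, da, aa), (sb, db, ab) in zip(a.segments, b.segments))
        out[i] = WordTemplate(label=b.label, segments=segs)
    return out


@dataclass
class LipDataset:
    """A labelled collection of utterances with a frozen train/test split."""

    utterances: list
    split: list          # "train" / "test" per utterance
    labels: list         # class label names, index = class id
    y: np.ndarray        # integer class per utterance
    n_per_class: int
    base_seed: int

    def __post_init__(self) -> None:
        counts = np.bincount(self.y, minlength=len(self.labels))
        if len(set(self.labels)) != len(self.labels):
            raise ManifestError("duplicate class labels")
        if np.any(counts != self.n_per_class):
            raise ManifestError("per-class sample counts must be equal")
        if set(self.split) - {"train", "test"}:
            raise ManifestError("split tags must be 'train' or 'test'")

    @property
    def n_classes(self) -> int:
        return len(self.labels)

    def indices(self, tag: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.split) == tag)

    def manifest(self) -> dict:
        """JSON-serializable manifest (no waveform payload)."""
        return {
            "n_classes": self.n_classes,
            "n_per_class": self.n_per_class,
            "base_seed": self.base_seed,
            "labels": list(self.labels),
            "entries": [
                {"index": i, "label": u.label, "speaker": u.speaker,
                 "seed": u.seed, "split": tag}
                for i, (u, tag) in enumerate(zip(self.utterances, self.split))
            ],
        }


def make_dataset(n_classes: int = 20, n_per_class: int = 100,
                 templates: list | None = None,
                 profile: SpeakerProfile | None = None,
                 base_seed: int = 0, similarity: float = 0.0,
                 train_fraction: float = 0.8,
                 rate: float = DEFAULT_RATE) -> LipDataset:
    """Generate the default classification dataset.

    Defaults mirror the study protocol: 20 word classes with 100 samples
    each, split 80/20 into train and test.  All randomness flows from
    ``base_seed`` via per-sample child seeds, so identical arguments produce
    identical datasets.
    """
    if n_classes < 2:
        raise ValueError("need at least two classes")
    templates = templates or default_templates(n_classes)
    if len(templates) != n_classes:
        raise ValueError("number of templates must equal n_classes")
    templates = _blend_templates(templates, similarity)
    profile = profile or SpeakerProfile()
    rng = np.random.default_rng(base_seed)

    utterances, split, y = [], [], []
    n_train = int(round(train_fraction * n_per_class))
    for ci, tpl in enumerate(templates):
        tags = np.array(["train"] * n_train + ["test"] * (n_per_class - n_train))
        tags = tags[rng.permutation(n_per_class)]
        for si in range(n_per_class):
            seed = int(rng.integers(2 ** 31))
            utterances.append(synth_word(tpl, profile, seed=seed, rate=rate))
            split.append(str(tags[si]))
            y.append(ci)
    return LipDataset(utterances=utterances, split=split,
                      labels=[t.label for t in templates],
                      y=np.asarray(y), n_per_class=n_per_class,
                      base_seed=base_seed)
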