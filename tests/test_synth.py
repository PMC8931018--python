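"""Synthetic utterance generator: determinism, timing and dataset layout."""

import numpy as np
import pytest

import liplang as ll
import liplang.preprocess as pp
from liplang.synth import ManifestError, TemplateError, _blend_templates


@pytest.fixture()
def apple():
    return ll.fruit_template("apple")


class TestWordTemplate:
    def test_must_start_and_end_closed(self):
        with pytest.raises(TemplateError):
            ll.WordTemplate("bad", (("opening", 0.1, 0.5),))

    def test_amplitude_bounds(self):
        with pytest.raises(TemplateError):
            ll.WordTemplate("bad", (("closed", 0.1, 0.0),
                                    ("opening", 0.1, 1.5),
                                    ("closed", 0.1, 0.0)))


class TestSynthWord:
    def test_seed_determinism(self, apple):
        u1 = ll.synth_word(apple, seed=42)
        u2 = ll.synth_word(apple, seed=42)
        assert np.array_equal(u1.lip.samples, u2.lip.samples)
        assert not np.array_equal(
            u1.lip.samples, ll.synth_word(apple, seed=43).lip.samples)

    def test_clean_peak_matches_template(self, apple):
        u = ll.synth_word(apple, seed=0, noise_50hz_frac=0, noise_white_frac=0,
                          jitter=False)
        assert np.abs(u.clean).max() == pytest.approx(0.90, abs=1e-12)

    def test_speed_factor_halves_duration(self, apple):
        slow = ll.synth_word(apple, seed=0, noise_50hz_frac=0,
                             noise_white_frac=0, jitter=False)
        prof = ll.SpeakerProfile(speed_factor=2.0)
        fast = ll.synth_word(apple, prof, seed=0, noise_50hz_frac=0,
                             noise_white_frac=0, jitter=False)
        assert abs(len(slow.lip) - 2 * len(fast.lip)) <= len(apple.segments)

    def test_polarity_structure(self, apple):
        # opening lobes positive, closing lobes negative, silence in between
        u = ll.synth_word(apple, seed=0, noise_50hz_frac=0, noise_white_frac=0,
                          jitter=False)
        x = u.clean
        assert x[:10].max() == 0.0                 # leading closed
        assert x.max() > 0 and x.min() < 0

    def test_initial_trough_style(self, apple):
        prof = ll.SpeakerProfile(initial_trough=True, trough_depth=0.1)
        u = ll.synth_word(apple, prof, seed=0, noise_50hz_frac=0,
                          noise_white_frac=0, jitter=False)
        first_pos = np.flatnonzero(u.clean > 0.05)[0]
        assert u.clean[:first_pos].min() <= -0.05  # dip before the first lobe


class TestSynthPhrase:
    def test_zero_compression_preserves_core_duration(self, apple):
        mango = ll.fruit_template("mango")
        sep = [ll.synth_word(t, seed=0, noise_50hz_frac=0, noise_white_frac=0,
                             jitter=False) for t in (apple, mango)]
        core = sum(seg.duration for u in sep
                   for seg in pp.detect_onsets(pp.normalize(u.lip),
                                               threshold_frac=0.01))
        ph = ll.synth_phrase([apple, mango], compression=0.0, seed=0,
                             noise_50hz_frac=0, noise_white_frac=0, jitter=False)
        cont = pp.detect_onsets(pp.normalize(ph.lip), threshold_frac=0.01,
                                min_gap_s=10.0)[0].duration
        assert cont == pytest.approx(core, rel=0.03)

    def test_compression_shortens(self, apple):
        mango = ll.fruit_template("mango")
        p0 = ll.synth_phrase([apple, mango], compression=0.0, seed=0, jitter=False)
        p4 = ll.synth_phrase([apple, mango], compression=0.4, seed=0, jitter=False)
        assert p4.lip.duration < p0.lip.duration

    @pytest.mark.parametrize("sep_total,cont,expected", [
        (2.398, 1.648, 31.3),   # four-word phrase, reported durations
        (1.286, 1.100, 14.5),   # two-word phrase, reported durations
    ])
    def test_efficiency_closed_loop(self, expected, sep_total, cont):
        """Planting the reported duration ratio reproduces the reported gain.

        Durations are measured by threshold crossing (1% of peak on clean
        signals); the sub-threshold lobe feet at word junctions bias the
        measured efficiency by up to about one point, hence the tolerance.
        """
        words = [ll.fruit_template(w) for w in ("apple", "mango")]
        c = 1.0 - cont / sep_total
        sep = [ll.synth_word(t, seed=0, noise_50hz_frac=0, noise_white_frac=0,
                             jitter=False) for t in words]
        durs = [pp.detect_onsets(pp.normalize(u.lip),
                                 threshold_frac=0.01)[0].duration for u in sep]
        ph = ll.synth_phrase(words, compression=c, seed=0, noise_50hz_frac=0,
                             noise_white_frac=0, jitter=False)
        cont_meas = pp.detect_onsets(pp.normalize(ph.lip), threshold_frac=0.01,
                                     min_gap_s=10.0)[0].duration
        got = pp.efficiency(durs, cont_meas)
        assert got == pytest.approx(expected, abs=1.5)

    def test_empty_phrase_rejected(self):
        with pytest.raises(ValueError):
            ll.synth_phrase([], compression=0.1)


class TestSoundEnvelope:
    def test_zero_advance_simultaneous(self, apple):
        u = ll.synth_sound_envelope(ll.synth_word(apple, seed=1), advance_ms=0)
        adv = pp.onset_advance(pp.normalize(pp.lowpass(u.lip)),
                               pp.normalize(u.sound))
        assert abs(adv) <= 2.0

    def test_advance_shifts_onset_index(self, apple):
        u0 = ll.synth_word(apple, seed=2, noise_50hz_frac=0, noise_white_frac=0,
                           jitter=False)
        u = ll.synth_sound_envelope(u0, advance_ms=100)
        s0 = ll.synth_sound_envelope(u0, advance_ms=0)
        i1 = np.flatnonzero(u.sound.samples > 0.05 * u.sound.samples.max())[0]
        i0 = np.flatnonzero(s0.sound.samples > 0.05 * s0.sound.samples.max())[0]
        assert i1 - i0 == 100      # 100 ms at 1 kHz

    def test_advance_longer_than_utterance_rejected(self, apple):
        with pytest.raises(ValueError):
            ll.synth_sound_envelope(ll.synth_word(apple, seed=0),
                                    advance_ms=60_000)

    def test_duration_fraction_band(self, apple):
        u = ll.synth_sound_envelope(ll.synth_word(apple, seed=7),
                                    advance_ms=50, duration_frac=0.7)
        lip_seg = pp.detect_onsets(pp.normalize(pp.lowpass(u.lip)))[0]
        snd_seg = pp.detect_onsets(pp.normalize(u.sound), min_gap_s=10.0)[0]
        frac = pp.duration_fraction(snd_seg, lip_seg)
        assert 60.8 <= frac <= 85.4


class TestMakeDataset:
    def test_counts_and_split(self, small_dataset):
        ds = small_dataset
        assert len(ds.utterances) == 5 * 12
        assert len(ds.indices("train")) == 5 * 10   # 80/20 stratified
        assert len(ds.indices("test")) == 5 * 2
        counts = np.bincount(ds.y)
        assert np.all(counts == 12)

    def test_study_protocol_split_arithmetic(self):
        # 20 classes x 100 samples -> 1600 train / 400 test
        ds = ll.make_dataset(n_classes=3, n_per_class=10, base_seed=0)
        assert len(ds.indices("train")) == 3 * 8
        assert round(0.8 * 20 * 100) == 1600 and 20 * 100 - 1600 == 400

    def test_manifest_roundtrip_fields(self, small_dataset):
        m = small_dataset.manifest()
        assert m["n_classes"] == 5 and m["n_per_class"] == 12
        tags = {e["split"] for e in m["entries"]}
        assert tags == {"train", "test"}

    def test_seed_reproducibility(self):
        d1 = ll.make_dataset(n_classes=2, n_per_class=4, base_seed=3)
        d2 = ll.make_dataset(n_classes=2, n_per_class=4, base_seed=3)
        for u1, u2 in zip(d1.utterances, d2.utterances):
            assert np.array_equal(u1.lip.samples, u2.lip.samples)

    def test_duplicate_labels_rejected(self):
        tpl = ll.fruit_template("apple")
        with pytest.raises(ManifestError):
            ll.make_dataset(n_classes=2, n_per_class=4,
                            templates=[tpl, tpl], base_seed=0)

    def test_similarity_knob_shrinks_template_distance(self):
        tpls = [ll.fruit_template(w) for w in ("olive", "berry")]
        def dist(a, b):
            return sum(abs(da - db) + abs(aa - ab)
                       for (_, da, aa), (_, db, ab)
                       in zip(a.segments, b.segments))
        base = dist(tpls[0], tpls[1])
        blended = _blend_templates(tpls, similarity=0.5)
        assert dist(blended[0], blended[1]) < base

    def test_between_class_exceeds_within_class_spread(self, small_arrays):
        """Class templates are farther apart than the per-sample jitter."""
        Xtr, ytr, _, _, _ = small_arrays
        means = np.stack([Xtr[ytr == c].mean(0) for c in np.unique(ytr)])
        d_between = min(np.linalg.norm(means[i] - means[j])
                        for i in range(len(means)) for j in range(i))
        d_within = max(np.linalg.norm(Xtr[ytr == c] - means[c], axis=1).mean()
                       for c in np.unique(ytr))
        assert d_between > d_within
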