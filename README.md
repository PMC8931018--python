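# liplang

Decoding lip language from triboelectric sensor signals.

People who cannot vocalise — after laryngectomy, with vocal-cord lesions —
can still articulate. A flexible triboelectric sensor worn at the corner of
the mouth turns each mouth open-close event into a biphasic voltage pulse
(press: positive lobe; release: negative lobe), and a sequence classifier
turns those pulse trains into words. `liplang` implements the computational
core of such a silent-speech interface:

* **`liplang.sensor`** — a parametric simulator of the contact-separation
  triboelectric sensor, calibrated to its reported characterisation (force
  sensitivity 0.376 V/N, short-circuit current 1.88→9.66 nA over 1-5 Hz,
  matched-load power 3.50 nW at 97.1 MΩ, durability 1.40→1.38 V over 2000
  cycles).
* **`liplang.synth`** — a seeded generator of synthetic lip-motion
  utterances (word templates of closed/opening/closing mouth states,
  speaker-style variation, 50 Hz power-line interference, paired sound
  envelopes lagging the lip signal by 18-417 ms). It stands in for the
  original recordings, which are not available in machine-readable form.
* **`liplang.preprocess`** — the conditioning and timing chain: 20 Hz
  zero-phase low-pass, max-abs normalisation, onset segmentation with
  hysteresis, STFT, duration-efficiency / onset-advance / data-volume
  statistics.
* **`liplang.model`** — a dilated GRU recurrent feature extractor
  (4 layers × 50 units, dilations 1, 2, 4, 8) with **prototype learning**:
  classification by Euclidean distance to one learned prototype per class,
  `p(k|f) ∝ exp(−γ‖f − m_k‖²)`, trained with distance-based cross-entropy
  plus a pull term `λ‖f − m_y‖²`; a softmax classification layer is the
  baseline. Implemented from scratch in numpy with hand-derived
  backpropagation, exposed as a scikit-learn estimator
  (`DilatedGRUClassifier`).
* **`liplang.evaluate`** — confusion analysis, the small-sample sweep
  (training set reduced to 100/80/60/40/20%), 2-D feature separability,
  open-set identity verification by prototype distance, and word→command
  mapping.

## Worked example

```python
import numpy as np
import liplang as ll

# --- sensor simulation: force sensitivity of the 20x20x5 mm sensor
spec = ll.SensorSpec()
peaks = [np.abs(ll.simulate_waveform(
             spec, ll.Excitation(force_n=F, frequency_hz=1.0)).samples).max()
         for F in range(1, 6)]
print("slope V/N:", round(np.polyfit(range(1, 6), peaks, 1)[0], 3))

# --- timing statistics on the reported phrase durations
print("efficiency %:", round(ll.efficiency([2.398], 1.648), 1))
print("volume ratio:", ll.data_volume_ratio(12, 576))

# --- synthesize a small word dataset and train the classifier
ds = ll.make_dataset(n_classes=5, n_per_class=12, base_seed=11)
Xtr, ytr, Xte, yte, labels = ll.dataset_to_arrays(ds)
clf = ll.DilatedGRUClassifier(epochs=150, random_state=0)
clf.fit(Xtr, ytr, X_val=Xte, y_val=yte)
rep = ll.evaluate_model(clf, Xte, yte)
print("test accuracy:", rep.accuracy)
print("classes at 100%:", round(rep.frac_perfect, 2))
```

prints

```
slope V/N: 0.376
efficiency %: 31.3
volume ratio: 0.020833333333333332
test accuracy: 1.0
classes at 100%: 1.0
```

The slope is the simulator reproducing the sensor's force sensitivity; the
31.3% is the speaking-time saving of pronouncing the four-word phrase
continuously instead of word by word; 12 KB / 576 KB = 1/48 is the lip-to-
sound data-volume ratio; and the classifier separates the five synthetic
word classes perfectly at this small scale. On the full protocol —
20 classes × 100 samples, 80/20 split — a 100-epoch run reaches ~91% test
accuracy with the prototype head versus ~89% for the softmax baseline, and
at 20% of the training data the prototype head's median advantage grows to
~7 points (83% vs 77%), the small-sample behaviour prototype learning is
chosen for.

A command-line surface wraps the same pipeline:

```sh
liplang simulate-sensor --force-n 5 --freq-hz 1 --cycles 3 --out sim.csv
liplang synth-dataset --classes 20 --per-class 100 --seed 0 --out-dir data/
liplang train --manifest data/ --head prototype --epochs 100 --seed 0 --out model.npz
liplang evaluate --manifest data/ --model model.npz --out report.json
```

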