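# Methods

This note documents the models implemented in `liplang`, the choices made
where the design was genuinely open, and what the
synthetic data can and cannot establish.

## Sensor model

A contact-separation triboelectric sensor converts one mouth open-close
event into a biphasic pulse: pressing drives current one way (positive
lobe), releasing drives it back (negative lobe), with zero transfer at the
fully-closed and fully-open turning points.  `cycle_shape` realises this as
raised-cosine lobes, `sign(0.5 - phase) * (1 - cos(4*pi*phase)) / 2`: smooth,
zero with zero slope at the stage boundaries, and with exactly zero net area
over a cycle, which is the charge-conservation constraint a short-circuit
current must satisfy.  No closed-form pulse shape is published for this
sensor; any smooth zero-net-area biphasic template would serve, and the
raised cosine is the simplest.

Peak amplitudes come from a calibration table of reported characterisation
anchors, composed multiplicatively relative to the reference condition
(20 x 20 x 5 mm sensor, 5 N, 1 Hz), because the characterisation varies one
axis at a time and never jointly:

| axis | anchors | behaviour |
| --- | --- | --- |
| force (V) | slope 0.376 V/N above 1 N; linear from 0 below 1 N | piecewise linear |
| frequency (V) | flat factor 1.0 across 1-5 Hz | constant |
| frequency (nA) | 1.88 nA at 1 Hz to 9.66 nA at 5 Hz | monotone linear |
| area | 1.10 -> 3.08 V and 1.52 -> 4.39 nA from D=20 to D=50 mm | used as ratios |
| thickness | rises to saturation at T = 2 mm, flat above | clamped factor |
| durability | amplitude scale 1.0 at cycle 0 to 1.38/1.40 at cycle 2000 | linear, clamped |

The reported series are not mutually consistent in absolute volts: a
0.376 V/N slope over 1-5 N spans more than either reported 5 N voltage
(0.89-0.91 V frequency series; 1.10 V area series), so no composition with
positive outputs can reproduce all three absolutely.  The force/frequency
series of the reference sensor anchors the absolute scale (V = 0.376 * F,
hence 1.88 V at 5 N), and the area and thickness series contribute relative
factors only; their reported voltages are honoured as ratios (3.08/1.10 =
2.8x from D = 20 to D = 50 mm).  Interpolation between anchors is monotone
piecewise-linear; queries outside the anchored range raise unless
extrapolation is explicitly enabled, in which case values clamp to the
nearest anchor.

The load curve uses a Thevenin model, `P(R) = V^2 R / (R + R_int)^2` with
`R_int = 97.1 MOhm` and the source amplitude chosen so the matched-load
power is 3.50 nW; power then peaks exactly at `R = R_int` (matched-load
theorem).  Series/parallel combination is ideal superposition of identical
units: series adds voltages, parallel adds currents, which reproduces the
observed ordering (series voltage stronger than parallel).

## Synthetic utterances

The study's raw recordings are unavailable, so `liplang.synth` generates
signals with the structure its analyses assume.  A word template is an
alternation of mouth states `closed / opening / closing`, rendered as
raised-cosine lobes (positive for opening, negative for closing).  Twenty
hand-authored fruit-word templates differ in syllable count, relative lobe
amplitudes and durations; "berry" and "olive" are deliberately close,
emulating the observation that some word pairs give similar waveforms.
Defaults, fixed once as the study conditions:

* sampling rate 1 kHz (desk-scale; a 20 s line is 20k samples);
* power-line interference: 50 Hz sinusoid at 10% of the clean peak, plus
  white noise at 2% (amplitudes are unpublished; these motivate the 20 Hz
  low-pass without drowning the signal);
* per-sample jitter: amplitude CV 10%, per-segment duration CV 5%,
  log-normal speed jitter with sigma = 0.08;
* speaker style: speed factor, optional leading trough, and the
  lip-before-sound onset advance range 18-417 ms;
* dataset protocol: 20 classes x 100 samples, stratified 80/20 train/test
  split, all randomness derived from one base seed.

The paired sound channel is an amplitude envelope (rectified, 10 ms
moving-average-smoothed clean lip signal) delayed by the planted advance and
optionally tapered so the sound occupies a configurable fraction of the lip
duration (default band 60.8-85.4%).  It is *not* audio: every analysis that
touches sound uses only onsets and durations.

What the generator does not emulate: real articulator dynamics (lobes are
stylised, real pulses are asymmetric), sensor drift and contact
nonstationarity, inter-session electrode placement shifts, or real
coarticulation (phrase compression is a uniform time scaling, not a
phonetic process).  Classification results on this data therefore establish
that the pipeline and model behave as designed — not field performance on
real lip-motion recordings, whose headline accuracies depend on the
original dataset.

## Signal conditioning

* Low-pass: 4th-order Butterworth at 20 Hz, zero-phase (forward-backward),
  with *even* edge extension — an odd extension turns a recording that
  starts mid-oscillation of the 50 Hz pickup into a low-frequency edge bump
  that survives the filter and fakes an onset at t = 0.  The default
  attenuates 50 Hz by more than 60 dB and leaves the sub-10 Hz motion band
  within 1 dB, without moving onsets.
* Normalisation: per-utterance division by the maximum absolute value
  (sign preserved, idempotent), the convention implied by reporting
  sub-peak amplitudes as fractions of the maximum.
* Segmentation: a sample is active when |x| exceeds 5% of the global peak;
  active runs merged across silent gaps shorter than 150 ms, runs shorter
  than 50 ms discarded.  Against generator ground truth (the clean signal's
  first 5% crossing) boundaries are recovered within +-2 samples at 1 kHz
  across 100 seeded utterances; planted sound advances of 18 and 417 ms are
  recovered within +-2 ms.
* Timing statistics are pure arithmetic on segment durations: duration
  efficiency `100 * (sum(separate) - continuous) / sum(separate)` (the only
  definition consistent with both reported duration pairs), sound/lip
  duration fraction, and the raw data-volume ratio.
* Model input: sequences are decimated from 1 kHz to 50 Hz (polyphase,
  anti-aliased) and fixed to 75 samples (1.5 s).  After the 20 Hz low-pass
  the signal is band-limited near the decimated Nyquist rate, so this holds
  the information while cutting the recurrent computation 13-fold; longer
  inputs are resampled to length, shorter ones centre-padded.

## Classifier

The feature extractor is a 4-layer dilated GRU, 50 units per layer,
dilations (1, 2, 4, 8): layer *l* updates its hidden state from the state
`d_l` steps back.  Dilation changes connectivity only — the parameter count
is identical to the undilated stack — and is evaluated by folding the
interleaved subsequences into the batch axis, which makes the skip
recurrence exact and fast.  The GRU cell is the standard update/reset-gate
form with reset-gated recurrence, `n = tanh(Wx x + Wh (r * h))`.  The
feature vector is a linear map of the top layer's final states, one per
interleaved chain (their mean, then a learned projection to 32 dimensions;
2 for visualisation).

Two heads share this extractor:

* **prototype learning** — one learned prototype `m_k` per class;
  `p(k | f)` proportional to `exp(-gamma ||f - m_k||^2)`; loss is this
  distance-based cross-entropy plus a pull term `lambda ||f - m_y||^2`.
  Defaults `gamma = 3`, `lambda = 0.1`: both are free scale parameters of
  the method, and with too small a `gamma` the squared distances between
  the initially small, near-collapsed features produce almost uniform
  class probabilities, which stalls the head in the early epochs; sharper
  distances and a stronger pull reproduce the method's characteristic
  fast, stable convergence.  Prototypes start at the class means of the
  initial (untrained) features, a one-pass initialisation that makes the
  distance geometry sensible from epoch 1;
* **softmax** — a linear classification layer with cross-entropy, the
  conventional baseline.

Training uses Adam at learning rate 3e-3 with cosine annealing to zero
over the run (a constant rate leaves the endpoint ~1.5 points below the
late-training peak on the default task), batch 32, shuffled every epoch,
all seeded.  The published setting trains 500 epochs; the package default
follows it, while the test suite and the worked examples use 100-epoch runs
at which the synthetic task has converged.  A learning rate of 1e-3 was
found to underfit this task within 100 epochs (the loss is still falling
steeply); 3e-3 converges cleanly and is the default.  The training loop
runs in float32 — the backward-through-time pass is BLAS-bound, and single
precision halves its cost at ample precision for stochastic optimisation —
while all network mathematics is validated in float64 against central
finite differences (1e-5) and a scalar re-derivation of the GRU step
(1e-10).  Ties in the argmax resolve to the lowest class index.

Numerical edge cases: probabilities are computed with max-subtracted
softmax; an all-zero waveform cannot be normalised and raises; sequences
shorter than the largest dilation raise rather than silently pad.

## Evaluation harness

The confusion matrix is row-normalised from integer counts, with summary
fractions of classes at 100%, above 90% and above 80% accuracy.  The
small-sample sweep subsamples the training split per class (seeded,
stratified) at fractions 1.0/0.8/0.6/0.4/0.2, retrains both heads from
scratch, and reports the median over 3 seeds — the published protocol
reports single numbers without a seed policy, and a median over a few seeds
is the honest summary at this scale.  Identity verification is open-set:
the enrolled prototype is the mean feature of the genuine utterances and
the acceptance threshold is the 95th percentile of genuine distances, so
acceptance is monotone in the threshold with the expected limits at 0 and
infinity.  Command mapping is a bijective word-to-token table.

## Known limitations

* All accuracy statements concern the synthetic generator's conditions;
  they transfer to real recordings only insofar as the generator's
  structure (biphasic lobes, jitter scales, noise model) matches them.
* The absolute voltage scale of the sensor simulator follows the
  force-sensitivity series; the area-series voltages hold as ratios only
  (see the calibration discussion above).
* Training determinism is per-BLAS-configuration: fixed seeds reproduce
  bit-identical runs on the same library stack.
* The recurrent core is pure numpy; it is adequate at the package's
  problem sizes (minutes per 1600-sequence training run on one CPU) but is
  not a general-purpose deep-learning runtime.
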