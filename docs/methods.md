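# Methods

## The framework

`auscon` pretrains a convolutional encoder *f* on unlabeled auscultation
spectrograms by contrasting pairs of views. A projection head *g* (one
linear layer, default output 256; 64 in the desk-scale profile) maps the
length-N representation *h = f(x)* to *z = g(h)*; the loss operates on
L2-normalized *z* with cosine similarity and temperature *T* (default 0.5).
Two losses are implemented:

* **NT-Xent** — one positive per anchor, contrasted against all other views
  in the batch (the candidate set *A(i)* is every view except the anchor,
  so it includes the positive; both views of every pair serve as anchors
  and the batch loss is the mean over anchors).
* **Supervised contrastive with weak labels** — multiple positives *P(i)*,
  with the average over positives taken *inside* the logarithm. With
  |P(i)| = 1 it reduces exactly to NT-Xent, which the tests assert. The
  variant with the logarithm inside the average is deliberately not
  offered.

Views come from one of two families:

* **Augmentation schemes** (`split`, `time_mask`, `freq_mask`, `spec_mask`,
  `spec_mask_split`): two independent stochastic transforms of one
  recording. Whether the two views share a draw is a config question; the
  package uses independent draws per view, the usual convention for this
  family.
* **Metadata schemes**: a positive pair is two distinct recordings of one
  patient (optionally at the same or at different auscultation locations),
  with **no augmentation**, so any downstream difference is attributable to
  pair selection. Negative selection is implemented through batch
  composition: under `neg_sim_age`, `neg_sim_sex`, `neg_sim_age_sex` and
  `pos_same_loc_neg_same_loc` every batch member shares the named trait, so
  all in-batch negatives are "hard" with respect to it. For `pos_sim_age`
  the age band acts as a weak label through the supervised contrastive
  loss.

Mechanism: raising any negative's similarity to the anchor strictly
increases the loss (asserted numerically in the tests), so trait-sharing
batches define a strictly harder pretraining task whenever the trait
correlates with acoustic structure.

## Data handling

Recordings (PCM WAV) become log-power mel spectrograms (25 ms window,
10 ms hop, 64 mel bands by default; 32 bands in the desk-scale profile —
STFT parameters are configuration
with logged defaults). All spectrograms are standardized to the cohort's
75th-quantile frame count (linear-interpolation quantile, rounded half-up):
longer recordings keep a centered window (odd excess dropped on the right),
shorter ones are zero-padded symmetrically (odd deficit padded on the
right). The pad extents are carried on the `Spectrogram` object and all
augmentations are confined to the non-padded region — padding cells are
never modified, which the property tests assert on every trial.

Each spectrogram's data region is then z-scored per recording
(`normalize_per_recording`, on by default). This serves two purposes: it
removes per-recording gain as a nuisance, and it makes the padding value
(exactly zero) coincide with the data mean. Without it the padding sits
tens of dB above the log-power cells, the embedding space starts out
nearly collapsed (cosine similarities ≈ 0.99 at initialization), and
contrastive training can stall at the uniform-softmax plateau.

Missing demographics are imputed by chained categorical regression: age
band and sex are patient-level (broadcast across a patient's recordings
before modelling), location is per-recording; five sweeps of one-hot
logistic/multinomial regression per field, seeded; a patient with no
metadata at all receives the per-field mode. A field missing for the whole
cohort is an error.

## Masking calibration

Band counts are fixed (5 time bands, 2 frequency bands). Bands are placed
independently and uniformly inside the data region, so overlaps are
allowed; the open width parameter is calibrated so the **expected** masked
fraction of the data region hits the 50% target, per scheme. For a single
axis the expected union coverage of *n* bands of fractional width *w*
(edge effects included) is integrated numerically and solved by root
finding; for combined time+frequency masking each axis is calibrated to
*t = 1 − √(1 − target)* so that *t + f − t·f = target* with *t = f*.
Discretization (integer band widths on a 64×200 grid) perturbs the
realized mean by well under a percentage point, which the Monte-Carlo
checks bracket.

## Batch construction

Batches hold 2×batch_size views from batch_size **distinct** patients
(preventing accidental extra positives in the denominator). Patients are
sampled with replacement across batches but without replacement within a
batch, so small trait cells can still fill batches. Trait-constrained
batches first draw a trait value from the feasible cells (those with at
least batch_size eligible patients) with probability proportional to the
cell's eligible-patient count, then fill the batch from that cell.
Patients with no pair satisfying the positive rule are skipped with a
logged warning. A validator re-checks every invariant and returns
machine-readable violations.

## Training pipelines

Reference hyperparameters: batch 16, learning rate 1e-5, L2 penalty 1e-6
(pretraining) / 1e-2 (downstream heads), 5,000 epochs for linear
evaluation, 25 for fine-tuning, 500 (heart) / 1,000 (lung) for the
flattened-spectrogram logistic baseline; 20 replicate models at the 10%
label level, 5 at 100%. The optimizer is Adam with the L2 penalty applied
as a gradient penalty (no decay on biases or normalization parameters);
no early stopping or schedule is used, and the validation split is held
for monitoring only.

Three evaluation pipelines:

* **Linear evaluation** (representations): encoder frozen — its weights
  are checksummed before and after, and the run asserts they are
  bit-identical — with a single linear+sigmoid head trained on a
  class-stratified fraction of the fine-tune split.
* **Fine-tuning** (initializations): a two-layer SSL evaluator
  (linear N→N, batch norm, ReLU, linear N→1, sigmoid) appended to the
  encoder; all parameters trainable. The random-initialization arm of the
  comparison ignores any checkpoint. Batch norm makes a training batch of
  one an error; the loader folds such remainders away.
* **Baseline**: logistic model on flattened standardized spectrograms,
  features scaled by the training split's global mean/std.

Splits: test and validation sets are reserved with a 1:1 class ratio; the
remainder is the pre-train set; the fine-tune set (again 1:1) is drawn
from — and remains part of — the pre-train pool. `make_splits` operates at
the recording level. For cohorts with several recordings per patient and
patient-level labels, `make_patient_splits` assigns whole patients to the
reserved sets so that no model can recognize a test patient from
supervised training; the benchmark comparisons use this variant.

## Networks

The encoder contract is a configurable backbone producing a length-N
embedding; the concrete architectures are compact CNNs written directly in
NumPy with exact hand-derived backward passes (verified against central
finite differences): `tiny_cnn` (two 3×3 conv layers with leaky ReLU,
average pooling, global average pooling, linear head; used by the unit
tests) and `small_cnn` (three conv blocks; used by the benchmark profile).
Leaky activations are used in the encoders because at desk scale a dead
first layer can freeze the whole contrastive task. Checkpoints store
weights, the full encoder config and the seed, and reproduce evaluations
bit-for-bit.

## Evaluation statistics

AUROC is the Mann–Whitney probability that a random positive outscores a
random negative, ties counted one half (rank-based; the tests cross-check
against exhaustive pair counting). Confidence intervals are percentile
bootstrap over resamples of the test set (1,000 replicates by default;
single-class replicates are redrawn and logged, with a warning above a 10%
redraw rate). BCa corrections are deliberately omitted — the percentile
interval is the simplest method consistent with the protocol. Model
comparison uses a classical two-sided paired t test; pairing is by
bootstrap replicate on shared resample indices by default (replicate-model
pairing is available), and zero-variance differences are an error rather
than an infinite statistic.

## Synthetic benchmark

The generator emulates the statistical structure the method exploits, not
auscultation acoustics:

* **Cohort**: 80 patients; age band (45% child) and sex (50% female) drawn
  independently; binary diagnosis from a logistic model (intercept −1.6,
  +2.4 log-odds for children, +0.7 for female patients), giving ≈46%
  prevalence and a strong age–label association like the one that motivates
  age-conditioned negatives.
* **Recordings**: 3–5 per patient at random named locations. Each waveform
  is a low-passed noise "breath" bed, a patient-specific narrowband tone
  (within-patient correlation, scaled by `patient_effect`), a
  location-specific spectral tilt, white noise, and a ±3 dB per-recording
  gain nuisance. Durations are log-normal (median 0.9 s) so the
  75th-quantile rule both crops and pads.
* **Class signature**: an amplitude-modulation rate. The breath bed and a
  wheeze tone share a patient-level modulation rate — 5–9 Hz ripple for
  abnormal patients, 0.5–2.5 Hz drift for normal ones — with
  class-independent modulation depth, power and carrier placement. Per-cell
  spectrogram expectations are therefore class-identical, so a flattened
  linear readout has essentially no population-level cue (it hovers near
  chance on patient-grouped splits), while temporal convolution filters can
  read the ripple anywhere in the grid. Setting `signal_effect=0` removes
  the class difference entirely; `patient_effect=0` removes within-patient
  correlation. This construction realizes the benchmark's design goal: the
  representation-vs-baseline gap measures whether pretraining extracted the
  temporal class structure, not whether a linear model can memorize bins.

What the benchmark does **not** emulate: realistic heart/lung sound
morphology, label noise, class imbalance across sites, recording-device
batch effects, or multi-class diagnosis. Passing the ordering tests
therefore shows the pipelines behave as designed on data with the assumed
structure; it does not certify performance on clinical recordings.

## Problem sizes and numerical choices

The test suite and benchmark run on a desk-scale profile chosen as the
package's own default study conditions: 32-mel spectrograms (~115 frames),
the `small_cnn` encoder (32-dim embeddings, 64-dim projections), batch 8,
learning rate 1e-3, 60 pretraining epochs, 300-epoch linear/baseline
schedules, 10% label fraction, five replicate seeds, and 200-replicate
bootstrap inside the pipelines (1,000 where the interval itself is under
study). The full-scale reference schedules remain the `RunConfig` defaults.
Tie-breaks are fixed (round half-up for quantiles and band widths; extra
crop frame dropped on the right, extra pad frame added on the right);
log-power has a −100 dB floor so silent input yields a uniform finite
grid; cosine similarity errors on zero vectors rather than returning a
convention value.

## Known limitations

* The NumPy networks are CPU-bound and desk-scale; the full-scale
  ResNet-18 configuration of the original protocol is out of scope here
  (the encoder is a contract, not a fixed architecture).
* Linear-probe quality after contrastive pretraining varies noticeably
  across seeds at this scale; the benchmark assertions are about means
  over five seeds, not per-seed guarantees.
* Chained-equation imputation uses point predictions (no multiple draws),
  which understates imputation uncertainty.
* `pos_same_loc` / `pos_dif_loc` use unconstrained batches; the metadata
  schemes are dataset-agnostic even though the motivating protocol applied
  them to lung sounds only.
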