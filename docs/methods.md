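# Methods

This note documents the models, assumptions and numerical choices behind
`pclr`, in the spirit of a package reference manual: what is computed,
what the defaults mean, and what a green test does and does not establish.

## 1. The pre-training objective

Patient-contrastive pre-training treats patient identity over time as the
supervisory signal. A minibatch holds `2N` ECGs from `N` distinct
patients, two per patient. After the encoder `f` and projection head `g`,
the per-pair loss on projections `z` is the normalized temperature-scaled
cross entropy (NT-Xent)

    ℓ(i, j) = −log exp(sim(z_i, z_j)/τ) / Σ_{k≠i} exp(sim(z_i, z_k)/τ),

with `sim` the cosine similarity and `τ = 0.1`. The batch loss is the
**asymmetric** sum `Σ_p ℓ(p1, p2)`: one anchor per patient. The SimCLR
literature usually sums both directions; `LossConfig(symmetric=True)`
provides that convention, but the default follows the asymmetric printed
form. With Adam the two differ only by a gradient scale and the anchor
weighting, and both are exercised by the oracle tests.

Numerics: the softmax is log-sum-exp stabilized (at `τ = 0.1` exponents
reach ±10; smaller temperature sweeps must not overflow), and projection
norms are floored at `1e-12` before normalization so a ReLU head that
momentarily emits a zero vector degrades gracefully instead of aborting a
training run. The standalone `cosine_similarity` utility, by contrast,
raises on zero vectors — an undefined quantity in an analysis context.

## 2. Architecture

The encoder follows the residual 1-D convolutional template common in
12-lead ECG classification: conv/BN/ReLU/max-pool stem, residual blocks
(two conv/BN stages, additive skip with a strided 1×1 convolution when
shape changes), then global average pooling over time. The full-size
instance uses kernel width 16 everywhere, stages (64, 128, 196, 256, 320)
with downsampling 4 per block, and emits a 320-dimensional `h` from a
4,096 × 12 input. The block-internal details (block count, per-stage
widths, skip construction) are a faithful-in-spirit default rather than a
layer-for-layer port of any published checkpoint; every element is
configurable, and build-time validation rejects input lengths that do not
divide through the downsampling chain.

The projection head is Dense(320) → ReLU → Dense(320) with no final
activation; it exists only during pre-training. Downstream consumers
always read `h`, never `z`.

There is no autodiff backend: all layers implement explicit backward
passes (`pclr._nn`), each validated against central finite differences to
~1e-9 relative error. Batch-norm uses batch statistics in training and
exponential running statistics (momentum 0.9) at inference; determinism
holds per-process for a fixed seed and thread count.

## 3. Pair sampling

Patients with one record are removed (they carry no positive pair). Per
epoch, eligible patients are permuted with a `(seed, epoch)`-keyed
generator and chunked into batches of `n_patients_per_batch` (default
512, i.e. 1,024 ECGs); the trailing incomplete chunk is dropped to keep
the exact `2N` structure. Within a batch each patient contributes exactly
two records drawn uniformly without replacement — uniform over unordered
pairs, ignoring acquisition time and intervening health change. Patients
are sampled without replacement across an epoch (each appears in at most
one batch); whether the original procedure resampled patients within an
epoch is unknowable, and the without-replacement choice gives clean
epoch-coverage semantics.

## 4. Optimization

Adam with conventional moments (β₁ = 0.9, β₂ = 0.999). The learning rate
is decayed once per epoch along a half-period cosine realized as
`lr(t) = lr₀ (1 + cos(π t/T))/2`, which starts at `lr₀` (default 0.1) and
reaches exactly 0 at `t = T` (default 50); epochs past the period clamp
to the final value and log a warning. A quarter-period variant is
available behind `TrainConfig(schedule=...)`. The train/validation split
is by patient (default 90/10) — never by record, so checkpoint selection
cannot leak identity — and the returned model is the epoch with the best
validation loss.

The from-scratch baseline trains the same encoder plus a linear head
(2-way softmax with cross entropy for classification; single output with
MSE for regression) over a 3 × 3 grid of learning rate {1e-2, 1e-3, 1e-4}
× conv-dropout {0, 0.1, 0.2}, each cell early-stopped after 5
non-improving validation epochs with its best checkpoint restored; the
cell with the lowest validation loss wins. Batch size (default 64) and
epoch cap are desk-scale choices documented in `ScratchConfig`.

## 5. Preprocessing contract

Each lead's integer microvolt samples are divided by 1,000 and linearly
interpolated from native length `L` onto 4,096 points at source positions
`k (L−1)/4095` — endpoint-inclusive, so the first and last samples are
preserved exactly and a 4,096-sample lead passes through untouched (up to
scaling). Columns follow the fixed order I, II, III, AVR, AVL, AVF,
V1–V6; output is float32. Deliberately absent: filtering, detrending,
artifact removal — the method is meant to see routine-quality signals.
Whether the original pipeline's interpolation was endpoint-inclusive is
not documented anywhere we could verify; the choice here was made for
testability and is asserted, not inferred.

## 6. Linear evaluation

Features are z-scored per column with statistics computed on training
rows only; holdout tables are always normalized with the stored training
statistics (a leakage test asserts that corrupting holdout rows cannot
change them). Constant columns get a standard-deviation floor of 1e-12,
logged. The penalty grid is 10 values log-evenly spaced over
[1e-6, 1e5] (consecutive ratio `10^(11/9) ≈ 16.68`, both endpoints
included); 4-fold seeded cross-validation scores each penalty with the
task metric (positive-class f1 or r²), ties break toward less
regularization, and the winner is refit on all training rows. For
logistic probes the grid value λ enters scikit-learn as `C = 1/λ`, so
both probe types share the grid's semantics. Holdout results report the
point estimate ± one SD over seeded bootstrap resamples (default 1,000,
same size as the holdout, with replacement); classification resamples
whose truth collapses to a single class are redrawn and counted. Model
comparison uses *paired* bootstrap: all models are scored on shared
resamples, the best point estimate is flagged, and a competitor ties if
the 2.5–97.5% interval of the paired difference includes zero.

The f1 convention is positive-class f1 (class 1); for the balanced
sex-like task the designated positive class is configurable
(`positive_class`). Macro/micro alternatives were not implemented because
all bundled tasks are binary.

## 7. The synthetic world

The generator emulates exactly the structure the method exploits, and no
more. Each patient draws once: a per-wave (P, Q, R, S, T) amplitude
offset (sd = 15% of the base amplitude) and width multiplier (lognormal,
sd 0.08), an R-amplitude scale (lognormal, sd 0.3), a sex-like binary
attribute, an AF propensity (zero for 80% of patients, else 0.3–1.0), and
a baseline heart rate (60–85 bpm). Waves are Gaussians on a 3-component
dipole projected to 12 correlated leads through a fixed full-rank 12 × 3
matrix — analytically controllable, so label realizability is provable,
at the cost of physiological fidelity (no conduction dynamics, no
respiratory modulation, no electrode placement variation).

Labels:

- **hypertrophy-like** (patient-stable): deterministically
  `amplitude_scale > 1.25` (~22% prevalence), mirroring a voltage
  criterion; linearly recoverable from clean-template R amplitudes
  (AUC > 0.95, asserted).
- **sex-like** (patient-stable): T amplitude ×1.15/×0.85, QRS width
  ×1.03/×0.97, +3 bpm. Chosen at physiological scale: strong enough that
  the full signal supports f1 ≈ 0.8 (the field's reported range for ECG
  sex classification), weak enough that per-patient morphology offsets
  make a single record genuinely ambiguous. An early draft used ±50% T
  amplitude, which let a small supervised network solve the task from 48
  labels — destroying the label-scarce regime the package exists to
  study — and was corrected once, before the test suite was frozen.
- **age** (per-record): baseline age plus elapsed days/365.25.
- **AF-like** (per-record): active with the patient's propensity; when
  active, P-wave amplitude is zero and RR intervals are lognormal with
  CV 0.25, redrawn until the realized CV ≥ 0.15.

Visits: 2–4 per patient, gaps uniform in [30, 500] days (mean ≈ 265,
matching the order of real inter-ECG gaps); heart-rate jitter sd 5 bpm;
white noise 0.05–0.25 mV and sinusoidal baseline wander 0.05–0.40 mV at
0.15–0.35 Hz — routine-recording artifact levels, applied per lead after
projection. Amplitudes are emitted as int16 microvolts (saturating),
10 s at 250 or 500 Hz. Rhythmic records are evaluated on wrapped phase,
so a noiseless 60 bpm / 250 Hz record is *exactly* periodic — a testable
contract. Generation is bit-exact reproducible from the seed via
per-patient spawned generators.

What a green test does **not** establish: anything about real ECGs. The
synthetic world has no pathology beyond the four probed labels, no
pediatric range, no lead misplacement, and its noise is stationary
Gaussian plus a single sinusoid.

## 8. Desk-scale experiment design

The reference experiments (`pclr.experiments`) shrink the method, not the
contract:

- model input 1,024 samples (102.4 Hz): the smallest grid that keeps the
  QRS resolved (R-wave σ ≈ 18 ms ≈ 2 samples); 256 samples alias it away.
  The 4,096-sample preprocessing contract is unchanged — tensors are
  resampled only as model input for the tiny instance.
- tiny encoder: kernel 8, stages (8, 16, 32), 32-dim representation
  (~17k parameters). A 16-dim head was too narrow: once identity
  structure fills the space, patient-stable morphology axes (T amplitude)
  were measurably not linearly readable.
- pre-training: 400 patients, 10 epochs, 64-patient batches, initial lr
  0.01. The full-size 0.1 start pairs with 1,024-ECG batches; at this
  parameter count it diverges. 400 patients is the observed knee below
  which the T-amplitude axis fails to enter the representation (linear
  read-out r² < 0 at 200 patients vs ≈ 0.43 at 400).

The mechanism-recovery experiment pre-trains on one cohort, then probes
sex-like on a disjoint 320-record cohort with 64 labels, comparing the
pre-trained probe, a random-encoder probe, and the from-scratch grid
baseline, across 5 seeds; the package's acceptance suite requires the
pre-trained probe to win in ≥ 4 of 5 (observed: 5/5) and same-patient
projection similarity to exceed cross-patient similarity on held-out
patients in every seed.

## 9. Known limitations

- Single-threaded NumPy: full-size pre-training is functional but slow;
  the full 3.2M-ECG regime is out of scope by design.
- Dropout interacts with the skip path only through the main branch;
  alternative placements were not explored.
- The scratch baseline's batch size and epoch cap are not grid-searched.
- `run_pipeline` caches on config hashes, not on file content hashes; a
  hand-edited artifact with an unchanged config will be reused.
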