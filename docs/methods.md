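# Methods

This note documents the models and procedures implemented in `fswolf`, the
choices made where the design was genuinely open, and what the synthetic
study conditions do and do not establish.

## Problem setting

The package classifies histology-style RGB texture images into two classes
(benign-like vs malignant-like) with a hybrid pipeline:

1. **Preprocessing** — resize to a fixed square side, optional Reinhard color
   transfer in LAB space, per-image z-scoring.
2. **Texture features** — multilevel 2-D fast discrete wavelet transform;
   four statistics per subband.
3. **Redundancy filtering** — greedy Pearson-correlation filter over feature
   columns.
4. **Wrapper feature selection and hyperparameter tuning** — an adaptive
   multi-objective grey wolf optimizer (AGWO) with a Pareto archive,
   hypercube grid and roulette leader election.
5. **Classifier** — a compact residual CNN whose output stage is a fuzzy
   scoring layer.

No external dataset is required: a synthetic generator emulates the two
texture classes with a controlled separability dial.

## Preprocessing

Images are resized with anti-aliased bilinear interpolation, optionally
Reinhard-normalized (per-channel LAB mean/std matched to a reference computed
from the training split's pooled pixels), and finally z-scored jointly over
all pixels and channels so each image has mean 0 and variance 1. Constant
images are rejected (the z-score is undefined); a constant LAB channel is
passed through the color transfer unscaled with a warning.

The correlation machinery implements the Pearson coefficient
r = S_XY/sqrt(S_XX·S_YY), the coefficient of determination
R² = 1 − SSE/S_YY, and the sample covariance with its Cauchy–Schwarz bound
|cov| ≤ s_x·s_y. The redundancy filter scans feature columns left to right
and drops a column iff its |r| with an already-kept column exceeds the
threshold (default 0.95); first-seen columns win, so the result is
deterministic and order-stable. The filter is applied to the wavelet feature
table (the only tabular object in the pipeline where pairwise correlation is
well defined), after extraction and before wrapper selection. Constant
columns have undefined correlation; they are kept and flagged.

## Wavelet features

The transform is the classical orthonormal fast DWT with **periodic
(wrap-around) boundary handling**. Analysis is correlation-form
(`a[k] = Σ_n h[n]·x[(2k+n) mod N]`), with the mother (highpass) filter the
quadrature mirror of the father (lowpass) filter: `g[n] = (−1)^n h[L−1−n]`.
The highpass taps sum to zero — the discrete admissibility condition — so
detail bands annihilate constants exactly. Synthesis is the adjoint
operator, which inverts the analysis exactly for any even length; odd
lengths are handled by one periodic pad sample, which keeps the round trip
exact. Filter taps come from PyWavelets (`haar`, `db2`, `db4`); the filter
bank itself is implemented in-package because the coefficient convention
(correlation form, periodic wrap) is part of the package's documented
contract; PyWavelets serves as an independent cross-check in the tests
(exact for Haar; for longer filters pywt uses a different decimation phase,
so only reconstruction/energy are comparable).

Per subband the feature vector carries mean |coeff|, standard deviation,
energy (mean squared coefficient) and the Shannon entropy of the 64-bin
normalized |coeff| histogram (0·log 0 := 0), giving (3J+1)×4 features for J
levels (default Haar, J=3). RGB is reduced to luminance with ITU-R 601
weights before decomposition. These four statistics are the standard
wavelet-texture set; the choice keeps the table small and every statistic
cheaply recomputable by brute force in tests.

## Grey wolf optimization

The single-objective core maintains a pack of wolves in a box search space.
Each iteration re-ranks the three best solutions (alpha, beta, delta) and
moves every wolf to the average of three randomized encircling steps

    D = |C∘X_leader − X|,  X' = X_leader − A∘D,
    A = 2a·r1 − a,  C = 2·r2,  r1, r2 ~ U[0,1] per dimension,

with the exploration scalar a = 2(1 − t/T) decaying linearly from 2 to 0.
Positions are clamped to the box after every update.

The adaptive multi-objective variant adds:

- a **Pareto archive** (capacity 100 by default) holding mutually
  non-dominated solutions; a candidate dominated by a member is rejected,
  members dominated by a candidate are removed;
- a **hypercube grid** over objective space (10 divisions per objective,
  bounds inflated 10% beyond the observed ranges, rebuilt when a candidate
  falls outside); on overflow one member is evicted uniformly at random from
  the most crowded cell;
- **roulette leader election**: a cell is chosen with probability
  proportional to c/N_i (occupancy N_i, constant c = 2 > 1), then a member
  uniformly within it; chosen members are excluded from subsequent draws so
  alpha, beta, delta are distinct whenever the archive holds ≥ 3 solutions
  (with fewer, leaders may repeat).

### Feature-selection front-end

Positions in [0,1]^d decode to masks by thresholding at tau = 0.5 (an
all-zero mask keeps the single largest coordinate). The two objectives,
both minimized, are the held-out error of a fixed cheap reference
classifier (logistic regression) under seeded stratified 5-fold
cross-validation of the training portion, and the selected-feature
fraction. The error objective adds the validation log-loss scaled by 1e-3 —
well below the 1/n error quantum — because the 0/1 error cannot order masks
once every borderline sample falls on the right side of the boundary, while
the margin-sensitive term still rewards features that tighten it. The final
mask is the archive member with the lowest error objective (ties: fewest
features, then lexicographically smallest mask). The reference classifier
is deliberately not the CNN so that wrapper selection runs at desk scale.

### Hyperparameter front-end

Positions in [0,1]^3 decode to learning rate (log-uniform over
[1e-4, 1e-2]), batch size ({32, 64, 128} by thirds) and weight decay
(log-uniform over [1e-6, 1e-2]). The pipeline tunes with a bi-objective run
(validation error, validation cross-entropy) over short proxy trainings,
warm-starting the pack with the incumbent configuration so the tuner never
regresses below the defaults as judged on validation, and takes the
lowest-error archive member. Tuning and feature selection are two separate
runs invoked by the pipeline. In the ablation, the two AGWO arms share one
tuning run per repeat, with proxies ranked by the crisp head: tuning
selects general optimization hyperparameters, not head-specific ones.

## FS-ResNet

The network is a small self-contained numpy CNN: three convolutions, one
cascaded residual block, global average pooling, and a fully connected head
emitting per-class energies E (negative logits; P = softmax(−E), computed
stably by subtracting the minimum energy). Default stages for 64×64 inputs:
5×5×8 stride 1, 3×3×12 stride 2, 3×3×16 stride 2, then a residual block of
two 3×3 convolutions with dense intra-block wiring (the second convolution
receives the block input concatenated with the first convolution's rectified
output), identity shortcut, and a second nonlinearity after the addition.
A 1×1 projection W_s replaces the identity when channel counts differ.

The stride-1 first stage matters: dyadic downsampling before the first
nonlinearity aliases exactly the high-frequency texture energy that
separates the classes once color normalization has equalized global
statistics.

Training is mini-batch Adam (defaults: lr 1e-3, batch 16, weight decay
1e-4, 25 epochs) with a step decay (×0.3 at 70%, ×0.1 at 90% of the
schedule) and per-epoch train/validation monitoring, in float32 by default
(`dtype`; float64 is available, e.g. for finite-difference checks).
Initialization, batch order and therefore the entire history are
determined by the seed. A NaN loss aborts with a diagnostic. Optionally
the parameters of the best validation epoch are restored at the end
(`restore_best`).

### Fuzzy scoring head

Classes are indexed 1..m. For class i and window extents a (benign-ward)
and b (malignant-ward), clipped to [1, m]:

- window centroid: V0 = Σ_{j∈window} j·P_j / Σ_{j∈window} P_j, the
  probability-weighted mean class index. (A variant that multiplies the
  whole window sum by the fixed index i reduces to V0 = i identically;
  the weighted mean is the only form that makes |i−V0| informative, and
  is the implemented one.)
- redistributed probability: P̃_i = (|i−V0| / (a+b)) · Σ_{j∈window} P_j.
  The window width a+b (not b−a, which can be zero or negative for valid
  extents) normalizes the centroid distance, guaranteeing
  0 ≤ |i−V0|/(a+b) < 1 strictly.
- reported errors: ε_i = y_i − P_i, ε̃_i = y_i − P̃_i, and their delta
  φ = P̃_i − P_i.

**Damping property.** φ ≤ 0 — the fuzzy modification shrinks the error
contribution — holds provably for symmetric unclipped windows when class i
carries the window maximum (|i−V0| ≤ P_i·a(a+1)/(2S) gives
φ ≤ ((a+1)/4 − 1)·P_i ≤ 0 for a = b ≤ 3), and unconditionally when the
whole window mass is at most P_i. It is **not** true for general
asymmetric or edge-clipped windows; property sweeps in the test suite
exhibit counterexamples, and the assertions are scoped to the regimes where
the claim is a theorem. The binary default (m=2, a=b=1) is always in the
symmetric regime.

**Training signal.** The output-layer error of the fuzzy head is the plain
error modulated per sample by the window-centroid distance of its true
class, normalized to unit maximum: dL/dz = (|i−V0|/max(a,b)) · (P − y); for
the binary head the factor is exactly 1 − P_true. A confidently correct
sample pulls V0 onto i and contributes a vanishing signal; a misclassified
or ambiguous sample keeps a full one — precisely the φ ≤ 0 damping regime.
Substituting the redistributed probability itself for P in the error (an
additive reading of the modification) makes the signal *grow* with
confidence (P̃_i → 0 as V0 → i, so ε̃_i → 1 for a confidently correct
sample); under any optimizer this diverges — we verified empirically that
every additive variant collapses training to chance accuracy through
runaway logits. The multiplicative form is therefore the operative training
signal; the reporting quantities (ε, ε̃, φ) keep their literal definitions.
Because early training has no confident samples to damp — and the
focal-style reweighting otherwise suppresses the emerging pattern on
marginal data — the modulation ramps in linearly over the first fifth of
the schedule (`fuzzy_warmup_frac`). Hidden layers backpropagate the
modulated signal unchanged, so the fuzzy and plain heads differ only in
the output-layer error term (a unit test forces the head error to the
plain formula and obtains bitwise-identical training).

**Memberships and thresholds.** After training, per-class Gaussian
membership curves are fitted over a scalar summary (projection of the
penultimate activation onto the class weight vector); spreads are floored
at 1e-3. A validation grid search may rescale spreads and move the
positive-class decision threshold, maximizing balanced accuracy with a
deterministic tie-break (larger spread, then lower threshold). Prediction
gates the positive call at the threshold (default 0.5); an exact tie falls
to the lower class index and is flagged uncertain. The continuous score
S̃ = V0 around the predicted class is a decimal-valued class index.

## Synthetic study conditions

The generator renders Poisson-placed elliptical blobs with
harmonic-perturbed boundaries on a tinted background plus additive white
noise. Class 0 is sparse, round and smooth; class 1 dense, irregular and
noisy. A separability dial s ∈ [0,1] scales the gap of every class
parameter around a common midpoint; s = 0 is an exact null (identical
distributions), s = 1 the maximal gap. Defaults: side 64 (224 supported),
pixel noise sd 0.02, 100 images per class. The parameter gap is carried by
blob density (4↔18 per 10⁴ px²), radius (4.1–6.7 ↔ 2.3–4.3 px),
irregularity (0 ↔ 0.9), noise amplitude (0.01 ↔ 0.08) and a small
chromatic tint shift, so the contrast shows up in wavelet-band energies —
the feature family the pipeline extracts.

The tabular generator plants class-informative Gaussian columns (shift =
effect size, default 3), pure-noise columns, and optional redundant copies
(source + Gaussian noise) for the correlation filter.

What passing these conditions shows: the pipeline recovers a strong planted
texture signal, invents none under the exact null, and the optimizer
recovers planted informative features. What it does not show: performance
on real stained tissue — the cartoon blobs have no nuclei morphology,
staining physics, magnification variation or label noise.

## Evaluation protocol

Stratified seeded 60/20/20 train/validation/test splits. Metrics: precision,
recall, F1, accuracy (the standard (TP+TN)/total ratio), and
ROC-AUC via the tie-adjusted Mann–Whitney rank statistic. Undefined ratios
are reported as null with a flag, never as zero. Model comparison is
normality-gated: Shapiro–Wilk on the paired differences chooses the paired
t test (p > 0.05) or the Wilcoxon signed-rank test; constant differences
fall back to an exact sign test, flagged. Hyperparameter grid search uses
stratified 5-fold cross-validation with a deterministic tie-break (lower
learning rate, then smaller batch).

The four-arm ablation (baseline / fuzzy-only / AGWO-only / full) shares
data, splits and seeds within each repeat; arms differ from the baseline
only in documented switches (fuzzy head on/off, AGWO hyperparameter tuning
and feature selection on/off). Per-arm accuracy vectors across repeats feed
the significance machinery.

## Numerical choices and degenerate inputs

- Correlations clamp to [−1, 1]; zero-variance inputs raise.
- The window centroid clamps to the clipped window to guard float
  round-off at the edges.
- Softmax subtracts the minimum energy before exponentiation.
- Archive dominance uses exact tuple comparison; equal-fitness candidates
  are rejected as duplicates.
- All randomness flows from `numpy.random.default_rng` seeded explicitly;
  artifacts contain no timestamps, so identical configurations reproduce
  byte-identical outputs.

## Problem sizes

The default test suite and the acceptance script run at desk scale, chosen
so the full suite completes in minutes on one CPU: 64×64 images, 100 per
class for the end-to-end runs (the no-signal check is asserted on the
median over five seeds, since a single 40-sample test split carries
binomial noise of sd ≈ 0.08); 10 seeds at 20 wolves × 40 iterations for
feature-selection recovery; 30 wolves × 300 iterations for the sphere
benchmark. The ablation runs 5 repeats at 40 images per class, side 48,
separability 0.5, pixel noise 0.08 and no color transfer (the generator
models a single staining protocol, and at half separability the transfer
removes most of the class signal at this scale, which would leave every
arm at chance and make the directional comparison vacuous), with a shared
3-wolf × 1-iteration tuning budget at 10-epoch proxy fidelity.

## Known limitations

- The fuzzy damping claim fails for asymmetric/clipped windows (see above);
  the head is used in its symmetric binary regime.
- Reinhard transfer toward a pooled reference removes global color/contrast
  cues; on the synthetic generator this is the intended hard setting (the
  texture signal remains), but it also means color-borne class differences
  do not contribute.
- The CNN is desk-scale by design; no transfer learning, no GPU path, no
  deep (152-layer) configuration.
- Curvelets and undecimated transforms are out of scope; the "wrapping"
  reading of the transform is periodic boundary handling.
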