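# Methods

## Federated PCA by scatter-matrix aggregation

Each site's cases are masked 3D volumes flattened (C order, axis 0 slowest)
into vectors of length `d = resolution³`. Masking zeroes voxels rather than
cropping them so `d` is identical across sites — a requirement for the
scatter matrices to be linearly aggregable. A site streams its data in
batches of `b` rows and ships only `(N_i, μ_i, S_i)`.

Two scatter conventions are implemented:

- **pooled_exact (default).** The site accumulates `Σ xxᵀ` and subtracts
  `N_i μ_i μ_iᵀ`, giving the scatter about the site mean; the server adds the
  between-site correction `Σ N_i (μ_i − μ)(μ_i − μ)ᵀ`. The result is
  *identical* to the scatter of the pooled data about the pooled mean, for
  any partition into sites and any batch sizes. This is the only convention
  under which "batch size does not affect the components" holds, and the
  package treats that invariance as the defining contract (it is enforced to
  1e-8 in the test suite against a centralized oracle).
- **paper_literal.** Each batch contributes `(B − μ_B)ᵀ(B − μ_B)` with no
  cross-batch or cross-site mean corrections. This drops the between-batch
  mean variance — on the two-batch example {0,2},{4,6} it yields S = 4
  instead of the pooled 20 — and is therefore batch-size dependent. It is
  kept behind a flag for fidelity experiments only.

The global mean is the sample-size-weighted mean of site means — the unique
choice consistent with pooled centering. `Cov = S / N_total` (population
normalization, matching the `S/N` definition of the aggregate) is
eigendecomposed densely (`scipy.linalg.eigh`, top-k subset); this is
appropriate at the desk scales targeted here (d ≤ ~4000). Determinism: each
component's sign is fixed so its largest-magnitude entry is positive;
eigenvalue ties are resolved by the decomposition's stable ordering. Note
`explained_variance_` in the scikit-learn wrapper therefore differs from
`sklearn.decomposition.PCA` by the factor `(n−1)/n`.

Default `k = 10`: at that dimension the synthetic study retains roughly
two-thirds of total variance while the downstream classifier converges in
tens of rounds; the `pc_sweep` utility exposes the k-versus-stop-round
trade-off. Sites can join in **inference-only mode**: projection
`(X − μ) W` needs no site statistics, so a held-out center (or one too small
for a stable scatter estimate) can use the basis without contributing to it.

No per-feature standardization precedes the PCA: the aggregation operates on
raw gray values, and centering is the only harmonization applied before
projection. (Standardized features appear only in the raw-space arm of the
centroid-distance diagnostic, using pooled statistics with zero-variance
features left centered.)

## Client model and loss

The classifier is Dense(128)+BatchNorm+ReLU → Dense(64)+BatchNorm+ReLU →
Dropout(0.5) → Dense(2)+softmax, written directly on numpy (Glorot-uniform
init, manual backprop, Adam). Trainable parameters for input dimension k:
`128k + 128 + 256 + 8256 + 128 + 130` (10,178 at k = 10); batch-norm betas
and gammas are trainable, and the running means/variances — though not
trained — are part of the exchanged parameter vector, because the averaged
global model is unusable at inference without them.

The per-sample loss with `p` the positive-class softmax probability and
`y ∈ {0,1}`:

```
L = L_CE(y, p) + λ_FN · y (1 − p) + λ_FP · (1 − y) p + λ_AUC · (p − y)²
```

λ = (2, 1, 0.1) by default: the false-negative penalty is twice the
false-positive penalty, reflecting the clinical asymmetry in a
cancer-detection task with ~28% prevalence; the squared-error term is a
small Brier-style regularizer that pushes probabilities toward the correct
extreme. `p` is clipped to [1e-7, 1 − 1e-7] inside the logarithms (and the
gradient uses the same clipping). With λ = 0 the loss is exactly weighted
cross-entropy. Balanced inverse-frequency class weights
`w_c = n / (2 n_c)` multiply the per-sample loss; they satisfy
`Σ_c w_c n_c = n`.

Per-round local training uses Adam at the round-indexed rate
`lr(t) = lr0 · decay_rate^⌊t/decay_steps⌋` (staircase; defaults lr0 = 1e-3,
decay 0.9 every 25 rounds — the decay cadence is part of the protocol, the
base rate and factor are tunable and deliberately conservative). A
continuous-exponent variant sits behind `staircase=False`. Each fit
early-stops when validation loss has not improved for 5 consecutive epochs
(max 50 epochs per round), restores the best-validation weights, and reports
that state's loss and accuracy — so the reported validation loss never
exceeds the best seen. The optimizer state is reset each round
(re-compilation semantics). Validation metrics use inference mode: batch-norm
running statistics, no dropout, class-weighted custom loss.

An optional **warm start** runs one plain cross-entropy local fit before the
federation begins. By default it also seeds the client's first round (round
1 trains from the warm-started weights rather than the broadcast); setting
`warm_start_contributes=False` makes it purely diagnostic. Both paths exist
because the pre-loop fit's role in the first aggregate is a genuinely open
protocol choice.

Determinism contract: for a fixed seed on one platform the whole run is
reproducible (exactly for the PCA numbers; to floating-point accumulation
order for training). Bit-exactness across BLAS builds is not promised.

## Server control

Aggregation weights are `n_k · a_k` (training size × current-round
validation accuracy, no smoothing); the aggregate is a convex combination,
so every coordinate stays within the clients' range. If every accuracy is
zero — legitimate in early rounds on tiny sites — the server logs a warning
and falls back to sample weighting instead of dividing by zero.

The stopping controller keeps `(L_best, wait c)`: a loss below
`L_best − δ` updates the best and resets `c`; a loss within `L_best + ε`
resets `c` *without* updating the best; anything else increments `c`; the
loop stops when `c ≥ patience` and `t ≥ t_min`. The ε-branch is transcribed
deliberately: a loss hovering just above the best is treated as "still
converging" and never accumulates patience. This means a run whose loss
plateaus inside the ε-band will not stop until the band is exceeded —
an unusual but intentional reading of the controller. Defaults
`patience 10, ε = 1e-3, δ = 1e-4, t_min = 20, T = 200` are config-exposed
and recorded in every round log.

The federation is simulated in-process with sequential clients. The
exchange objects (parameter vectors with a shape manifest, center
statistics as HDF5) are exactly the wire payloads a networked deployment
would send; the privacy surface of the PCA step is the
`(center_id, N, μ, S, mode)` schema, which contains no per-case field (this
is asserted in the tests).

## Synthetic cohorts

The generator emulates a three-center study: sizes 800/350/350, positive
prevalences 0.295/0.311/0.228, with the third site held out entirely.
Positive counts are deterministic (`round(n · prevalence)`) so cohort tables
reproduce exactly; which cases are positive is randomized per seed.

Each case is built on a cubic grid (default resolution 12, d = 1728) with a
centered ellipsoidal "organ" mask (radius 0.8 of the half-width). Intensity
model per case: a case-level baseline drawn from
`N(intensity_mean, intensity_sd)` — shared by all voxels, emulating
per-acquisition gain — plus i.i.d. per-voxel noise `N(0, noise_sd²)`.
Site heterogeneity enters through `intensity_mean` (100/130/160 across the
default sites, the scanner-vendor analog). Positive cases receive one
ellipsoidal lesion blob (+50 gray values, radius ~0.35 of the mask radius)
centered uniformly at random among in-mask voxels. Defaults
`intensity_sd = 8`, `noise_sd = 10` were chosen once as a plausible
contrast-to-noise regime in which the lesion is learnable but not trivial;
they are part of the study conditions, not tuning knobs.

What this emulates — and what it does not: the generator reproduces the
*statistical* structure the method targets (site-level intensity shift,
prevalence imbalance, a localized positive-class signal inside an organ
mask, uniform feature dimension). It does not attempt MRI physics, bias
fields, anatomy, multi-sequence inputs, or realistic lesion morphology.
Passing tests therefore demonstrate the correctness and the qualitative
behavior of the machinery (harmonization, convergence, early stopping) on
non-IID data — not clinical performance on real prostate MRI, where
absolute metrics would differ.

Train/validation splits are stratified by label with `round(n · fraction)`
totals (the larger class absorbs the rounding remainder), matching
640/160 and 280/70 at the default sizes.

## Experiment arms

- `adaptive` — FIPCA features, accuracy-weighted aggregation, server stopper.
- `fedavg_fixed` — raw flattened voxel features, sample-weighted FedAvg,
  exactly T rounds (the standard baseline; client-side settings identical).
- `fipca_only` — FIPCA features, plain FedAvg, fixed rounds.
- `earlystop_only` — raw features, plain FedAvg plus the server stopper.
- `central` — all training-site data pooled into one locally trained model
  (same architecture/loss/client early stopping, max 200 epochs, no
  federation loop): the privacy-free upper-bound comparator.

All arms share the FIPCA basis fit on training sites only; the test site is
projected inference-only, and its labels live in a vault object whose access
counter is checked before evaluation (leakage guard). The baseline arm
disables only the server stopper — whether the client-side protocol should
also change is unknowable from the protocol description, so it is held
fixed for a controlled comparison.

The energy figure is the `power × time` product applied to each arm's
measured simulation wall-time at the configured device power bounds
(20–30 W). It is an arithmetic analog for comparing arms, not a hardware
measurement.

## Numerical and degenerate-input choices

- Scatter symmetry is enforced by averaging `(S + Sᵀ)/2` after streaming
  accumulation; asymmetry beyond 1e-8 (relative) on input raises.
- `k = 0`, `k > d`, empty data, single-class sites (for class weights,
  stratified splits, AUC), zero total variance, and non-finite losses all
  raise with named-field messages rather than propagating NaNs.
- A single-row site legitimately reports a zero scatter matrix.
- Bootstrap CIs: non-stratified case resampling, percentile interval,
  single-class resamples redrawn (cap 100), 1000 resamples by default.
- The relative centroid distance is
  `‖μ_a − μ_b‖₂ / sqrt((v̄_a + v̄_b)/2)` with `v̄` the mean per-feature
  population variance; no convention-free definition exists, so the same
  statistic is used on both sides of the before/after comparison, making
  the reported *reduction* insensitive to the normalization constant.
- Sensitivity/specificity use a 0.5 operating threshold (config-exposed).

## Known limitations

- Dense d×d scatter matrices bound the feasible resolution (memory is
  O(d²)); the implementation targets desk-scale grids, not full-resolution
  MRI.
- The linear basis cannot capture nonlinear site effects; kernel or
  autoencoder variants are out of scope.
- No asynchronous clients, stragglers, secure aggregation, differential
  privacy, or FedProx/SCAFFOLD-style drift corrections.
- The DeLong AUC-comparison test is not reimplemented; report hooks accept
  externally computed p-values.
- Accuracy-weighted aggregation uses raw current-round accuracies; with
  very heterogeneous validation sets this can over-weight lucky small
  clients (no smoothing is applied, by design fidelity).
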