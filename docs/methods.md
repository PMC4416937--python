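# Methods

## Model

An epoch is a zero-mean matrix `X ∈ ℝ^{N×T}` with label in `1..C`.
The spatial filter network maps it to an output vector `Φ ∈ (−1,1)^O`:

1. **Spatial filter layer.** Each of the M columns `w_m` of
   `W ∈ ℝ^{N×M}` is applied through its unit-norm version,
   `y_m(t) = (w_m/‖w_m‖)ᵀ x(t)`. Normalization makes the objective
   invariant to positive rescaling of any column — the optimizer
   effectively moves on the unit hypersphere — and consequently the
   error gradient is exactly orthogonal to each `w_m`, and the
   Gauss–Newton matrix `JᵀJ` is structurally rank-deficient by one per
   filter (the damping term `μI` handles this; no special casing is
   needed).
2. **Features.** `f_m = log((1/T) Σ_t y_m(t)²)`, the log band power,
   with the population (1/T) variance convention and the mean of `y`
   taken as exactly zero. This is legitimate because the container
   enforces per-channel zero mean (tolerance 1e-8 relative to the
   channel standard deviation); the preprocessing chain re-centers
   defensively after cropping.
3. **Classifier layer.** `z = Vᵀf + b`, `Φ = tanh(z)`. Binary
   problems use O = 1 with decision threshold 0; multiclass uses O = C
   with argmax (a linear machine — no ambiguous region), ties broken to
   the lowest class index.

Targets are `D_o = +1` for the true class and `−1` elsewhere (binary: a
scalar ±1), matching the tanh range and the zero threshold. Because
`tanh` never reaches ±1, the per-epoch error `E = ½‖Φ − D‖²` cannot be
exactly zero; training stops at a mean-error threshold instead. Target
shrinking (e.g. ±0.9) is deliberately not the default.

## Training

**Backpropagation** presents one epoch at a time and applies
`θ ← θ − μ ∂E/∂θ` to W, V and b with learning rate μ (default 1e-3).
Presentation order is sequential, optionally shuffled per pass by the
seeded generator. The iteration cap counts epoch presentations; the
trace records one mean error per full pass, and convergence is declared
when the mean error over the last pass reaches `emin`.

**Levenberg–Marquardt** evaluates the whole training set per iteration,
stacking residuals `e = D − Φ` epoch-major/output-minor and their
Jacobian `J` (rows = error components, columns = the flat weight vector
`q` = W row-major, then V row-major, then b). The update is
`q ← q − (JᵀJ + μI)⁻¹ Jᵀe`; note `Jᵀe` equals the error gradient
`∂E/∂q` exactly (an identity the tests verify), so large damping turns
the step into a short steepest-descent move, while small damping gives
the (pseudoinverse) Gauss–Newton step. Per iteration: evaluate; if the
mean error decreased versus the last accepted iteration, accept and set
`μ ← μ/β`; otherwise revert the weights to the last accepted state and
set `μ ← μβ`; then solve the next step from the accepted state. The
first iteration always accepts, the accepted-error sequence is
non-increasing, and the trainer returns the last *accepted* weights
(the final proposed step is never returned unevaluated). The identity
in `JᵀJ + μI` is the plain identity matrix, not Marquardt's diagonal
scaling.

The stopping statistic for both trainers is the mean per-epoch error
`(1/K) Σ_k E_k`, so `emin` does not depend on the training-set size K.
Defaults (`emin = 0.1`, `maxitr = 1000`) suit preprocessed EEG at
realistic epoch counts; the toy experiments below use `emin = 1e-3` and
their own budgets. Initial weights are i.i.d. Normal(0, 0.1²).

## CSP baseline

Per-epoch covariances are trace-normalized (`R = XXᵀ/tr(XXᵀ)`), making
every downstream quantity invariant to global amplitude scaling. The
Rayleigh problem is solved as the generalized *symmetric* eigenproblem
`R̄₁w = λR̄₂w` rather than forming `R̄₂⁻¹R̄₁` — same spectrum, better
conditioning — with a ridge `ε = 1e-10·tr(R̄₂)/N` added only when `R̄₂`
is near-singular. Returned filters are unit-norm with the sign fixed by
making the largest-magnitude component positive (signs do not affect
band-power features). For a pair bank the 2m features normalize by the
sum over all 2m row variances; for a one-versus-rest bank the sum runs
over all C·m rows — the consistent choice, since the feature identity
`Σ_k exp(f_k) = 1` then holds for any bank. LDA uses the pooled
within-class covariance without shrinkage, empirical priors, and one
linear discriminant per class with argmax.

## Preprocessing

Channel subset (motor-cortex electrodes), Butterworth band-pass 8–30 Hz
of order 5, cue-relative crop `[cue + round(0.5·fs), cue + round(2.0·fs))`
(150 samples at 100 Hz), then per-channel mean subtraction. Filtering is
**causal** by default — forward-only filtering matches an online BCI and
the stated filter order — with zero-phase two-pass filtering behind
`zero_phase=True`; initial conditions are zero (no padding), so tests
discard the initial transient. Rejected trials are excluded at read
time by label masking.

## Synthetic data

The toy generator draws, per epoch, a uniform class label and T i.i.d.
samples from `N(0, Σ_label)`, then subtracts the realized per-channel
mean so the zero-mean invariant holds exactly rather than only in
expectation. The presets use N = 2, T = 100, K = 100:

* `two_class`: covariance ellipses with axes (2.0, 0.2) oriented at
  +45° and −45°. Both classes have identical marginal channel variances
  and opposite channel correlation, so no channel is informative alone
  but a ±45° filter pair separates the classes completely.
* `four_class`: ellipses at 0°, 90°, 45°, 135° with axis pairs
  (4, 0.4), (4, 0.4), (1, 0.1), (10, 1) — distinguishable in 2-D
  log-variance space by orientation and total power.

What this emulates is exactly the covariance structure spatial
filtering exploits; what it does **not** emulate is everything else
about EEG — 1/f spectra, artifacts, epoch-to-epoch covariance drift
(non-stationarity), volume-conduction forward models. Passing tests on
this generator therefore validate the optimization machinery and the
covariance-driven separability mechanism, not robustness on real
recordings.

## Observed behavior at the default study conditions

On the `two_class` preset (ten seeds, identical initializations), both
trainers reach mean error ≤ 1e-3: Levenberg–Marquardt in 7–16
iterations, backpropagation in roughly 280–490 passes at μ = 1e-3 —
these are the numbers `scripts/acceptance.py` recomputes. Training
accuracy is 100% (the preset is separable by construction).

One comparison comes out the other way and is reported as measured: the
Fisher separation `tr(S_B)/tr(S_W)` of *trained* SFN features is
**lower** than that of CSP features on this toy data (medians ≈ 58–66
vs ≈ 77–82 depending on the draw). The reason is structural. With
clean, fixed per-class Gaussian covariances, the class-average
covariance CSP diagonalizes is a near-perfect sufficient statistic, and
a grid search over all unit-norm filter pairs shows CSP sits within a
few percent of the global separation optimum. The network, by contrast,
minimizes tanh classification error; once outputs saturate near the ±1
targets its gradients vanish and it has no incentive to push the
features further apart. The advertised separation advantage of jointly
trained filters arises on real EEG, where per-epoch covariances drift
and averaging degrades CSP — precisely the non-stationarity this
generator deliberately omits. The corresponding comparison test is kept
and fails on the toy conditions; it documents this limitation rather
than a defect of either implementation.

## Numerical choices and edge cases

* Analytic gradients and Jacobian rows are verified against central
  finite differences (step 1e-6, relative tolerance 1e-5); measured
  agreement is ~1e-9.
* Zero-variance projections and zero-norm filter columns raise
  immediately (a collapsed filter would otherwise produce −∞ features);
  non-finite training errors abort with a diagnostic rather than
  propagate NaNs.
* Quantiles in repeated-run summaries use linear interpolation so
  summaries are bit-reproducible.
* The Fisher criterion is the trace ratio; a determinant ratio was
  rejected because it degenerates at M = 2 with near-collinear
  features. Zero within-class scatter reports +inf with a warning.
* All randomness flows through `numpy.random.default_rng` seeds;
  identical seeds give bitwise-identical data sets, models and
  summaries.

## Scope

Epoch containers are plain text (delimited matrices plus a key=value
manifest); reading vendor EEG archives (EDF/GDF/MAT) is out of scope,
as are regularized CSP variants, artifact removal, topographic head
maps and multi-layer spatial filter stacks.
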