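# sfnet — spatial filter networks and CSP for motor-imagery EEG

`sfnet` classifies motor-imagery EEG epochs by *jointly* learning spatial
filters and a classifier, and ships the classical common spatial
patterns (CSP) pipeline it is usually compared against.

## The problem

In a motor-imagery brain–computer interface, a user imagines a movement
(left hand, right hand, foot, …) and the system must decode which one
from a multichannel EEG epoch `X ∈ ℝ^{N×T}` (N channels, T samples).
Volume conduction mixes cortical sources across electrodes, so the raw
channels are poorly discriminative; a *spatial filter* `w ∈ ℝ^N`
projects the epoch to a single time series `wᵀX` whose band power
(variance) carries the class information (event-related
desynchronization of sensorimotor rhythms).

**CSP** finds filters maximizing the Rayleigh quotient
`wᵀR̄₁w / wᵀR̄₂w` of the two class-average covariance matrices
`R̄_c` (each per-epoch covariance is trace-normalized,
`R = XXᵀ/tr(XXᵀ)`), solved as the generalized eigenproblem
`R̄₁w = λR̄₂w`. The bank keeps the m largest- and m smallest-eigenvalue
filters, features are `f_k = log(var_k / Σ_l var_l)`, and a linear
discriminant (LDA) classifies them. The one-versus-rest variant handles
C > 2 classes by maximizing each class's power against the summed power
of the rest.

**The spatial filter network (SFN)** replaces this two-stage pipeline by
a single trainable structure:

    y_m(t) = (w_m/‖w_m‖)ᵀ x(t)            spatial filter layer, unit-norm
    f_m    = log( (1/T) Σ_t y_m(t)² )      log-variance features
    Φ      = tanh(Vᵀ f + b)                classifier layer, Φ ∈ (−1,1)^O

trained to minimize the squared error `E = ½‖Φ − D‖²` against ±1
one-versus-rest targets D, either by per-epoch backpropagation or by
batch Levenberg–Marquardt (damped Gauss–Newton on the stacked residuals
`e = D − Φ`, update `q ← q − (JᵀJ + μI)⁻¹Jᵀe`, with the damping μ
divided by β after an error decrease and multiplied by β — with a
weight revert — after an increase). Because filters enter only through
`w_m/‖w_m‖`, the search lives on the unit hypersphere and every filter
is identified up to positive scale. Unlike CSP, which compresses each
class into one average covariance matrix, the network sees every
training epoch and optimizes classification error directly.

## Worked example

Synthetic 2-class epochs (2 channels × 100 samples, 100 epochs, one
fixed covariance per class — ellipses oriented at ±45° so that no single
channel separates the classes):

```
$ sfnet simulate --preset two_class --seed 3 --out toy
wrote toy
$ sfnet train-sfn --epochs toy --method lm --m 2 --emin 1e-3 \
      --maxitr 300 --seed 1 --model-out model.txt --trace-out trace.txt
converged	True
iterations	16
final mean error	0.000609074
$ sfnet classify --epochs toy --model model.txt
accuracy	1.0000
$ sfnet train-csp --epochs toy --m 1 --bank-out bank.txt --lda-out lda.txt
training accuracy	1.0000
```

Levenberg–Marquardt reaches the target mean per-epoch error 10⁻³ in 16
iterations and classifies the training set perfectly; CSP with one
filter pair plus LDA does the same on this separable toy problem. The
trace file records the accepted mean error, the damping μ and revert
events per iteration. `sfnet gradcheck` verifies the analytic backward
equations against finite differences, and `sfnet compare --runs 30`
retrains from many seeds and reports accuracy quartiles (initialization
makes single runs stochastic).

The same commands apply to real recordings once they are converted to
the plain-text epoch container (`manifest.txt` plus one matrix file per
epoch; see `sfnet.epochs`); `sfnet preprocess` applies the standard
chain — motor-cortex channel subset, 8–30 Hz 5th-order Butterworth
band-pass, 0.5–2.0 s post-cue segment, per-channel mean removal.

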