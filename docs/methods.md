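# Methods

## The source-mixing model

`cohsim` simulates and analyzes inter-areal coherence that arises from
*source mixing*: the observed signal (e.g. an LFP) of a receiving brain
area is the linear superposition of its own oscillatory activity, the
weighted and delayed projections it receives from other areas, and
uncorrelated aperiodic background. No oscillatory coupling or phase
locking is assumed — all cross-areal correlation is carried by the
projection terms.

Each area's intrinsic activity is a pseudo-periodic AR(2) process

    x[t] = a1 x[t-1] + a2 x[t-2] + sigma eps[t],   eps ~ N(0, 1),

a damped harmonic oscillator under stochastic drive. Its complex root
modulus R = sqrt(-a2) sets spectral concentration and the peak sits at
omega_max = arccos(a1 (a2-1) / (4 a2)) radians per sample. The design
algebra (`ar2_design`) inverts these relations: given a peak frequency
and either R, a peak power, or a variance, it returns coefficients and
the drive scale. Where a closed-form inversion is not available
(modulus from a variance/peak-power pair), a bracketed Brent root find
on R in (0, 1) is used, verified by substitution to 1e-10.

A receiver filters every incoming projection through its *input
transfer function* before superposition:

* **flat** — all-pass; the receiver treats all input frequencies alike;
* **integrator** — first-order exponential moving average
  `x[n] = (1-alpha) x[n-1] + alpha u[n]`, a monotone low-pass with
  corner frequency `(fs/2pi) arccos(1 - alpha^2 / (2(1-alpha)))`;
* **resonator** — a causal AR(2) band-pass matched to the receiver's
  intrinsic spectrum, with its input gain scaled so the magnitude
  response peaks at exactly `g` at the resonant frequency.

For a feedforward pair with connectivity weight `w` and power ratio
`alpha(f) = S11_int / (S22_int + background)`, magnitude-squared
coherence has the closed logistic form

    C^2(f) = w^2 alpha |H|^2 / (w^2 alpha |H|^2 + 1).

When the resonator exactly matches the receiver's spectrum the
frequency dependence cancels and (absent background) coherence becomes
invariant to the receiver's power spectrum — the property the
matched-resonator sweep verifies.

**Explained Power** re-expresses coherence in the receiver's power
units, `E12 = C^2 S22 = |S12|^2 / S11`, and equals the transmitted
signal `w^2 S11 |H|^2` in the feedforward case. Derived measures:
corrected EP (`|S12|^2 / (S11 - S_baseline)`, for senders carrying
un-projected power), PEP (`E12 / integral(S22 df)`, the per-frequency
proportion of total explained variance), and the input-transfer-function
estimate (`E12 / S11 = w^2 |H|^2`). The Wiener identity
`integral(S22 C^2) df = Var - Var_residual` ties PEP to time-domain
prediction; an acausal least-squares FIR fit provides the independent
check.

## Reference simulation conditions

| parameter | default | note |
|---|---|---|
| sampling rate | 1000 Hz | all delays are integer samples |
| epoch length | 1000 samples | one taper segment per epoch |
| epochs / runs | 2500 / 15 | epochs are independent realizations |
| burn-in | 50,000 samples per epoch | discarded before epoching |
| pair weight w | 0.35 | delay 3 ms |
| sender peaks | 60–100 Hz | receiver fixed at 60 Hz |
| integrator cutoff | 100 Hz | |
| resonator gain g | 1.5 (pairs), 1.6 (triplet) | |
| triplet weights | w_ff = 0.12, w_fb = 0.06 | delay 3 ms |
| triplet senders | 62 and 66 Hz | mutually unconnected |
| oscillator peak power | 1 | in the two-sided spectral units |
| root modulus R | 0.97 | see below |
| background | f0 = 60 Hz, P = 1/3, amplitude^2 = 0.1 | see below |

Two oscillator parameters are package choices rather than externally
fixed quantities:

* **Root modulus R = 0.97.** At fs = 1000 Hz this gives a spectral
  full width at half maximum of roughly 10 Hz, typical of prominent
  visual-cortical gamma. It is also the sharpness needed for the
  triplet's 4 Hz sender spacing (62 vs 66 Hz) to produce coherence
  contrasts resolvable at the reference epoch counts; a much broader
  oscillator (R ≈ 0.95, FWHM ≈ 16 Hz) blurs the two senders together.
* **Background amplitude 0.1 (power).** The 1/f generator filters
  unit-variance white noise through an FIR filter whose magnitude is
  `(f0/f)^P` on the epoch FFT grid (DC forced to zero, kernel centered
  for a smooth off-grid response); the drive is scaled so the
  background power at f0 = 60 Hz sits one order of magnitude below the
  unit oscillation peak. A strong gamma rhythm rising ~10x above the
  aperiodic floor at its peak is physiologically reasonable, and it
  leaves the sweep orderings (integrator increasing, resonator
  decreasing) and the triplet contrasts clearly resolvable. Note that
  with filter magnitude `(f0/f)^P` the realized noise PSD falls as
  `f^(-2P)`.

### What the generator does and does not emulate

The generator reproduces stationary, linear, Gaussian dynamics:
pseudo-periodic rhythms of fixed peak frequency, linear projection with
fixed weight and delay, and power-law background that is neither
projected nor correlated across areas. It does not emulate
nonstationarity (frequency or amplitude drift, bursting),
cross-frequency or other nonlinear interactions, non-Gaussian noise,
conduction-delay dispersion, or measurement noise. Passing tests
therefore certify the measures' behavior under the linear
source-mixing assumptions, not robustness to those violations; on real
recordings the corrected-EP/ITF estimates additionally require a
high-SNR sender band and a credible projection-free baseline.

## Numerical and estimation choices

* **Spectral estimator.** One Hann taper per epoch, no within-epoch
  segmentation; PSD/CSD averaged across epochs (and across runs for
  run-averaged results), coherence formed from the averaged spectra.
  One-sided densities are normalized so `sum(psd) df` equals the
  windowed signal's variance in expectation; the analytic two-sided
  spectra convert to this scale by `2/fs`.
* **Epoch independence and seeding.** Every epoch is generated from a
  fresh drive realization after its own burn-in; each (run, node,
  epoch, role∈{drive, background}) tuple keys an independent
  `SeedSequence` substream of the base seed, so any sub-computation is
  reproducible in isolation.
* **Burn-in.** The protocol default discards 50,000 samples per epoch.
  The oscillator transient decays with time constant −1/ln R ≈ 33
  samples, so the test and acceptance protocols use a 5000-sample
  burn-in (~150 time constants) — statistically indistinguishable, and
  it keeps the suite's simulation volume proportionate.
* **Feedback recurrence.** The loop equations are not externally
  prescribed; by default a node in a loop projects its full oscillatory
  state (intrinsic plus filtered received inputs, never its
  background), which creates a genuine closed loop detectable by
  directed measures. Projecting intrinsic activity only is available
  via `project_received=False`. Loops are integrated sample by sample;
  acyclic graphs are resolved by vectorized filtering in topological
  order (the two paths agree to machine precision on acyclic graphs).
* **Resonator phase.** The resonator is applied as a causal recursion,
  not a zero-phase magnitude filter: it preserves causality, and the
  coherence magnitudes under study are phase-invariant.
* **FWHM validity band.** Corrected EP and the ITF estimate are only
  reported where the sender has power: the contiguous band where the
  sender PSD exceeds half its maximum, with linearly interpolated
  edges. Corrected-EP bins whose denominator `S11 - S_baseline` falls
  below 10% of `S11` are masked (the estimator can turn negative
  there); masks are carried explicitly, never encoded as zeros.
* **Peak summaries.** Peak coherence values are read from 5-bin
  moving-average-smoothed spectra restricted to 30–150 Hz; the
  background filter's zero DC response otherwise distorts unsmoothed
  full-grid maxima.
* **Granger–Geweke causality.** Nonparametric: the estimated 2×2
  spectral matrix (uniform grid, DC through Nyquist) is factorized
  into a causal, minimum-phase transfer function and innovation
  covariance by Wilson's iteration, then Geweke's log-ratio is formed
  per direction. Implementation details: initialization from the
  Cholesky factor of the zero-lag autocovariance; the plus operator
  keeps nonnegative lags with the zero-lag matrix split
  lower-triangularly and — essential on an even grid — the lag-N/2
  coefficient halved, since that bin aliases the +N/2 and −N/2
  coefficients of a Hermitian function (without the split the
  iteration stalls at a finite residual instead of converging
  quadratically). Convergence: relative change < 1e-8, at most 500
  iterations; non-positive-definite bins are diagonally loaded with a
  warning. The factorization is validated against a VAR(1) model whose
  transfer function and innovation covariance are known in closed
  form.
* **Bidirectional data.** Separating feedforward from feedback
  Explained Power is not attempted; EP computed on recordings with
  loops carries a `bidirectional` caveat flag.

## Problem sizes

The full reference protocol is 2500 epochs × 15 runs per condition;
the README example, the test suite and the acceptance script run the
same pipelines at reduced averaging — typically 2500 epochs × 2–8 runs for
identity/agreement checks, 500 epochs × 3 runs for the background
sweep orderings, with the 5000-sample burn-in throughout. Tolerances in
the tests are set to the estimator scatter expected at those sizes.
The statistically hardest identity check (Explained Power on the
frequency-matched 60 Hz pair, where coherence is lowest) uses the full
15-run averaging.

## Known limitations

* The recurrent (feedback) integrator is a per-sample Python/NumPy
  loop over time; it is the slowest path and scales linearly in epochs
  × samples.
* Nonparametric GGC inherits the known biases of the method: additive
  noise in the sender can reverse apparent directionality, and weak
  feedback (the 62 Hz sender's, at the reference weights) can fall
  below the estimator's detection floor at practical epoch counts.
* The corrected-EP baseline must come from a projection-free condition
  of the same sender; the package does not estimate baselines itself.
* Only pair and triplet topologies are validated end to end, though
  the engine accepts arbitrary small graphs.
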