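# cohsim

Simulation and analysis of inter-areal coherence under **source
mixing** — the hypothesis that coherence between two brain areas'
field potentials arises from linear superposition of the sender's
projected activity onto the receiver, not from oscillatory coupling.

The package is aimed at systems/computational neuroscientists who want
to (a) simulate coupled cortical areas as pseudo-periodic AR(2)
oscillators with controlled peak frequency, spectral sharpness and peak
power, connected by weighted, delayed projections filtered by the
receiver's input transfer function (all-pass, integrator low-pass, or
resonator band-pass), plus 1/f background; and (b) quantify the
resulting interactions with spectral coherence, **Explained Power** and
its relatives, and nonparametric Granger–Geweke causality.

## The model and measures

Each area's intrinsic rhythm is the AR(2) process
`x[t] = a1 x[t-1] + a2 x[t-2] + σ ε[t]` with complex roots of modulus
`R = sqrt(-a2)` and spectral peak `ω_max = arccos(a1(a2-1)/(4a2))`.
A feedforward pair observes

    x1 = x1_int + η1
    x2 = x2_int + w (h_input * x1_int)[t - τ] + η2

and its magnitude-squared coherence has the closed logistic form

    C²(f) = w² α(f) |H(f)|² / (w² α(f) |H(f)|² + 1),
    α(f) = S11_int(f) / (S22_int(f) + S_background(f)).

Coherence therefore moves with the *power ratio* between sender and
receiver — a frequency shift in the sender changes coherence without
any change in connectivity. The package's central measure re-expresses
coherence in power units:

    Explained Power  E12(f) = C²(f) S22(f) = |S12(f)|² / S11(f)
                            = w² S11(f) |H_input(f)|²   (feedforward),

with the Proportion of Explained Power `PEP = E12 / ∫S22 df` (fraction
of the receiver's total variance explained per frequency) and the
input-transfer-function estimate `E12 / S11 = w² |H_input|²`, which
reads the receiver's input filter off the data inside the sender's
FWHM band.

See `docs/methods.md` for assumptions, parameter defaults and
numerical choices.

## Worked example

```python
import numpy as np
from cohsim import (
    REDUCED_PROTOCOL, analytic_coherence, ar2_psd_density,
    compute_connectivity, estimate_spectra, frequency_response,
    make_pair_network, simulate_network,
)
from cohsim.spectral_estimation import band_peak

# 80 Hz sender -> 60 Hz integrator receiver (cutoff 100 Hz), w = 0.35,
# 3 ms delay, no background; 500 independent 1 s epochs
net = make_pair_network(80.0, "integrator", background=False,
                        protocol=REDUCED_PROTOCOL)
rec = simulate_network(net, run_index=0)
est = estimate_spectra(rec)

f = est.freqs
coh = est.pair_coherence2("sender", "receiver")
s11 = ar2_psd_density(net.node("sender").intrinsic, f)
s22 = ar2_psd_density(net.node("receiver").intrinsic, f)
h2 = np.abs(frequency_response(net.node("receiver").input_tf, f)) ** 2
pred = analytic_coherence(s11, s22, w=0.35, tf_mag2=h2)

fpk, cpk = band_peak(f, coh)
print(f"peak coherence {cpk:.3f} at {fpk:.0f} Hz "
      f"(closed form: {pred[int(fpk)]:.3f})")

res = compute_connectivity(est, "sender", "receiver")
lo, hi = res.validity_band
itf = res.itf_mag2_scaled
print(f"sender FWHM band: {lo:.1f}-{hi:.1f} Hz")
print(f"ITF estimate (median over band): {np.ma.median(itf):.4f} "
      f"vs w^2|H(80)|^2 = {0.35**2 * h2[80]:.4f}")
print(f"explained variance: {res.explained_variance_total:.4f} "
      f"of {np.sum(est.psd['receiver']) * est.df:.4f}")
```

Output:

```
peak coherence 0.640 at 81 Hz (closed form: 0.650)
sender FWHM band: 75.1-84.9 Hz
ITF estimate (median over band): 0.0758 vs w^2|H(80)|^2 = 0.0743
explained variance: 0.0024 of 0.0323
```

The estimated peak coherence matches the closed-form source-mixing
prediction, and the ITF estimate recovers the receiver's input filter
scaled by w² (0.0758 estimated vs 0.0743 analytic at 80 Hz): the
sender explains about 7% of the receiver's total variance,
concentrated in the sender's band.

Preset experiments (the sender-frequency sweeps with integrator or
resonator receivers, and the two-sender triplet with or without
feedback) are available from the command line:

```
cohsim run pair-integrator --seed 1 --out results   # reduced protocol
cohsim run triplet-feedback --full --seed 1 --out results
cohsim measures recording.h5 --pairs sender,receiver --ggc
cohsim compare results/a/measures.csv results/b/measures.csv
```

Each run writes tidy `spectra.csv` / `measures.csv` tables and a
provenance JSON; identical seeds reproduce the tables byte for byte.

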