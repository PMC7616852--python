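"""Additive 1/f-type background fluctuations.

Local field potentials ride on broadband aperiodic activity whose power
falls off with frequency.  The background generator filters white
Gaussian noise with a zero-phase FIR filter whose magnitude response is

    B(f) = (f0 / f)^P

on the FFT grid of one epoch (the FIR length equals the epoch length).  The DC bin is set to zero — the power law diverges
there — which also centers the noise.  With a unit-variance white
drive, the noise power spectrum is B(f)^2 = (f0 / f)^(2P) in the same
two-sided spectral units used for the oscillators
(:mod:`cohsim.ar2_design`), i.e. the background power equals the
oscillators' peak power (one) at the reference frequency f0.

The background is never projected between areas and is generated from
its own random substream, so it is uncorrelated with every intrinsic
oscillation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .ar2_design import ParameterDomainError

__all__ = ["BackgroundSpec", "one_over_f_filter", "generate_background", "background_power_spectrum"]


@dataclass(frozen=True)
class BackgroundSpec:
    """Power-law background specification.

    ``reference_freq_hz`` (f0) anchors the filter magnitude response at
    one; ``exponent_P`` is the power-law exponent of the filter
    magnitude (the noise PSD falls as f^(-2P)); ``n_taps`` is the FIR
    length and should equal the epoch length.  ``amplitude`` is the
    standard deviation of the white drive, so the background power
    spectrum at f0 equals amplitude^2 in the oscillators' spectral
    units (amplitude^2 = 0.1 puts the aperiodic floor one order of
    magnitude below a unit-peak-power oscillation at its peak).
    """

    reference_freq_hz: float = 60.0
    exponent_P: float = 1.0 / 3.0
    n_taps: int = 1000
    enabled: bool = True
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.reference_freq_hz <= 0.0:
            raise ParameterDomainError("reference_freq_hz must be > 0")
        if self.n_taps < 2:
            raise ParameterDomainError("n_taps must be >= 2")
        if self.amplitude < 0.0:
            raise ParameterDomainError("amplitude must be >= 0")

    def to_dict(self) -> dict:
        return {
            "reference_freq_hz": self.reference_freq_hz,
            "exponent_P": self.exponent_P,
            "n_taps": self.n_taps,
            "enabled": self.enabled,
            "amplitude": self.amplitude,
        }


def one_over_f_filter(spec: BackgroundSpec, sampling_rate_hz: float) -> np.ndarray:
    """Real FIR taps realizing the power-law magnitude response.

    Built by inverse-FFT of the Hermitian-symmetric target magnitude
    (f0 / |f|)^P on the length-``n_taps`` FFT grid; the magnitude
    response at f0 is exactly one when f0 lies on the grid.  The
    symmetric kernel is centered (linear phase): leaving it wrapped
    around the array edges would make the response ring between grid
    frequencies and flatten the realized spectral slope.
    """
    n = spec.n_taps
    freqs = np.fft.fftfreq(n, d=1.0 / sampling_rate_hz)
    mag = np.zeros(n)
    nz = freqs != 0.0
    mag[nz] = (spec.reference_freq_hz / np.abs(freqs[nz])) ** spec.exponent_P
    taps = np.fft.ifft(mag)
    # even real magnitude -> real symmetric taps; drop rounding residue
    return np.ascontiguousarray(np.fft.fftshift(taps.real))


def _filtered_noise(noise: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Linear convolution keeping only fully-overlapped (steady-state) samples."""
    n_taps = taps.shape[0]
    full = signal.fftconvolve(noise, taps[None, :] if noise.ndim == 2 else taps, axes=-1)
    start = n_taps - 1
    return full[..., start : start + noise.shape[-1] - n_taps + 1]


def generate_background(
    spec: BackgroundSpec,
    n_samples: int,
    sampling_rate_hz: float,
    rng_seed,
) -> np.ndarray:
    """One realization of the filtered background noise.

    White unit-variance Gaussian noise filtered by
    :func:`one_over_f_filter`; the FIR edge transient is absorbed by
    generating ``n_taps`` extra leading samples.  Disabled specs return
    zeros.  Deterministic given the seed.
    """
    if not spec.enabled:
        return np.zeros(n_samples)
    if n_samples < spec.n_taps:
        raise ValueError("n_samples must be >= n_taps")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    taps = one_over_f_filter(spec, sampling_rate_hz)
    noise = spec.amplitude * rng.standard_normal(n_samples + spec.n_taps - 1 + spec.n_taps)
    out = _filtered_noise(noise, taps)
    return out[..., -n_samples:]


def background_power_spectrum(spec: BackgroundSpec, freqs) -> np.ndarray:
    """Analytic background power spectrum (f0 / f)^(2P), two-sided units.

    Zero at DC, matching the filter construction.  Exact at epoch-grid
    frequencies; between grid points it is the smooth envelope of the
    FIR response.
    """
    freqs = np.asarray(freqs, dtype=float)
    out = np.zeros_like(freqs)
    nz = freqs != 0.0
    if spec.enabled:
        out[nz] = spec.amplitude**2 * (
            spec.reference_freq_hz / np.abs(freqs[nz])
        ) ** (2.0 * spec.exponent_P)
    return out
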