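"""Design and simulation of pseudo-periodic AR(2) oscillators.

A brain area's intrinsic rhythm is modelled as a damped harmonic
oscillator excited by white noise, i.e. the second-order autoregression

    x[t] = a1 x[t-1] + a2 x[t-2] + sigma eps[t],    eps ~ N(0, 1)

with complex characteristic roots.  The root modulus R = sqrt(-a2)
controls spectral concentration (R -> 1: near-sinusoidal; R -> 0: flat),
and the spectral peak sits at the angular frequency
omega_max = arccos(a1 (a2 - 1) / (4 a2)) radians per sample.

This module provides the forward design algebra: choose coefficients
from a desired peak frequency and modulus, set the drive scale sigma so
the spectral peak has a prescribed power, convert between modulus,
peak power and time-domain variance, and simulate realizations.

Spectral convention
-------------------
``analytic_psd`` returns the power spectrum in the two-sided
radians-per-sample convention

    S(omega) = sigma^2 / (1 + a1^2 + a2^2 - 2 a1 (1 - a2) cos omega
               - 2 a2 cos 2 omega)

for which Var[x] = (1/2pi) * integral_{-pi}^{pi} S(omega) d omega; a flat
spectrum of a white-noise process equals sigma^2 everywhere.  Multiply by
2 / fs to obtain a one-sided density in units^2 per Hz (see
:func:`cohsim.spectral_estimation.ar2_psd_density`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, signal

__all__ = [
    "AR2Spec",
    "ParameterDomainError",
    "InfeasibleTargetError",
    "coefficients_from_peak",
    "peak_frequency",
    "analytic_psd",
    "ar2_power_spectrum",
    "ar2_variance",
    "peak_power",
    "drive_std_for_peak_power",
    "process_variance",
    "variance_from_modulus",
    "solve_modulus",
    "simulate_ar2",
]


class ParameterDomainError(ValueError):
    """A parameter lies outside its mathematically valid domain."""


class InfeasibleTargetError(ValueError):
    """A requested target value cannot be reached by any valid parameter."""


def _peak_cosine(a1: float, a2: float) -> float:
    """cos(omega_max) for an AR(2); raises if no interior spectral peak."""
    if a2 >= 0.0 or a2 <= -1.0:
        raise ParameterDomainError(
            f"a2 must lie in (-1, 0) for a stationary complex-rooted AR(2); got {a2}"
        )
    if a1 * a1 + 4.0 * a2 >= 0.0:
        raise ParameterDomainError(
            f"real-rooted coefficients (a1^2 + 4 a2 = {a1 * a1 + 4 * a2:g} >= 0): "
            "no spectral peak"
        )
    c = a1 * (a2 - 1.0) / (4.0 * a2)
    if abs(c) >= 1.0:
        raise ParameterDomainError(
            f"|a1 (a2 - 1) / (4 a2)| = {abs(c):g} >= 1: no spectral peak"
        )
    return c


@dataclass(frozen=True)
class AR2Spec:
    """One area's intrinsic oscillator.

    Parameters
    ----------
    a1, a2
        AR coefficients.  Validity requires -1 < a2 < 0 (stationary
        complex roots together with a1^2 + 4 a2 < 0) and an interior
        spectral peak, |a1 (a2 - 1) / (4 a2)| < 1.
    peak_freq_hz
        Location of the spectral peak; must be consistent with (a1, a2)
        to 1e-9 relative error.
    sampling_rate_hz
        Samples per second.
    drive_std
        Standard deviation sigma of the white-noise drive (signal
        units).  ``None`` means "not yet chosen"; zero is allowed as a
        degenerate (silent) oscillator.
    """

    a1: float
    a2: float
    peak_freq_hz: float
    sampling_rate_hz: float
    drive_std: float | None = None

    def __post_init__(self) -> None:
        c = _peak_cosine(self.a1, self.a2)
        if not (0.0 < self.peak_freq_hz < self.sampling_rate_hz / 2.0):
            raise ParameterDomainError(
                f"peak_freq_hz={self.peak_freq_hz} outside (0, Nyquist="
                f"{self.sampling_rate_hz / 2.0})"
            )
        implied = self.sampling_rate_hz / (2.0 * math.pi) * math.acos(c)
        if abs(implied - self.peak_freq_hz) > 1e-9 * max(1.0, abs(implied)):
            raise ParameterDomainError(
                f"peak_freq_hz={self.peak_freq_hz} inconsistent with coefficients "
                f"(implied {implied!r})"
            )
        if self.drive_std is not None and self.drive_std < 0.0:
            raise ParameterDomainError("drive_std must be >= 0")

    @property
    def modulus_R(self) -> float:
        """Modulus of the complex characteristic roots, sqrt(-a2)."""
        return math.sqrt(-self.a2)

    @property
    def omega_max(self) -> float:
        """Peak frequency in radians per sample."""
        return 2.0 * math.pi * self.peak_freq_hz / self.sampling_rate_hz

    def with_drive_std(self, drive_std: float) -> "AR2Spec":
        return replace(self, drive_std=drive_std)

    def with_peak_power(self, target_peak_power: float) -> "AR2Spec":
        """Return a copy whose drive scale yields the given peak power."""
        sigma = drive_std_for_peak_power(self.a1, self.a2, target_peak_power)
        return replace(self, drive_std=sigma)

    def to_dict(self) -> dict:
        return {
            "a1": self.a1,
            "a2": self.a2,
            "peak_freq_hz": self.peak_freq_hz,
            "sampling_rate_hz": self.sampling_rate_hz,
            "drive_std": self.drive_std,
        }


def coefficients_from_peak(
    peak_freq_hz: float,
    modulus_R: float,
    sampling_rate_hz: float,
    drive_std: float | None = None,
) -> AR2Spec:
    """AR(2) coefficients with a prescribed spectral peak and root modulus.

    Inverts the peak-frequency relation: a2 = -R^2 and
    a1 = 4 a2 cos(omega_max) / (a2 - 1), omega_max = 2 pi f / fs.
    """
    if not (0.0 < modulus_R < 1.0):
        raise ParameterDomainError(f"modulus_R={modulus_R} outside (0, 1)")
    if not (0.0 < peak_freq_hz < sampling_rate_hz / 2.0):
        raise ParameterDomainError(
            f"peak_freq_hz={peak_freq_hz} outside (0, Nyquist="
            f"{sampling_rate_hz / 2.0})"
        )
    a2 = -modulus_R * modulus_R
    omega = 2.0 * math.pi * peak_freq_hz / sampling_rate_hz
    a1 = 4.0 * a2 * math.cos(omega) / (a2 - 1.0)
    return AR2Spec(
        a1=a1,
        a2=a2,
        peak_freq_hz=peak_freq_hz,
        sampling_rate_hz=sampling_rate_hz,
        drive_std=drive_std,
    )


def peak_frequency(a1: float, a2: float, sampling_rate_hz: float) -> float:
    """Spectral-peak frequency in Hz, (fs / 2 pi) arccos(a1 (a2 - 1) / (4 a2))."""
    c = _peak_cosine(a1, a2)
    return sampling_rate_hz / (2.0 * math.pi) * math.acos(c)


def ar2_power_spectrum(
    a1: float, a2: float, drive_std: float, freqs, sampling_rate_hz: float
) -> np.ndarray:
    """Closed-form AR power spectrum for any stationary (a1, a2).

    Low-level form of :func:`analytic_psd` without the complex-root
    requirement; a1 = a2 = 0 yields the flat white-noise spectrum
    sigma^2.
    """
    freqs = np.asarray(freqs, dtype=float)
    omega = 2.0 * math.pi * freqs / sampling_rate_hz
    denom = (
        1.0
        + a1 * a1
        + a2 * a2
        - 2.0 * a1 * (1.0 - a2) * np.cos(omega)
        - 2.0 * a2 * np.cos(2.0 * omega)
    )
    return drive_std**2 / denom


def analytic_psd(spec: AR2Spec, freqs) -> np.ndarray:
    """Closed-form AR(2) power spectrum at the given frequencies (Hz).

    Two-sided radians-per-sample convention (see module docstring);
    strictly positive for a stationary spec with drive_std > 0.
    """
    if spec.drive_std is None:
        raise ParameterDomainError("spec.drive_std is unset")
    return ar2_power_spectrum(
        spec.a1, spec.a2, spec.drive_std, freqs, spec.sampling_rate_hz
    )


def peak_power(spec: AR2Spec) -> float:
    """Spectral power at the peak frequency,

    S_max = sigma^2 (a2 - 1)^2 / ((a2 + 1)^2 (a2^2 + 2 a2 cos(2 omega_max) + 1)).
    """
    if spec.drive_std is None:
        raise ParameterDomainError("spec.drive_std is unset")
    a2 = spec.a2
    w = spec.omega_max
    return (
        spec.drive_std**2
        * (a2 - 1.0) ** 2
        / ((a2 + 1.0) ** 2 * (a2 * a2 + 2.0 * a2 * math.cos(2.0 * w) + 1.0))
    )


def drive_std_for_peak_power(a1: float, a2: float, target_peak_power: float) -> float:
    """Drive sigma that puts the spectral peak at ``target_peak_power``.

    The peak power is linear in sigma^2, so the inversion is exact.
    """
    if target_peak_power <= 0.0:
        raise InfeasibleTargetError("target_peak_power must be > 0")
    c = _peak_cosine(a1, a2)
    w = math.acos(c)
    gain = (a2 - 1.0) ** 2 / (
        (a2 + 1.0) ** 2 * (a2 * a2 + 2.0 * a2 * math.cos(2.0 * w) + 1.0)
    )
    return math.sqrt(target_peak_power / gain)


def ar2_variance(a1: float, a2: float, drive_std: float) -> float:
    """Stationary AR variance in coefficient form,

    Var[x] = (1 - a2) sigma^2 / ((1 + a2) ((1 - a2)^2 - a1^2));

    a1 = a2 = 0 reduces to the white-noise variance sigma^2.
    """
    return (
        (1.0 - a2) * drive_std**2 / ((1.0 + a2) * ((1.0 - a2) ** 2 - a1 * a1))
    )


def process_variance(spec: AR2Spec) -> float:
    """Stationary time-domain variance of a spec (coefficient form)."""
    if spec.drive_std is None:
        raise ParameterDomainError("spec.drive_std is unset")
    return ar2_variance(spec.a1, spec.a2, spec.drive_std)


def variance_from_modulus(
    modulus_R: float, peak_freq_hz: float, target_peak_power: float,
    sampling_rate_hz: float,
) -> float:
    """Stationary variance in the (R, omega_max, S_max) parameterization,

    Var = -S_max (R^4 - 1)(R^4 - 2 R^2 cos(2 omega_max) + 1)
          / ((R^2 + 1)^4 - 16 R^4 cos^2(omega_max)).
    """
    if not (0.0 < modulus_R < 1.0):
        raise ParameterDomainError(f"modulus_R={modulus_R} outside (0, 1)")
    w = 2.0 * math.pi * peak_freq_hz / sampling_rate_hz
    r2 = modulus_R * modulus_R
    r4 = r2 * r2
    num = -target_peak_power * (r4 - 1.0) * (r4 - 2.0 * r2 * math.cos(2.0 * w) + 1.0)
    den = (r2 + 1.0) ** 4 - 16.0 * r4 * math.cos(w) ** 2
    return num / den


def solve_modulus(
    peak_freq_hz: float,
    sampling_rate_hz: float,
    *,
    target_variance: float | None = None,
    peak_power: float | None = None,
    target_peak_power: float | None = None,
    variance: float | None = None,
) -> float:
    """Root modulus R achieving a variance or peak-power target.

    Two modes, both solving the variance/peak-power relation
    (:func:`variance_from_modulus`) by bracketed 1-D root finding on
    R in (0, 1):

    * ``target_variance`` with ``peak_power`` fixed, or
    * ``target_peak_power`` with ``variance`` fixed.

    The variance spans (0, S_max): R -> 0 flattens the spectrum
    (variance -> S_max) while R -> 1 approaches a pure sinusoid
    (variance -> 0).  Targets outside the attainable interval raise
    :class:`InfeasibleTargetError` naming the interval.
    """
    if (target_variance is None) == (target_peak_power is None):
        raise ValueError(
            "specify exactly one of target_variance (with peak_power fixed) "
            "or target_peak_power (with variance fixed)"
        )
    if target_variance is not None:
        if peak_power is None:
            raise ValueError("peak_power must be fixed when targeting a variance")
        smax, var = float(peak_power), float(target_variance)
    else:
        if variance is None:
            raise ValueError("variance must be fixed when targeting a peak power")
        smax, var = float(target_peak_power), float(variance)
    if not (0.0 < var < smax):
        raise InfeasibleTargetError(
            f"variance {var:g} unattainable: for peak power {smax:g} the "
            f"attainable interval is (0, {smax:g})"
        )

    def f(r: float) -> float:
        return variance_from_modulus(r, peak_freq_hz, smax, sampling_rate_hz) - var

    lo, hi = 1e-8, 1.0 - 1e-9
    root = optimize.brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16)
    achieved = variance_from_modulus(root, peak_freq_hz, smax, sampling_rate_hz)
    if abs(achieved - var) > 1e-10 * max(1.0, abs(var)):
        raise InfeasibleTargetError(
            f"root finding did not reach the target (residual {achieved - var:g})"
        )
    return float(root)


def simulate_ar2(
    spec: AR2Spec,
    n_samples: int,
    rng_seed,
    burn_in: int = 1000,
) -> np.ndarray:
    """Simulate one realization of the AR(2) recursion.

    The recursion starts from a zero state and ``burn_in`` leading
    samples are discarded, so the returned ``n_samples`` are effectively
    stationary.  ``rng_seed`` may be an integer seed, a SeedSequence or
    a ready Generator; output is deterministic given the seed.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if spec.drive_std is None:
        raise ParameterDomainError("spec.drive_std is unset")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    eps = spec.drive_std * rng.standard_normal(n_samples + burn_in)
    x = signal.lfilter([1.0], [1.0, -spec.a1, -spec.a2], eps)
    return x[burn_in:]
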