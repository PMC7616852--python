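"""Receiver input transfer functions: flat, integrator, resonator.

A receiver filters each sender's projected signal through an input
transfer function H_input before superposition:

* ``flat`` — all-pass, |H| = 1 at every frequency (the receiver treats
  all input frequencies identically).
* ``integrator`` — exponential moving average (first-order low pass),
  x[n] = (1 - alpha) x[n-1] + alpha u[n], with transfer function
  H(omega) = alpha / (1 - (1 - alpha) e^{-i omega}).  Parameterized
  interchangeably by the smoothing coefficient alpha, the decay time
  constant tau (alpha = 1 - exp(-dT / tau)) or the -3 dB corner
  frequency f_corner = (fs / 2 pi) arccos(1 - alpha^2 / (2 (1 - alpha))).
* ``resonator`` — band-pass shaped like an AR(2) resonance and applied
  as the causal AR(2) recursion on the input.  The recursion's input
  gain is scaled so the magnitude response peaks at exactly ``gain_g``
  at the resonant frequency (g = 1 gives a unit-gain band-pass).

Filters are applied causally; phase is that of the causal recursion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .ar2_design import AR2Spec, ParameterDomainError

__all__ = [
    "TransferFunctionSpec",
    "smoothing_from_time_constant",
    "time_constant_from_smoothing",
    "corner_frequency",
    "smoothing_from_corner",
    "frequency_response",
    "apply_filter",
]


def smoothing_from_time_constant(time_constant_ms: float, sample_interval_ms: float) -> float:
    """Smoothing coefficient of an exponential filter, alpha = 1 - exp(-dT / tau)."""
    if time_constant_ms <= 0.0 or sample_interval_ms <= 0.0:
        raise ParameterDomainError("time constant and sample interval must be > 0")
    return 1.0 - math.exp(-sample_interval_ms / time_constant_ms)


def time_constant_from_smoothing(smoothing: float, sample_interval_ms: float) -> float:
    """Inverse of :func:`smoothing_from_time_constant`."""
    if not (0.0 < smoothing < 1.0):
        raise ParameterDomainError(f"smoothing={smoothing} outside (0, 1)")
    return -sample_interval_ms / math.log(1.0 - smoothing)


def corner_frequency(smoothing: float, sampling_rate_hz: float) -> float:
    """-3 dB corner of the exponential filter,

    f_corner = (fs / 2 pi) arccos(1 - alpha^2 / (2 (1 - alpha))).
    """
    if not (0.0 < smoothing < 1.0):
        raise ParameterDomainError(f"smoothing={smoothing} outside (0, 1)")
    arg = 1.0 - smoothing**2 / (2.0 * (1.0 - smoothing))
    if arg < -1.0:
        raise ParameterDomainError(
            f"smoothing={smoothing} places the corner above Nyquist"
        )
    return sampling_rate_hz / (2.0 * math.pi) * math.acos(arg)


def smoothing_from_corner(corner_freq_hz: float, sampling_rate_hz: float) -> float:
    """Smoothing coefficient with a prescribed -3 dB corner (closed form).

    Solves alpha^2 = K (1 - alpha) with K = 2 (1 - cos omega_c), taking
    the root in (0, 1).
    """
    if not (0.0 < corner_freq_hz < sampling_rate_hz / 2.0):
        raise ParameterDomainError(
            f"corner {corner_freq_hz} Hz outside (0, Nyquist="
            f"{sampling_rate_hz / 2.0} Hz)"
        )
    k = 2.0 * (1.0 - math.cos(2.0 * math.pi * corner_freq_hz / sampling_rate_hz))
    alpha = (-k + math.sqrt(k * k + 4.0 * k)) / 2.0
    return alpha


@dataclass(frozen=True)
class TransferFunctionSpec:
    """Receiver input filter specification.

    Use the classmethod constructors :meth:`flat`, :meth:`integrator`
    and :meth:`resonator`; ``smoothing_alpha`` is the canonical
    integrator parameter, the time-constant and corner-frequency forms
    are derived properties.
    """

    kind: str
    sampling_rate_hz: float
    smoothing_alpha: float | None = None
    resonator_ar2: AR2Spec | None = None
    gain_g: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("flat", "integrator", "resonator"):
            raise ParameterDomainError(f"unknown transfer-function kind {self.kind!r}")
        if self.kind == "integrator":
            a = self.smoothing_alpha
            if a is None or not (0.0 < a <= 1.0):
                raise ParameterDomainError(
                    f"integrator smoothing_alpha={a} outside (0, 1]"
                )
        if self.kind == "resonator":
            if self.resonator_ar2 is None:
                raise ParameterDomainError("resonator requires resonator_ar2")
            if self.gain_g <= 0.0:
                raise ParameterDomainError("gain_g must be > 0")

    @classmethod
    def flat(cls, sampling_rate_hz: float) -> "TransferFunctionSpec":
        return cls(kind="flat", sampling_rate_hz=sampling_rate_hz)

    @classmethod
    def integrator(
        cls,
        sampling_rate_hz: float,
        *,
        alpha: float | None = None,
        time_constant_ms: float | None = None,
        corner_freq_hz: float | None = None,
    ) -> "TransferFunctionSpec":
        given = [alpha is not None, time_constant_ms is not None, corner_freq_hz is not None]
        if sum(given) != 1:
            raise ValueError(
                "specify exactly one of alpha, time_constant_ms, corner_freq_hz"
            )
        if time_constant_ms is not None:
            alpha = smoothing_from_time_constant(time_constant_ms, 1000.0 / sampling_rate_hz)
        elif corner_freq_hz is not None:
            alpha = smoothing_from_corner(corner_freq_hz, sampling_rate_hz)
        return cls(kind="integrator", sampling_rate_hz=sampling_rate_hz, smoothing_alpha=alpha)

    @classmethod
    def resonator(
        cls, resonator_ar2: AR2Spec, gain_g: float = 1.0
    ) -> "TransferFunctionSpec":
        return cls(
            kind="resonator",
            sampling_rate_hz=resonator_ar2.sampling_rate_hz,
            resonator_ar2=resonator_ar2,
            gain_g=gain_g,
        )

    @property
    def time_constant_ms(self) -> float:
        if self.kind != "integrator":
            raise ParameterDomainError("time constant defined only for integrators")
        return time_constant_from_smoothing(
            self.smoothing_alpha, 1000.0 / self.sampling_rate_hz
        )

    @property
    def corner_freq_hz(self) -> float:
        if self.kind != "integrator":
            raise ParameterDomainError("corner frequency defined only for integrators")
        return corner_frequency(self.smoothing_alpha, self.sampling_rate_hz)

    def to_dict(self) -> dict:
        d = {"kind": self.kind, "sampling_rate_hz": self.sampling_rate_hz}
        if self.kind == "integrator":
            d["smoothing_alpha"] = self.smoothing_alpha
        if self.kind == "resonator":
            d["resonator_ar2"] = self.resonator_ar2.to_dict()
            d["gain_g"] = self.gain_g
        return d


def _resonator_input_gain(tf: TransferFunctionSpec) -> float:
    """Input gain c making the causal AR(2) band-pass peak at |H| = g.

    The raw recursion 1 / (1 - a1 z^-1 - a2 z^-2) peaks at
    1 / sqrt(D(omega_max)); scaling the input by c = g sqrt(D(omega_max))
    pins the peak magnitude to g exactly.
    """
    ar = tf.resonator_ar2
    a1, a2, w = ar.a1, ar.a2, ar.omega_max
    dmin = (
        1.0
        + a1 * a1
        + a2 * a2
        - 2.0 * a1 * (1.0 - a2) * math.cos(w)
        - 2.0 * a2 * math.cos(2.0 * w)
    )
    return tf.gain_g * math.sqrt(dmin)


def frequency_response(tf: TransferFunctionSpec, freqs) -> np.ndarray:
    """Complex response of the filter at the given frequencies (Hz)."""
    freqs = np.asarray(freqs, dtype=float)
    omega = 2.0 * np.pi * freqs / tf.sampling_rate_hz
    if tf.kind == "flat":
        return np.ones_like(omega, dtype=complex)
    z = np.exp(-1j * omega)
    if tf.kind == "integrator":
        a = tf.smoothing_alpha
        return a / (1.0 - (1.0 - a) * z)
    ar = tf.resonator_ar2
    c = _resonator_input_gain(tf)
    return c / (1.0 - ar.a1 * z - ar.a2 * z * z)


def apply_filter(tf: TransferFunctionSpec, series: np.ndarray, axis: int = -1) -> np.ndarray:
    """Filter a time series (or an array of epochs) causally.

    State starts at zero; flat and alpha = 1 integrators return the
    input unchanged.  Output length equals input length along ``axis``.
    """
    series = np.asarray(series, dtype=float)
    if series.shape[axis] < 1:
        raise ValueError("series must contain at least one sample")
    if tf.kind == "flat":
        return series
    if tf.kind == "integrator":
        a = tf.smoothing_alpha
        if a == 1.0:
            return series
        return signal.lfilter([a], [1.0, -(1.0 - a)], series, axis=axis)
    ar = tf.resonator_ar2
    c = _resonator_input_gain(tf)
    return signal.lfilter([c], [1.0, -ar.a1, -ar.a2], series, axis=axis)
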