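"""Spectral estimation and closed-form coherence under source mixing.

PSD/CSD estimation averages single-taper (Hann) periodograms across
epochs — one segment per epoch, no sub-segmentation — and coherence is
computed from the epoch-averaged spectra:

    C^2_ab(f) = |S_ab(f)|^2 / (S_aa(f) S_bb(f)).

Estimated densities are one-sided in units^2 per Hz, normalized so that
sum(psd) * df equals the time-domain variance of the windowed signal in
expectation; the analytic two-sided AR(2)/background spectra of
:mod:`cohsim.ar2_design` and :mod:`cohsim.background_noise` convert to
this scale through the factor 2 / fs (:func:`ar2_psd_density`).

The closed-form coherence of a source-mixing pair with connectivity
weight w, receiver input transfer function H and power ratio
alpha(f) = S11_int / (S22_int + background) is the logistic

    C^2(f) = w^2 alpha |H|^2 / (w^2 alpha |H|^2 + 1),

which is what :func:`analytic_coherence` evaluates (optionally
accounting for un-projected background in the sender as well).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .ar2_design import AR2Spec, analytic_psd
from .background_noise import BackgroundSpec, background_power_spectrum
from .network_simulator import Recording

__all__ = [
    "SpectralEstimates",
    "estimate_spectra",
    "spectra_from_epochs",
    "analytic_coherence",
    "coherence_null_bound",
    "ar2_psd_density",
    "background_psd_density",
    "band_peak",
]


def band_peak(
    freqs: np.ndarray,
    values: np.ndarray,
    band: tuple[float, float] = (30.0, 150.0),
    smooth_bins: int = 5,
) -> tuple[float, float]:
    """Peak of a smoothed spectrum restricted to a frequency band.

    Returns (peak_frequency, peak_value) of the moving-average-smoothed
    curve inside ``band``.  Smoothing suppresses single-bin estimator
    noise; the band excludes the DC region where the background filter's
    zero response distorts coherence summaries.
    """
    freqs = np.asarray(freqs, dtype=float)
    values = np.asarray(values, dtype=float)
    if smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        values = np.convolve(values, kernel, mode="same")
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(sel):
        raise ValueError("band contains no frequency bins")
    k = int(np.argmax(values[sel]))
    return float(freqs[sel][k]), float(values[sel][k])


@dataclass
class SpectralEstimates:
    """Per-frequency PSD, complex CSD and magnitude-squared coherence.

    ``psd`` maps node name to a one-sided density; ``csd`` maps an
    ordered pair (a, b) to the complex cross-density S_ab (with
    S_ba = conj(S_ab)); ``coherence2`` maps the same pairs to
    |S_ab|^2 / (S_aa S_bb).
    """

    freqs: np.ndarray
    psd: dict[str, np.ndarray]
    csd: dict[tuple[str, str], np.ndarray]
    coherence2: dict[tuple[str, str], np.ndarray]
    n_epochs_used: int
    sampling_rate_hz: float

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def pair_csd(self, a: str, b: str) -> np.ndarray:
        if (a, b) in self.csd:
            return self.csd[(a, b)]
        if (b, a) in self.csd:
            return np.conj(self.csd[(b, a)])
        raise KeyError((a, b))

    def pair_coherence2(self, a: str, b: str) -> np.ndarray:
        if (a, b) in self.coherence2:
            return self.coherence2[(a, b)]
        if (b, a) in self.coherence2:
            return self.coherence2[(b, a)]
        raise KeyError((a, b))

    def spectral_matrix(self, a: str, b: str) -> np.ndarray:
        """Full 2x2 Hermitian cross-spectral matrix, shape (n_freqs, 2, 2)."""
        s = np.empty((self.freqs.size, 2, 2), dtype=complex)
        s[:, 0, 0] = self.psd[a]
        s[:, 1, 1] = self.psd[b]
        s[:, 0, 1] = self.pair_csd(a, b)
        s[:, 1, 0] = np.conj(s[:, 0, 1])
        return s

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table (frequency, channel, quantity, value)."""
        rows = []
        for name, v in self.psd.items():
            rows.append(
                pd.DataFrame(
                    {
                        "frequency_hz": self.freqs,
                        "channel": name,
                        "quantity": "psd",
                        "value": v,
                    }
                )
            )
        for (a, b), v in self.coherence2.items():
            rows.append(
                pd.DataFrame(
                    {
                        "frequency_hz": self.freqs,
                        "channel": f"{a}|{b}",
                        "quantity": "coherence2",
                        "value": v,
                    }
                )
            )
        for (a, b), v in self.csd.items():
            for part, vals in (("csd_re", v.real), ("csd_im", v.imag)):
                rows.append(
                    pd.DataFrame(
                        {
                            "frequency_hz": self.freqs,
                            "channel": f"{a}|{b}",
                            "quantity": part,
                            "value": vals,
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


def spectra_from_epochs(
    epochs_by_name: dict[str, np.ndarray],
    sampling_rate_hz: float,
    node_pairs: list[tuple[str, str]] | None = None,
    window: str = "hann",
) -> SpectralEstimates:
    """Epoch-averaged Hann periodogram spectra of epoched channels.

    Each value of ``epochs_by_name`` has shape (n_epochs, n_samples);
    all channels must share the same shape.  At least two epochs are
    required (single-epoch coherence is degenerately one).
    """
    names = list(epochs_by_name)
    shapes = {epochs_by_name[n].shape for n in names}
    if len(shapes) != 1:
        raise ValueError("all channels must have the same (n_epochs, n_samples) shape")
    n_epochs, n_samples = shapes.pop()
    if n_epochs < 2:
        raise ValueError("need at least 2 epochs (coherence is degenerate at 1)")
    if window == "hann":
        win = np.hanning(n_samples)
    elif window in ("boxcar", "rectangular", None):
        win = np.ones(n_samples)
    else:
        from scipy.signal import get_window

        win = get_window(window, n_samples)
    scale = 1.0 / (sampling_rate_hz * np.sum(win**2))
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate_hz)
    one_sided = np.full(freqs.size, 2.0)
    one_sided[0] = 1.0
    if n_samples % 2 == 0:
        one_sided[-1] = 1.0

    ffts = {
        n: np.fft.rfft(epochs_by_name[n] * win, axis=-1) for n in names
    }
    psd = {
        n: (np.mean(np.abs(f) ** 2, axis=0) * scale * one_sided).real
        for n, f in ffts.items()
    }
    if node_pairs is None:
        node_pairs = list(combinations(names, 2))
    csd = {}
    coh = {}
    for a, b in node_pairs:
        s_ab = np.mean(ffts[a] * np.conj(ffts[b]), axis=0) * scale * one_sided
        csd[(a, b)] = s_ab
        coh[(a, b)] = np.abs(s_ab) ** 2 / (psd[a] * psd[b])
    return SpectralEstimates(
        freqs=freqs,
        psd=psd,
        csd=csd,
        coherence2=coh,
        n_epochs_used=n_epochs,
        sampling_rate_hz=sampling_rate_hz,
    )


def estimate_spectra(
    recording: Recording,
    node_pairs: list[tuple[str, str]] | None = None,
    window: str = "hann",
) -> SpectralEstimates:
    """Spectral estimates of a simulated or loaded recording."""
    return spectra_from_epochs(
        recording.data,
        recording.protocol.sampling_rate_hz,
        node_pairs=node_pairs,
        window=window,
    )


def analytic_coherence(
    sender_psd_int,
    receiver_psd_int,
    w: float,
    tf_mag2=1.0,
    background_psd=0.0,
    sender_background_psd=0.0,
) -> np.ndarray:
    """Closed-form source-mixing magnitude-squared coherence.

    With alpha(f) = S11_int / (S22_int + background) the coherence is
    w^2 alpha |H|^2 / (w^2 alpha |H|^2 + 1); unprojected sender
    background (``sender_background_psd``) further dilutes it by the
    factor S11_int / (S11_int + B1).  Spectral units cancel as long as
    all inputs share one convention.
    """
    s11 = np.asarray(sender_psd_int, dtype=float)
    s22 = np.asarray(receiver_psd_int, dtype=float)
    h2 = np.broadcast_to(np.asarray(tf_mag2, dtype=float), s11.shape)
    b2 = np.broadcast_to(np.asarray(background_psd, dtype=float), s11.shape)
    b1 = np.broadcast_to(np.asarray(sender_background_psd, dtype=float), s11.shape)
    denom_int = s22 + b2
    if np.any(denom_int <= 0.0) or np.any(s11 < 0.0):
        raise ValueError("power densities must be positive (zero density divides)")
    z = w**2 * (s11 / denom_int) * h2
    coh = z / (z + 1.0)
    dilution = np.where(s11 + b1 > 0.0, s11 / (s11 + b1), 0.0)
    return coh * dilution


def coherence_null_bound(n_epochs: int, confidence: float = 0.95) -> float:
    """Upper quantile of coherence^2 between independent signals.

    For spectra averaged over n independent epochs the null coherence
    satisfies P(C^2 > c) = (1 - c)^(n - 1), giving the bound
    1 - (1 - p)^(1 / (n - 1)).
    """
    if n_epochs < 2:
        raise ValueError("n_epochs must be >= 2")
    if not (0.0 <= confidence < 1.0):
        raise ValueError("confidence must be in [0, 1)")
    return 1.0 - (1.0 - confidence) ** (1.0 / (n_epochs - 1))


def ar2_psd_density(spec: AR2Spec, freqs) -> np.ndarray:
    """Analytic AR(2) spectrum as a one-sided density (units^2 / Hz)."""
    return 2.0 / spec.sampling_rate_hz * analytic_psd(spec, freqs)


def background_psd_density(
    spec: BackgroundSpec, freqs, sampling_rate_hz: float
) -> np.ndarray:
    """Analytic background spectrum as a one-sided density (units^2 / Hz)."""
    return 2.0 / sampling_rate_hz * background_power_spectrum(spec, freqs)
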