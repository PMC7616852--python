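"""Frequency-resolved measures of inter-areal interaction.

Explained Power family
----------------------
Coherence alone can mislead: under source mixing its magnitude depends
on the receiver's own spectrum and input filtering, not only on what
the sender transmits.  Explained Power re-expresses coherence in the
receiver's power units:

    E_12(f) = C^2_12(f) S_22(f) = |S_12(f)|^2 / S_11(f),

which for a feedforward pair equals the transmitted signal
w^2 S_11(f) |H_input(f)|^2.  Derived quantities:

* corrected EP — |S_12|^2 / (S_11 - S_baseline) removes un-projected
  power in the sender (e.g. 1/f) using a projection-free baseline; it is
  only defined where the sender has substantial power (FWHM band) and is
  masked where the corrected denominator becomes unstable.
* PEP — E_12 / integral(S_22 df): the per-frequency proportion of the
  receiver's total variance explained by the sender.
* ITF estimate — E_12 / S_11 = w^2 |H_input|^2: the receiver's input
  transfer function (times w^2), readable off the data inside the
  sender's FWHM band.

The Wiener-filter identity integral(S_22 C^2) df = Var - Var_residual
links PEP to time-domain prediction; :func:`wiener_residual` fits an
acausal FIR predictor by least squares as an independent check.

Granger-Geweke causality
------------------------
Directed spectral influence computed nonparametrically: the estimated
2x2 cross-spectral matrix is factorized into a causal transfer function
and innovation covariance with Wilson's algorithm, then Geweke's
log-ratio is formed per direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .spectral_estimation import SpectralEstimates

__all__ = [
    "ConnectivityResult",
    "GewekeResult",
    "WienerFit",
    "fwhm_band",
    "band_mask",
    "explained_power",
    "corrected_explained_power",
    "pep",
    "itf_estimate",
    "wiener_residual",
    "wilson_spectral_factorization",
    "granger_geweke",
    "compute_connectivity",
    "SpectralFactorizationError",
]

#: corrected-EP denominators below this fraction of the sender PSD are masked
CORRECTED_EP_DENOM_FRACTION = 0.10


class SpectralFactorizationError(RuntimeError):
    """Wilson iteration failed to converge."""


def fwhm_band(freqs: np.ndarray, psd: np.ndarray) -> tuple[float, float]:
    """Contiguous full-width-at-half-maximum band around the PSD peak.

    Edges are linearly interpolated between the bracketing frequency
    bins; if the response never falls below half maximum on one side,
    the band extends to the grid edge.
    """
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    k = int(np.argmax(psd))
    half = psd[k] / 2.0

    def _cross(lo_dir: bool) -> float:
        rng = range(k, 0, -1) if lo_dir else range(k, psd.size - 1)
        for i in rng:
            j = i - 1 if lo_dir else i + 1
            if psd[j] < half:
                # interpolate between j and i
                f = freqs[j] + (freqs[i] - freqs[j]) * (half - psd[j]) / (
                    psd[i] - psd[j]
                )
                return float(f)
        return float(freqs[0] if lo_dir else freqs[-1])

    return _cross(True), _cross(False)


def band_mask(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    return (freqs >= lo) & (freqs <= hi)


def explained_power(coherence2: np.ndarray, receiver_psd: np.ndarray) -> np.ndarray:
    """E_12(f) = C^2(f) S_22(f), in the receiver PSD's units."""
    coherence2 = np.asarray(coherence2, dtype=float)
    receiver_psd = np.asarray(receiver_psd, dtype=float)
    if coherence2.shape != receiver_psd.shape:
        raise ValueError("coherence and receiver PSD are on different grids")
    if np.any((coherence2 < -1e-12) | (coherence2 > 1.0 + 1e-12)):
        raise ValueError("coherence2 must lie in [0, 1]")
    return np.clip(coherence2, 0.0, 1.0) * receiver_psd


def corrected_explained_power(
    csd_pair: np.ndarray,
    sender_psd: np.ndarray,
    baseline_psd: np.ndarray,
    freqs: np.ndarray,
    validity_band: tuple[float, float],
) -> np.ma.MaskedArray:
    """|S_12|^2 / (S_11 - S_baseline), masked outside its validity region.

    The baseline is the sender's un-projected power estimated from a
    projection-free condition.  Values are masked outside
    ``validity_band`` and wherever the corrected denominator falls below
    10% of the sender PSD (where the estimator is unstable and can turn
    negative); masked bins are never reported as zeros.
    """
    num = np.abs(np.asarray(csd_pair)) ** 2
    s11 = np.asarray(sender_psd, dtype=float)
    sb = np.asarray(baseline_psd, dtype=float)
    denom = s11 - sb
    unstable = denom < CORRECTED_EP_DENOM_FRACTION * s11
    outside = ~band_mask(np.asarray(freqs, dtype=float), validity_band)
    mask = unstable | outside
    in_band = ~outside
    if not np.any(in_band) or np.all(unstable[in_band]):
        warnings.warn(
            "baseline power meets or exceeds sender power across the whole "
            "validity band; corrected EP is fully masked",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = num / denom
    return np.ma.masked_array(vals, mask=mask)


def pep(
    explained_power_vals: np.ndarray,
    receiver_psd: np.ndarray,
    freqs: np.ndarray,
) -> np.ndarray:
    """Proportion of Explained Power, E_12 / integral(S_22 df).

    Integrates to the total explained-variance fraction; a PEP of 0.01
    at some frequency means the sender explains 1% of the receiver's
    total signal energy there.
    """
    ep = np.asarray(explained_power_vals, dtype=float)
    s22 = np.asarray(receiver_psd, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if ep.shape != s22.shape or ep.shape != freqs.shape:
        raise ValueError("inputs are on different grids")
    df = freqs[1] - freqs[0]
    total = np.sum(s22) * df
    if total <= 0.0:
        raise ValueError("receiver total power is zero")
    return ep / total


def itf_estimate(
    explained_power_vals: np.ndarray,
    sender_psd: np.ndarray,
    freqs: np.ndarray,
    validity_band: tuple[float, float],
) -> np.ma.MaskedArray:
    """Input-transfer-function estimate E_12 / S_11 = w^2 |H_input|^2.

    Reliable only where the sender has power; masked outside the
    validity band (typically the sender's FWHM band).
    """
    ep = np.asarray(explained_power_vals, dtype=float)
    s11 = np.asarray(sender_psd, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = ep / s11
    mask = ~band_mask(np.asarray(freqs, dtype=float), validity_band) | (s11 <= 0.0)
    return np.ma.masked_array(vals, mask=mask)


@dataclass
class WienerFit:
    """Acausal FIR least-squares prediction of one channel from another."""

    residual_variance: float
    total_variance: float
    coefficients: np.ndarray
    lags: np.ndarray

    @property
    def explained_fraction(self) -> float:
        return 1.0 - self.residual_variance / self.total_variance


def wiener_residual(
    sender_epochs: np.ndarray,
    receiver_epochs: np.ndarray,
    filter_half_width: int = 40,
    max_epochs: int | None = None,
) -> WienerFit:
    """Least-squares acausal FIR prediction of the receiver from the sender.

    Predicts receiver[t] from sender[t - L .. t + L] pooled over epochs
    (edge samples are dropped so every prediction uses a full window).
    The residual variance is the minimum mean squared error of the
    linear prediction and independently realizes the spectral identity
    Var_residual = integral S_22 (1 - C^2) df.
    """
    x = np.asarray(sender_epochs, dtype=float)
    y = np.asarray(receiver_epochs, dtype=float)
    if x.shape != y.shape or x.ndim != 2:
        raise ValueError("sender and receiver must be matching (n_epochs, n) arrays")
    if max_epochs is not None and x.shape[0] > max_epochs:
        x, y = x[:max_epochs], y[:max_epochs]
    n_ep, n = x.shape
    L = int(filter_half_width)
    width = 2 * L + 1
    if n <= width:
        raise ValueError("epochs are too short for the requested filter width")
    windows = np.lib.stride_tricks.sliding_window_view(x, width, axis=-1)
    design = windows.reshape(-1, width)
    target = y[:, L : n - L].reshape(-1)
    coef, _, rank, _ = np.linalg.lstsq(design, target, rcond=None)
    if rank < width:
        warnings.warn(
            "normal equations are rank deficient; prediction coefficients "
            "were regularized by the pseudo-inverse",
            stacklevel=2,
        )
    resid = target - design @ coef
    return WienerFit(
        residual_variance=float(np.mean(resid**2)),
        total_variance=float(np.mean(target**2)),
        coefficients=coef,
        lags=np.arange(-L, L + 1),
    )


def _plus_operator(g: np.ndarray) -> np.ndarray:
    """Causal part of a Hermitian matrix function on the full FFT circle.

    Keeps nonnegative-lag Fourier coefficients.  The zero-lag matrix is
    split as tril(g0, -1) + diag(g0)/2 so that at a fixed point the
    factor's zero-lag coefficient stays lower triangular (pinning the
    unitary ambiguity of the factorization).  On an even-length grid the
    lag n/2 bin aliases the +n/2 and -n/2 coefficients of the Hermitian
    function together, so it is halved too; without that split the
    iteration stalls at a finite residual instead of converging
    quadratically.
    """
    n = g.shape[0]
    gam = np.fft.ifft(g, axis=0)
    g0 = gam[0]
    gam[0] = np.tril(g0, -1) + np.diag(np.diag(g0)) / 2.0
    if n % 2 == 0:
        gam[n // 2] = gam[n // 2] / 2.0
    gam[n // 2 + 1 :] = 0.0
    return np.fft.fft(gam, axis=0)


def wilson_spectral_factorization(
    spectral_matrix: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Factorize S(f) = H(f) Sigma H(f)^* with H causal and minimum phase.

    ``spectral_matrix`` holds the one-sided Hermitian cross-spectral
    matrices on a uniform grid from DC to Nyquist inclusive, shape
    (n_freqs, m, m).  Returns (H, Sigma): the causal transfer function
    on the same one-sided grid (normalized so its zero-lag coefficient
    is the identity) and the innovation covariance.

    Non-positive-definite bins are regularized by diagonal loading with
    a warning; failure to reach ``tol`` relative change within
    ``max_iter`` iterations raises :class:`SpectralFactorizationError`.
    """
    S = np.asarray(spectral_matrix, dtype=complex)
    nf, m, m2 = S.shape
    if m != m2:
        raise ValueError("spectral matrices must be square")
    n = 2 * (nf - 1)

    # regularize non-PD bins (coherence ~ 1 or numerical noise)
    eigmin = np.min(np.linalg.eigvalsh((S + np.conj(S.transpose(0, 2, 1))) / 2.0), axis=1)
    tr = np.real(np.trace(S, axis1=1, axis2=2))
    bad = eigmin <= 1e-12 * np.maximum(tr, 1e-300)
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} spectral matrix bins are not positive definite; "
            "applying diagonal loading",
            stacklevel=2,
        )
        load = (1e-8 * tr[bad] + 1e-12)[:, None] * np.eye(m)[None]
        S = S.copy()
        S[bad] += load

    Sfull = np.empty((n, m, m), dtype=complex)
    Sfull[:nf] = S
    Sfull[nf:] = np.conj(S[-2:0:-1])

    gamma0 = np.real(np.mean(Sfull, axis=0))
    psi = np.tile(np.linalg.cholesky(gamma0), (n, 1, 1)).astype(complex)
    eye = np.eye(m)
    achieved = np.inf
    for _ in range(max_iter):
        psi_inv = np.linalg.inv(psi)
        g = psi_inv @ Sfull @ np.conj(psi_inv.transpose(0, 2, 1)) + eye
        gp = _plus_operator(g)
        psi_new = psi @ gp
        denom = np.max(np.abs(psi))
        achieved = np.max(np.abs(psi_new - psi)) / max(denom, 1e-300)
        psi = psi_new
        if achieved < tol:
            break
    else:
        raise SpectralFactorizationError(
            f"Wilson iteration did not converge: relative change {achieved:.3e} "
            f"after {max_iter} iterations (tolerance {tol:.1e})"
        )
    a0 = np.real(np.fft.ifft(psi, axis=0)[0])
    sigma = a0 @ a0.T
    h = psi[:nf] @ np.linalg.inv(a0)
    return h, sigma


@dataclass
class GewekeResult:
    """Directional Granger-Geweke spectra for one channel pair."""

    freqs: np.ndarray
    gc: dict[str, np.ndarray]
    total_interdependence: np.ndarray
    sigma: np.ndarray


def granger_geweke(
    est: SpectralEstimates,
    pair: tuple[str, str],
    tol: float = 1e-8,
    max_iter: int = 500,
) -> GewekeResult:
    """Nonparametric Granger-Geweke causality for a channel pair.

    Factorizes the estimated 2x2 spectral matrix (Wilson algorithm) and
    forms Geweke's log-ratio per direction,

        f_{b->a}(f) = ln S_aa(f) / (S_aa(f) - (Sig_bb - Sig_ab^2/Sig_aa) |H_ab(f)|^2).

    Directions are keyed "a->b" and "b->a" for pair = (a, b); values
    are nonnegative.  Also reports the total linear interdependence
    -ln(1 - C^2) which upper-bounds each directional component under
    the Geweke decomposition.
    """
    a, b = pair
    s = est.spectral_matrix(a, b)
    h, sigma = wilson_spectral_factorization(s, tol=tol, max_iter=max_iter)
    saa = np.real(s[:, 0, 0])
    sbb = np.real(s[:, 1, 1])

    def _direction(i: int, j: int, s_ii: np.ndarray) -> np.ndarray:
        # influence of channel j on channel i
        noise = sigma[j, j] - sigma[i, j] ** 2 / sigma[i, i]
        denom = s_ii - noise * np.abs(h[:, i, j]) ** 2
        denom = np.maximum(denom, 1e-300)
        return np.maximum(np.log(s_ii / denom), 0.0)

    gc = {
        f"{b}->{a}": _direction(0, 1, saa),
        f"{a}->{b}": _direction(1, 0, sbb),
    }
    coh = np.clip(est.pair_coherence2(a, b), 0.0, 1.0 - 1e-15)
    total = -np.log(1.0 - coh)
    return GewekeResult(freqs=est.freqs, gc=gc, total_interdependence=total, sigma=sigma)


@dataclass
class ConnectivityResult:
    """Bundle of sender -> receiver interaction measures on one grid.

    ``explained_power`` and derived arrays are in the receiver PSD's
    density units; ``itf_mag2_scaled`` is the dimensionless w^2 |H|^2.
    ``bidirectional`` flags results computed on a bidirectional
    recording, where separating feedforward from feedback explained
    power is not attempted and EP carries an interpretive caveat.
    """

    freqs: np.ndarray
    sender: str
    receiver: str
    explained_power: np.ndarray
    pep: np.ndarray
    itf_mag2_scaled: np.ma.MaskedArray
    validity_band: tuple[float, float]
    explained_variance_total: float
    corrected_ep: np.ma.MaskedArray | None = None
    gc: GewekeResult | None = None
    bidirectional: bool = False

    def to_frame(self) -> "pd.DataFrame":
        import pandas as pd

        pair = f"{self.sender}|{self.receiver}"
        blocks = [
            ("explained_power", np.asarray(self.explained_power, dtype=float), None),
            ("pep", np.asarray(self.pep, dtype=float), None),
            (
                "itf_mag2_scaled",
                np.asarray(self.itf_mag2_scaled.filled(np.nan), dtype=float),
                np.asarray(self.itf_mag2_scaled.mask, dtype=bool),
            ),
        ]
        if self.corrected_ep is not None:
            blocks.append(
                (
                    "corrected_ep",
                    np.asarray(self.corrected_ep.filled(np.nan), dtype=float),
                    np.asarray(self.corrected_ep.mask, dtype=bool),
                )
            )
        if self.gc is not None:
            for direction, vals in self.gc.gc.items():
                blocks.append((f"gc[{direction}]", vals, None))
        rows = []
        for quantity, values, mask in blocks:
            frame = pd.DataFrame(
                {
                    "frequency_hz": self.freqs,
                    "pair": pair,
                    "quantity": quantity,
                    "value": values,
                    "masked": False if mask is None else mask,
                }
            )
            rows.append(frame)
        return pd.concat(rows, ignore_index=True)


def compute_connectivity(
    est: SpectralEstimates,
    sender: str,
    receiver: str,
    *,
    baseline_psd: np.ndarray | None = None,
    validity_band: tuple[float, float] | None = None,
    include_gc: bool = False,
    bidirectional: bool = False,
    gc_tol: float = 1e-8,
    gc_max_iter: int = 500,
) -> ConnectivityResult:
    """Compute the Explained-Power family (and optionally GGC) for a pair.

    ``validity_band`` defaults to the sender's FWHM band; it bounds the
    ITF and corrected-EP estimates.  ``baseline_psd`` enables corrected
    EP (sender PSD from a projection-free condition).
    """
    coh = est.pair_coherence2(sender, receiver)
    s11 = est.psd[sender]
    s22 = est.psd[receiver]
    if validity_band is None:
        validity_band = fwhm_band(est.freqs, s11)
    ep = explained_power(coh, s22)
    pep_vals = pep(ep, s22, est.freqs)
    itf = itf_estimate(ep, s11, est.freqs, validity_band)
    corrected = None
    if baseline_psd is not None:
        corrected = corrected_explained_power(
            est.pair_csd(sender, receiver), s11, baseline_psd, est.freqs, validity_band
        )
    gc = None
    if include_gc:
        gc = granger_geweke(est, (sender, receiver), tol=gc_tol, max_iter=gc_max_iter)
    return ConnectivityResult(
        freqs=est.freqs,
        sender=sender,
        receiver=receiver,
        explained_power=ep,
        pep=pep_vals,
        itf_mag2_scaled=itf,
        validity_band=validity_band,
        explained_variance_total=float(np.sum(ep) * est.df),
        corrected_ep=corrected,
        gc=gc,
        bidirectional=bidirectional,
    )
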