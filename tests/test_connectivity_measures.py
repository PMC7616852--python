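"""Explained Power family, Wiener prediction, Granger-Geweke causality."""

import numpy as np
import pytest

from cohsim.connectivity_measures import (
    SpectralFactorizationError,
    band_mask,
    compute_connectivity,
    corrected_explained_power,
    explained_power,
    fwhm_band,
    granger_geweke,
    pep,
    wiener_residual,
    wilson_spectral_factorization,
)
from cohsim.experiments import make_pair_network
from cohsim.network_simulator import SimulationProtocol, simulate_network
from cohsim.spectral_estimation import (
    SpectralEstimates,
    estimate_spectra,
    spectra_from_epochs,
)

FS = 1000.0


@pytest.fixture(scope="module")
def mixed_pair():
    """Integrator pair (sender 80 Hz, no background) with spectra."""
    proto = SimulationProtocol(n_epochs=800, n_runs=1, burn_in=2000, base_seed=4)
    net = make_pair_network(80.0, "integrator", False, proto)
    rec = simulate_network(net, 0)
    return net, rec, estimate_spectra(rec)


class TestFwhmBand:
    def test_triangular_spectrum_has_interpolated_half_power_edges(self):
        freqs = np.arange(0.0, 11.0)
        psd = np.maximum(0.0, 5.0 - np.abs(freqs - 5.0)) + 1e-9
        lo, hi = fwhm_band(freqs, psd)
        assert lo == pytest.approx(2.5, abs=0.01)
        assert hi == pytest.approx(7.5, abs=0.01)

    def test_band_extends_to_grid_edge_when_never_below_half(self):
        freqs = np.arange(0.0, 8.0)
        lo, hi = fwhm_band(freqs, np.ones(8))
        assert (lo, hi) == (0.0, 7.0)


class TestExplainedPower:
    def test_zero_coherence_explains_nothing(self):
        np.testing.assert_array_equal(
            explained_power(np.zeros(16), np.ones(16)), 0.0
        )

    def test_two_defining_forms_agree_bin_wise(self, mixed_pair):
        _, _, est = mixed_pair
        coh = est.pair_coherence2("sender", "receiver")
        ep_product = explained_power(coh, est.psd["receiver"])
        ep_ratio = np.abs(est.pair_csd("sender", "receiver")) ** 2 / est.psd["sender"]
        np.testing.assert_allclose(ep_product, ep_ratio, rtol=1e-12)

    def test_explained_power_never_exceeds_receiver_power(self, mixed_pair):
        _, _, est = mixed_pair
        coh = est.pair_coherence2("sender", "receiver")
        ep = explained_power(coh, est.psd["receiver"])
        assert np.all(ep <= est.psd["receiver"] * (1.0 + 1e-12))

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            explained_power(np.zeros(8), np.ones(9))


class TestCorrectedExplainedPower:
    def test_zero_baseline_reduces_to_explained_power(self, mixed_pair):
        _, _, est = mixed_pair
        csd = est.pair_csd("sender", "receiver")
        coh = est.pair_coherence2("sender", "receiver")
        ep = explained_power(coh, est.psd["receiver"])
        band = fwhm_band(est.freqs, est.psd["sender"])
        corrected = corrected_explained_power(
            csd, est.psd["sender"], np.zeros_like(est.freqs), est.freqs, band
        )
        sel = ~corrected.mask
        np.testing.assert_allclose(corrected[sel], ep[sel], rtol=1e-12)
        assert np.all(band_mask(est.freqs, band)[sel])

    def test_recovers_projection_under_known_sender_background(self):
        # sender carries un-projected 1/f: naive EP underestimates the
        # transmitted w^2 S11_int |H|^2, the corrected form recovers it
        from cohsim.spectral_estimation import (
            ar2_psd_density,
            background_psd_density,
        )
        from cohsim.transfer_functions import frequency_response

        proto = SimulationProtocol(n_epochs=2000, n_runs=1, burn_in=2000, base_seed=8)
        net = make_pair_network(80.0, "integrator", True, proto)
        rec = simulate_network(net, 0)
        est = estimate_spectra(rec)
        f = est.freqs
        sender = net.node("sender")
        s11_int = ar2_psd_density(sender.intrinsic, f)
        baseline = background_psd_density(sender.background, f, FS)
        h2 = np.abs(frequency_response(net.node("receiver").input_tf, f)) ** 2
        truth = net.edges[0].weight ** 2 * s11_int * h2
        band = fwhm_band(f, s11_int)
        corrected = corrected_explained_power(
            est.pair_csd("sender", "receiver"), est.psd["sender"], baseline, f, band
        )
        naive = explained_power(
            est.pair_coherence2("sender", "receiver"), est.psd["receiver"]
        )
        sel = ~corrected.mask
        kernel = np.ones(5) / 5

        def sm(v):
            return np.convolve(v, kernel, "same")

        # smooth the raw values; the mask only marks validity
        corr_err = np.max(
            np.abs(sm(np.asarray(corrected.data))[sel] / sm(truth)[sel] - 1.0)
        )
        naive_bias = np.mean(sm(naive)[sel] / sm(truth)[sel] - 1.0)
        assert corr_err < 0.10
        assert naive_bias < -0.05  # systematic underestimate

    def test_unstable_denominator_is_masked_not_negative(self):
        freqs = np.arange(0.0, 10.0)
        s11 = np.ones(10)
        baseline = np.full(10, 0.95)  # denominator below 10% of s11
        with pytest.warns(UserWarning, match="masked"):
            out = corrected_explained_power(
                np.ones(10, dtype=complex), s11, baseline, freqs, (0.0, 9.0)
            )
        assert np.all(out.mask)


class TestPep:
    def test_full_coherence_integrates_to_one(self):
        freqs = np.arange(0.0, 501.0)
        s22 = np.exp(-((freqs - 60.0) ** 2) / 50.0) + 0.1
        ep = explained_power(np.ones_like(s22), s22)
        vals = pep(ep, s22, freqs)
        assert np.sum(vals) * 1.0 == pytest.approx(1.0, rel=1e-12)

    def test_zero_total_power_rejected(self):
        freqs = np.arange(0.0, 4.0)
        with pytest.raises(ValueError):
            pep(np.zeros(4), np.zeros(4), freqs)


class TestWiener:
    def test_unconnected_pair_explains_nothing(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((60, 400))
        y = rng.standard_normal((60, 400))
        fit = wiener_residual(x, y, filter_half_width=10)
        assert fit.residual_variance == pytest.approx(fit.total_variance, rel=0.02)

    def test_delayed_copy_is_fully_predicted(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((40, 400))
        y = np.roll(x, 3, axis=-1)
        fit = wiener_residual(x, y, filter_half_width=10)
        assert fit.residual_variance / fit.total_variance < 1e-10

    def test_spectral_and_time_domain_residuals_agree(self, mixed_pair):
        # integral S22 (1 - C^2) df equals the acausal FIR's MSE
        _, rec, est = mixed_pair
        coh = est.pair_coherence2("sender", "receiver")
        spectral = np.sum(est.psd["receiver"] * (1.0 - coh)) * est.df
        fit = wiener_residual(
            rec.data["sender"], rec.data["receiver"], filter_half_width=40
        )
        assert fit.residual_variance == pytest.approx(spectral, rel=0.02)


class TestWilsonFactorization:
    @staticmethod
    def _var1_spectra(nf=129):
        a = np.array([[0.5, 0.0], [0.4, 0.3]])
        sigma = np.array([[1.0, 0.2], [0.2, 0.7]])
        omegas = np.pi * np.arange(nf) / (nf - 1)
        eye = np.eye(2)
        s = np.empty((nf, 2, 2), dtype=complex)
        h = np.empty((nf, 2, 2), dtype=complex)
        for k, w in enumerate(omegas):
            hk = np.linalg.inv(eye - a * np.exp(-1j * w))
            h[k] = hk
            s[k] = hk @ sigma @ hk.conj().T
        return s, h, sigma

    def test_recovers_var1_transfer_and_innovations(self):
        s, h_true, sigma_true = self._var1_spectra()
        h, sigma = wilson_spectral_factorization(s, tol=1e-10)
        np.testing.assert_allclose(sigma, sigma_true, atol=1e-8)
        np.testing.assert_allclose(h, h_true, atol=1e-7)

    def test_factorization_reconstructs_spectrum(self):
        s, _, _ = self._var1_spectra(65)
        h, sigma = wilson_spectral_factorization(s, tol=1e-10)
        recon = h @ sigma @ np.conj(h.transpose(0, 2, 1))
        np.testing.assert_allclose(recon, s, atol=1e-8)

    def test_non_convergence_raises_with_achieved_tolerance(self):
        s, _, _ = self._var1_spectra(33)
        with pytest.raises(SpectralFactorizationError, match="relative change"):
            wilson_spectral_factorization(s, tol=1e-30, max_iter=2)

    def test_rank_deficient_bins_are_loaded_with_warning(self):
        s, _, _ = self._var1_spectra(33)
        s = s.copy()
        s[5] = np.array([[1.0, 1.0], [1.0, 1.0]])  # perfectly coherent bin
        with pytest.warns(UserWarning, match="diagonal loading"):
            wilson_spectral_factorization(s, tol=1e-6)


class TestGrangerGeweke:
    def test_var1_directionality_matches_structure(self):
        # channel x drives y; no reverse influence
        s, _, _ = TestWilsonFactorization._var1_spectra()
        nf = s.shape[0]
        est = SpectralEstimates(
            freqs=np.linspace(0.0, FS / 2.0, nf),
            psd={"x": np.real(s[:, 0, 0]), "y": np.real(s[:, 1, 1])},
            csd={("x", "y"): s[:, 0, 1]},
            coherence2={
                ("x", "y"): np.abs(s[:, 0, 1]) ** 2
                / (np.real(s[:, 0, 0]) * np.real(s[:, 1, 1]))
            },
            n_epochs_used=1,
            sampling_rate_hz=FS,
        )
        res = granger_geweke(est, ("x", "y"), tol=1e-10)
        assert np.max(res.gc["y->x"]) < 1e-8
        assert np.max(res.gc["x->y"]) > 0.1
        assert np.all(res.gc["x->y"] >= 0.0)

    def test_independent_channels_have_negligible_gc(self):
        rng = np.random.default_rng(5)
        est = spectra_from_epochs(
            {
                "a": rng.standard_normal((1500, 256)),
                "b": rng.standard_normal((1500, 256)),
            },
            FS,
        )
        res = granger_geweke(est, ("a", "b"))
        assert np.max(res.gc["a->b"]) < 0.01
        assert np.max(res.gc["b->a"]) < 0.01

    def test_total_interdependence_bounds_each_direction(self, mixed_pair):
        # the Geweke decomposition bounds each directional component by
        # the total linear interdependence; the factorization-based
        # per-bin estimate obeys it up to estimation scatter (the
        # factorization pools information across bins, the coherence
        # total does not)
        _, _, est = mixed_pair
        res = granger_geweke(est, ("sender", "receiver"))
        total = res.total_interdependence
        slack = np.maximum(0.05, 0.2 * total)
        for direction in res.gc.values():
            assert np.all(direction <= total + slack)


class TestComputeConnectivity:
    def test_bundle_is_internally_consistent(self, mixed_pair):
        _, _, est = mixed_pair
        res = compute_connectivity(est, "sender", "receiver")
        coh = est.pair_coherence2("sender", "receiver")
        np.testing.assert_allclose(
            res.explained_power, coh * est.psd["receiver"], rtol=1e-12
        )
        assert res.explained_variance_total == pytest.approx(
            np.sum(res.explained_power) * est.df
        )
        # ITF is masked outside the sender's FWHM band
        outside = ~band_mask(est.freqs, res.validity_band)
        assert np.all(res.itf_mag2_scaled.mask[outside])
        frame = res.to_frame()
        assert set(frame["quantity"]) >= {"explained_power", "pep", "itf_mag2_scaled"}

    def test_flat_receiver_itf_estimates_squared_weight(self):
        proto = SimulationProtocol(n_epochs=800, n_runs=1, burn_in=2000, base_seed=12)
        net = make_pair_network(80.0, "flat", False, proto)
        est = estimate_spectra(simulate_network(net, 0))
        res = compute_connectivity(est, "sender", "receiver")
        vals = res.itf_mag2_scaled.compressed()
        w2 = net.edges[0].weight ** 2
        assert np.median(vals) == pytest.approx(w2, rel=0.10)
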