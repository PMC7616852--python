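"""Source-mixing network simulation: superposition, seeds, IO."""

import numpy as np
import pytest

from cohsim.ar2_design import coefficients_from_peak
from cohsim.background_noise import BackgroundSpec
from cohsim.experiments import make_pair_network, make_triplet_network
from cohsim.network_simulator import (
    ConfigError,
    EdgeSpec,
    NodeSpec,
    RecordingFormatError,
    SimulationProtocol,
    read_recording,
    simulate_network,
    simulate_pair,
    simulate_triplet,
    write_recording,
)
from cohsim.spectral_estimation import (
    ar2_psd_density,
    background_psd_density,
    coherence_null_bound,
    estimate_spectra,
)
from cohsim.transfer_functions import TransferFunctionSpec, frequency_response

FS = 1000.0
FAST = SimulationProtocol(n_epochs=300, n_runs=1, burn_in=2000, base_seed=0)


def _node(name, freq, kind="flat", background=False):
    ar = coefficients_from_peak(freq, 0.97, FS).with_peak_power(1.0)
    if kind == "flat":
        tf = TransferFunctionSpec.flat(FS)
    elif kind == "integrator":
        tf = TransferFunctionSpec.integrator(FS, corner_freq_hz=100.0)
    else:
        tf = TransferFunctionSpec.resonator(ar, gain_g=1.5)
    bg = BackgroundSpec(n_taps=FAST.epoch_length, amplitude=0.3) if background else None
    return NodeSpec(name=name, intrinsic=ar, input_tf=tf, background=bg)


class TestEdgeValidation:
    def test_fractional_sample_delay_rejected(self):
        edge = EdgeSpec(source="a", target="b", weight=0.3, delay_ms=2.5)
        with pytest.raises(ConfigError, match="integer"):
            edge.delay_samples(FS)

    def test_negative_weight_rejected(self):
        with pytest.raises(ConfigError):
            EdgeSpec(source="a", target="b", weight=-0.1, delay_ms=3.0)


class TestPair:
    def test_zero_weight_leaves_pair_incoherent(self):
        edge = EdgeSpec(source="s", target="r", weight=0.0, delay_ms=3.0)
        rec = simulate_pair(_node("s", 60.0), _node("r", 60.0), edge, FAST)
        est = estimate_spectra(rec)
        # family-wise bound across all frequency bins
        bound = coherence_null_bound(
            FAST.n_epochs, confidence=1.0 - 0.001 / est.freqs.size
        )
        assert np.max(est.pair_coherence2("s", "r")) < bound

    def test_receiver_psd_matches_superposition_prediction(self):
        # observed receiver density = intrinsic + w^2 |H|^2 sender + background
        proto = SimulationProtocol(n_epochs=1200, n_runs=1, burn_in=2000, base_seed=1)
        net = make_pair_network(80.0, "integrator", True, proto)
        rec = simulate_network(net, 0)
        est = estimate_spectra(rec)
        f = est.freqs
        sender, receiver = net.node("sender"), net.node("receiver")
        h2 = np.abs(frequency_response(receiver.input_tf, f)) ** 2
        w = net.edges[0].weight
        predicted = (
            ar2_psd_density(receiver.intrinsic, f)
            + w**2 * ar2_psd_density(sender.intrinsic, f) * h2
            + background_psd_density(receiver.background, f, FS)
        )
        sel = (f >= 30.0) & (f <= 150.0)
        kernel = np.ones(5) / 5
        ratio = np.convolve(est.psd["receiver"], kernel, "same")[sel] / np.convolve(
            predicted, kernel, "same"
        )[sel]
        assert np.max(np.abs(ratio - 1.0)) < 0.05

    def test_superposition_bookkeeping_is_exact(self):
        proto = SimulationProtocol(n_epochs=40, n_runs=1, burn_in=2000, base_seed=3)
        net = make_pair_network(70.0, "integrator", True, proto)
        rec = simulate_network(net, 0, return_components=True)
        resid = (
            rec.data["receiver"]
            - rec.components["receiver.intrinsic"]
            - rec.components["receiver.background"]
            - rec.components["sender->receiver.projection"]
        )
        assert np.max(np.abs(resid)) < 1e-10
        resid_s = (
            rec.data["sender"]
            - rec.components["sender.intrinsic"]
            - rec.components["sender.background"]
        )
        assert np.max(np.abs(resid_s)) < 1e-10

    def test_mismatched_edge_endpoints_rejected(self):
        edge = EdgeSpec(source="x", target="r", weight=0.3, delay_ms=3.0)
        with pytest.raises(ConfigError):
            simulate_pair(_node("s", 60.0), _node("r", 60.0), edge, FAST)


class TestDeterminismAndSeeds:
    def test_identical_seed_reproduces_recording(self):
        net = make_pair_network(80.0, "integrator", True, FAST)
        a = simulate_network(net, 0)
        b = simulate_network(net, 0)
        for name in a.data:
            assert np.array_equal(a.data[name], b.data[name])

    def test_runs_are_independent_streams(self):
        net = make_pair_network(80.0, "flat", False, FAST)
        a = simulate_network(net, 0)
        b = simulate_network(net, 1)
        assert not np.array_equal(a.data["sender"], b.data["sender"])

    def test_zeroed_weights_kill_all_cross_coherence(self):
        nodes = (_node("a", 60.0), _node("b", 75.0), _node("c", 90.0))
        from cohsim.network_simulator import NetworkConfig

        net = NetworkConfig(nodes=nodes, edges=(), protocol=FAST)
        est = estimate_spectra(simulate_network(net, 0))
        bound = coherence_null_bound(
            FAST.n_epochs, confidence=1.0 - 0.001 / (3 * est.freqs.size)
        )
        for pair in (("a", "b"), ("a", "c"), ("b", "c")):
            assert np.max(est.pair_coherence2(*pair)) < bound


class TestTriplet:
    def test_zero_feedback_reduces_to_feedforward(self):
        proto = SimulationProtocol(n_epochs=60, n_runs=1, burn_in=2000, base_seed=5)
        ff = make_triplet_network("integrator", True, proto, feedback=False)
        fb0 = make_triplet_network("integrator", True, proto, feedback=True,
                                   fb_weight=0.0)
        # the feedback variant uses the recurrent engine; same seeds
        rec_ff = simulate_network(ff, 0)
        rec_fb = simulate_network(fb0, 0)
        for name in rec_ff.data:
            np.testing.assert_allclose(
                rec_ff.data[name], rec_fb.data[name], atol=1e-10
            )

    def test_senders_remain_mutually_incoherent(self):
        net = make_triplet_network("integrator", True, FAST, feedback=False)
        est = estimate_spectra(simulate_network(net, 0))
        bound = coherence_null_bound(
            FAST.n_epochs, confidence=1.0 - 0.001 / est.freqs.size
        )
        assert np.max(est.pair_coherence2("sender62", "sender66")) < bound

    def test_asymmetric_feedback_warns(self):
        s = (_node("s1", 62.0, "integrator"), _node("s2", 66.0, "integrator"))
        r = _node("r", 60.0, "integrator")
        ff = tuple(
            EdgeSpec(source=n.name, target="r", weight=0.12, delay_ms=3.0) for n in s
        )
        fb = (
            EdgeSpec(source="r", target="s1", weight=0.06, delay_ms=3.0),
            EdgeSpec(source="r", target="s2", weight=0.03, delay_ms=3.0),
        )
        with pytest.warns(UserWarning, match="asymmetric"):
            simulate_triplet(s, r, ff, fb, FAST)

    def test_components_unavailable_for_loops(self):
        net = make_triplet_network("integrator", False, FAST, feedback=True)
        with pytest.raises(ValueError, match="feedforward"):
            simulate_network(net, 0, return_components=True)


class TestRecordingIO:
    def _small_recording(self, seed=0):
        proto = SimulationProtocol(n_epochs=8, n_runs=1, burn_in=500, base_seed=seed)
        net = make_pair_network(60.0, "flat", False, proto)
        return simulate_network(net, 0)

    def test_round_trip_is_bit_exact(self, tmp_path):
        rec = self._small_recording()
        path = tmp_path / "rec.h5"
        write_recording(rec, path)
        back = read_recording(path)
        assert back.node_names == rec.node_names
        for name in rec.data:
            assert np.array_equal(back.data[name], rec.data[name])
        assert back.protocol == rec.protocol

    def test_different_seeds_produce_different_files(self, tmp_path):
        a, b = tmp_path / "a.h5", tmp_path / "b.h5"
        write_recording(self._small_recording(seed=1), a)
        write_recording(self._small_recording(seed=2), b)
        assert a.read_bytes() != b.read_bytes()

    def test_truncated_file_raises_integrity_error(self, tmp_path):
        path = tmp_path / "rec.h5"
        write_recording(self._small_recording(), path)
        blob = path.read_bytes()
        path.write_bytes(blob[: len(blob) // 2])
        with pytest.raises(RecordingFormatError):
            read_recording(path)

    def test_foreign_file_rejected(self, tmp_path):
        path = tmp_path / "other.h5"
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("x", data=np.arange(4))
        with pytest.raises(RecordingFormatError):
            read_recording(path)
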