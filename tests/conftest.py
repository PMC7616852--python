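"""Shared fixtures and helpers.

Heavy simulation caches used by the acceptance tests are session-scoped
and built lazily, so unit-test-only runs stay fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from cohsim.experiments import average_spectra_over_runs, make_pair_network
from cohsim.network_simulator import SimulationProtocol

# 2500-sample-per-epoch protocol of the reference conditions, with the
# per-epoch burn-in shortened to 5000 samples (about 150 oscillator time
# constants, still far beyond the transient) to keep runtimes bounded.
ACCEPTANCE_PROTOCOL = SimulationProtocol(n_epochs=2500, n_runs=4, burn_in=5000)
REDUCED = SimulationProtocol(n_epochs=500, n_runs=3, burn_in=5000)

SENDER_FREQS = (60.0, 70.0, 80.0, 90.0, 100.0)
ASSERT_BAND = (30.0, 150.0)


def smooth(values: np.ndarray, bins: int = 5) -> np.ndarray:
    kernel = np.ones(bins) / bins
    return np.convolve(values, kernel, mode="same")


def band_sel(freqs: np.ndarray, band=ASSERT_BAND) -> np.ndarray:
    return (freqs >= band[0]) & (freqs <= band[1])


@pytest.fixture(scope="session")
def pair_suite():
    """Run-averaged spectra of all no-background sender sweeps.

    Keys are (receiver_kind, sender_freq); values carry the averaged
    SpectralEstimates and the network config.  Built once per session;
    shared across the coherence, Explained-Power, ITF and GGC checks.
    """
    suite = {}
    for kind in ("integrator", "resonator", "flat"):
        for fpk in SENDER_FREQS:
            net = make_pair_network(fpk, kind, False, ACCEPTANCE_PROTOCOL)
            est = average_spectra_over_runs(net, base_seed=7)
            suite[(kind, fpk)] = {"net": net, "est": est}
    return suite


@pytest.fixture(scope="session")
def background_sweeps():
    """Reduced-protocol sender sweeps with 1/f background on."""
    sweeps = {}
    for kind in ("integrator", "resonator"):
        rows = []
        for fpk in SENDER_FREQS:
            net = make_pair_network(fpk, kind, True, REDUCED)
            est = average_spectra_over_runs(net, base_seed=3)
            rows.append((fpk, net, est))
        sweeps[kind] = rows
    return sweeps
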