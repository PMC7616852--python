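"""Config-driven experiments: study presets, runner, comparisons.

The shipped presets encode the reference simulation conditions:

* ``pair-integrator`` / ``pair-resonator`` — five bivariate
  sender -> receiver configurations with sender peak frequencies 60-100
  Hz, receiver fixed at 60 Hz, w = 0.35, 3 ms delay, 1/f background on;
  the receiver is an exponential-moving-average integrator (cutoff
  100 Hz) or a matched resonator (gain 1.5).
* ``pair-flat`` / ``pair-integrator-nobg`` / ``pair-resonator-nobg`` —
  the same sweeps without background, used for the Explained-Power,
  PEP and input-transfer-function analyses.
* ``triplet-integrator`` / ``triplet-resonator`` — two senders (62 and
  66 Hz) competing for one 60 Hz receiver through feedforward edges
  (w_ff = 0.12, 3 ms), background on.
* ``triplet-feedback`` — the integrator triplet with feedback edges
  from the receiver to both senders (w_fb = 0.06, 3 ms) closing a loop;
  all nodes are integrators, and Granger-Geweke causality is computed.

All oscillators have peak power one; their root modulus defaults to
R = 0.97 (a gamma-like ~10 Hz linewidth at fs = 1000 Hz), and the
background floor at the receiver's peak frequency sits one order of
magnitude below the oscillation peak; both are configurable.
Each preset runs ``protocol.n_runs`` independent runs, averages the
spectra across runs, and writes tidy CSV tables plus a provenance JSON.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, replace
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ar2_design import AR2Spec, coefficients_from_peak, process_variance, solve_modulus
from .background_noise import BackgroundSpec
from .connectivity_measures import compute_connectivity
from .network_simulator import (
    ConfigError,
    EdgeSpec,
    NetworkConfig,
    NodeSpec,
    SimulationProtocol,
    simulate_network,
)
from .spectral_estimation import SpectralEstimates, estimate_spectra
from .transfer_functions import TransferFunctionSpec

__all__ = [
    "ExperimentConfig",
    "PRESETS",
    "DEFAULT_MODULUS",
    "make_pair_network",
    "make_triplet_network",
    "preset",
    "run_experiment",
    "compare_conditions",
    "config_from_yaml",
]

DEFAULT_MODULUS = 0.97
SENDER_FREQS = (60.0, 70.0, 80.0, 90.0, 100.0)
TRIPLET_SENDER_FREQS = (62.0, 66.0)
RECEIVER_FREQ = 60.0
PAIR_WEIGHT = 0.35
DELAY_MS = 3.0
INTEGRATOR_CUTOFF_HZ = 100.0
PAIR_RESONATOR_GAIN = 1.5
TRIPLET_RESONATOR_GAIN = 1.6
FF_WEIGHT = 0.12
FB_WEIGHT = 0.06
BACKGROUND_F0_HZ = 60.0
BACKGROUND_EXPONENT = 1.0 / 3.0
# aperiodic floor one order of magnitude below the unit oscillation peak
BACKGROUND_AMPLITUDE = 0.1**0.5


@dataclass(frozen=True)
class ExperimentConfig:
    """A named set of simulation conditions and requested measures."""

    name: str
    conditions: tuple[tuple[str, NetworkConfig], ...]
    pairs: tuple[tuple[str, str], ...]
    measures: tuple[str, ...] = ("psd", "coherence", "ep", "pep", "itf")

    def with_protocol(self, protocol: SimulationProtocol) -> "ExperimentConfig":
        conditions = tuple(
            (label, replace(net, protocol=protocol)) for label, net in self.conditions
        )
        return replace(self, conditions=conditions)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "conditions": {label: net.to_dict() for label, net in self.conditions},
            "pairs": [list(p) for p in self.pairs],
            "measures": list(self.measures),
        }


def _oscillator(
    peak_freq_hz: float,
    sampling_rate_hz: float,
    modulus: float = DEFAULT_MODULUS,
    peak_power: float = 1.0,
) -> AR2Spec:
    return coefficients_from_peak(
        peak_freq_hz, modulus, sampling_rate_hz
    ).with_peak_power(peak_power)


def _receiver_tf(
    kind: str,
    sampling_rate_hz: float,
    receiver_ar2: AR2Spec,
    gain: float,
) -> TransferFunctionSpec:
    if kind == "flat":
        return TransferFunctionSpec.flat(sampling_rate_hz)
    if kind == "integrator":
        return TransferFunctionSpec.integrator(
            sampling_rate_hz, corner_freq_hz=INTEGRATOR_CUTOFF_HZ
        )
    if kind == "resonator":
        return TransferFunctionSpec.resonator(receiver_ar2, gain_g=gain)
    raise ConfigError(f"unknown receiver kind {kind!r}")


def _background(protocol: SimulationProtocol, enabled: bool) -> BackgroundSpec | None:
    if not enabled:
        return None
    return BackgroundSpec(
        reference_freq_hz=BACKGROUND_F0_HZ,
        exponent_P=BACKGROUND_EXPONENT,
        n_taps=protocol.epoch_length,
        enabled=True,
        amplitude=BACKGROUND_AMPLITUDE,
    )


def make_pair_network(
    sender_freq_hz: float,
    receiver_kind: str,
    background: bool,
    protocol: SimulationProtocol,
    *,
    weight: float = PAIR_WEIGHT,
    delay_ms: float = DELAY_MS,
    receiver_freq_hz: float = RECEIVER_FREQ,
    modulus: float = DEFAULT_MODULUS,
    resonator_gain: float = PAIR_RESONATOR_GAIN,
) -> NetworkConfig:
    """Bivariate sender -> receiver network in the reference conditions."""
    fs = protocol.sampling_rate_hz
    bg = _background(protocol, background)
    sender_ar2 = _oscillator(sender_freq_hz, fs, modulus)
    receiver_ar2 = _oscillator(receiver_freq_hz, fs, modulus)
    sender = NodeSpec(
        name="sender",
        intrinsic=sender_ar2,
        input_tf=TransferFunctionSpec.flat(fs),
        background=bg,
    )
    receiver = NodeSpec(
        name="receiver",
        intrinsic=receiver_ar2,
        input_tf=_receiver_tf(receiver_kind, fs, receiver_ar2, resonator_gain),
        background=bg,
    )
    edge = EdgeSpec(source="sender", target="receiver", weight=weight, delay_ms=delay_ms)
    return NetworkConfig(nodes=(sender, receiver), edges=(edge,), protocol=protocol)


def make_triplet_network(
    receiver_kind: str,
    background: bool,
    protocol: SimulationProtocol,
    *,
    feedback: bool = False,
    sender_freqs_hz: tuple[float, float] = TRIPLET_SENDER_FREQS,
    receiver_freq_hz: float = RECEIVER_FREQ,
    ff_weight: float = FF_WEIGHT,
    fb_weight: float = FB_WEIGHT,
    delay_ms: float = DELAY_MS,
    modulus: float = DEFAULT_MODULUS,
    resonator_gain: float = TRIPLET_RESONATOR_GAIN,
) -> NetworkConfig:
    """Two-sender/one-receiver network, optionally with symmetric feedback.

    In the feedback variant every node is an integrator (the senders
    filter the fed-back input with the same transfer function as the
    receiver) and the receiver projects the identical signal to both
    senders with equal weight and delay.
    """
    fs = protocol.sampling_rate_hz
    bg = _background(protocol, background)
    receiver_ar2 = _oscillator(receiver_freq_hz, fs, modulus)
    receiver_tf = _receiver_tf(receiver_kind, fs, receiver_ar2, resonator_gain)
    sender_tf = receiver_tf if feedback else TransferFunctionSpec.flat(fs)
    senders = tuple(
        NodeSpec(
            name=f"sender{int(f)}",
            intrinsic=_oscillator(f, fs, modulus),
            input_tf=sender_tf,
            background=bg,
        )
        for f in sender_freqs_hz
    )
    receiver = NodeSpec(
        name="receiver", intrinsic=receiver_ar2, input_tf=receiver_tf, background=bg
    )
    edges = [
        EdgeSpec(source=s.name, target="receiver", weight=ff_weight, delay_ms=delay_ms)
        for s in senders
    ]
    if feedback:
        edges += [
            EdgeSpec(source="receiver", target=s.name, weight=fb_weight, delay_ms=delay_ms)
            for s in senders
        ]
    return NetworkConfig(
        nodes=(*senders, receiver), edges=tuple(edges), protocol=protocol
    )


def _pair_sweep(
    name: str, receiver_kind: str, background: bool, protocol: SimulationProtocol
) -> ExperimentConfig:
    conditions = tuple(
        (
            f"sender{int(f)}",
            make_pair_network(f, receiver_kind, background, protocol),
        )
        for f in SENDER_FREQS
    )
    return ExperimentConfig(
        name=name, conditions=conditions, pairs=(("sender", "receiver"),)
    )


def _triplet(
    name: str,
    receiver_kind: str,
    protocol: SimulationProtocol,
    feedback: bool,
    measures: tuple[str, ...],
) -> ExperimentConfig:
    net = make_triplet_network(
        receiver_kind, background=True, protocol=protocol, feedback=feedback
    )
    pairs = tuple(
        (f"sender{int(f)}", "receiver") for f in TRIPLET_SENDER_FREQS
    )
    return ExperimentConfig(
        name=name, conditions=(("triplet", net),), pairs=pairs, measures=measures
    )


def preset(name: str, protocol: SimulationProtocol | None = None) -> ExperimentConfig:
    """Build a shipped preset, optionally overriding the protocol."""
    proto = protocol if protocol is not None else SimulationProtocol()
    base_measures = ("psd", "coherence", "ep", "pep", "itf")
    builders = {
        "pair-integrator": lambda: _pair_sweep("pair-integrator", "integrator", True, proto),
        "pair-resonator": lambda: _pair_sweep("pair-resonator", "resonator", True, proto),
        "pair-flat": lambda: _pair_sweep("pair-flat", "flat", False, proto),
        "pair-integrator-nobg": lambda: _pair_sweep(
            "pair-integrator-nobg", "integrator", False, proto
        ),
        "pair-resonator-nobg": lambda: _pair_sweep(
            "pair-resonator-nobg", "resonator", False, proto
        ),
        "triplet-integrator": lambda: _triplet(
            "triplet-integrator", "integrator", proto, False, base_measures
        ),
        "triplet-resonator": lambda: _triplet(
            "triplet-resonator", "resonator", proto, False, base_measures
        ),
        "triplet-feedback": lambda: _triplet(
            "triplet-feedback", "integrator", proto, True, base_measures + ("ggc",)
        ),
    }
    if name not in builders:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(builders))}"
        )
    return builders[name]()


PRESETS = (
    "pair-integrator",
    "pair-resonator",
    "pair-flat",
    "pair-integrator-nobg",
    "pair-resonator-nobg",
    "triplet-integrator",
    "triplet-resonator",
    "triplet-feedback",
)


def average_spectra_over_runs(
    net: NetworkConfig, base_seed: int, n_runs: int | None = None
) -> SpectralEstimates:
    """Simulate n_runs independent runs and average their psd/csd.

    Coherence is recomputed from the run-averaged spectra, so the
    effective epoch count is n_runs * n_epochs.
    """
    proto = replace(net.protocol, base_seed=base_seed)
    net = replace(net, protocol=proto)
    runs = proto.n_runs if n_runs is None else n_runs
    acc: SpectralEstimates | None = None
    for r in range(runs):
        rec = simulate_network(net, run_index=r)
        est = estimate_spectra(rec)
        if acc is None:
            acc = est
        else:
            for k in acc.psd:
                acc.psd[k] = acc.psd[k] + est.psd[k]
            for k in acc.csd:
                acc.csd[k] = acc.csd[k] + est.csd[k]
    for k in acc.psd:
        acc.psd[k] = acc.psd[k] / runs
    for k in acc.csd:
        acc.csd[k] = acc.csd[k] / runs
    for a, b in list(acc.coherence2):
        acc.coherence2[(a, b)] = (
            np.abs(acc.csd[(a, b)]) ** 2 / (acc.psd[a] * acc.psd[b])
        )
    acc.n_epochs_used = runs * proto.n_epochs
    return acc


def run_experiment(
    config: ExperimentConfig,
    out_dir,
    base_seed: int = 0,
    protocol: SimulationProtocol | None = None,
) -> Path:
    """Run every condition of an experiment and write result tables.

    Writes ``spectra.csv`` (per-condition PSD/coherence/CSD),
    ``measures.csv`` (EP/PEP/ITF and optionally GGC per requested pair)
    and ``provenance.json`` under ``out_dir/<name>/``.  Partial outputs
    are removed if any condition fails.
    """
    if protocol is not None:
        config = config.with_protocol(protocol)
    out = Path(out_dir) / config.name
    out.mkdir(parents=True, exist_ok=True)
    try:
        spectra_frames = []
        measure_frames = []
        for label, net in config.conditions:
            est = average_spectra_over_runs(net, base_seed)
            sf = est.to_frame()
            sf.insert(0, "condition", label)
            spectra_frames.append(sf)
            bidirectional = _has_cycle(net)
            for sender, receiver in config.pairs:
                res = compute_connectivity(
                    est,
                    sender,
                    receiver,
                    include_gc="ggc" in config.measures,
                    bidirectional=bidirectional,
                )
                mf = res.to_frame()
                mf.insert(0, "condition", label)
                measure_frames.append(mf)
        pd.concat(spectra_frames, ignore_index=True).to_csv(
            out / "spectra.csv", index=False
        )
        pd.concat(measure_frames, ignore_index=True).to_csv(
            out / "measures.csv", index=False
        )
        provenance = {
            "experiment": config.to_dict(),
            "base_seed": base_seed,
            "cohsim_version": __version__,
        }
        (out / "provenance.json").write_text(
            json.dumps(provenance, indent=2, sort_keys=True)
        )
    except Exception:
        shutil.rmtree(out, ignore_errors=True)
        raise
    return out


def _has_cycle(net: NetworkConfig) -> bool:
    from .network_simulator import _topological_order

    names = [n.name for n in net.nodes]
    idx = {n: i for i, n in enumerate(names)}
    return (
        _topological_order(
            len(names), [(idx[e.source], idx[e.target]) for e in net.edges]
        )
        is None
    )


_KEYS = ["frequency_hz", "quantity"]


def compare_conditions(
    a: pd.DataFrame, b: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Signed per-frequency differences (A - B) and peak-value summaries.

    Both inputs are tidy tables as written by :func:`run_experiment`
    (one condition each); they must cover identical frequency grids and
    quantities.  Bins masked (NaN) in both inputs are dropped — they
    carry no comparable value.  Returns ``(differences, peaks)`` where
    ``peaks`` holds, per channel/pair and quantity, the spectral peak
    value of each input and their difference.
    """
    key_cols = [c for c in ("channel", "pair") if c in a.columns] + _KEYS
    for frame in (a, b):
        missing = [c for c in key_cols + ["value"] if c not in frame.columns]
        if missing:
            raise ValueError(f"result table is missing columns {missing}")
    a_ = a[key_cols + ["value"]].rename(columns={"value": "value_a"})
    b_ = b[key_cols + ["value"]].rename(columns={"value": "value_b"})
    merged = a_.merge(b_, on=key_cols, how="outer", indicator=True)
    if (merged["_merge"] != "both").any():
        raise ValueError("result tables do not share a common grid/measure set")
    merged = merged.drop(columns="_merge")
    merged = merged[
        ~(merged["value_a"].isna() & merged["value_b"].isna())
    ].reset_index(drop=True)
    merged["difference"] = merged["value_a"] - merged["value_b"]
    group_cols = [c for c in key_cols if c != "frequency_hz"]
    peaks = (
        merged.groupby(group_cols, sort=True)
        .agg(
            peak_a=("value_a", "max"),
            peak_b=("value_b", "max"),
        )
        .reset_index()
    )
    peaks["peak_difference"] = peaks["peak_a"] - peaks["peak_b"]
    return merged, peaks


# ---------------------------------------------------------------------------
# YAML configuration


def _ar2_from_config(d: dict, sampling_rate_hz: float) -> AR2Spec:
    peak = float(d["peak_freq_hz"])
    modulus = d.get("modulus_R", d.get("modulus"))
    peak_power = d.get("peak_power")
    variance = d.get("variance")
    drive_std = d.get("drive_std")
    if modulus is None:
        if peak_power is None or variance is None:
            raise ConfigError(
                "oscillator needs modulus_R, or both peak_power and variance"
            )
        modulus = solve_modulus(
            peak, sampling_rate_hz, target_variance=variance, peak_power=peak_power
        )
    spec = coefficients_from_peak(peak, float(modulus), sampling_rate_hz)
    if peak_power is not None:
        return spec.with_peak_power(float(peak_power))
    if drive_std is not None:
        return spec.with_drive_std(float(drive_std))
    if variance is not None:
        unit = process_variance(spec.with_drive_std(1.0))
        return spec.with_drive_std(float(np.sqrt(variance / unit)))
    return spec.with_peak_power(1.0)


def _tf_from_config(d: dict | None, sampling_rate_hz: float) -> TransferFunctionSpec:
    if d is None:
        return TransferFunctionSpec.flat(sampling_rate_hz)
    kind = d.get("kind", "flat")
    if kind == "flat":
        return TransferFunctionSpec.flat(sampling_rate_hz)
    if kind == "integrator":
        return TransferFunctionSpec.integrator(
            sampling_rate_hz,
            alpha=d.get("alpha"),
            time_constant_ms=d.get("tau_ms"),
            corner_freq_hz=d.get("cutoff_hz"),
        )
    if kind == "resonator":
        ar = _ar2_from_config(
            {
                "peak_freq_hz": d.get("peak_freq_hz", RECEIVER_FREQ),
                "modulus": d.get("modulus", DEFAULT_MODULUS),
                "peak_power": d.get("peak_power", 1.0),
            },
            sampling_rate_hz,
        )
        return TransferFunctionSpec.resonator(ar, gain_g=float(d.get("gain_g", 1.0)))
    raise ConfigError(f"unknown transfer-function kind {kind!r}")


def _bg_from_config(d: dict | None, epoch_length: int) -> BackgroundSpec | None:
    if d is None or not d.get("enabled", True):
        return None
    return BackgroundSpec(
        reference_freq_hz=float(d.get("f0_hz", BACKGROUND_F0_HZ)),
        exponent_P=float(d.get("exponent", BACKGROUND_EXPONENT)),
        n_taps=int(d.get("n_taps", epoch_length)),
        enabled=True,
        amplitude=float(d.get("amplitude", BACKGROUND_AMPLITUDE)),
    )


def config_from_yaml(path) -> ExperimentConfig:
    """Load a custom experiment (single condition) from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text())
    proto = SimulationProtocol(**raw.get("protocol", {}))
    nodes = tuple(
        NodeSpec(
            name=nd["name"],
            intrinsic=_ar2_from_config(nd, proto.sampling_rate_hz),
            input_tf=_tf_from_config(nd.get("tf"), proto.sampling_rate_hz),
            background=_bg_from_config(nd.get("background"), proto.epoch_length),
        )
        for nd in raw["nodes"]
    )
    edges = tuple(
        EdgeSpec(
            source=e["source"],
            target=e["target"],
            weight=float(e["weight"]),
            delay_ms=float(e["delay_ms"]),
        )
        for e in raw.get("edges", [])
    )
    net = NetworkConfig(nodes=nodes, edges=edges, protocol=proto)
    names = [n.name for n in nodes]
    pairs = tuple(
        tuple(p) for p in raw.get("pairs", list(combinations(names, 2)))
    )
    measures = tuple(raw.get("measures", ("psd", "coherence", "ep", "pep", "itf")))
    name = raw.get("name", Path(path).stem)
    return ExperimentConfig(
        name=name, conditions=((name, net),), pairs=pairs, measures=measures
    )
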