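"""Source-mixing network simulator.

Coupled "areas" are simulated as AR(2) oscillators whose outputs are
projected to other areas through weighted, delayed connections, after
passing through the receiving area's input transfer function.  The
observed signal of an area is the linear superposition

    observed = intrinsic + sum_edges w * (H_input * projected_source)[t - tau]
               + background,

where only the *oscillatory* part of a source is projected — its 1/f
background is never transmitted and never correlated across areas.

In feedforward networks a source's projected signal is its intrinsic
activity.  When the graph contains a loop (feedback), each node's
projected signal is by default its full oscillatory state — intrinsic
activity plus its filtered received inputs (``project_received=True``);
the alternative, projecting intrinsic activity only, is available via
``project_received=False``.

Epochs are statistically independent: each epoch is generated from a
fresh drive realization and its own burn-in, drawn from a dedicated
random substream keyed by (run, node, epoch, role), so any run of a
configuration is exactly reproducible from its base seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import h5py
import numpy as np
from scipy import signal

from .ar2_design import AR2Spec
from .background_noise import BackgroundSpec, one_over_f_filter, _filtered_noise
from .transfer_functions import TransferFunctionSpec, apply_filter

__all__ = [
    "ConfigError",
    "RecordingFormatError",
    "EdgeSpec",
    "NodeSpec",
    "SimulationProtocol",
    "REDUCED_PROTOCOL",
    "NetworkConfig",
    "Recording",
    "simulate_network",
    "simulate_pair",
    "simulate_triplet",
    "write_recording",
    "read_recording",
]

_ROLE_DRIVE = 0
_ROLE_BACKGROUND = 1

# epoch chunks are sized to roughly this many samples per working array
_CHUNK_SAMPLES = 16_000_000


class ConfigError(ValueError):
    """Invalid network or protocol configuration."""


class RecordingFormatError(RuntimeError):
    """A recording file is malformed, truncated or not a recording."""


@dataclass(frozen=True)
class EdgeSpec:
    """Directed projection between two areas.

    ``weight`` is the dimensionless connectivity weight w and
    ``delay_ms`` the transmission delay tau; the delay must be an
    integer number of samples at the protocol's sampling rate.
    """

    source: str
    target: str
    weight: float
    delay_ms: float

    def __post_init__(self) -> None:
        if self.weight < 0.0:
            raise ConfigError("edge weight must be >= 0")
        if self.delay_ms < 0.0:
            raise ConfigError("edge delay must be >= 0")

    def delay_samples(self, sampling_rate_hz: float) -> int:
        d = self.delay_ms * sampling_rate_hz / 1000.0
        di = round(d)
        if abs(d - di) > 1e-9:
            raise ConfigError(
                f"delay {self.delay_ms} ms is not an integer number of samples "
                f"at fs={sampling_rate_hz} Hz"
            )
        return int(di)

    def to_dict(self) -> dict:
        return {
            "source": self.source,
            "target": self.target,
            "weight": self.weight,
            "delay_ms": self.delay_ms,
        }


@dataclass(frozen=True)
class NodeSpec:
    """One simulated area: intrinsic oscillator, input filter, background.

    The input transfer function applies identically to every incoming
    projection of the node.  ``background=None`` (or a disabled spec)
    means no 1/f background.
    """

    name: str
    intrinsic: AR2Spec
    input_tf: TransferFunctionSpec
    background: BackgroundSpec | None = None

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "intrinsic": self.intrinsic.to_dict(),
            "input_tf": self.input_tf.to_dict(),
            "background": None if self.background is None else self.background.to_dict(),
        }


@dataclass(frozen=True)
class SimulationProtocol:
    """Sampling and epoching protocol.

    Defaults are the full study conditions: fs = 1000 Hz, 1000-sample
    epochs, 2500 independent epochs per run, 15 runs, and a 50,000
    sample burn-in discarded at the start of every epoch's recursion.
    """

    sampling_rate_hz: float = 1000.0
    epoch_length: int = 1000
    n_epochs: int = 2500
    n_runs: int = 15
    burn_in: int = 50_000
    base_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("epoch_length", "n_epochs", "n_runs"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.burn_in < 0:
            raise ConfigError("burn_in must be >= 0")

    def to_dict(self) -> dict:
        return {
            "sampling_rate_hz": self.sampling_rate_hz,
            "epoch_length": self.epoch_length,
            "n_epochs": self.n_epochs,
            "n_runs": self.n_runs,
            "burn_in": self.burn_in,
            "base_seed": self.base_seed,
        }


#: Reduced protocol for quick exploratory runs: same epoching, fewer
#: epochs and runs, and a 5000-sample burn-in (still orders of magnitude
#: beyond the oscillators' transient).
REDUCED_PROTOCOL = SimulationProtocol(n_epochs=500, n_runs=3, burn_in=5000)


@dataclass(frozen=True)
class NetworkConfig:
    """Nodes, edges and protocol of one simulated network."""

    nodes: tuple[NodeSpec, ...]
    edges: tuple[EdgeSpec, ...]
    protocol: SimulationProtocol

    def __post_init__(self) -> None:
        names = [n.name for n in self.nodes]
        if len(set(names)) != len(names):
            raise ConfigError("node names must be unique")
        for e in self.edges:
            if e.source not in names or e.target not in names:
                raise ConfigError(f"edge {e.source}->{e.target} references unknown node")
            if e.source == e.target:
                raise ConfigError("self-loops are not supported")
            e.delay_samples(self.protocol.sampling_rate_hz)

    def node(self, name: str) -> NodeSpec:
        for n in self.nodes:
            if n.name == name:
                return n
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "nodes": [n.to_dict() for n in self.nodes],
            "edges": [e.to_dict() for e in self.edges],
            "protocol": self.protocol.to_dict(),
        }


@dataclass
class Recording:
    """Epoched observed signals of every node for a single run.

    ``data[name]`` has shape (n_epochs, epoch_length).  ``components``
    optionally carries bookkeeping series (intrinsic, background,
    per-edge projections) for verification.
    """

    data: dict[str, np.ndarray]
    protocol: SimulationProtocol
    config: dict
    run_index: int = 0
    components: dict[str, np.ndarray] | None = None

    def epochs(self, name: str) -> np.ndarray:
        return self.data[name]

    @property
    def node_names(self) -> list[str]:
        return list(self.data)


def _epoch_rng(base_seed: int, run: int, node_index: int, epoch: int, role: int):
    ss = np.random.SeedSequence(base_seed, spawn_key=(run, node_index, epoch, role))
    return np.random.default_rng(ss)


def _noise_block(
    base_seed: int, run: int, node_index: int, epochs: range, length: int, role: int
) -> np.ndarray:
    """Independent standard-normal rows, one substream per epoch."""
    out = np.empty((len(epochs), length))
    for i, e in enumerate(epochs):
        out[i] = _epoch_rng(base_seed, run, node_index, e, role).standard_normal(length)
    return out


def _topological_order(n_nodes: int, edges: list[tuple[int, int]]) -> list[int] | None:
    """Kahn's algorithm; None if the graph has a cycle."""
    indeg = [0] * n_nodes
    out = [[] for _ in range(n_nodes)]
    for s, t in edges:
        indeg[t] += 1
        out[s].append(t)
    queue = [i for i in range(n_nodes) if indeg[i] == 0]
    order: list[int] = []
    while queue:
        i = queue.pop()
        order.append(i)
        for j in out[i]:
            indeg[j] -= 1
            if indeg[j] == 0:
                queue.append(j)
    return order if len(order) == n_nodes else None


def _recurrent_chunk(
    xint: np.ndarray,
    edges: list[tuple[int, int, float, int]],
    tf_codes: list[tuple],
) -> np.ndarray:
    """Sample-by-sample update of the projected (oscillatory) state.

    ``xint``: (n_nodes, n_epochs, L) intrinsic series.  Each node's
    state p = intrinsic + H_input(sum of delayed weighted inputs); used
    when the graph has a loop, in which case every edge in the loop
    must have delay >= 1 sample.
    """
    n_nodes, n_ep, length = xint.shape
    p = np.empty_like(xint)
    incoming: list[list[tuple[int, float, int]]] = [[] for _ in range(n_nodes)]
    for s, t, w, d in edges:
        if d < 1:
            raise ConfigError("edges in a feedback loop require delay >= 1 sample")
        incoming[t].append((s, w, d))
    y1 = np.zeros((n_nodes, n_ep))
    y2 = np.zeros((n_nodes, n_ep))
    passive = [i for i in range(n_nodes) if not incoming[i]]
    active = [i for i in range(n_nodes) if incoming[i]]
    for i in passive:
        p[i] = xint[i]
    inp = np.empty(n_ep)
    for t in range(length):
        for i in active:
            inp[:] = 0.0
            for s, w, d in incoming[i]:
                if t >= d:
                    inp += w * p[s, :, t - d]
            code = tf_codes[i]
            if code[0] == "flat":
                y = inp
            elif code[0] == "integrator":
                alpha = code[1]
                y1[i] *= 1.0 - alpha
                y1[i] += alpha * inp
                y = y1[i]
            else:  # resonator
                a1, a2, c = code[1], code[2], code[3]
                y = a1 * y1[i] + a2 * y2[i] + c * inp
                y2[i] = y1[i]
                y1[i] = y
            p[i, :, t] = xint[i, :, t] + y
    return p


def _tf_code(tf: TransferFunctionSpec) -> tuple:
    if tf.kind == "flat":
        return ("flat",)
    if tf.kind == "integrator":
        return ("integrator", tf.smoothing_alpha)
    from .transfer_functions import _resonator_input_gain

    ar = tf.resonator_ar2
    return ("resonator", ar.a1, ar.a2, _resonator_input_gain(tf))


def simulate_network(
    config: NetworkConfig,
    run_index: int = 0,
    *,
    project_received: bool = True,
    return_components: bool = False,
) -> Recording:
    """Simulate one run of a configured network.

    Feedforward graphs are resolved by vectorized filtering in
    topological order; graphs with loops fall back to a sample-by-sample
    recurrent update.  Deterministic given ``protocol.base_seed`` and
    ``run_index``.
    """
    proto = config.protocol
    fs = proto.sampling_rate_hz
    n_nodes = len(config.nodes)
    names = [n.name for n in config.nodes]
    idx = {name: i for i, name in enumerate(names)}
    edges_i = [
        (idx[e.source], idx[e.target], e.weight, e.delay_samples(fs))
        for e in config.edges
    ]
    topo = _topological_order(n_nodes, [(s, t) for s, t, _, _ in edges_i])
    recurrent = project_received and topo is None
    if topo is None and not project_received:
        topo = list(range(n_nodes))  # sources are intrinsic-only: order is free

    length = proto.burn_in + proto.epoch_length
    n_ep = proto.n_epochs
    chunk = max(1, min(n_ep, _CHUNK_SAMPLES // length))
    out = {name: np.empty((n_ep, proto.epoch_length)) for name in names}
    comps: dict[str, np.ndarray] | None = {} if return_components else None
    if return_components:
        if recurrent:
            raise ValueError(
                "return_components is only supported for feedforward networks"
            )
        for name in names:
            comps[f"{name}.intrinsic"] = np.empty((n_ep, proto.epoch_length))
            comps[f"{name}.background"] = np.zeros((n_ep, proto.epoch_length))
        for e in config.edges:
            comps[f"{e.source}->{e.target}.projection"] = np.empty(
                (n_ep, proto.epoch_length)
            )

    keep = slice(proto.burn_in, proto.burn_in + proto.epoch_length)
    tf_codes = [_tf_code(n.input_tf) for n in config.nodes]

    for start in range(0, n_ep, chunk):
        epochs = range(start, min(start + chunk, n_ep))
        sel = slice(epochs.start, epochs.stop)
        xint: list[np.ndarray] = []
        for i, node in enumerate(config.nodes):
            drive = _noise_block(
                proto.base_seed, run_index, i, epochs, length, _ROLE_DRIVE
            )
            sigma = node.intrinsic.drive_std
            if sigma is None:
                raise ConfigError(f"node {node.name!r}: intrinsic drive_std is unset")
            drive *= sigma
            ar = node.intrinsic
            xint.append(signal.lfilter([1.0], [1.0, -ar.a1, -ar.a2], drive, axis=-1))

        if recurrent:
            obs = list(_recurrent_chunk(np.stack(xint), edges_i, tf_codes))
        else:
            # projected state of each node, resolved in topological order
            p: list[np.ndarray | None] = [None] * n_nodes
            for i in topo:
                incoming = [e for e in edges_i if e[1] == i]
                if not incoming:
                    p[i] = xint[i]
                    continue
                acc = xint[i].copy()
                for s, _t, w, d in incoming:
                    src = xint[s] if not project_received else p[s]
                    filtered = apply_filter(config.nodes[i].input_tf, src, axis=-1)
                    if d > 0:
                        acc[:, d:] += w * filtered[:, :-d]
                    else:
                        acc += w * filtered
                    if return_components:
                        lo = proto.burn_in - d
                        comps[f"{names[s]}->{names[i]}.projection"][sel] = (
                            w * filtered[:, lo : lo + proto.epoch_length]
                        )
                p[i] = acc
            obs = p

        for i, node in enumerate(config.nodes):
            kept = obs[i][:, keep].copy()
            if return_components:
                comps[f"{node.name}.intrinsic"][sel] = xint[i][:, keep]
            bg_spec = node.background
            if bg_spec is not None and bg_spec.enabled:
                noise_len = proto.epoch_length + 2 * bg_spec.n_taps - 1
                noise = bg_spec.amplitude * _noise_block(
                    proto.base_seed, run_index, i, epochs, noise_len, _ROLE_BACKGROUND
                )
                taps = one_over_f_filter(bg_spec, fs)
                bg = _filtered_noise(noise, taps)[:, -proto.epoch_length :]
                kept += bg
                if return_components:
                    comps[f"{node.name}.background"][sel] = bg
            out[node.name][sel] = kept

    return Recording(
        data=out,
        protocol=proto,
        config=config.to_dict(),
        run_index=run_index,
        components=comps,
    )


def simulate_pair(
    sender: NodeSpec,
    receiver: NodeSpec,
    edge: EdgeSpec,
    protocol: SimulationProtocol,
    run_index: int = 0,
    *,
    return_components: bool = False,
) -> Recording:
    """Simulate a unidirectional sender -> receiver pair.

    The receiver observes its intrinsic activity plus the weighted,
    delayed, input-filtered intrinsic activity of the sender (the
    sender's background, if any, is not projected).
    """
    if edge.source != sender.name or edge.target != receiver.name:
        raise ConfigError("edge must run from the sender to the receiver")
    config = NetworkConfig(nodes=(sender, receiver), edges=(edge,), protocol=protocol)
    return simulate_network(config, run_index, return_components=return_components)


def simulate_triplet(
    senders: tuple[NodeSpec, NodeSpec],
    receiver: NodeSpec,
    ff_edges: tuple[EdgeSpec, ...],
    fb_edges: tuple[EdgeSpec, ...] = (),
    protocol: SimulationProtocol | None = None,
    run_index: int = 0,
    *,
    project_received: bool = True,
    return_components: bool = False,
) -> Recording:
    """Two mutually unconnected senders projecting to one receiver.

    ``ff_edges`` run from the senders to the receiver; optional
    ``fb_edges`` run back from the receiver to the senders, closing a
    loop (the receiver then projects its full oscillatory state by
    default, see ``project_received``).  Asymmetric feedback weights or
    delays are allowed but flagged with a warning, since the reference
    configuration projects the identical signal to both senders.
    """
    if protocol is None:
        protocol = SimulationProtocol()
    sender_names = {s.name for s in senders}
    for e in ff_edges:
        if e.source not in sender_names or e.target != receiver.name:
            raise ConfigError("feedforward edges must run sender -> receiver")
    for e in fb_edges:
        if e.source != receiver.name or e.target not in sender_names:
            raise ConfigError("feedback edges must run receiver -> sender")
    if len(fb_edges) >= 2:
        ws = {e.weight for e in fb_edges}
        ds = {e.delay_ms for e in fb_edges}
        if len(ws) > 1 or len(ds) > 1:
            warnings.warn(
                "asymmetric feedback weights/delays: the reference triplet "
                "projects the identical signal to both senders",
                stacklevel=2,
            )
    config = NetworkConfig(
        nodes=(*senders, receiver),
        edges=(*ff_edges, *fb_edges),
        protocol=protocol,
    )
    return simulate_network(
        config,
        run_index,
        project_received=project_received,
        return_components=return_components,
    )


_FORMAT = "cohsim-recording"
_FORMAT_VERSION = 1


def write_recording(recording: Recording, path) -> None:
    """Serialize a recording (epoched arrays + config provenance) to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["format"] = _FORMAT
        f.attrs["format_version"] = _FORMAT_VERSION
        f.attrs["config_json"] = json.dumps(recording.config)
        f.attrs["run_index"] = recording.run_index
        f.attrs["n_epochs"] = recording.protocol.n_epochs
        f.attrs["epoch_length"] = recording.protocol.epoch_length
        f.attrs["node_order"] = json.dumps(list(recording.data))
        g = f.create_group("nodes")
        for name, arr in recording.data.items():
            g.create_dataset(name, data=arr)


def read_recording(path) -> Recording:
    """Load a recording written by :func:`write_recording`.

    Raises :class:`RecordingFormatError` on truncated, malformed or
    foreign files.
    """
    try:
        with h5py.File(path, "r") as f:
            if f.attrs.get("format") != _FORMAT:
                raise RecordingFormatError(f"{path}: not a cohsim recording")
            config = json.loads(f.attrs["config_json"])
            run_index = int(f.attrs["run_index"])
            n_epochs = int(f.attrs["n_epochs"])
            epoch_length = int(f.attrs["epoch_length"])
            order = json.loads(f.attrs["node_order"])
            if set(order) != set(f["nodes"].keys()):
                raise RecordingFormatError(
                    f"{path}: node datasets do not match the declared order"
                )
            data = {}
            for name in order:
                arr = f["nodes"][name][()]
                if arr.shape != (n_epochs, epoch_length):
                    raise RecordingFormatError(
                        f"{path}: node {name!r} has shape {arr.shape}, "
                        f"expected {(n_epochs, epoch_length)}"
                    )
                data[name] = arr
            if not data:
                raise RecordingFormatError(f"{path}: recording contains no nodes")
    except (OSError, KeyError) as exc:
        raise RecordingFormatError(f"{path}: unreadable or truncated ({exc})") from exc
    protocol = SimulationProtocol(**config["protocol"])
    return Recording(data=data, protocol=protocol, config=config, run_index=run_index)
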