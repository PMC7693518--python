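"""The 3-D spiking reservoir: geometry, small-world wiring, LIF dynamics, STDP.

A cube of N leaky integrate-and-fire neurons (default 1000 on a 10x10x10
unit-spaced grid) is wired at initialisation: every ordered pair of neurons
within the small-world radius (default 2.5 grid units) is connected with
probability ``conn_prob``, with an initial magnitude drawn uniform on (0, w0]
and scaled by 1/distance; a seeded fraction of connections is inhibitory.
EEG channels map onto the grid neurons nearest their (scaled) 10-20 scalp
coordinates, and each channel's signed spike events are injected as signed
input current at its site.

Dynamics are discrete-time at the EEG sample resolution.  Per step each
non-refractory neuron decays (u <- u * (1 - leak)), integrates recurrent
input from neurons that fired on the previous step plus any external input,
and fires when u >= firing_threshold, resetting to zero and pausing for the
refractory period.  Membrane potential is not floored, so inhibitory input
can drive it negative.

Unsupervised training uses a nearest-neighbour, one-step spike-timing rule:
when presynaptic i fired at t-1 and postsynaptic j fires at t over an
existing connection, |w_ij| grows by the learning rate (capped at w_cap); the
reverse order shrinks |w_ij| by the same amount (floored at 0).  Within one
step, potentiation is applied before depression.  The sparsity pattern and
the sign of every connection are fixed at initialisation; plasticity moves
magnitudes only.  Recurrent input at step t uses the weights as updated
through step t-1.
"""

from __future__ import annotations

import dataclasses
import hashlib
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
from numba import njit
from scipy.spatial import cKDTree

from .encoding import SpikeTrainSet
from .synthetic import DEAP_CHANNELS

DEFAULT_N = 1000
DEFAULT_GRID = (10, 10, 10)
DEFAULT_RADIUS = 2.5
DEFAULT_CONN_PROB = 0.15
DEFAULT_INHIBITORY_FRACTION = 0.25
DEFAULT_FIRING_THRESHOLD = 0.5
DEFAULT_LEAK = 0.1
DEFAULT_REFRACTORY = 3
DEFAULT_INPUT_GAIN = 1.0
DEFAULT_W0 = 0.2
DEFAULT_W_CAP = 1.0
DEFAULT_STDP_RATE = 0.01



@dataclass
class ReservoirGeometry:
    """Neuron grid coordinates and the channel -> input-neuron mapping."""

    coords: np.ndarray  # (N, 3) float64, grid units
    input_map: dict[str, int]
    grid_shape: tuple[int, int, int]

    @property
    def n_neurons(self) -> int:
        return self.coords.shape[0]


@dataclass
class ReservoirNet:
    """A wired cube: geometry plus signed sparse weights and LIF parameters.

    ``signs`` (int8, +/-1 on connections, 0 elsewhere) fixes the sparsity
    pattern and excitatory/inhibitory identity; ``magnitudes`` (float64 >= 0)
    carries the plastic part.  The effective weight matrix is their product.
    """

    geometry: ReservoirGeometry
    signs: np.ndarray
    magnitudes: np.ndarray
    firing_threshold: float = DEFAULT_FIRING_THRESHOLD
    leak: float = DEFAULT_LEAK
    refractory: int = DEFAULT_REFRACTORY
    radius: float = DEFAULT_RADIUS
    conn_prob: float = DEFAULT_CONN_PROB
    inhibitory_fraction: float = DEFAULT_INHIBITORY_FRACTION
    input_gain: float = DEFAULT_INPUT_GAIN
    w_cap: float = DEFAULT_W_CAP
    rng_seed: int = 0

    @property
    def n_neurons(self) -> int:
        return self.geometry.n_neurons

    @property
    def n_connections(self) -> int:
        return int(np.count_nonzero(self.signs))

    def effective_weights(self) -> np.ndarray:
        return self.signs.astype(np.float64) * self.magnitudes

    def weights_sparse(self):
        """Effective signed weights as a scipy CSR matrix."""
        from scipy.sparse import csr_matrix

        return csr_matrix(self.effective_weights())

    def fingerprint(self) -> str:
        """Hash of geometry + weights; guards classifier/reservoir pairing."""
        h = hashlib.sha256()
        h.update(self.geometry.coords.tobytes())
        h.update(self.signs.tobytes())
        h.update(self.magnitudes.tobytes())
        return h.hexdigest()


@dataclass
class CubeStateRecord:
    """Per-neuron first-spike time (-1 = never) and spike count for one sample."""

    first_spike_time: np.ndarray  # (N,) int64, -1 when the neuron never fired
    spike_count: np.ndarray  # (N,) int64
    duration: int

    def validate(self) -> None:
        never = self.first_spike_time < 0
        if np.any(self.first_spike_time[~never] >= self.duration):
            raise ValueError("first spike beyond duration")
        if np.any((self.spike_count == 0) != never):
            raise ValueError("spike_count inconsistent with first_spike_time")


@lru_cache(maxsize=1)
def _standard_positions() -> dict[str, np.ndarray]:
    """3-D scalp positions (metres, head frame) for the DEAP montage channels,
    from the standard 10-20 montage shipped with mne."""
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        montage = mne.channels.make_standard_montage("standard_1020")
    pos = montage.get_positions()["ch_pos"]
    lookup = {name.lower(): np.asarray(p, dtype=np.float64) for name, p in pos.items()}
    out = {}
    for ch in DEAP_CHANNELS:
        out[ch.lower()] = lookup[ch.lower()]
    return out


def build_geometry(
    n_neurons: int = DEFAULT_N,
    grid_shape: tuple[int, int, int] = DEFAULT_GRID,
    channels: tuple[str, ...] = ("FP1", "F3", "C4", "C3"),
) -> ReservoirGeometry:
    """Unit-spaced grid coordinates plus a channel -> nearest-neuron map.

    Channel scalp positions (10-20 montage) are min-max scaled, over the full
    32-channel DEAP montage, into the grid bounding box; each requested
    channel maps to the nearest grid neuron, with collisions resolved to the
    next-nearest free neuron in channel order.
    """
    if int(np.prod(grid_shape)) != n_neurons:
        raise ValueError(f"grid_shape {grid_shape} does not hold {n_neurons} neurons")
    axes = [np.arange(s, dtype=np.float64) for s in grid_shape]
    coords = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)

    std = _standard_positions()
    ref = np.stack([std[ch.lower()] for ch in DEAP_CHANNELS])
    lo, hi = ref.min(axis=0), ref.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    box = np.array(grid_shape, dtype=np.float64) - 1.0

    input_map: dict[str, int] = {}
    taken: set[int] = set()
    for ch in channels:
        key = ch.lower()
        if key not in std:
            raise ValueError(f"unknown channel {ch!r}: not in the DEAP 10-20 montage")
        target = (std[key] - lo) / span * box
        order = np.argsort(np.linalg.norm(coords - target[None, :], axis=1), kind="stable")
        idx = next(int(i) for i in order if int(i) not in taken)
        input_map[ch] = idx
        taken.add(idx)
    return ReservoirGeometry(coords=coords, input_map=input_map, grid_shape=tuple(grid_shape))


def init_connections(
    geometry: ReservoirGeometry,
    radius: float = DEFAULT_RADIUS,
    conn_prob: float = DEFAULT_CONN_PROB,
    inhibitory_fraction: float = DEFAULT_INHIBITORY_FRACTION,
    seed: int = 0,
    w0: float = DEFAULT_W0,
    firing_threshold: float = DEFAULT_FIRING_THRESHOLD,
    leak: float = DEFAULT_LEAK,
    refractory: int = DEFAULT_REFRACTORY,
    input_gain: float = DEFAULT_INPUT_GAIN,
    w_cap: float = DEFAULT_W_CAP,
) -> ReservoirNet:
    """Small-world wiring within ``radius``; seeded and fully deterministic.

    Ordered pairs (i, j), i != j, with Euclidean distance <= radius are
    connected independently with probability ``conn_prob``; magnitudes are
    uniform on (0, w0] scaled by 1/distance; a seeded ``inhibitory_fraction``
    of the realised connections is negative.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if not 0 < conn_prob <= 1:
        raise ValueError("conn_prob must lie in (0, 1]")
    n = geometry.n_neurons
    tree = cKDTree(geometry.coords)
    pairs = tree.query_pairs(r=radius, output_type="ndarray")
    if pairs.size:
        ordered = np.vstack([pairs, pairs[:, ::-1]])
        lex = np.lexsort((ordered[:, 1], ordered[:, 0]))
        ordered = ordered[lex]
    else:
        ordered = np.empty((0, 2), dtype=np.intp)

    rng = np.random.default_rng(seed)
    keep = rng.random(len(ordered)) < conn_prob
    kept = ordered[keep]
    dist = np.linalg.norm(
        geometry.coords[kept[:, 0]] - geometry.coords[kept[:, 1]], axis=1
    )
    mags = (1.0 - rng.random(len(kept))) * w0 / dist
    inhibitory = rng.random(len(kept)) < inhibitory_fraction

    signs = np.zeros((n, n), dtype=np.int8)
    magnitudes = np.zeros((n, n), dtype=np.float64)
    signs[kept[:, 0], kept[:, 1]] = np.where(inhibitory, -1, 1).astype(np.int8)
    magnitudes[kept[:, 0], kept[:, 1]] = np.minimum(mags, w_cap)

    degree = np.count_nonzero(signs, axis=0) + np.count_nonzero(signs, axis=1)
    isolated = int(np.sum(degree == 0))
    if isolated:
        warnings.warn(
            f"{isolated} neurons have no connections at radius {radius}",
            stacklevel=2,
        )
    return ReservoirNet(
        geometry=geometry,
        signs=signs,
        magnitudes=magnitudes,
        firing_threshold=firing_threshold,
        leak=leak,
        refractory=refractory,
        radius=radius,
        conn_prob=conn_prob,
        inhibitory_fraction=inhibitory_fraction,
        input_gain=input_gain,
        w_cap=w_cap,
        rng_seed=seed,
    )


def _external_input(net: ReservoirNet, spikes: SpikeTrainSet):
    try:
        in_idx = np.array(
            [net.geometry.input_map[ch] for ch in spikes.channel_names], dtype=np.intp
        )
    except KeyError as exc:
        raise KeyError(f"spike channel {exc.args[0]!r} has no input-neuron mapping") from None
    ext = np.zeros((spikes.n_timepoints, len(in_idx)), dtype=np.float64)
    for c, (t, p) in enumerate(zip(spikes.times, spikes.polarities)):
        ext[t, c] = p
    return in_idx, ext


@njit(cache=True)
def _sim_kernel(
    indptr, indices, edge_mag, edge_sign,  # CSR over outgoing connections
    in_idx, ext,  # input-neuron indices, (T, n_inputs) signed external events
    decay, thresh, gain, refractory, cap, rate,
    plastic, record,
    n, T,
):  # pragma: no cover - exercised via _simulate
    u = np.zeros(n, dtype=np.float64)
    refr = np.zeros(n, dtype=np.int64)
    first = np.full(n, -1, dtype=np.int64)
    counts = np.zeros(n, dtype=np.int64)
    prev = np.zeros(n, dtype=np.bool_)
    raster = np.zeros((T if record else 1, n), dtype=np.bool_)

    for t in range(T):
        # leak, then recurrent input from last step's spikes (current weights)
        for i in range(n):
            u[i] *= decay
        for i in range(n):
            if prev[i]:
                for e in range(indptr[i], indptr[i + 1]):
                    u[indices[e]] += edge_sign[e] * edge_mag[e]
        for c in range(in_idx.shape[0]):
            u[in_idx[c]] += gain * ext[t, c]
        # refractory neurons are clamped at rest and cannot fire
        cur = np.zeros(n, dtype=np.bool_)
        for i in range(n):
            if refr[i] > 0:
                u[i] = 0.0
            elif u[i] >= thresh:
                cur[i] = True

        if plastic:
            # potentiation first: pre fired at t-1, post fires at t
            for i in range(n):
                if prev[i]:
                    for e in range(indptr[i], indptr[i + 1]):
                        if cur[indices[e]]:
                            w = edge_mag[e] + rate
                            edge_mag[e] = w if w < cap else cap
            # depression: post fired at t-1, pre fires at t
            for i in range(n):
                if cur[i]:
                    for e in range(indptr[i], indptr[i + 1]):
                        if prev[indices[e]]:
                            w = edge_mag[e] - rate
                            edge_mag[e] = w if w > 0.0 else 0.0

        for i in range(n):
            if refr[i] > 0:
                refr[i] -= 1
            if cur[i]:
                if first[i] < 0:
                    first[i] = t
                counts[i] += 1
                u[i] = 0.0
                refr[i] = refractory
                if record:
                    raster[t, i] = True
        prev = cur
    return first, counts, raster


def _edges_csr(net: ReservoirNet):
    """Connection list in CSR form (by presynaptic neuron, postsynaptic ascending)."""
    pre, post = np.nonzero(net.signs)
    n = net.n_neurons
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.add.at(indptr[1:], pre, 1)
    indptr = np.cumsum(indptr)
    return indptr, post.astype(np.int64), pre


def _simulate(
    net: ReservoirNet,
    spikes: SpikeTrainSet,
    edges: tuple | None = None,
    edge_mag: np.ndarray | None = None,
    stdp_rate: float | None = None,
    record_raster: bool = False,
):
    """Shared simulation core.

    When ``stdp_rate`` is given, ``edge_mag`` (CSR-ordered connection
    magnitudes) is updated in place by the one-step temporal-order rule,
    potentiation before depression within a step.  Returns
    (CubeStateRecord, raster-or-None).
    """
    n = net.n_neurons
    in_idx, ext = _external_input(net, spikes)
    if edges is None:
        edges = _edges_csr(net)
    indptr, post, pre = edges
    if edge_mag is None:
        edge_mag = net.magnitudes[pre, post].copy()
    edge_sign = net.signs[pre, post].astype(np.float64)

    first, counts, raster = _sim_kernel(
        indptr, post, edge_mag, edge_sign,
        in_idx.astype(np.int64), ext,
        1.0 - net.leak, net.firing_threshold, net.input_gain,
        net.refractory, net.w_cap,
        0.0 if stdp_rate is None else float(stdp_rate),
        stdp_rate is not None, record_raster,
        n, spikes.n_timepoints,
    )
    record = CubeStateRecord(
        first_spike_time=first, spike_count=counts, duration=spikes.n_timepoints
    )
    record.validate()
    out_raster = (
        [np.nonzero(raster[t])[0] for t in range(spikes.n_timepoints)]
        if record_raster
        else None
    )
    return record, out_raster


def run_sample(
    net: ReservoirNet, spikes: SpikeTrainSet, record_dynamics: bool = False
):
    """Propagate one encoded sample through the cube (weights fixed).

    Membrane state starts from rest; nothing persists between calls.  Returns
    a :class:`CubeStateRecord`, or ``(record, raster)`` when
    ``record_dynamics`` is set, where raster is a per-step list of fired
    neuron index arrays.
    """
    record, raster = _simulate(net, spikes, record_raster=record_dynamics)
    return (record, raster) if record_dynamics else record


def train_stdp(
    net: ReservoirNet,
    encoded: list[SpikeTrainSet],
    rate: float = DEFAULT_STDP_RATE,
    passes: int = 1,
) -> ReservoirNet:
    """Unsupervised STDP over the encoded samples, in order; returns a new net.

    The input net is left untouched; only connection magnitudes change (signs
    and sparsity are structural).
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    if passes < 1:
        raise ValueError("passes must be >= 1")
    edges = _edges_csr(net)
    indptr, post, pre = edges
    edge_mag = net.magnitudes[pre, post].copy()
    for _ in range(passes):
        for spikes in encoded:
            _simulate(net, spikes, edges=edges, edge_mag=edge_mag, stdp_rate=rate)
    magnitudes = net.magnitudes.copy()
    magnitudes[pre, post] = edge_mag
    return dataclasses.replace(net, magnitudes=magnitudes)


def raster_to_spiketrains(raster: list[np.ndarray], n_neurons: int) -> SpikeTrainSet:
    """Re-shape a per-step raster into the columnar spike-train container
    (one pseudo-channel per neuron, all events +1)."""
    times: list[list[int]] = [[] for _ in range(n_neurons)]
    for t, fired in enumerate(raster):
        for j in fired:
            times[int(j)].append(t)
    return SpikeTrainSet(
        channel_names=tuple(f"n{j:04d}" for j in range(n_neurons)),
        times=tuple(np.array(t, dtype=np.int64) for t in times),
        polarities=tuple(np.ones(len(t), dtype=np.int8) for t in times),
        n_timepoints=max(len(raster), 2),
    )


def save_reservoir(net: ReservoirNet, path: str | Path) -> None:
    """Serialise the full reservoir state to a single ``.npz`` container."""
    channels = list(net.geometry.input_map)
    np.savez(
        path,
        coords=net.geometry.coords,
        grid_shape=np.array(net.geometry.grid_shape),
        input_channels=np.array(channels),
        input_indices=np.array([net.geometry.input_map[c] for c in channels]),
        signs=net.signs,
        magnitudes=net.magnitudes,
        params=np.array(
            [
                net.firing_threshold,
                net.leak,
                float(net.refractory),
                net.radius,
                net.conn_prob,
                net.inhibitory_fraction,
                net.input_gain,
                net.w_cap,
                float(net.rng_seed),
            ]
        ),
    )


def load_reservoir(path: str | Path) -> ReservoirNet:
    with np.load(path) as a:
        geometry = ReservoirGeometry(
            coords=a["coords"],
            input_map={
                str(c): int(i) for c, i in zip(a["input_channels"], a["input_indices"])
            },
            grid_shape=tuple(int(s) for s in a["grid_shape"]),
        )
        p = a["params"]
        return ReservoirNet(
            geometry=geometry,
            signs=a["signs"],
            magnitudes=a["magnitudes"],
            firing_threshold=float(p[0]),
            leak=float(p[1]),
            refractory=int(p[2]),
            radius=float(p[3]),
            conn_prob=float(p[4]),
            inhibitory_fraction=float(p[5]),
            input_gain=float(p[6]),
            w_cap=float(p[7]),
            rng_seed=int(p[8]),
        )
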