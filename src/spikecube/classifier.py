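"""Dynamic-evolving output layer (deSNN-style) over cube state records.

Training grows one output neuron per training sample.  Its weight vector over
the cube neurons is set by rank-order coding: ordering cube neurons by first
spike time (ties broken by lowest neuron index), the r-th earliest spiker
gets weight mod^r (mod = 0.8 by default, so 1.0, 0.8, 0.64, ...), and
never-spiking neurons get 0.  Each neuron's weight then drifts up by
``drift`` (default 0.005) for every spike it emitted after its first, and is
floored at 0.  A test sample is labelled by the nearest output neuron(s) in
Euclidean distance between state vectors (k = 1 by default; majority vote for
larger k, ties resolved to the single nearest).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .reservoir import CubeStateRecord

DEFAULT_MOD = 0.8
DEFAULT_DRIFT = 0.005


@dataclass
class DeSNNModel:
    """One weight vector + label per training sample; the trained classifier."""

    weights: np.ndarray  # (n_output_neurons, N)
    labels: list[str]
    sample_ids: list[int]
    mod: float = DEFAULT_MOD
    drift: float = DEFAULT_DRIFT
    k: int = 1
    reservoir_fingerprint: str | None = None

    @property
    def n_output_neurons(self) -> int:
        return self.weights.shape[0]

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.labels)))


def state_vector(
    record: CubeStateRecord, mod: float = DEFAULT_MOD, drift: float = DEFAULT_DRIFT
) -> np.ndarray:
    """Rank-order weights (mod^rank over first-spike order) plus drift.

    Cube neurons are ranked by first spike time with ties broken by lowest
    index; rank r receives mod^r.  Every spike after a neuron's first adds
    ``drift``.  Never-spiking neurons stay at 0; the result is floored at 0.
    """
    if not 0.0 < mod < 1.0:
        raise ValueError("mod must lie in (0, 1)")
    if drift < 0.0:
        raise ValueError("drift must be >= 0")
    first = record.first_spike_time
    counts = record.spike_count
    n = first.shape[0]
    w = np.zeros(n, dtype=np.float64)
    spiked = np.nonzero(first >= 0)[0]
    if spiked.size == 0:
        warnings.warn("no spikes in record: state vector is all-zero", stacklevel=2)
        return w
    order = spiked[np.lexsort((spiked, first[spiked]))]
    w[order] = mod ** np.arange(order.size, dtype=np.float64)
    w[spiked] += drift * (counts[spiked] - 1)
    return np.maximum(w, 0.0)


def train(
    records: list[CubeStateRecord],
    labels: list[str],
    mod: float = DEFAULT_MOD,
    drift: float = DEFAULT_DRIFT,
    k: int = 1,
    sample_ids: list[int] | None = None,
    reservoir_fingerprint: str | None = None,
) -> DeSNNModel:
    """One output neuron per record, in training order."""
    if len(records) != len(labels):
        raise ValueError("records and labels must be parallel")
    if len(records) < 2:
        raise ValueError("need at least 2 training samples")
    if len(set(labels)) < 2:
        raise ValueError("training labels contain a single class; classification undefined")
    if k < 1:
        raise ValueError("k must be >= 1")
    weights = np.stack([state_vector(r, mod, drift) for r in records])
    return DeSNNModel(
        weights=weights,
        labels=list(labels),
        sample_ids=list(sample_ids) if sample_ids is not None else list(range(len(records))),
        mod=mod,
        drift=drift,
        k=k,
        reservoir_fingerprint=reservoir_fingerprint,
    )


def classify(
    model: DeSNNModel,
    record: CubeStateRecord,
    k: int | None = None,
    reservoir_fingerprint: str | None = None,
) -> str:
    """Label of the k nearest output neurons (Euclidean on state vectors).

    Majority vote for k > 1; any tie (in distance or in votes) resolves to
    the single nearest output neuron, and among equal distances to the lowest
    output-neuron index.
    """
    if (
        reservoir_fingerprint is not None
        and model.reservoir_fingerprint is not None
        and reservoir_fingerprint != model.reservoir_fingerprint
    ):
        raise ValueError("record comes from a different reservoir than the model")
    k = model.k if k is None else k
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sv = state_vector(record, model.mod, model.drift)
    if not np.any(sv):
        warnings.warn("all-zero test state vector", stacklevel=2)
    d = np.linalg.norm(model.weights - sv[None, :], axis=1)
    order = np.argsort(d, kind="stable")
    if k == 1:
        return model.labels[int(order[0])]
    top = [model.labels[int(i)] for i in order[:k]]
    counts = {c: top.count(c) for c in set(top)}
    winners = [c for c, n in counts.items() if n == max(counts.values())]
    if len(winners) > 1:
        return model.labels[int(order[0])]
    return winners[0]


def classify_batch(
    model: DeSNNModel,
    records: list[CubeStateRecord],
    k: int | None = None,
    reservoir_fingerprint: str | None = None,
) -> list[str]:
    return [classify(model, r, k, reservoir_fingerprint) for r in records]


def save_model(model: DeSNNModel, path: str | Path) -> None:
    """Serialise to a single ``.npz`` container, fingerprint included."""
    np.savez(
        path,
        weights=model.weights,
        labels=np.array(model.labels),
        sample_ids=np.array(model.sample_ids, dtype=np.int64),
        params=np.array([model.mod, model.drift, float(model.k)]),
        fingerprint=np.array(model.reservoir_fingerprint or ""),
    )


def load_model(path: str | Path) -> DeSNNModel:
    with np.load(path) as a:
        fp = str(a["fingerprint"])
        return DeSNNModel(
            weights=a["weights"],
            labels=[str(x) for x in a["labels"]],
            sample_ids=[int(x) for x in a["sample_ids"]],
            mod=float(a["params"][0]),
            drift=float(a["params"][1]),
            k=int(a["params"][2]),
            reservoir_fingerprint=fp or None,
        )
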