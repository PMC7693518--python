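"""Independent brute-force references used as oracles by the test suite.

These deliberately share no code with the package internals: the TBR
reference enumerates differences one by one in pure Python; the LIF/STDP
reference walks neurons and dict-keyed connections step by step, summing
synaptic input with math.fsum.
"""

from __future__ import annotations

import math
import statistics

import numpy as np


def reference_tbr(x, threshold_factor: float, mode: str = "relative"):
    """Enumerate signed threshold crossings of the first differences.

    Returns a list of (time_index, polarity) tuples for one channel.
    """
    x = [float(v) for v in np.asarray(x, dtype=np.float64)]
    diffs = [x[t] - x[t - 1] for t in range(1, len(x))]
    if mode == "relative":
        abs_d = [abs(d) for d in diffs]
        theta = threshold_factor * statistics.pstdev(abs_d) if len(abs_d) else 0.0
    else:
        theta = threshold_factor
    events = []
    for t, d in enumerate(diffs, start=1):
        if d > theta:
            events.append((t, 1))
        elif d < -theta:
            events.append((t, -1))
    return events


def reference_simulate(net, spikes, stdp_rate=None):
    """Naive step-by-step LIF (+ optional one-step STDP) simulator.

    Implements the documented dynamics contract: per step, decay by
    (1 - leak), add recurrent input from last step's spikes through the
    current weights, add signed external input, clamp refractory neurons at
    rest, fire at u >= threshold with reset-to-zero; during plasticity,
    potentiate pre(t-1)->post(t) pairs before depressing post(t-1)<-pre(t)
    pairs, each connection at most once per rule per step, clipped to
    [0, w_cap].  Returns (first_spike_times, spike_counts, magnitudes).
    """
    n = net.n_neurons
    conns = {}
    for i in range(n):
        for j in range(n):
            if net.signs[i, j] != 0:
                conns[(i, j)] = [int(net.signs[i, j]), float(net.magnitudes[i, j])]
    incoming = {}
    for (i, j) in conns:
        incoming.setdefault(j, []).append(i)

    events = {}
    for ch, ts, ps in zip(spikes.channel_names, spikes.times, spikes.polarities):
        site = net.geometry.input_map[ch]
        for t, p in zip(ts, ps):
            events.setdefault(int(t), []).append((site, int(p)))

    u = [0.0] * n
    refr = [0] * n
    first = [-1] * n
    counts = [0] * n
    prev: set[int] = set()
    for t in range(spikes.n_timepoints):
        for j in range(n):
            u[j] *= 1.0 - net.leak
        for j in range(n):
            terms = [
                conns[(i, j)][0] * conns[(i, j)][1]
                for i in incoming.get(j, [])
                if i in prev
            ]
            if terms:
                u[j] += math.fsum(terms)
        for site, pol in events.get(t, []):
            u[site] += net.input_gain * pol
        fired = []
        for j in range(n):
            if refr[j] > 0:
                u[j] = 0.0
            elif u[j] >= net.firing_threshold:
                fired.append(j)
        if stdp_rate is not None:
            for i in prev:
                for j in fired:
                    if (i, j) in conns:
                        conns[(i, j)][1] = min(conns[(i, j)][1] + stdp_rate, net.w_cap)
            for i in fired:
                for j in prev:
                    if (i, j) in conns:
                        conns[(i, j)][1] = max(conns[(i, j)][1] - stdp_rate, 0.0)
        for j in range(n):
            if refr[j] > 0:
                refr[j] -= 1
        for j in fired:
            if first[j] < 0:
                first[j] = t
            counts[j] += 1
            u[j] = 0.0
            refr[j] = net.refractory
        prev = set(fired)

    magnitudes = net.magnitudes.copy()
    for (i, j), (_, m) in conns.items():
        magnitudes[i, j] = m
    return np.array(first), np.array(counts), magnitudes


def random_spike_train_set(rng, channels, n_timepoints, density=0.2, signed=True):
    """Random spike trains (signed by default) for oracle comparisons."""
    from spikecube.encoding import SpikeTrainSet

    times, pols = [], []
    for _ in channels:
        mask = rng.random(n_timepoints - 1) < density
        idx = np.nonzero(mask)[0] + 1
        times.append(idx.astype(np.int64))
        if signed:
            pols.append(rng.choice(np.array([-1, 1], dtype=np.int8), size=len(idx)))
        else:
            pols.append(np.ones(len(idx), dtype=np.int8))
    return SpikeTrainSet(
        channel_names=tuple(channels),
        times=tuple(times),
        polarities=tuple(pols),
        n_timepoints=n_timepoints,
    )
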