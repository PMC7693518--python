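"""Threshold-based representation (TBR) spike encoding of EEG segments.

TBR turns a continuous signal into a signed event train: a +1 spike wherever
the step-to-step change exceeds a threshold, a -1 spike wherever it falls
below the negative threshold.  The threshold factor of 0.5 is interpreted, by
default, relative to each channel's own difference statistics
(theta = factor * sd(|diff|)), which makes the encoding invariant to overall
amplitude scaling; an absolute mode (theta = factor in signal units) is also
available.  Encoding is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import LabeledSampleSet, TrialSample

DEFAULT_THRESHOLD_FACTOR = 0.5

_MODES = ("relative", "absolute")


@dataclass
class SpikeTrainSet:
    """Per-channel signed spike events for one encoded sample.

    ``times[c]`` holds strictly increasing sample indices (>= 1, since events
    sit on first differences) and ``polarities[c]`` the matching +1/-1 signs.
    """

    channel_names: tuple[str, ...]
    times: tuple[np.ndarray, ...]
    polarities: tuple[np.ndarray, ...]
    n_timepoints: int

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    @property
    def n_events(self) -> int:
        return int(sum(len(t) for t in self.times))

    def events_per_channel(self) -> dict[str, int]:
        return {ch: len(t) for ch, t in zip(self.channel_names, self.times)}

    def validate(self) -> None:
        for ch, t, p in zip(self.channel_names, self.times, self.polarities):
            if len(t) != len(p):
                raise ValueError(f"channel {ch}: times/polarities length mismatch")
            if len(t) and (t[0] < 1 or t[-1] > self.n_timepoints - 1):
                raise ValueError(f"channel {ch}: event time out of range")
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"channel {ch}: event times not strictly increasing")
            if np.any(np.abs(p) != 1):
                raise ValueError(f"channel {ch}: polarity must be +/-1")

    def to_tsv(self, path: str | Path) -> None:
        """Write the columnar text format: channel, time_index, polarity."""
        lines = [
            f"# n_timepoints={self.n_timepoints}",
            f"# channels={','.join(self.channel_names)}",
            "channel\ttime_index\tpolarity",
        ]
        for ch, t, p in zip(self.channel_names, self.times, self.polarities):
            lines.extend(f"{ch}\t{int(ti)}\t{int(pi)}" for ti, pi in zip(t, p))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SpikeTrainSet":
        n_timepoints = None
        channels: tuple[str, ...] = ()
        events: dict[str, list[tuple[int, int]]] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("# n_timepoints="):
                n_timepoints = int(line.split("=", 1)[1])
            elif line.startswith("# channels="):
                channels = tuple(line.split("=", 1)[1].split(","))
                events = {ch: [] for ch in channels}
            elif line.startswith("channel\t"):
                continue
            else:
                ch, t, p = line.split("\t")
                events[ch].append((int(t), int(p)))
        if n_timepoints is None or not channels:
            raise ValueError(f"{path}: missing header lines")
        times = tuple(
            np.array([t for t, _ in events[ch]], dtype=np.int64) for ch in channels
        )
        pols = tuple(
            np.array([p for _, p in events[ch]], dtype=np.int8) for ch in channels
        )
        return cls(
            channel_names=channels, times=times, polarities=pols, n_timepoints=n_timepoints
        )


def tbr_encode(
    sample: TrialSample | np.ndarray,
    threshold_factor: float = DEFAULT_THRESHOLD_FACTOR,
    mode: str = "relative",
    channel_names: tuple[str, ...] | None = None,
) -> SpikeTrainSet:
    """Encode one multi-channel segment into signed spike trains.

    Per channel, first differences d(t) = x(t) - x(t-1) are compared against
    theta = ``threshold_factor`` * sd(|d|) (relative mode, default) or
    theta = ``threshold_factor`` in signal units (absolute mode): d(t) > theta
    emits +1 at t, d(t) < -theta emits -1.  An all-constant channel yields no
    events (sd = 0 is not an error).
    """
    if threshold_factor <= 0:
        raise ValueError("threshold_factor must be > 0")
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}")
    values = sample.values if isinstance(sample, TrialSample) else np.asarray(sample)
    if values.ndim == 1:
        values = values[None, :]
    if not np.all(np.isfinite(values)):
        raise ValueError("sample contains non-finite values")
    n_ch, n_t = values.shape
    if channel_names is None:
        channel_names = tuple(f"ch{i}" for i in range(n_ch))
    if len(channel_names) != n_ch:
        raise ValueError("channel_names length does not match sample")

    times: list[np.ndarray] = []
    pols: list[np.ndarray] = []
    for c in range(n_ch):
        d = np.diff(values[c].astype(np.float64))
        theta = (
            threshold_factor * float(np.std(np.abs(d)))
            if mode == "relative"
            else float(threshold_factor)
        )
        pos = d > theta
        neg = d < -theta
        idx = np.nonzero(pos | neg)[0]
        times.append((idx + 1).astype(np.int64))
        pols.append(np.where(pos[idx], 1, -1).astype(np.int8))
    out = SpikeTrainSet(
        channel_names=tuple(channel_names),
        times=tuple(times),
        polarities=tuple(pols),
        n_timepoints=n_t,
    )
    out.validate()
    return out


def encode_set(
    samples: LabeledSampleSet,
    threshold_factor: float = DEFAULT_THRESHOLD_FACTOR,
    mode: str = "relative",
) -> list[SpikeTrainSet]:
    """Order-preserving TBR encoding of every sample in a set.

    The per-channel threshold is computed independently for each sample.
    """
    return [
        tbr_encode(s, threshold_factor, mode, channel_names=samples.channel_names)
        for s in samples.samples
    ]
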