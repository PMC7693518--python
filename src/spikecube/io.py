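"""Reading DEAP-style datasets and constructing the experiment sample sets.

The experiments operate on small subsets of the 1280-trial DEAP layout: four
channels (FP1, F3, C4, C3), a 1152-point window starting at 34 s into each
trial, and ratings binarised at 5 into low/high on the valence or arousal
dimension.  Four named presets select 40- or 60-sample subsets by participant
and trial ranges; a seeded stratified permutation split divides each set
80/20 into train and test.
"""

from __future__ import annotations

import dataclasses
import math
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataFormatError
from .synthetic import (
    DEAP_CHANNELS,
    DEFAULT_RATING_THRESHOLD,
    FS,
    RATING_COLUMNS,
    RATING_MAX,
    RATING_MIN,
    DeapStyleDataset,
    Participant,
    _METADATA_FILENAME,
)

#: The four channels used as raw features, in the order they are listed.
EXPERIMENT_CHANNELS: tuple[str, ...] = ("FP1", "F3", "C4", "C3")

#: Window: 1152 points starting at 34 s (the stated point count wins over the
#: stated 42 s end, which would give only 1024 points at 128 Hz).
WINDOW_START_S = 34.0
WINDOW_LEN_POINTS = 1152

PRESET_NAMES = ("Exp1", "Exp2", "Exp3", "Exp4")


@dataclass
class ExperimentSpec:
    """Everything needed to carve a labelled sample set out of a dataset."""

    name: str
    participant_indices: tuple[int, ...]
    trial_indices: tuple[int, ...]
    channels: tuple[str, ...] = EXPERIMENT_CHANNELS
    window_start_s: float = WINDOW_START_S
    window_len_points: int = WINDOW_LEN_POINTS
    dimension: str = "valence"
    rating_threshold: float = DEFAULT_RATING_THRESHOLD
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.dimension not in ("valence", "arousal"):
            raise ValueError("dimension must be 'valence' or 'arousal'")

    @property
    def n_samples(self) -> int:
        return len(self.participant_indices) * len(self.trial_indices)


@dataclass
class TrialSample:
    """One extracted EEG segment (channels x window points) with provenance."""

    values: np.ndarray
    participant_id: int
    trial_id: int


@dataclass
class LabeledSampleSet:
    """Ordered samples with parallel low/high labels on one dimension."""

    samples: list[TrialSample]
    labels: list[str]
    dimension: str
    channel_names: tuple[str, ...] = EXPERIMENT_CHANNELS

    def __len__(self) -> int:
        return len(self.samples)

    def class_counts(self) -> dict[str, int]:
        return {c: self.labels.count(c) for c in ("low", "high")}


@dataclass
class SplitIndices:
    """Disjoint train/test index lists covering a sample set."""

    train_ids: list[int]
    test_ids: list[int]
    seed: int


def _read_metadata(directory: Path) -> dict[str, str]:
    path = directory / _METADATA_FILENAME
    meta: dict[str, str] = {}
    if path.exists():
        for line in path.read_text().splitlines():
            line = line.strip()
            if line and "=" in line:
                key, _, value = line.partition("=")
                meta[key.strip()] = value.strip()
    return meta


def load_deap(directory: str | Path) -> DeapStyleDataset:
    """Load a DEAP-style directory of per-participant ``.npz`` files.

    Files are taken in filename order; each must hold a 3-D ``data`` array and
    a matching ``labels`` array of shape (n_trials, 4) with ratings in [1, 9].
    Shapes are validated against the ``metadata.txt`` sidecar when present
    (and against the DEAP defaults of 32 channels x 8064 points otherwise).
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise DataFormatError(f"not a directory: {directory}")
    files = sorted(directory.glob("*.npz"))
    if not files:
        raise DataFormatError(f"no participants found in {directory}")

    meta = _read_metadata(directory)
    fs = int(meta.get("fs", FS))
    channels = tuple(meta["channels"].split(",")) if "channels" in meta else DEAP_CHANNELS
    n_timepoints = int(meta.get("n_timepoints", 63 * fs))
    n_trials_expected = int(meta["n_trials"]) if "n_trials" in meta else None

    participants: list[Participant] = []
    for path in files:
        with np.load(path) as archive:
            if "data" not in archive or "labels" not in archive:
                raise DataFormatError(f"{path.name}: missing 'data' or 'labels' array")
            data = archive["data"]
            labels = archive["labels"]
        if data.ndim != 3:
            raise DataFormatError(f"{path.name}: 'data' must be 3-D, got {data.shape}")
        n_trials, n_ch, n_t = data.shape
        if n_ch != len(channels):
            raise DataFormatError(
                f"{path.name}: {n_ch} channels, expected {len(channels)}"
            )
        if n_t != n_timepoints:
            raise DataFormatError(
                f"{path.name}: {n_t} time points, expected {n_timepoints}"
            )
        if n_trials_expected is not None and n_trials != n_trials_expected:
            raise DataFormatError(
                f"{path.name}: {n_trials} trials, expected {n_trials_expected}"
            )
        if labels.shape != (n_trials, 4):
            raise DataFormatError(
                f"{path.name}: 'labels' must be ({n_trials}, 4), got {labels.shape}"
            )
        if np.any(labels < RATING_MIN) or np.any(labels > RATING_MAX):
            raise DataFormatError(f"{path.name}: rating outside [1, 9]")
        participants.append(
            Participant(
                eeg=data,
                ratings=pd.DataFrame(labels, columns=list(RATING_COLUMNS)),
            )
        )
    return DeapStyleDataset(participants=participants, channel_names=channels, fs=fs)


def load_deap_python(directory: str | Path) -> DeapStyleDataset:
    """Adapter for the real DEAP "python preprocessed" per-participant files.

    Reads ``s??.dat`` pickles holding ``data`` (40 x 40 x 8064; 32 EEG + 8
    peripheral channels) and ``labels`` (40 x 4), keeps the 32 EEG channels,
    and returns the same :class:`DeapStyleDataset` the synthetic layout yields.
    Requires the (access-restricted) DEAP download; untouched by the test suite.
    """
    directory = Path(directory)
    files = sorted(directory.glob("s*.dat"))
    if not files:
        raise DataFormatError(f"no DEAP .dat files found in {directory}")
    participants = []
    for path in files:
        with open(path, "rb") as fh:
            record = pickle.load(fh, encoding="latin1")
        data = np.asarray(record["data"])[:, : len(DEAP_CHANNELS), :]
        labels = np.asarray(record["labels"], dtype=np.float64)
        participants.append(
            Participant(eeg=data, ratings=pd.DataFrame(labels, columns=list(RATING_COLUMNS)))
        )
    return DeapStyleDataset(participants=participants, channel_names=DEAP_CHANNELS, fs=FS)


def experiment_preset(name: str, dimension: str = "valence", seed: int = 0) -> ExperimentSpec:
    """Return one of the four named experiment subsets.

    Exp1: trials 1-10 of participants 1-6 (60 samples).
    Exp2: trials 1-10 of participants 1-4 (40 samples).
    Exp3: trials 11-20 of participants 7-12 (60 samples).
    Exp4: the first 40 samples of Exp3's enumeration, i.e. trials 11-20 of
    participants 7-10.  (1-based ranges as conventionally described; indices
    are 0-based internally.)
    """
    key = name.strip().lower()
    presets = {
        "exp1": (range(0, 6), range(0, 10)),
        "exp2": (range(0, 4), range(0, 10)),
        "exp3": (range(6, 12), range(10, 20)),
        "exp4": (range(6, 10), range(10, 20)),
    }
    if key not in presets:
        raise ValueError(f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}")
    participants, trials = presets[key]
    return ExperimentSpec(
        name=PRESET_NAMES[int(key[-1]) - 1],
        participant_indices=tuple(participants),
        trial_indices=tuple(trials),
        dimension=dimension,
        seed=seed,
    )


def _channel_indices(channel_names: tuple[str, ...], wanted: tuple[str, ...]) -> list[int]:
    lookup = {name.lower(): i for i, name in enumerate(channel_names)}
    indices = []
    for ch in wanted:
        if ch.lower() not in lookup:
            raise ValueError(f"channel {ch!r} not present in dataset montage")
        indices.append(lookup[ch.lower()])
    return indices


def build_samples(ds: DeapStyleDataset, spec: ExperimentSpec) -> LabeledSampleSet:
    """Extract the spec's channels and window for every (participant, trial).

    Labels are high iff the trial's rating on ``spec.dimension`` is >= the
    threshold, else low; the EEG values themselves are sliced untouched.
    Enumeration is participant-major in spec order.
    """
    chan_idx = _channel_indices(ds.channel_names, spec.channels)
    start = int(round(spec.window_start_s * ds.fs))
    stop = start + spec.window_len_points
    dim = spec.dimension

    samples: list[TrialSample] = []
    labels: list[str] = []
    for p_idx in spec.participant_indices:
        if not 0 <= p_idx < ds.n_participants:
            raise ValueError(f"participant index {p_idx} out of range")
        participant = ds.participants[p_idx]
        if stop > participant.eeg.shape[2]:
            raise ValueError(
                f"window [{start}, {stop}) exceeds trial length {participant.eeg.shape[2]}"
            )
        for t_idx in spec.trial_indices:
            if not 0 <= t_idx < participant.n_trials:
                raise ValueError(f"trial index {t_idx} out of range")
            values = participant.eeg[t_idx, chan_idx, start:stop]
            if not np.all(np.isfinite(values)):
                raise ValueError(
                    f"non-finite values in participant {p_idx}, trial {t_idx}"
                )
            rating = float(participant.ratings.iloc[t_idx][dim])
            samples.append(TrialSample(values=values, participant_id=p_idx, trial_id=t_idx))
            labels.append("high" if rating >= spec.rating_threshold else "low")
    return LabeledSampleSet(
        samples=samples, labels=labels, dimension=dim, channel_names=spec.channels
    )


def split_train_test(
    sample_set: LabeledSampleSet | list[str],
    train_fraction: float = 0.8,
    seed: int = 0,
    stratify: bool = True,
) -> SplitIndices:
    """Seeded permutation split into train/test index lists.

    Train size is floor(train_fraction * n).  In stratified mode (default)
    the split is per class, with floor remainders assigned to the classes
    with the largest fractional parts, and adjusted so that every class with
    at least two members keeps at least one sample on each side.
    """
    labels = sample_set.labels if isinstance(sample_set, LabeledSampleSet) else list(sample_set)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    n_train = math.floor(train_fraction * n)
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)

    if not stratify:
        perm = rng.permutation(n)
        return SplitIndices(
            train_ids=sorted(int(i) for i in perm[:n_train]),
            test_ids=sorted(int(i) for i in perm[n_train:]),
            seed=seed,
        )

    classes = sorted(set(labels))
    by_class = {c: [i for i, lab in enumerate(labels) if lab == c] for c in classes}
    quotas: dict[str, int] = {}
    fracs: list[tuple[float, str]] = []
    for c in classes:
        exact = train_fraction * len(by_class[c])
        quotas[c] = math.floor(exact)
        fracs.append((exact - quotas[c], c))
    # top up to n_train, largest fractional part first (ties by class name)
    fracs.sort(key=lambda t: (-t[0], t[1]))
    i = 0
    while sum(quotas.values()) < n_train and i < len(fracs):
        c = fracs[i][1]
        if quotas[c] < len(by_class[c]):
            quotas[c] += 1
        i += 1
    for c in classes:
        n_c = len(by_class[c])
        if n_c >= 2:
            quotas[c] = min(max(quotas[c], 1), n_c - 1)

    train_ids: list[int] = []
    test_ids: list[int] = []
    for c in classes:
        idx = np.array(by_class[c])
        perm = idx[rng.permutation(len(idx))]
        train_ids.extend(int(i) for i in perm[: quotas[c]])
        test_ids.extend(int(i) for i in perm[quotas[c]:])
    return SplitIndices(train_ids=sorted(train_ids), test_ids=sorted(test_ids), seed=seed)
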