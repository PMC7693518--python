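"""Synthetic DEAP-format EEG generation.

The DEAP benchmark ships, per participant, a 40-trial x 32-channel x 8064-point
array of preprocessed EEG (128 Hz, 4-45 Hz passband, 63 s per trial) and a
40 x 4 table of self-reported ratings (valence, arousal, dominance, liking) on
a continuous 1-9 scale.  This module emulates exactly that layout with a
controllable class-dependent signal: each trial is assigned a low or high
class on one affective dimension, receives a class-specific narrow-band
oscillation plus white noise on every channel, and a rating drawn from that
class's distribution.  The point is not EEG realism but a dataset in which the
class structure is known, tunable, and reachable by a spike encoder, so the
whole downstream pipeline is testable without any download.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: DEAP sampling rate after down-sampling, Hz.
FS = 128

#: Samples per trial: 63 s at 128 Hz.
N_TIMEPOINTS = 63 * FS

#: The 32 EEG channels of the DEAP montage, in DEAP (Geneva) order.
DEAP_CHANNELS: tuple[str, ...] = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "Cz",
    "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2",
)

RATING_COLUMNS: tuple[str, ...] = ("valence", "arousal", "dominance", "liking")

#: DEAP preprocessing passband, Hz; synthetic oscillations must lie inside it.
PASSBAND = (4.0, 45.0)

RATING_MIN, RATING_MAX = 1.0, 9.0

#: Low/high split point on the 1-9 rating scale.
DEFAULT_RATING_THRESHOLD = 5.0

CLASSES = ("low", "high")

_METADATA_FILENAME = "metadata.txt"


@dataclass(frozen=True)
class ClassSignalParams:
    """Generative parameters for one class (low or high) of trials.

    Parameters
    ----------
    band_center
        Centre frequency of the class oscillation, Hz.  Must lie in the DEAP
        passband (4-45 Hz).  Default 10 Hz (alpha-band-like).
    band_amplitude
        Amplitude of the oscillation (signal units).
    noise_sd
        Standard deviation of the additive white noise, independent per
        channel and sample.
    amplitude_jitter_sd
        Per-trial Gaussian jitter on ``band_amplitude``.
    rating_mean, rating_sd
        Distribution of the trial's self-report rating on the generated
        dimension; ratings are clipped to [1, 9].
    """

    band_center: float = 10.0
    band_amplitude: float = 1.0
    noise_sd: float = 0.5
    amplitude_jitter_sd: float = 0.1
    rating_mean: float = 5.0
    rating_sd: float = 1.0

    def __post_init__(self) -> None:
        if not (PASSBAND[0] <= self.band_center <= PASSBAND[1]):
            raise ValueError(
                f"band_center {self.band_center} Hz outside the "
                f"{PASSBAND[0]}-{PASSBAND[1]} Hz passband"
            )
        for name in ("noise_sd", "amplitude_jitter_sd", "rating_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.band_amplitude < 0:
            raise ValueError("band_amplitude must be >= 0")


@dataclass
class Participant:
    """One participant: EEG array [n_trials x n_channels x n_timepoints] and
    a ratings table [n_trials x 4] with columns valence/arousal/dominance/liking."""

    eeg: np.ndarray
    ratings: pd.DataFrame

    @property
    def n_trials(self) -> int:
        return self.eeg.shape[0]


@dataclass
class DeapStyleDataset:
    """A collection of participants sharing a montage and sampling rate.

    The common currency of real and synthetic inputs: the loader for on-disk
    DEAP-style directories and the synthetic generator both produce this.
    """

    participants: list[Participant]
    channel_names: tuple[str, ...] = DEAP_CHANNELS
    fs: int = FS

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def validate(self) -> None:
        for i, p in enumerate(self.participants):
            if p.eeg.ndim != 3:
                raise ValueError(f"participant {i}: EEG must be 3-D")
            if p.eeg.shape[1] != self.n_channels:
                raise ValueError(
                    f"participant {i}: {p.eeg.shape[1]} channels, "
                    f"expected {self.n_channels}"
                )
            if len(p.ratings) != p.n_trials:
                raise ValueError(f"participant {i}: ratings/trials mismatch")
            vals = p.ratings.to_numpy()
            if np.any(vals < RATING_MIN) or np.any(vals > RATING_MAX):
                raise ValueError(f"participant {i}: rating outside [1, 9]")


def default_class_params() -> dict[str, ClassSignalParams]:
    """Moderately separated low/high classes around the rating threshold of 5."""
    return {
        "low": ClassSignalParams(band_amplitude=0.5, rating_mean=3.0),
        "high": ClassSignalParams(band_amplitude=1.5, rating_mean=7.0),
    }


def strongly_separated_params() -> dict[str, ClassSignalParams]:
    """A large-amplitude-gap, noise-free-rating condition.

    High class: 10 Hz oscillation of amplitude 2.0; low class: amplitude 0.2;
    both on noise of sd 0.2, no amplitude jitter, ratings exactly at 8 / 2.
    Used as the clearly-separable regime for end-to-end checks.
    """
    return {
        "low": ClassSignalParams(
            band_amplitude=0.2, noise_sd=0.2, amplitude_jitter_sd=0.0,
            rating_mean=2.0, rating_sd=0.0,
        ),
        "high": ClassSignalParams(
            band_amplitude=2.0, noise_sd=0.2, amplitude_jitter_sd=0.0,
            rating_mean=8.0, rating_sd=0.0,
        ),
    }


def generate_dataset(
    n_participants: int,
    n_trials: int = 40,
    params_by_class: dict[str, ClassSignalParams] | None = None,
    dimension: str = "valence",
    seed: int = 0,
    n_channels: int | None = None,
    rating_threshold: float = DEFAULT_RATING_THRESHOLD,
) -> DeapStyleDataset:
    """Generate a seeded DEAP-format dataset with two-class signal structure.

    Each trial is randomly (seeded) assigned to the low or high class of
    ``dimension``.  Its EEG is ``amplitude * sin(2*pi*f*t + phase)`` on every
    channel (amplitude jittered per trial, phase random per trial) plus
    channel-independent white noise.  Its rating on ``dimension`` is drawn
    from the class's rating distribution and clipped to [1, 9]; the other
    three rating columns are uniform on [1, 9].

    Returns a :class:`DeapStyleDataset` of ``n_participants`` participants,
    each ``n_trials x 32 x 8064`` at 128 Hz (float32).
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if dimension not in RATING_COLUMNS[:2]:
        raise ValueError("dimension must be 'valence' or 'arousal'")
    params = params_by_class if params_by_class is not None else default_class_params()
    if set(params) != set(CLASSES):
        raise ValueError(f"params_by_class must have exactly the keys {CLASSES}")
    if not params["high"].rating_mean > rating_threshold:
        raise ValueError("high-class rating_mean must exceed the rating threshold")
    if not params["low"].rating_mean < rating_threshold:
        raise ValueError("low-class rating_mean must be below the rating threshold")

    channels = DEAP_CHANNELS if n_channels is None else DEAP_CHANNELS[:n_channels]
    n_ch = len(channels)
    rng = np.random.default_rng(seed)
    t = np.arange(N_TIMEPOINTS, dtype=np.float64) / FS
    dim_col = RATING_COLUMNS.index(dimension)

    participants: list[Participant] = []
    for _ in range(n_participants):
        eeg = np.empty((n_trials, n_ch, N_TIMEPOINTS), dtype=np.float32)
        ratings = np.empty((n_trials, 4), dtype=np.float64)
        for trial in range(n_trials):
            cls = CLASSES[rng.integers(0, 2)]
            p = params[cls]
            amp = max(p.band_amplitude + rng.normal(0.0, p.amplitude_jitter_sd), 0.0)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            wave = amp * np.sin(2.0 * np.pi * p.band_center * t + phase)
            noise = rng.normal(0.0, p.noise_sd, size=(n_ch, N_TIMEPOINTS))
            eeg[trial] = (wave[None, :] + noise).astype(np.float32)
            ratings[trial] = rng.uniform(RATING_MIN, RATING_MAX, size=4)
            ratings[trial, dim_col] = np.clip(
                rng.normal(p.rating_mean, p.rating_sd), RATING_MIN, RATING_MAX
            )
        participants.append(
            Participant(eeg=eeg, ratings=pd.DataFrame(ratings, columns=list(RATING_COLUMNS)))
        )
    ds = DeapStyleDataset(participants=participants, channel_names=channels, fs=FS)
    ds.validate()
    return ds


def write_deap_format(ds: DeapStyleDataset, directory: str | Path) -> list[Path]:
    """Write one container file per participant plus a metadata sidecar.

    Layout: ``s01.npz``, ``s02.npz``, ... each holding the arrays ``data``
    [n_trials x n_channels x n_timepoints] and ``labels`` [n_trials x 4]
    (valence, arousal, dominance, liking), plus ``metadata.txt`` with
    ``key=value`` lines for fs, n_trials, n_timepoints and the channel list.
    Round-trips bit-exactly through :func:`spikecube.io.load_deap`.
    """
    if not ds.participants:
        raise ValueError("refusing to write an empty dataset")
    ds.validate()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    for i, p in enumerate(ds.participants):
        path = directory / f"s{i + 1:02d}.npz"
        np.savez(path, data=p.eeg, labels=p.ratings.to_numpy())
        paths.append(path)
    first = ds.participants[0]
    meta = (
        f"fs={ds.fs}\n"
        f"n_trials={first.n_trials}\n"
        f"n_timepoints={first.eeg.shape[2]}\n"
        f"channels={','.join(ds.channel_names)}\n"
    )
    (directory / _METADATA_FILENAME).write_text(meta)
    return paths
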