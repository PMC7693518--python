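import numpy as np
import pandas as pd
import pytest

from spikecube import io, reservoir, synthetic


@pytest.fixture(scope="session")
def tiny_dataset():
    """2 participants x 6 trials, full DEAP trial shape, default class params."""
    return synthetic.generate_dataset(2, 6, seed=123)


@pytest.fixture(scope="session")
def separable_dataset():
    """6 participants x 10 trials under the strongly separated condition."""
    return synthetic.generate_dataset(
        6, 10, synthetic.strongly_separated_params(), seed=321
    )


@pytest.fixture
def short_spec():
    """A small extraction spec: 2 participants x 4 trials, 256-point window."""
    return io.ExperimentSpec(
        name="short",
        participant_indices=(0, 1),
        trial_indices=(0, 1, 2, 3),
        window_start_s=1.0,
        window_len_points=256,
    )


@pytest.fixture(scope="session")
def small_geometry():
    return reservoir.build_geometry(27, (3, 3, 3), channels=("FP1", "C4"))


@pytest.fixture
def small_net(small_geometry):
    return reservoir.init_connections(
        small_geometry, radius=1.8, conn_prob=0.5, seed=11
    )


def make_manual_dataset(ratings_valence, n_channels=8, n_timepoints=512, seed=0):
    """A hand-built dataset with fully controlled valence ratings."""
    rng = np.random.default_rng(seed)
    n_trials = len(ratings_valence)
    ratings = rng.uniform(1, 9, size=(n_trials, 4))
    ratings[:, 0] = ratings_valence
    eeg = rng.normal(0, 1, size=(n_trials, n_channels, n_timepoints)).astype(np.float32)
    participant = synthetic.Participant(
        eeg=eeg,
        ratings=pd.DataFrame(ratings, columns=list(synthetic.RATING_COLUMNS)),
    )
    return synthetic.DeapStyleDataset(
        participants=[participant],
        channel_names=synthetic.DEAP_CHANNELS[:n_channels],
        fs=synthetic.FS,
    )
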