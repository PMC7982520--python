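import numpy as np
import pytest

from erpdecode.io import EpochSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_epochs(
    n_trials=6,
    channel_names=("Fz", "Cz", "Pz", "Oz"),
    sampling_rate=100.0,
    epoch_window=(-200.0, 800.0),
    labels="auto",
    seed=0,
    scale=5.0,
):
    """Small random EpochSet for unit tests."""
    gen = np.random.default_rng(seed)
    n_samples = int(round((epoch_window[1] - epoch_window[0]) / 1000.0 * sampling_rate))
    data = scale * gen.standard_normal((n_trials, len(channel_names), n_samples))
    if isinstance(labels, str) and labels == "auto":
        labels = np.asarray(["accept", "reject"] * (n_trials // 2 + 1))[:n_trials]
    return EpochSet(
        data=data,
        channel_names=list(channel_names),
        sampling_rate=sampling_rate,
        epoch_window=epoch_window,
        labels=labels,
        subject_id="unit",
    )


@pytest.fixture
def small_epochs():
    return make_epochs()
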