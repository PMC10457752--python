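import numpy as np
import pytest

import pulsesite as ps
from pulsesite import experiment, segment


@pytest.fixture(scope="session")
def study_recordings():
    """The study-condition dataset: 3 x 60 s recordings per artery class."""
    return ps.make_dataset(None, n_recordings_per_class=3, seed=11,
                           duration=60.0)


@pytest.fixture(scope="session")
def windows_100k(study_recordings):
    """Conditioned, peak-centered period windows of the 100 kHz EBI channel."""
    return experiment.windows_for_channel(study_recordings, "z_100k")


@pytest.fixture(scope="session")
def xy_100k(windows_100k):
    return segment.windows_to_arrays(windows_100k)


@pytest.fixture
def clean_config():
    """A noise-, drift- and jitter-free recording configuration."""
    return ps.default_config("D", seed=7, noise_sd=0.0, drift_amp=0.0,
                             rppg_noise_sd=0.0, rppg_drift_amp=0.0,
                             resp_mod_depth=0.0, heart_rate_sd=0.0)


def binomial_band(p: float, n: int, z: float = 2.576) -> float:
    """Half-width of the z-sigma binomial band around p at sample size n."""
    return z * np.sqrt(p * (1 - p) / n)
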