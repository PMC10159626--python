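import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from wormmem.study import study_effects, study_trace_config, study_track_config
from wormmem.synthetic import gen_trace_dataset, gen_track_dataset


@pytest.fixture(scope="session")
def planted_dataset():
    """Canonical planted trace dataset: 5 groups x 15 animals x 6 neurons."""
    cfg = study_trace_config(seed=20259)
    records, schedule, truth = gen_trace_dataset(cfg, study_effects())
    return records, schedule, truth


@pytest.fixture(scope="session")
def planted_tracks():
    """Canonical planted track dataset: 3 locomotion groups x 40 tracks."""
    cfg = study_track_config(seed=777)
    tracks, truth = gen_track_dataset(cfg)
    return tracks, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
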