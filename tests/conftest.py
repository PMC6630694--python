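import sys
import warnings
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from pcgkit.io import PCGRecord
from pcgkit.synthetic import SyntheticConfig, generate_dataset, generate_pcg


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def normal_record():
    """10 s normal synthetic record at 60 bpm, seed 7."""
    return generate_pcg(SyntheticConfig(seed=7, duration_s=10.0,
                                        heart_rate_bpm=60.0), "normal")


@pytest.fixture(scope="session")
def abnormal_record():
    return generate_pcg(SyntheticConfig(seed=7, duration_s=10.0,
                                        heart_rate_bpm=60.0), "abnormal")


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """8 normal / 4 abnormal records on disk with a manifest."""
    out = tmp_path_factory.mktemp("dataset")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cfg = SyntheticConfig(duration_s=8.0)
        manifest = generate_dataset(8, 4, out, cfg, seed=11)
    return manifest


@pytest.fixture
def tone_record():
    """Pure 100 Hz tone, 2 s at 2000 Hz (integer number of periods)."""
    t = np.arange(4000) / 2000.0
    return PCGRecord("tone100", 0.5 * np.sin(2 * np.pi * 100 * t), 2000)
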