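import numpy as np
import pytest

from stratmix.binning import bin_rts
from stratmix.simulate import ParticipantDataset, baseline_config, generate_participant


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def baseline_participant():
    """One baseline two-state participant (500 trials) with its 20-bin view."""
    cfg = baseline_config(master_seed=7)
    ds = generate_participant(cfg, np.random.default_rng(7))
    return cfg, ds, bin_rts(ds.rt_ms, cfg.n_bins)


@pytest.fixture()
def tiny_dataset():
    """Ten fixed trials for brute-force emission/likelihood oracles."""
    rt = np.array([420.0, 510.0, 640.0, 705.0, 560.0, 900.0, 1010.0, 450.0, 620.0, 770.0])
    correct = np.array([1, 0, 1, 1, 0, 1, 1, 0, 1, 1])
    return ParticipantDataset("tiny", rt, correct, None)
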