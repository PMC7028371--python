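import numpy as np
import pytest

import smkinetics as smk


@pytest.fixture(scope="session")
def small_recording():
    """A quick reference-condition recording shared across read-only tests."""
    cfg = smk.SimConfig(seed=123, n_dna_locations=150, n_control_locations=150)
    rec, truth = smk.simulate_cosmos_recording(cfg)
    return cfg, rec, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
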