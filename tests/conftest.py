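import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def two_module_subject():
    """Noise-free two-module synthetic subject, shared across tests."""
    from modwalk import synth

    config = synth.SyntheticSubjectConfig(true_n_modules=2, noise_sd=0.0, seed=7)
    truth = synth.make_truth_templates(2, 7)
    rec, events = synth.generate_emg(config, truth)
    return config, truth, rec, events
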