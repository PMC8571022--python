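import numpy as np
import pytest

import eegstates as es


@pytest.fixture(scope="session")
def small_recording():
    """16-channel, 20-s, 250 Hz synthetic recording with ground truth."""
    cfg = es.GeneratorConfig(
        n_channels=16, sampling_rate=250.0, duration=20.0, noise_sigma=0.1, seed=101
    )
    rec, gt = es.simulate_subject(cfg)
    return rec, gt, cfg


@pytest.fixture(scope="session")
def clean_epochs(small_recording):
    rec, gt, cfg = small_recording
    return es.epoch(es.rereference_average(rec), 2.0)


@pytest.fixture(scope="session")
def noise_free_subject():
    """Noise-free 32-channel subject: every sample is exactly a scaled map."""
    cfg = es.GeneratorConfig(
        n_channels=32, sampling_rate=250.0, duration=60.0, noise_sigma=0.0, seed=7
    )
    rec, gt = es.simulate_subject(cfg)
    return rec, gt, cfg
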