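import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

import voltstim as vs

FS = 828.0


@pytest.fixture(scope="session")
def short_dbs_session():
    """A compact 2-trial DBS-only session with ground truth (threshold spiking)."""
    cfg = vs.dbs_scenario(40.0, n_trials=2, target_sbr=6.0, seed=1)
    protocol = vs.generate_protocol(cfg)
    truth = vs.generate_vm_and_spikes(cfg, protocol)
    trace = vs.render_trace(truth, cfg, protocol)
    return cfg, protocol, truth, trace


@pytest.fixture(scope="session")
def detrended_session(short_dbs_session):
    cfg, protocol, truth, trace = short_dbs_session
    detrended = vs.detrend_trace(trace, protocol)
    spikes = vs.detect_spikes(detrended)
    return cfg, protocol, truth, detrended, spikes


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
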