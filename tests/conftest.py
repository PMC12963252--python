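import pytest

import neurostate as ns


@pytest.fixture(scope="session")
def small_session():
    """12 trials, 16 channels, default tuning — quick end-to-end fodder."""
    cfg = ns.SessionConfig(n_trials=12, n_channels=16)
    tune = ns.NeuralTuningParams()
    return ns.simulate_session(cfg, tune, seed=11)


@pytest.fixture(scope="session")
def small_rates_labels(small_session):
    return [(ns.estimate_firing_rates(t.spikes), t.truth) for t in small_session]
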