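import dataclasses

import numpy as np
import pytest

from svtrace import RetrievalFractionDist, SimulationConfig, generate_experiment


def noiseless_config(**overrides) -> SimulationConfig:
    """Deterministic single-event-friendly configuration (no noise, no bleach)."""
    base = dict(
        sampling_rate_hz=10.0,
        duration_s=60.0,
        stimulus_times_s=[10.0],
        p_release=1.0,
        noise_sd=0.0,
        bleach_amplitude=0.0,
        multivesicular_prob=0.0,
        quantal_cv=0.0,
        mode_weights=(0.0, 1.0, 0.0),
        retrieval_fraction_dist=RetrievalFractionDist(
            weights=(0.0, 1.0, 0.0), quantal_sd=0.0, dwell_dependent=False
        ),
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def default_experiment():
    """A medium noisy experiment at the default (2 mM Ca, 24 C) condition."""
    return generate_experiment(SimulationConfig(seed=123), 60)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def replace(config, **kw):
    return dataclasses.replace(config, **kw)
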