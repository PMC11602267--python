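import numpy as np
import pytest

from resl_sirs.protocol import NeuronalField, ProtocolParams
from resl_sirs.synth import CohortSpec, PhantomSpec, generate_cohort, generate_subject


@pytest.fixture(scope="session")
def default_params():
    """The study protocol: TR 139.55 ms, 6 slices, TSL 70 ms, f_SL 8 Hz."""
    return ProtocolParams()


@pytest.fixture(scope="session")
def scaled_params():
    """Desk-scale protocol: 3 slices, 90 repetitions, same TR/TSL/f_SL."""
    return ProtocolParams(n_slices=3, n_reps=90)


@pytest.fixture(scope="session")
def small_spec():
    """16x16x3 phantom with 12 parcels (default nuisance amplitudes)."""
    return PhantomSpec(grid=(16, 16, 3), n_parcels=12)


def clean_spec(**overrides):
    """Noise-free 16x16x3 phantom: no noise, drift, BOLD, spikes or ghost
    unless overridden."""
    kw = dict(grid=(16, 16, 3), n_parcels=12, noise_sigma=0.0,
              drift_amplitude=0.0, bold_amplitude=0.0, spike_rate=0.0,
              static_ghost=False)
    kw.update(overrides)
    return PhantomSpec(**kw)


@pytest.fixture(scope="session")
def responder_subject(scaled_params, small_spec):
    return generate_subject(small_spec, scaled_params, responder=True, seed=11)


@pytest.fixture(scope="session")
def small_cohort(scaled_params, small_spec):
    return generate_cohort(CohortSpec(master_seed=5), small_spec, scaled_params)
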