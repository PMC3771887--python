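import dataclasses

import numpy as np
import pytest

import bex


@pytest.fixture(scope="session")
def montage() -> bex.Montage:
    return bex.make_montage()


@pytest.fixture(scope="session")
def small_design():
    """Design scaled to 2 trials/condition/block (16 per condition)."""
    return bex.generate_design(bex.DesignSpec(n_subjects=3).scaled(2))


@pytest.fixture
def noiseless_effects():
    """Deterministic generator: default components, no noise, no subject gain."""
    return dataclasses.replace(bex.ErpEffectParams(), noise_sd=0.0,
                               subject_gain_sd=0.0)


def make_epochs(montage, conditions, effects=None, seed=0):
    """One subject's EpochSet for the given condition labels."""
    if effects is None:
        effects = dataclasses.replace(bex.ErpEffectParams(), noise_sd=0.0,
                                      subject_gain_sd=0.0)
    rng = np.random.default_rng(seed)
    return bex.simulate_subject_epochs(np.asarray(conditions, dtype=object),
                                       effects, montage, rng)
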