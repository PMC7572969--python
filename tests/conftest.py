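from dataclasses import replace

import numpy as np
import pytest

from pibquant.synthetic_cohort import (
    default_reference_profiles,
    default_schedule,
    make_input_function,
    simulate_profile,
    target_profile,
)


@pytest.fixture(scope="session")
def schedule():
    return default_schedule()


@pytest.fixture(scope="session")
def input_function():
    fn, _ = make_input_function()
    return fn


@pytest.fixture(scope="session")
def gmcb_tac(input_function, schedule):
    """Cerebellar-grey reference TAC with the default blood-volume term."""
    return simulate_profile(default_reference_profiles()["GMCB"], input_function, schedule)


@pytest.fixture(scope="session")
def ideal_gmcb_tac(input_function, schedule):
    """Blood-volume-free one-tissue reference TAC (reference-tissue theory holds)."""
    profile = replace(default_reference_profiles()["GMCB"], Vb=0.0)
    return simulate_profile(profile, input_function, schedule)


def ideal_target_tac(dvr, input_function, schedule, model="1T"):
    profile = replace(target_profile("target", dvr, model=model), Vb=0.0)
    return simulate_profile(profile, input_function, schedule)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260924)
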