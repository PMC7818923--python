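import pytest

from ivfjoint.cohort import Cohort, Embryo, PatientCycle
from ivfjoint.model import pretreatment_specs
from ivfjoint.simulate import (GeneratorConfig, default_parameters,
                               simulate_cohort)


@pytest.fixture
def tiny_cohort():
    """Three hand-built cycles covering the full stage funnel.

    Cycle 1 completes with a double transfer and a live birth; cycle 2
    fails at fertilisation (one oocyte, no embryos); cycle 3 never yields
    oocytes, so everything downstream is undefined.
    """
    cycles = [
        PatientCycle("c1", 34.0, 36.0, "1", 9, mixed=1, n_embryos=2,
                     transferred=1, det=1, lbe=1),
        PatientCycle("c2", 30.0, 33.0, "2", 1, mixed=1, n_embryos=0),
        PatientCycle("c3", 41.0, 45.0, "3", 0),
    ]
    embryos = [
        Embryo("c1", 3, 4, 1),
        Embryo("c1", 2, 3, 1),
    ]
    return Cohort.from_records(cycles, embryos)


@pytest.fixture(scope="session")
def default_params():
    return default_parameters()


@pytest.fixture(scope="session")
def specs():
    return pretreatment_specs()


@pytest.fixture(scope="session")
def sim_cohort_500():
    """Medium synthetic cohort shared across read-only tests."""
    return simulate_cohort(GeneratorConfig(n_cycles=500, seed=42))


def make_cohort(n, seed, params=None, **kwargs):
    cfg = GeneratorConfig(
        n_cycles=n, seed=seed,
        params=params if params is not None else default_parameters(),
        **kwargs)
    return simulate_cohort(cfg)
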