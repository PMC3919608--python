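"""Shared fixtures: reduced-scale domain libraries for unit tests and one
session-scoped default cohort with its pipeline result for end-to-end
and acceptance checks."""

from __future__ import annotations

import numpy as np
import pytest

from cfampol.pipeline import run_cohort_pipeline
from cfampol.synthetic import GeneratorConfig, make_cohort, make_domain_library

#: reduced domain lengths for fast unit-scale tests
TINY_LENGTHS = {
    "PHP": 60,
    "Pol3": 90,
    "HhH": 30,
    "OB": 30,
    "CTD": 40,
    "NTD": 45,
    "Exo": 40,
    "UDG": 35,
    "Lar": 25,
}


@pytest.fixture(scope="session")
def tiny_library():
    return make_domain_library(1, lengths=TINY_LENGTHS)


@pytest.fixture(scope="session")
def tiny_profiles(tiny_library):
    return tiny_library.build_profiles()


@pytest.fixture(scope="session")
def library():
    """Full-scale domain library shared across slower tests."""
    return make_domain_library(11)


@pytest.fixture(scope="session")
def profiles(library):
    return library.build_profiles()


@pytest.fixture(scope="session")
def default_cohort():
    """The reference study conditions: 100 genomes at 15% divergence."""
    return make_cohort(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def pipeline_result(default_cohort):
    return run_cohort_pipeline(default_cohort, seed=11)


@pytest.fixture(scope="session")
def pipeline_result_repeat(default_cohort):
    """Second run under identical seed, for determinism checks."""
    return run_cohort_pipeline(default_cohort, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
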