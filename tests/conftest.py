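"""Shared fixtures: small seeded synthetic populations and cohorts."""

from pathlib import Path

import numpy as np
import pytest

from emrisk import SimConfig, generate_population
from emrisk.cohort import DEFAULT_PTSD_CODES, CodeSets, build_cohort
from emrisk.synthetic import DEFAULT_ASUD_CODE

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def code_sets() -> CodeSets:
    return CodeSets(
        ptsd_codes=DEFAULT_PTSD_CODES,
        asud_codes=frozenset({DEFAULT_ASUD_CODE}),
    )


@pytest.fixture(scope="session")
def tiny_population():
    """Small planted-effect population shared by read-only tests."""
    config = SimConfig(
        n_patients=300,
        planted_effects={"A01": np.log(3.0), "RX0005": np.log(1 / 3)},
        seed=42,
    )
    return generate_population(config)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_population, code_sets):
    return build_cohort(
        tiny_population.events,
        code_sets,
        demographics=tiny_population.demographics,
        sdoh_table=tiny_population.sdoh_zip,
        min_lab_frequency=5,
    )


@pytest.fixture()
def manual_trace_events():
    from emrisk.synthetic import read_events

    return read_events(DATA_DIR / "manual_trace_events.csv")
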