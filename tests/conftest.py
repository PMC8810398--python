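import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# empty-pool and rare-cause warnings are expected on small fixtures
logging.getLogger("opiomort.cohort").setLevel(logging.ERROR)
logging.getLogger("opiomort.smr").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def codelist():
    from opiomort.causes import load_default_codelist

    return load_default_codelist()


@pytest.fixture(scope="session")
def demo_study(codelist):
    """A mid-sized default-study cohort shared across test modules:
    registry, matched cohort, and classified Lexis cells."""
    from opiomort.cohort import build_cohort
    from opiomort.causes import classify_cells
    from opiomort.lexis import expand_cohort
    from opiomort.synthetic import (
        default_study_config,
        simulate_icd10_codes,
        simulate_population,
    )

    registry, truth = simulate_population(default_study_config(6000, seed=11))
    registry = simulate_icd10_codes(registry, codelist, seed=12)
    members, sets = build_cohort(registry, seed=13)
    cells = classify_cells(expand_cohort(registry=registry, members=members), codelist)
    return {
        "registry": registry,
        "truth": truth,
        "members": members,
        "sets": sets,
        "cells": cells,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
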