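import warnings

import numpy as np
import pandas as pd
import pytest

import riskupdate as ru
from riskupdate import preprocessing as pp


def complete_record(**overrides):
    """A fully observed participant record; override fields as needed."""
    rec = {
        "sex": "F",
        "age": 50.0,
        "bmi": 26.0,
        "waist": 75.0,
        "sbp": 120.0,
        "dbp": 70.0,
        "antihypertensive_meds": 0,
        "lipid_lowering_meds": 0,
        "corticosteroids": 0,
        "mother_diabetes": 0,
        "father_diabetes": 0,
        "sister_diabetes": 0,
        "brother_diabetes": 0,
        "smoking": "never",
        "drinking": "never",
        "education": "primary",
    }
    rec.update(overrides)
    return rec


@pytest.fixture(scope="session")
def registry():
    return ru.load_model_registry()


@pytest.fixture(scope="session")
def raw_cohort():
    return ru.generate_cohort(ru.CohortConfig(seed=7))


@pytest.fixture(scope="session")
def prepared(raw_cohort):
    """Missingness-injected, excluded, imputed and split frames."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        masked = ru.inject_missingness(raw_cohort, seed=11)
        imputed = pp.simple_impute(pp.exclude_diagnosed(masked))
        split = pp.split_cohort(imputed, seed=3)
    return {"imputed": imputed, "train": split.train, "test": split.test}


@pytest.fixture(scope="session")
def clean_cohort():
    """A complete (no missingness) screening cohort without exclusions."""
    return ru.generate_cohort(
        ru.CohortConfig(n_recruited=1083, n_previously_diagnosed=0, seed=21)
    )
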