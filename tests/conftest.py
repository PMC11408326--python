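import numpy as np
import pandas as pd
import pytest

from pvborda import (
    EligibilityRules,
    apply_eligibility,
    build_analysis_matrix,
    default_fixture,
    simulate_cohort,
)
from pvborda.simulate import TARGET_ATC


@pytest.fixture(scope="session")
def tiny_cohort():
    """Tiny simulated cohort (all four ADR classes) shared across tests."""
    config = default_fixture("tiny", seed=42)
    tables, truth = simulate_cohort(config)
    return config, tables, truth


@pytest.fixture(scope="session")
def tiny_matrix(tiny_cohort):
    _, tables, _ = tiny_cohort
    rules = EligibilityRules(
        target_atc=TARGET_ATC,
        washout_atc_prefixes=("B01AF", "B01AA"),
        require_target_use=False,
    )
    elig = apply_eligibility(tables, rules)
    return build_analysis_matrix(tables, elig.eligible_ids, TARGET_ATC, min_count=3)


def make_persons(rows):
    """Helper: persons frame from (pid, sex, birth_year, entry, exit, provider)."""
    return pd.DataFrame(
        rows,
        columns=["patient_id", "sex", "birth_year", "cohort_entry", "cohort_exit", "provider_id"],
    )


def make_dispensations(rows):
    return pd.DataFrame(rows, columns=["patient_id", "atc", "dispense_date", "supply_days"])


def make_diagnoses(rows):
    return pd.DataFrame(rows, columns=["patient_id", "icd", "event_date", "inpatient"])
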