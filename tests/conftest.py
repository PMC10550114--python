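"""Shared fixtures: programmatic cohort builders (no stored data files)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from vettrial import schema
from vettrial.propensity import WeightSet, PropensityModelSpec

_DEFAULT_ROW = {
    "age_years": 3.0,
    "breed": "Crossbred",
    "bodyweight_cat": "<10",
    "insured": 0,
    "comorbidity": 0,
    "vomiting": 0,
    "reduced_appetite": 0,
    "haematochezia": 0,
    "pyrexia": 0,
    "duration_cat": "<24h",
    "vet_group": 1,
    "antimicrobial": 0,
    "nutraceutical": 0,
    "diet_advice": 0,
    "antiparasitic": 0,
    "gi_agent": 0,
    "resolved_30d": 1,
    "escalation_day": 30,
    "escalated": 0,
}

_RAW_EXTRAS = {
    "prior_diarrhoea_within_30d": 0,
    "prior_exposure_within_30d": 0,
    "excluded_diagnosis": 0,
    "duration_days_prior": 1.0,
    "iv_fluids": 0,
    "hospitalised": 0,
    "died_at_presentation": 0,
}


def build_cohort(rows: list[dict], raw: bool = False) -> pd.DataFrame:
    """Assemble a valid cohort frame from per-row overrides of a default dog."""
    base = {**_DEFAULT_ROW, **(_RAW_EXTRAS if raw else {})}
    records = []
    for i, overrides in enumerate(rows):
        rec = {"dog_id": f"dog{i}", **base, **overrides}
        records.append(rec)
    cols = schema.RAW_COLUMNS if raw else schema.COHORT_COLUMNS
    return pd.DataFrame(records)[list(cols)]


def unit_weightset(cohort: pd.DataFrame, exposure: str) -> WeightSet:
    """A WeightSet with all stabilised weights equal to one (e_i = p_A)."""
    n = len(cohort)
    p = float(cohort[exposure].mean())
    e = np.full(n, p)
    a = cohort[exposure].to_numpy()
    return WeightSet(
        exposure=exposure, propensity=e, p_treat=p,
        sw=np.ones(n), w=np.where(a == 1, 1 / p, 1 / (1 - p)),
        converged=True, coefficients=pd.DataFrame(),
        spec=PropensityModelSpec(exposure=exposure, main_terms=()),
    )


@pytest.fixture
def cohort_builder():
    return build_cohort


@pytest.fixture
def stratified_8dog_cohort() -> pd.DataFrame:
    """Single binary confounder (comorbidity) in two strata of four dogs.

    Stratum L=0: one exposed dog with outcome 1, three unexposed with
    outcomes {1, 0, 0}; stratum L=1: three exposed with {1, 1, 0}, one
    unexposed with 0.  Exact standardisation over strata gives marginal
    risks 5/6 vs 1/6 (risk difference 66.67 points).
    """
    rows = [
        {"comorbidity": 0, "antimicrobial": 1, "resolved_30d": 1},
        {"comorbidity": 0, "antimicrobial": 0, "resolved_30d": 1},
        {"comorbidity": 0, "antimicrobial": 0, "resolved_30d": 0},
        {"comorbidity": 0, "antimicrobial": 0, "resolved_30d": 0},
        {"comorbidity": 1, "antimicrobial": 1, "resolved_30d": 1},
        {"comorbidity": 1, "antimicrobial": 1, "resolved_30d": 1},
        {"comorbidity": 1, "antimicrobial": 1, "resolved_30d": 0},
        {"comorbidity": 1, "antimicrobial": 0, "resolved_30d": 0},
    ]
    return build_cohort(rows)
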