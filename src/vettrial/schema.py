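"""Cohort data model, CSV I/O and target-trial eligibility filtering.

A cohort is a :class:`pandas.DataFrame` with one row per dog.  Two column
sets are defined:

* the *cohort* schema — baseline covariates, the two candidate exposures
  (antimicrobial, gastrointestinal nutraceutical), the binary 30-day
  clinical-resolution outcome and the time-to-treatment-escalation outcome;
* the *raw presentation* schema — the cohort columns plus the pre-filter
  attributes needed to apply the trial eligibility rules (prior diarrhoea /
  prior exposure within 30 days, excluded diagnoses, prior duration, IV
  fluids, hospitalisation, death at presentation).

Category labels are fixed strings; "not recorded" is a legal level only for
bodyweight and duration (the two covariates handled downstream with the
missing-indicator method).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# --------------------------------------------------------------------------
# Schema constants
# --------------------------------------------------------------------------

BREED_LEVELS: tuple[str, ...] = (
    "Crossbred",
    "Purebred - other",
    "Labrador Retriever",
    "German Shepherd Dog",
    "Cockapoo",
    "Shih-tzu",
    "Staffordshire Bull Terrier",
    "French Bulldog",
    "Jack Russell Terrier",
    "Yorkshire Terrier",
)
BODYWEIGHT_LEVELS: tuple[str, ...] = ("<10", "10-<20", "20-<30", ">=30", "not recorded")
DURATION_LEVELS: tuple[str, ...] = ("<24h", "24-48h", "48-96h", "5-7d", "not recorded")
VET_GROUP_LEVELS: tuple[int, ...] = (1, 2, 3, 4, 5)

NOT_RECORDED = "not recorded"

#: covariates that may carry a "not recorded" level
MISSING_INDICATOR_FIELDS: tuple[str, ...] = ("bodyweight_cat", "duration_cat")

EXPOSURES: tuple[str, ...] = ("antimicrobial", "nutraceutical")

BINARY_FIELDS: tuple[str, ...] = (
    "insured",
    "comorbidity",
    "vomiting",
    "reduced_appetite",
    "haematochezia",
    "pyrexia",
    "antimicrobial",
    "nutraceutical",
    "diet_advice",
    "antiparasitic",
    "gi_agent",
    "resolved_30d",
    "escalated",
)

CATEGORICAL_LEVELS: dict[str, tuple] = {
    "breed": BREED_LEVELS,
    "bodyweight_cat": BODYWEIGHT_LEVELS,
    "duration_cat": DURATION_LEVELS,
    "vet_group": VET_GROUP_LEVELS,
}

#: full ordered cohort column set
COHORT_COLUMNS: tuple[str, ...] = (
    "dog_id",
    "age_years",
    "breed",
    "bodyweight_cat",
    "insured",
    "comorbidity",
    "vomiting",
    "reduced_appetite",
    "haematochezia",
    "pyrexia",
    "duration_cat",
    "vet_group",
    "antimicrobial",
    "nutraceutical",
    "diet_advice",
    "antiparasitic",
    "gi_agent",
    "resolved_30d",
    "escalation_day",
    "escalated",
)

RAW_BINARY_FIELDS: tuple[str, ...] = (
    "prior_diarrhoea_within_30d",
    "prior_exposure_within_30d",
    "excluded_diagnosis",
    "iv_fluids",
    "hospitalised",
    "died_at_presentation",
)

#: raw presentation = cohort columns + pre-filter attributes
RAW_COLUMNS: tuple[str, ...] = COHORT_COLUMNS + RAW_BINARY_FIELDS + ("duration_days_prior",)

#: the adjustment set implied by the causal diagram (used for balance tables
#: and as default propensity main terms; the concurrent-treatment columns are
#: filtered to exclude the exposure under analysis)
ADJUSTMENT_COVARIATES: tuple[str, ...] = (
    "age_years",
    "breed",
    "bodyweight_cat",
    "insured",
    "comorbidity",
    "vomiting",
    "reduced_appetite",
    "haematochezia",
    "pyrexia",
    "duration_cat",
    "vet_group",
    "antimicrobial",
    "nutraceutical",
    "diet_advice",
    "antiparasitic",
    "gi_agent",
)

#: eligibility rules in their fixed precedence order; each record is tallied
#: once under the first failing rule
ELIGIBILITY_RULES: tuple[str, ...] = (
    "age",
    "prior_diarrhoea",
    "prior_exposure",
    "excluded_diagnosis",
    "duration",
    "iv_fluids",
    "hospitalised",
    "died_at_presentation",
)

AGE_MIN_YEARS = 0.25   # 3 months, inclusive
AGE_MAX_YEARS = 10.0   # exclusive
MAX_PRIOR_DURATION_DAYS = 7.0   # "greater than 7 days" excluded; exactly 7 retained
HORIZON_DAYS = 30


class SchemaError(ValueError):
    """A required column is missing or the header does not match the schema."""


class CohortValidationError(ValueError):
    """A field value falls outside its enumerated or typed domain."""


# --------------------------------------------------------------------------
# Validation and I/O
# --------------------------------------------------------------------------

def _check_columns(df: pd.DataFrame, required: Iterable[str]) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")


def validate_cohort(df: pd.DataFrame, raw: bool = False) -> pd.DataFrame:
    """Validate and coerce a cohort table to its typed domain.

    Parameters
    ----------
    df : DataFrame with the cohort (or raw presentation) column schema.
    raw : if True, require and validate the pre-filter attributes too.

    Returns a coerced copy.  Raises :class:`SchemaError` for missing columns
    and :class:`CohortValidationError` (naming row and field) for values
    outside their domain.
    """
    required = RAW_COLUMNS if raw else COHORT_COLUMNS
    _check_columns(df, required)
    out = df.copy()

    out["dog_id"] = out["dog_id"].astype(str)
    if out["dog_id"].duplicated().any():
        dup = out.loc[out["dog_id"].duplicated(), "dog_id"].iloc[0]
        raise CohortValidationError(f"duplicate dog_id {dup!r}")

    for col in ("age_years", "escalation_day"):
        try:
            out[col] = pd.to_numeric(out[col], errors="raise").astype(float)
        except (ValueError, TypeError) as exc:
            raise CohortValidationError(f"column {col!r}: non-numeric value ({exc})") from exc

    binaries = list(BINARY_FIELDS) + (list(RAW_BINARY_FIELDS) if raw else [])
    for col in binaries:
        vals = pd.to_numeric(out[col], errors="coerce")
        bad = ~vals.isin([0, 1])
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortValidationError(
                f"row {i}, field {col!r}: value {out[col].iloc[i]!r} is not binary 0/1"
            )
        out[col] = vals.astype(int)

    for col, levels in CATEGORICAL_LEVELS.items():
        if col == "vet_group":
            vals = pd.to_numeric(out[col], errors="coerce")
            bad = ~vals.isin(levels)
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                raise CohortValidationError(
                    f"row {i}, field {col!r}: value {out[col].iloc[i]!r} "
                    f"not in enumerated levels {levels}"
                )
            out[col] = vals.astype(int)
        else:
            vals = out[col].astype(str)
            bad = ~vals.isin(levels)
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                raise CohortValidationError(
                    f"row {i}, field {col!r}: value {out[col].iloc[i]!r} "
                    f"not in enumerated levels {levels}"
                )
            out[col] = vals

    bad_day = (out["escalation_day"] < 0) | (out["escalation_day"] > HORIZON_DAYS)
    if bad_day.any():
        i = int(np.flatnonzero(bad_day.to_numpy())[0])
        raise CohortValidationError(
            f"row {i}, field 'escalation_day': {out['escalation_day'].iloc[i]} "
            f"outside [0, {HORIZON_DAYS}]"
        )
    if raw:
        neg = out["duration_days_prior"].astype(float) < 0
        if neg.any():
            i = int(np.flatnonzero(neg.to_numpy())[0])
            raise CohortValidationError(f"row {i}, field 'duration_days_prior': negative value")
        out["duration_days_prior"] = out["duration_days_prior"].astype(float)

    return out.reset_index(drop=True)


def read_cohort(
    path: str | Path,
    raw: bool = False,
    aliases: Mapping[str, Mapping[str, str]] | None = None,
) -> pd.DataFrame:
    """Read a cohort CSV and validate it against the schema.

    ``aliases`` optionally maps, per categorical field, non-canonical labels
    to canonical ones (e.g. ``{"breed": {"Lab Retriever": "Labrador
    Retriever"}}``) before validation.
    """
    # round_trip parsing so write_cohort -> read_cohort is bit-exact in floats
    df = pd.read_csv(path, dtype={"dog_id": str}, float_precision="round_trip")
    if aliases:
        for col, mapping in aliases.items():
            if col in df.columns:
                df[col] = df[col].replace(dict(mapping))
    return validate_cohort(df, raw=raw)


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table as UTF-8 CSV with header, one row per dog."""
    df.to_csv(path, index=False, encoding="utf-8")


# --------------------------------------------------------------------------
# Eligibility
# --------------------------------------------------------------------------

def apply_eligibility(raw_df: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the trial eligibility rules to validated presentation records.

    Retained dogs satisfy: age in [0.25, 10) years; no recorded diarrhoea or
    antimicrobial/nutraceutical prescription in the preceding 30 days; none
    of the excluded diagnoses; pre-presentation diarrhoea duration of at most
    7 days; and no IV fluids, hospitalisation or death at first presentation.

    Returns the retained records restricted to the cohort columns, and a
    tally dict counting each excluded record once under the first failing
    rule (fixed precedence: age, prior diarrhoea, prior exposure, excluded
    diagnosis, duration, IV fluids, hospitalisation, death), plus
    ``"retained"``.
    """
    _check_columns(raw_df, RAW_COLUMNS)
    fails = {
        "age": ~((raw_df["age_years"] >= AGE_MIN_YEARS) & (raw_df["age_years"] < AGE_MAX_YEARS)),
        "prior_diarrhoea": raw_df["prior_diarrhoea_within_30d"] == 1,
        "prior_exposure": raw_df["prior_exposure_within_30d"] == 1,
        "excluded_diagnosis": raw_df["excluded_diagnosis"] == 1,
        "duration": raw_df["duration_days_prior"] > MAX_PRIOR_DURATION_DAYS,
        "iv_fluids": raw_df["iv_fluids"] == 1,
        "hospitalised": raw_df["hospitalised"] == 1,
        "died_at_presentation": raw_df["died_at_presentation"] == 1,
    }
    assigned = pd.Series(False, index=raw_df.index)
    tally: dict[str, int] = {}
    for rule in ELIGIBILITY_RULES:
        hit = fails[rule] & ~assigned
        tally[rule] = int(hit.sum())
        assigned |= hit
    kept = raw_df.loc[~assigned, list(COHORT_COLUMNS)].reset_index(drop=True)
    tally["retained"] = int(len(kept))
    logger.info("eligibility: retained %d of %d records (%s)", len(kept), len(raw_df),
                {k: v for k, v in tally.items() if k != "retained" and v})
    return kept, tally


def write_exclusion_report(tally: Mapping[str, int], path: str | Path) -> None:
    Path(path).write_text(json.dumps(dict(tally), indent=2) + "\n", encoding="utf-8")


# --------------------------------------------------------------------------
# Descriptive summaries
# --------------------------------------------------------------------------

def summarize_cohort(cohort: pd.DataFrame, exposure: str) -> pd.DataFrame:
    """Per-level counts and within-arm percentages by exposure arm.

    One row per (covariate, level); count and percentage (1 dp) within the
    exposed and unexposed arms.  Arm sizes and overall n are attached as
    ``DataFrame.attrs`` (keys ``n``, ``n_exposed``, ``n_unexposed``).
    """
    if exposure not in EXPOSURES:
        raise ValueError(f"exposure must be one of {EXPOSURES}, got {exposure!r}")
    rows = []
    n = len(cohort)
    if n == 0:
        out = pd.DataFrame(columns=["covariate", "level", "count_exposed", "pct_exposed",
                                    "count_unexposed", "pct_unexposed"])
        out.attrs.update(n=0, n_exposed=0, n_unexposed=0, exposure=exposure)
        return out
    exposed = cohort[exposure] == 1
    n1, n0 = int(exposed.sum()), int((~exposed).sum())
    covs = [c for c in ADJUSTMENT_COVARIATES if c != exposure and c != "age_years"]
    for cov in covs:
        levels = CATEGORICAL_LEVELS.get(cov, (1, 0))
        for lev in levels:
            in_level = cohort[cov] == lev
            c1 = int((in_level & exposed).sum())
            c0 = int((in_level & ~exposed).sum())
            rows.append({
                "covariate": cov,
                "level": lev,
                "count_exposed": c1,
                "pct_exposed": round(100.0 * c1 / n1, 1) if n1 else float("nan"),
                "count_unexposed": c0,
                "pct_unexposed": round(100.0 * c0 / n0, 1) if n0 else float("nan"),
            })
    out = pd.DataFrame(rows)
    out.attrs.update(n=n, n_exposed=n1, n_unexposed=n0, exposure=exposure)
    return out


def treatment_prevalence(cohort: pd.DataFrame) -> dict[str, float]:
    """Percentage (1 dp) of dogs on each exposure and on both concurrently."""
    n = len(cohort)
    if n == 0:
        return {"antimicrobial": float("nan"), "nutraceutical": float("nan"),
                "both": float("nan")}
    both = (cohort["antimicrobial"] == 1) & (cohort["nutraceutical"] == 1)
    return {
        "antimicrobial": round(100.0 * (cohort["antimicrobial"] == 1).sum() / n, 1),
        "nutraceutical": round(100.0 * (cohort["nutraceutical"] == 1).sum() / n, 1),
        "both": round(100.0 * both.sum() / n, 1),
    }
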