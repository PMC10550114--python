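"""Treatment-assignment modelling and stabilised inverse-probability weights.

The propensity score e(L) is fitted by maximum-likelihood logistic
regression of the exposure on the adjustment covariates, with categorical
covariates reference-coded (reference = most frequent observed level),
"not recorded" levels of bodyweight and duration kept as their own
indicator columns (missing-indicator method), an optional quadratic term
for age, and optional pairwise interactions.

Stabilised weights replace the unit numerator of 1/e weights with the crude
exposure prevalence:  sw = p_A / e for exposed dogs and (1 − p_A) / (1 − e)
for unexposed dogs, shrinking extreme weights while preserving the
pseudo-population size.

Interaction selection is a greedy forward pass over user-supplied candidate
pairs, retaining a candidate only if it strictly reduces the maximum
post-weighting standardised mean difference across the adjustment set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import schema

logger = logging.getLogger(__name__)

#: stabilised weights outside this range are listed in the extreme-weight report
EXTREME_WEIGHT_RANGE = (0.1, 10.0)


@dataclass(frozen=True)
class PropensityModelSpec:
    """Terms of the treatment-assignment logistic model."""

    exposure: str
    main_terms: tuple[str, ...]
    quadratic_terms: tuple[str, ...] = ()
    interaction_terms: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        for a, b in self.interaction_terms:
            if a == b:
                raise ValueError(f"interaction pair ({a}, {b}) is not two distinct fields")

    def with_interaction(self, pair: tuple[str, str]) -> "PropensityModelSpec":
        return replace(self, interaction_terms=self.interaction_terms + (tuple(pair),))


@dataclass
class WeightSet:
    """Per-record propensities and IP weights from one fitted model."""

    exposure: str
    propensity: np.ndarray          # e_i = P(A=1 | L_i)
    p_treat: float                  # crude exposure prevalence (numerator)
    sw: np.ndarray                  # stabilised weights
    w: np.ndarray                   # unstabilised 1/e(A) weights
    converged: bool
    coefficients: pd.DataFrame      # term, estimate, se
    spec: PropensityModelSpec
    diagnostics: dict = field(default_factory=dict)

    def extreme_weight_report(self) -> pd.DataFrame:
        lo, hi = EXTREME_WEIGHT_RANGE
        mask = (self.sw < lo) | (self.sw > hi)
        return pd.DataFrame({"index": np.flatnonzero(mask), "sw": self.sw[mask]})


def default_spec(exposure: str) -> PropensityModelSpec:
    """The final published propensity model for each emulated trial.

    Main terms are the full adjustment set (the other concurrent treatments
    included, the exposure under analysis excluded) with a quadratic age
    term; the interaction sets are the ones retained by balance screening in
    the source study, shipped as the default configuration.
    """
    main = tuple(c for c in schema.ADJUSTMENT_COVARIATES if c != exposure)
    interactions = {
        "antimicrobial": (("age_years", "vomiting"),
                          ("haematochezia", "pyrexia"),
                          ("nutraceutical", "diet_advice")),
        "nutraceutical": (("age_years", "haematochezia"),),
    }[exposure]
    return PropensityModelSpec(exposure=exposure, main_terms=main,
                               quadratic_terms=("age_years",),
                               interaction_terms=interactions)


# --------------------------------------------------------------------------
# Design encoding
# --------------------------------------------------------------------------

def _encode_field(cohort: pd.DataFrame, name: str) -> dict[str, np.ndarray]:
    """Encode one covariate into named numeric columns.

    Categoricals are reference-coded against their most frequent observed
    level ("not recorded" is never the reference, so missingness always gets
    its own indicator); levels absent from the cohort are dropped with a
    warning since they carry no information and break estimability.
    """
    levels = schema.CATEGORICAL_LEVELS.get(name)
    if levels is None:
        return {name: cohort[name].to_numpy(dtype=float)}
    counts = cohort[name].value_counts()
    present = [lev for lev in levels if counts.get(lev, 0) > 0]
    absent = [lev for lev in levels if counts.get(lev, 0) == 0]
    if absent:
        logger.warning("field %r: empty level(s) %s dropped from design", name, absent)
    ref_candidates = [lev for lev in present if lev != schema.NOT_RECORDED] or present
    ref = max(ref_candidates, key=lambda lev: counts.get(lev, 0))
    out = {}
    for lev in present:
        if lev == ref:
            continue
        out[f"{name}[{lev}]"] = (cohort[name] == lev).to_numpy(dtype=float)
    return out


def encode_design(cohort: pd.DataFrame, spec: PropensityModelSpec) -> pd.DataFrame:
    """Build the model matrix (with intercept) for a propensity spec."""
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(cohort))}
    encoded: dict[str, dict[str, np.ndarray]] = {}
    for term in spec.main_terms:
        encoded[term] = _encode_field(cohort, term)
        cols.update(encoded[term])
    for term in spec.quadratic_terms:
        cols[f"{term}^2"] = cohort[term].to_numpy(dtype=float) ** 2
    for a, b in spec.interaction_terms:
        ea = encoded.get(a) or _encode_field(cohort, a)
        eb = encoded.get(b) or _encode_field(cohort, b)
        for na, va in ea.items():
            for nb, vb in eb.items():
                cols[f"{na}:{nb}"] = va * vb
    return pd.DataFrame(cols, index=cohort.index)


# --------------------------------------------------------------------------
# Fitting
# --------------------------------------------------------------------------

def fit_propensity(
    cohort: pd.DataFrame,
    spec: PropensityModelSpec,
    truncate_quantile: float | None = None,
) -> WeightSet:
    """Fit the assignment model and derive stabilised IP weights.

    ``truncate_quantile`` optionally symmetric-truncates the stabilised
    weights at the (q, 1−q) sample quantiles for sensitivity analyses; the
    default is no truncation.
    """
    y = cohort[spec.exposure].to_numpy(dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError(f"exposure {spec.exposure!r}: one arm is empty")
    X = encode_design(cohort, spec)
    p_treat = float(y.mean())

    converged = True
    bad_terms: list[str] = []
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200, method="newton", tol=1e-10)
        params = res.params
        bse = res.bse
        converged = bool(res.mle_retvals.get("converged", True))
    except Exception as exc:  # separation or singular information
        logger.warning("propensity fit failed (%s); falling back to lbfgs", exc)
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=500, method="lbfgs")
            params = res.params
            bse = pd.Series(np.nan, index=params.index)
            converged = False
        except Exception:
            raise
    e = np.asarray(res.predict(X), dtype=float)

    # standardised score check: a converged MLE has (numerically) zero score
    p = e
    g = X.to_numpy().T @ (y - p)
    info_diag = np.einsum("ij,i,ij->j", X.to_numpy(), p * (1 - p), X.to_numpy())
    with np.errstate(divide="ignore", invalid="ignore"):
        std_score = np.abs(g) / np.sqrt(np.where(info_diag > 0, info_diag, np.nan))
    max_score = float(np.nanmax(std_score)) if len(std_score) else 0.0
    if max_score > 1e-6:
        converged = False
    huge = np.abs(np.asarray(params)) > 15
    if huge.any():
        bad_terms = list(np.asarray(params.index)[huge])
        converged = False
        logger.warning("possible separation: extreme coefficients for %s", bad_terms)

    sw = np.where(y == 1, p_treat / e, (1 - p_treat) / (1 - e))
    w = np.where(y == 1, 1.0 / e, 1.0 / (1 - e))
    if truncate_quantile is not None:
        lo, hi = np.quantile(sw, [truncate_quantile, 1 - truncate_quantile])
        sw = np.clip(sw, lo, hi)

    coef = pd.DataFrame({"term": list(params.index),
                         "estimate": np.asarray(params, dtype=float),
                         "se": np.asarray(bse, dtype=float)})
    return WeightSet(
        exposure=spec.exposure, propensity=e, p_treat=p_treat, sw=sw, w=w,
        converged=converged, coefficients=coef, spec=spec,
        diagnostics={"max_std_score": max_score, "suspect_terms": bad_terms},
    )


# --------------------------------------------------------------------------
# Balance-driven interaction selection
# --------------------------------------------------------------------------

def select_interactions(
    cohort: pd.DataFrame,
    base_spec: PropensityModelSpec,
    candidates: Sequence[tuple[str, str]],
    balance_fn: Callable[[pd.DataFrame, WeightSet], float] | None = None,
) -> tuple[PropensityModelSpec, list[dict]]:
    """Greedy forward selection of interaction terms by covariate balance.

    Candidates are tried in the order supplied (they should be biologically
    plausible pairs); one is retained iff adding it strictly reduces the
    balance criterion — by default the maximum post-weighting standardised
    mean difference over the adjustment set.  Candidates whose fit fails to
    converge are skipped.  Returns the augmented spec and a per-candidate
    decision log.
    """
    if balance_fn is None:
        from .balance import max_weighted_smd
        balance_fn = max_weighted_smd

    current = base_spec
    ws = fit_propensity(cohort, current)
    current_metric = balance_fn(cohort, ws)
    log: list[dict] = []
    for pair in candidates:
        trial = current.with_interaction(tuple(pair))
        try:
            ws_trial = fit_propensity(cohort, trial)
        except Exception as exc:
            log.append({"candidate": list(pair), "kept": False,
                        "reason": f"fit error: {exc}"})
            continue
        if not ws_trial.converged:
            log.append({"candidate": list(pair), "kept": False,
                        "reason": "non-convergence", "metric": None})
            logger.warning("candidate %s skipped: non-convergence", pair)
            continue
        metric = balance_fn(cohort, ws_trial)
        kept = metric < current_metric
        log.append({"candidate": list(pair), "kept": bool(kept),
                    "metric": float(metric), "baseline_metric": float(current_metric)})
        if kept:
            current, current_metric = trial, metric
    return current, log
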