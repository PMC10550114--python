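"""Covariate-balance diagnostics via standardised mean differences.

The SMD for a covariate is |x̄₁ − x̄₀| / sqrt((s₁² + s₀²)/2) with weighted
means and variances under IP weighting; for a binary covariate the arm
variance is p(1 − p).  Weighted variances follow the frequency-weight
convention Σw(x − x̄_w)² / Σw.  A weighted SMD below 0.1 is conventionally
read as adequate balance.

Multi-level categoricals are expanded to level indicators; the
covariate-level summary is the maximum over its levels (a conservative
choice).  Contrasts with zero pooled variance but unequal means are
reported with a ``degenerate`` flag rather than an infinity so tables stay
serialisable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import schema

#: conventional balance threshold on the weighted SMD
BALANCE_THRESHOLD = 0.1


def _wmean(x: np.ndarray, w: np.ndarray) -> float:
    return float(np.sum(w * x) / np.sum(w))


def smd(
    x1: np.ndarray,
    x0: np.ndarray,
    w1: np.ndarray | None = None,
    w0: np.ndarray | None = None,
    binary: bool | None = None,
) -> float:
    """Absolute standardised mean difference between two arms.

    ``binary=None`` auto-detects a {0,1}-valued covariate.  Returns ``inf``
    for the degenerate zero-pooled-variance, unequal-means case and 0 when
    the means are equal.
    """
    x1 = np.asarray(x1, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    if len(x1) == 0 or len(x0) == 0:
        raise ValueError("both arms must be non-empty")
    w1 = np.ones_like(x1) if w1 is None else np.asarray(w1, dtype=float)
    w0 = np.ones_like(x0) if w0 is None else np.asarray(w0, dtype=float)
    if (w1 <= 0).any() or (w0 <= 0).any():
        raise ValueError("weights must be strictly positive")
    if binary is None:
        binary = set(np.unique(np.concatenate([x1, x0]))) <= {0.0, 1.0}

    m1, m0 = _wmean(x1, w1), _wmean(x0, w0)
    if binary:
        v1, v0 = m1 * (1 - m1), m0 * (1 - m0)
    else:
        v1 = _wmean((x1 - m1) ** 2, w1)
        v0 = _wmean((x0 - m0) ** 2, w0)
    pooled = (v1 + v0) / 2.0
    diff = abs(m1 - m0)
    if pooled <= 0:
        return 0.0 if diff == 0 else float("inf")
    return diff / np.sqrt(pooled)


def effective_sample_size(w: np.ndarray) -> float:
    """Kish effective sample size (Σw)² / Σw² of a weighted arm."""
    w = np.asarray(w, dtype=float)
    return float(np.sum(w) ** 2 / np.sum(w ** 2)) if len(w) else 0.0


def _balance_columns(cohort: pd.DataFrame, covariates) -> list[tuple[str, str, np.ndarray, bool]]:
    """(covariate, level-label, values, is_binary) rows for the balance table."""
    out = []
    for cov in covariates:
        levels = schema.CATEGORICAL_LEVELS.get(cov)
        if levels is None:
            vals = cohort[cov].to_numpy(dtype=float)
            binary = set(np.unique(vals)) <= {0.0, 1.0} if len(vals) else True
            out.append((cov, "", vals, binary))
        else:
            for lev in levels:
                out.append((cov, str(lev), (cohort[cov] == lev).to_numpy(dtype=float), True))
    return out


def balance_table(
    cohort: pd.DataFrame,
    exposure: str,
    weight_set=None,
    covariates=None,
) -> pd.DataFrame:
    """Standardised mean differences before and after weighting.

    One row per covariate level (continuous covariates get a single row),
    with ``smd_unweighted``, ``smd_weighted``, a ``balanced`` flag
    (weighted SMD < 0.1) and a ``degenerate`` flag for contrasts where one
    arm lacks the level entirely (zero pooled variance, unequal means).
    Arm sizes and Kish effective sample sizes are attached via
    ``DataFrame.attrs``.  Without a weight set the weighted column simply
    repeats the unweighted one.
    """
    if covariates is None:
        covariates = [c for c in schema.ADJUSTMENT_COVARIATES if c != exposure]
    a = cohort[exposure].to_numpy(dtype=int)
    i1, i0 = a == 1, a == 0
    sw = np.ones(len(cohort)) if weight_set is None else np.asarray(weight_set.sw, dtype=float)

    rows = []
    for cov, lev, vals, binary in _balance_columns(cohort, covariates):
        s_un = smd(vals[i1], vals[i0], binary=binary)
        s_w = smd(vals[i1], vals[i0], sw[i1], sw[i0], binary=binary)
        # positivity guard: a level wholly absent from (or universal in) one
        # arm is reported with a flag, never silently dropped
        degenerate = bool(np.isinf(s_un) or np.isinf(s_w) or (
            binary and (vals[i1].mean() in (0.0, 1.0) or vals[i0].mean() in (0.0, 1.0))))
        rows.append({
            "covariate": cov, "level": lev,
            "smd_unweighted": float(s_un) if np.isfinite(s_un) else np.nan,
            "smd_weighted": float(s_w) if np.isfinite(s_w) else np.nan,
            "balanced": bool(np.isfinite(s_w) and s_w < BALANCE_THRESHOLD),
            "degenerate": bool(degenerate),
        })
    out = pd.DataFrame(rows)
    out.attrs.update(
        exposure=exposure,
        n_exposed=int(i1.sum()), n_unexposed=int(i0.sum()),
        ess_exposed=effective_sample_size(sw[i1]),
        ess_unexposed=effective_sample_size(sw[i0]),
    )
    return out


def covariate_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse a level-wise balance table to one row per covariate (max SMD)."""
    return (table.groupby("covariate", sort=False)
            .agg(smd_unweighted=("smd_unweighted", "max"),
                 smd_weighted=("smd_weighted", "max"),
                 degenerate=("degenerate", "any"))
            .reset_index())


def max_weighted_smd(cohort: pd.DataFrame, weight_set, covariates=None) -> float:
    """Maximum post-weighting SMD over the adjustment set.

    The default criterion for balance-driven interaction selection;
    degenerate (NaN) rows are ignored.
    """
    tab = balance_table(cohort, weight_set.exposure, weight_set, covariates=covariates)
    return float(np.nanmax(tab["smd_weighted"].to_numpy()))


def love_plot_frame(table: pd.DataFrame) -> pd.DataFrame:
    """Long-format (covariate-level, stage, smd) frame ready for a love plot."""
    long = table.melt(
        id_vars=["covariate", "level"],
        value_vars=["smd_unweighted", "smd_weighted"],
        var_name="stage", value_name="smd",
    )
    long["stage"] = long["stage"].str.replace("smd_", "", regex=False)
    long["label"] = np.where(long["level"].astype(str) != "",
                             long["covariate"] + " [" + long["level"].astype(str) + "]",
                             long["covariate"])
    return long[["label", "covariate", "level", "stage", "smd"]]
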