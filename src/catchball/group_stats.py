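"""Group-level behavioral statistics.

One-sample t tests of the fitted coefficients against zero, repeated-measures
session effects on strong-ball counts toward the instigators (with the paired
tests for the two message-driven transitions: session 5 to 6 for P3 and 6 to
7 for P1), and trait regressions/correlations linking the Big-Five and IRI
scores to the conformity (b3) and target-change (b6) parameters.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence

from .behavior_model import N_SESSIONS, TARGETS, TaskRecord

__all__ = [
    "session_counts",
    "beta_one_sample_tests",
    "session_effect_tests",
    "trait_regression",
]

BETA_COLS = tuple(f"beta{k}" for k in range(1, 7))


def session_counts(records: Sequence[TaskRecord]) -> pd.DataFrame:
    """Per-participant, per-session throw counts by target and strength.

    Wide format with columns like ``strong_P1``; each participant's counts
    sum to the 64 throws of a complete run.
    """
    rows = []
    for rec in records:
        p2 = rec.p2_events()
        for session in range(1, N_SESSIONS + 1):
            row: dict = {"participant_id": rec.participant_id, "session": session}
            for strength in ("normal", "strong"):
                for target in TARGETS:
                    row[f"{strength}_{target}"] = sum(
                        1
                        for e in p2
                        if e.session == session
                        and e.target == target
                        and e.strength == strength
                    )
            rows.append(row)
    return pd.DataFrame(rows)


def beta_one_sample_tests(beta_frame: pd.DataFrame) -> pd.DataFrame:
    """Two-sided one-sample t vs 0 for beta1..beta6 (df = n - 1).

    A zero-variance coefficient is flagged and left untested.
    """
    n = len(beta_frame)
    if n < 3:
        raise ValueError(f"need at least 3 participants, got {n}")
    rows = []
    for col in BETA_COLS:
        x = beta_frame[col].to_numpy(dtype=float)
        if x.std(ddof=1) == 0:
            rows.append(
                {"parameter": col, "t": np.nan, "df": n - 1, "p": np.nan, "zero_variance": True}
            )
            continue
        res = stats.ttest_1samp(x, 0.0)
        rows.append(
            {
                "parameter": col,
                "t": float(res.statistic),
                "df": n - 1,
                "p": float(res.pvalue),
                "zero_variance": False,
            }
        )
    return pd.DataFrame(rows)


def session_effect_tests(counts: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Session effects on strong-ball counts to the instigators.

    Returns ``{"anova": ..., "transitions": ...}``: a one-way repeated-
    measures ANOVA over the 8 sessions for strong balls to P1 and to P3
    (uncorrected df, i.e. F(7, 7*(n-1))), and paired t tests for the
    boost-message transition (P3, sessions 5 to 6) and the threat/boost
    transition (P1, sessions 6 to 7).
    """
    have = set(counts["session"].unique())
    if have != set(range(1, N_SESSIONS + 1)):
        raise ValueError(f"counts must cover sessions 1..{N_SESSIONS}, got {sorted(have)}")

    anova_rows = []
    n_subj = counts["participant_id"].nunique()
    for target in ("P1", "P3"):
        if counts[f"strong_{target}"].nunique() == 1:
            # degenerate constant counts: no session effect by convention
            anova_rows.append(
                {
                    "target": target,
                    "F": 0.0,
                    "df1": N_SESSIONS - 1,
                    "df2": (N_SESSIONS - 1) * (n_subj - 1),
                    "p": 1.0,
                }
            )
            continue
        aov = pg.rm_anova(
            data=counts,
            dv=f"strong_{target}",
            within="session",
            subject="participant_id",
            correction=False,
            detailed=False,
        )
        anova_rows.append(
            {
                "target": target,
                "F": float(aov.loc[0, "F"]),
                "df1": int(aov.loc[0, "ddof1"]),
                "df2": int(aov.loc[0, "ddof2"]),
                "p": float(aov.loc[0, "p_unc"]),
            }
        )

    wide = counts.pivot(index="participant_id", columns="session")
    trans_rows = []
    for target, s_from, s_to in (("P3", 5, 6), ("P1", 6, 7)):
        a = wide[(f"strong_{target}", s_from)].to_numpy(dtype=float)
        b = wide[(f"strong_{target}", s_to)].to_numpy(dtype=float)
        if np.all(a == b):
            t_val, p_val = 0.0, 1.0
        else:
            res = stats.ttest_rel(b, a)
            t_val, p_val = float(res.statistic), float(res.pvalue)
        trans_rows.append(
            {
                "target": target,
                "session_from": s_from,
                "session_to": s_to,
                "t": t_val,
                "df": len(a) - 1,
                "p": p_val,
            }
        )
    return {"anova": pd.DataFrame(anova_rows), "transitions": pd.DataFrame(trans_rows)}


def _studentized_outliers(x: np.ndarray, y: np.ndarray, threshold: float = 3.0) -> np.ndarray:
    """Boolean mask of points with |externally studentized residual| > threshold
    in the simple regression of y on x."""
    model = sm.OLS(y, sm.add_constant(x)).fit()
    resid = OLSInfluence(model).resid_studentized_external
    return np.abs(resid) > threshold


def trait_regression(
    df: pd.DataFrame,
    outcome: str,
    predictors: Sequence[str],
    exclude_outliers: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """OLS of a behavioral parameter on a trait set, plus bivariate r.

    Returns ``(coefficients, correlations)``.  The coefficient table is the
    multiple regression with intercept (coef, t, p per predictor); the
    correlation table gives the simple Pearson r between the outcome and each
    predictor.  With ``exclude_outliers`` points with |externally studentized
    residual| > 3 in the bivariate fit are dropped from that correlation
    (off by default; the exclusion rule is a convention).
    """
    if outcome not in ("beta3", "beta6"):
        raise ValueError(f"outcome must be 'beta3' or 'beta6', got {outcome!r}")
    predictors = list(predictors)
    if len(df) <= len(predictors) + 1:
        raise ValueError("need n > number of predictors + 1")
    X = df[predictors].to_numpy(dtype=float)
    y = df[outcome].to_numpy(dtype=float)
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X])) < len(predictors) + 1:
        raise ValueError("rank-deficient predictor matrix; drop collinear traits")

    fit = sm.OLS(y, sm.add_constant(pd.DataFrame(X, columns=predictors))).fit()
    coef = pd.DataFrame(
        {
            "predictor": ["intercept"] + predictors,
            "coef": fit.params.to_numpy(),
            "t": fit.tvalues.to_numpy(),
            "p": fit.pvalues.to_numpy(),
        }
    )

    corr_rows = []
    for j, pred in enumerate(predictors):
        xj, yj = X[:, j], y
        if exclude_outliers:
            keep = ~_studentized_outliers(xj, yj)
            xj, yj = xj[keep], yj[keep]
        r, p = stats.pearsonr(xj, yj)
        corr_rows.append({"predictor": pred, "r": float(r), "p": float(p), "n": len(xj)})
    return coef, pd.DataFrame(corr_rows)
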