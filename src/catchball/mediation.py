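"""Single-mediator path analysis with bootstrap inference on the indirect effect.

The model is the classic three-variable decomposition

    M = i_a + a X            (path a)
    Y = i_b + c' X + b M     (paths b and c')
    Y = i_c + c X            (total effect c)

with the algebraic identity c = c' + a*b holding exactly for least-squares
point estimates in the no-covariate case.  Inference on the indirect effect
a*b uses a nonparametric bootstrap over participants (percentile two-sided p
by default, bias-corrected as an option); per-path standard errors and
normal-theory z/p are also reported.  In this package X is a trait score
(e.g. extraversion), M a connectivity edge, and Y a behavioral parameter
(e.g. the target-change coefficient b6).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MediationResult", "mediate", "mediation_screen"]


@dataclass(frozen=True)
class MediationResult:
    a: float
    b: float
    c: float
    c_prime: float
    ab: float
    se_a: float
    se_b: float
    se_c: float
    se_c_prime: float
    z_a: float
    z_b: float
    z_c: float
    z_c_prime: float
    p_a: float
    p_b: float
    p_c: float
    p_c_prime: float
    boot_p_ab: float
    boot_z_ab: float
    n_boot: int


def _simple_paths(x: np.ndarray, m: np.ndarray, y: np.ndarray):
    """Closed-form OLS paths; works on 1-D or (B, n) batched arrays."""
    xc = x - x.mean(axis=-1, keepdims=True)
    mc = m - m.mean(axis=-1, keepdims=True)
    yc = y - y.mean(axis=-1, keepdims=True)
    sxx = (xc * xc).sum(axis=-1)
    smm = (mc * mc).sum(axis=-1)
    sxm = (xc * mc).sum(axis=-1)
    sxy = (xc * yc).sum(axis=-1)
    smy = (mc * yc).sum(axis=-1)
    a = sxm / sxx
    c = sxy / sxx
    det = sxx * smm - sxm * sxm
    c_prime = (smm * sxy - sxm * smy) / det
    b = (sxx * smy - sxm * sxy) / det
    return a, b, c, c_prime


def _ols_se(x_cols: list[np.ndarray], y: np.ndarray) -> np.ndarray:
    """Classical OLS standard errors for a regression with intercept."""
    X = np.column_stack([np.ones(len(y))] + x_cols)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sigma2 = (resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return np.sqrt(np.diag(cov))[1:]


def mediate(
    x: Sequence[float],
    m: Sequence[float],
    y: Sequence[float],
    n_boot: int = 10_000,
    seed: int = 0,
    standardize: bool = False,
    bias_corrected: bool = False,
) -> MediationResult:
    """Estimate the mediation paths and bootstrap the indirect effect.

    The bootstrap resamples participants with replacement (``n_boot`` >= 1000,
    deterministic given ``seed``).  ``boot_p_ab`` is the two-sided percentile
    p: twice the smaller tail of the bootstrap a*b distribution around zero
    (bias-corrected variant on request).  ``boot_z_ab`` is the point estimate
    divided by the bootstrap standard deviation.  Variables are z-scored
    first only when ``standardize`` is set; path coefficients are otherwise
    on the raw scales.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (len(x) == len(m) == len(y)):
        raise ValueError("x, m, y must have equal lengths")
    n = len(x)
    if n < 10:
        raise ValueError(f"need at least 10 participants, got {n}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(m)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in mediation inputs")
    for name, v in (("x", x), ("m", m), ("y", y)):
        if v.std() == 0:
            raise ValueError(f"zero variance in {name}")
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000")
    if standardize:
        x = (x - x.mean()) / x.std()
        m = (m - m.mean()) / m.std()
        y = (y - y.mean()) / y.std()

    a, b, c, c_prime = (float(v) for v in _simple_paths(x, m, y))
    ab = a * b

    se_a = float(_ols_se([x], m)[0])
    se_c = float(_ols_se([x], y)[0])
    se_cp, se_b = (float(v) for v in _ols_se([x, m], y))

    def z_p(coef: float, se: float) -> tuple[float, float]:
        z = coef / se
        return z, float(2 * stats.norm.sf(abs(z)))

    z_a, p_a = z_p(a, se_a)
    z_b, p_b = z_p(b, se_b)
    z_c, p_c = z_p(c, se_c)
    z_cp, p_cp = z_p(c_prime, se_cp)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    a_b, b_b, _, _ = _simple_paths(x[idx], m[idx], y[idx])
    ab_boot = a_b * b_b
    ab_boot = ab_boot[np.isfinite(ab_boot)]
    nb = len(ab_boot)

    prop_le = np.mean(ab_boot <= 0)
    prop_ge = np.mean(ab_boot >= 0)
    if bias_corrected:
        frac_below = np.clip(np.mean(ab_boot < ab), 1 / (nb + 1), nb / (nb + 1))
        z0 = stats.norm.ppf(frac_below)
        q = np.clip(np.mean(ab_boot <= 0), 1 / (nb + 1), nb / (nb + 1))
        p_one = float(stats.norm.cdf(stats.norm.ppf(q) - 2 * z0))
        boot_p = 2 * min(p_one, 1 - p_one)
    else:
        boot_p = 2 * min(prop_le, prop_ge)
    boot_p = float(np.clip(boot_p, 1 / nb, 1.0))
    sd_boot = ab_boot.std(ddof=1)
    boot_z = float(ab / sd_boot) if sd_boot > 0 else np.inf

    return MediationResult(
        a=a, b=b, c=c, c_prime=c_prime, ab=ab,
        se_a=se_a, se_b=se_b, se_c=se_c, se_c_prime=se_cp,
        z_a=z_a, z_b=z_b, z_c=z_c, z_c_prime=z_cp,
        p_a=p_a, p_b=p_b, p_c=p_c, p_c_prime=p_cp,
        boot_p_ab=boot_p, boot_z_ab=boot_z, n_boot=n_boot,
    )


def mediation_screen(
    candidates: Sequence[tuple[str, str, str]],
    cohort: pd.DataFrame,
    n_boot: int = 10_000,
    seed: int = 0,
    **mediate_kwargs,
) -> pd.DataFrame:
    """Run :func:`mediate` over (x, m, y) column triples of a cohort table.

    Each candidate is ``(x_column, m_column, y_column)`` — typically a trait,
    an edge, and a behavioral parameter.  Rows flag significance of the
    indirect effect at alpha = 0.05 and marginal significance at 0.1;
    per-candidate failures are recorded in an ``error`` column rather than
    aborting the screen.
    """
    if len(candidates) == 0:
        raise ValueError("empty candidate list")
    seeds = np.random.SeedSequence(seed).generate_state(len(candidates)) % (2**31)
    rows = []
    for (x_col, m_col, y_col), s in zip(candidates, seeds):
        row: dict = {"x": x_col, "m": m_col, "y": y_col}
        try:
            res = mediate(
                cohort[x_col], cohort[m_col], cohort[y_col],
                n_boot=n_boot, seed=int(s), **mediate_kwargs,
            )
        except Exception as exc:  # noqa: BLE001 - screen must not abort
            row.update(
                {k: np.nan for k in ("a", "b", "c", "c_prime", "ab", "boot_p_ab", "boot_z_ab")}
            )
            row.update({"significant": False, "marginal": False, "error": str(exc)})
        else:
            row.update(
                {
                    "a": res.a, "b": res.b, "c": res.c, "c_prime": res.c_prime,
                    "ab": res.ab, "boot_p_ab": res.boot_p_ab, "boot_z_ab": res.boot_z_ab,
                    "significant": res.boot_p_ab < 0.05,
                    "marginal": res.boot_p_ab < 0.1,
                    "error": "",
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)
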