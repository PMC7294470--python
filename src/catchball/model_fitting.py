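"""Per-participant maximum-likelihood estimation of the utility-model parameters.

The intercept b0 cancels in the softmax and is therefore fixed at 0 and
reported as 0.  The remaining parameters (b1..b6, slope) are estimated by
bound-constrained quasi-Newton minimization (L-BFGS-B with an analytic
gradient) of the negative log-likelihood, with multiple restarts because the
joint (beta, slope) problem is scale-degenerate: (k*slope, beta/k) yields the
same likelihood for any k > 0.  The recommended path fixes slope = 1, which
makes the problem an ordinary (convex) multinomial logit and the coefficients
directly interpretable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .behavior_model import (
    DEFAULT_OPTIONS,
    BetaVector,
    ModelOptions,
    TaskRecord,
    build_design,
    N_TRIALS,
)

__all__ = ["FitConfig", "BetaEstimate", "fit_participant", "fit_cohort", "estimates_to_frame"]

logger = logging.getLogger(__name__)

PARAM_NAMES = ("beta1", "beta2", "beta3", "beta4", "beta5", "beta6", "slope")

#: box bounds: the printed-looking estimate "10.000" for a target-changer
#: suggests an active bound at 10, adopted as the default box.
DEFAULT_BOUNDS = tuple([(-10.0, 10.0)] * 6 + [(0.0, 10.0)])


@dataclass(frozen=True)
class FitConfig:
    """Optimizer plumbing for one maximum-likelihood fit."""

    bounds: tuple[tuple[float, float], ...] = DEFAULT_BOUNDS
    n_restarts: int = 10
    init_strategy: str = "zeros"  # first restart; remainder uniform in bounds
    tolerance: float = 1e-9
    seed: int = 0
    fix_slope: bool = False
    slope_value: float = 1.0
    options: ModelOptions = DEFAULT_OPTIONS

    def __post_init__(self) -> None:
        if len(self.bounds) != 7:
            raise ValueError("bounds must cover beta1..beta6 and slope (7 intervals)")
        for lo, hi in self.bounds:
            if lo > hi:
                raise ValueError(f"invalid bound ({lo}, {hi})")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.init_strategy not in ("zeros", "random-uniform-in-bounds"):
            raise ValueError(f"unknown init_strategy {self.init_strategy!r}")


@dataclass(frozen=True)
class BetaEstimate:
    beta: BetaVector
    nll: float
    converged: bool
    n_restarts_used: int
    at_bound: frozenset[str] = field(default_factory=frozenset)
    #: coefficients whose regressor is identically zero over the record (the
    #: change gate may never open); reported as 0, excluded from optimization
    unidentified: frozenset[str] = field(default_factory=frozenset)


def _nll_and_grad(theta: np.ndarray, G: np.ndarray, chosen: np.ndarray, fix_slope: bool, slope_value: float):
    """NLL and its gradient in the free parameters.

    With u = G @ b, z = slope*u:
        dNLL/db_k    = -slope * sum_t (G[t, x_t, k] - E_p[G[t, ., k]])
        dNLL/dslope  = -sum_t (u[t, x_t] - E_p[u[t, .]])
    """
    nb = G.shape[2]
    b = theta[:nb]
    slope = slope_value if fix_slope else theta[nb]
    u = G @ b
    z = slope * u
    zmax = z.max(axis=1, keepdims=True)
    ez = np.exp(z - zmax)
    denom = ez.sum(axis=1)
    p = ez / denom[:, None]
    t_idx = np.arange(len(chosen))
    ll = (z[t_idx, chosen] - zmax[:, 0]) - np.log(denom)
    nll = -ll.sum()

    g_chosen = G[t_idx, chosen, :]  # (T, 6)
    g_expect = np.einsum("ta,tak->tk", p, G)
    grad_b = -slope * (g_chosen - g_expect).sum(axis=0)
    if fix_slope:
        return nll, grad_b
    u_chosen = u[t_idx, chosen]
    u_expect = (p * u).sum(axis=1)
    grad_slope = -(u_chosen - u_expect).sum()
    return nll, np.concatenate([grad_b, [grad_slope]])


def _initial_points(config: FitConfig, rng: np.random.Generator) -> list[np.ndarray]:
    lo = np.array([b[0] for b in config.bounds])
    hi = np.array([b[1] for b in config.bounds])
    inits = []
    if config.init_strategy == "zeros":
        x0 = np.zeros(7)
        x0[6] = np.clip(1.0, lo[6], hi[6])  # slope 0 is a stationary plateau
        inits.append(np.clip(x0, lo, hi))
    while len(inits) < config.n_restarts:
        inits.append(rng.uniform(lo, hi))
    return inits[: config.n_restarts]


def fit_participant(record: TaskRecord, config: FitConfig | None = None) -> BetaEstimate:
    """Best-of-restarts MLE of (beta1..beta6, slope) for one record.

    Deterministic given ``config.seed``.  If every restart fails to converge
    the best iterate is still returned with ``converged=False``.
    """
    config = config or FitConfig()
    n_p2 = len(record.p2_indices())
    if n_p2 < N_TRIALS:
        warnings.warn(
            f"record {record.participant_id!r} has {n_p2} participant throws "
            f"(expected {N_TRIALS}); fitting anyway",
            stacklevel=2,
        )
    G, chosen = build_design(record, config.options)
    rng = np.random.default_rng(config.seed)

    # A regressor that is identically zero over the record (e.g. the change
    # gate for a participant who never met its precondition) leaves its
    # coefficient with a flat likelihood; it is pinned at 0 and flagged
    # rather than letting optimizer noise assign it an arbitrary value.
    active = [k for k in range(6) if np.any(G[:, :, k] != 0.0)]
    unidentified = frozenset(PARAM_NAMES[k] for k in range(6) if k not in active)
    Ga = G[:, :, active]

    free_idx = list(active) if config.fix_slope else list(active) + [6]
    bounds_free = [config.bounds[i] for i in free_idx]

    best_x = None
    best_nll = np.inf
    any_success = False
    for x0 in _initial_points(config, rng):
        x0_free = x0[free_idx]
        if not config.fix_slope:
            x0_free = np.concatenate([x0[active], [x0[6]]])
        res = minimize(
            _nll_and_grad,
            x0_free,
            args=(Ga, chosen, config.fix_slope, config.slope_value),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds_free,
            options={"ftol": config.tolerance, "gtol": 1e-8, "maxiter": 500},
        )
        any_success = any_success or bool(res.success)
        # strict improvement beyond a tie tolerance keeps near-flat ridge
        # solutions pinned at the earliest restart (the zeros initialization)
        if res.fun < best_nll - 1e-5:
            best_nll = float(res.fun)
            best_x = res.x

    assert best_x is not None
    theta = np.zeros(7)
    theta[active] = best_x[: len(active)]
    theta[6] = config.slope_value if config.fix_slope else best_x[-1]

    at_bound = set()
    for i, name in enumerate(PARAM_NAMES):
        if name in unidentified or (config.fix_slope and name == "slope"):
            continue
        lo, hi = config.bounds[i]
        if abs(theta[i] - lo) < 1e-6 or abs(theta[i] - hi) < 1e-6:
            at_bound.add(name)

    return BetaEstimate(
        beta=BetaVector.from_array(theta[:6], slope=theta[6]),
        nll=best_nll,
        converged=any_success,
        n_restarts_used=config.n_restarts,
        at_bound=frozenset(at_bound),
        unidentified=unidentified,
    )


def fit_cohort(
    records: Sequence[TaskRecord], config: FitConfig | None = None
) -> list[BetaEstimate]:
    """Fit every record; per-record failures are logged, not fatal."""
    if len(records) == 0:
        raise ValueError("fit_cohort requires at least one record")
    config = config or FitConfig()
    estimates: list[BetaEstimate] = []
    for rec in records:
        try:
            est = fit_participant(rec, config)
        except Exception as exc:  # noqa: BLE001 - cohort must not abort
            logger.warning("fit failed for %s: %s", rec.participant_id, exc)
            est = BetaEstimate(
                beta=BetaVector(), nll=float("nan"), converged=False, n_restarts_used=0
            )
        else:
            logger.info(
                "fit %s: nll=%.3f converged=%s at_bound=%s",
                rec.participant_id,
                est.nll,
                est.converged,
                sorted(est.at_bound),
            )
        estimates.append(est)
    return estimates


def estimates_to_frame(
    estimates: Sequence[BetaEstimate], participant_ids: Sequence[str] | None = None
) -> pd.DataFrame:
    """Tidy per-participant table: beta0..beta6, slope, nll, converged."""
    rows = []
    for i, est in enumerate(estimates):
        row = {
            "participant_id": participant_ids[i] if participant_ids else f"sub-{i + 1:03d}",
            "beta0": est.beta.beta0,
        }
        row.update({f"beta{k}": getattr(est.beta, f"beta{k}") for k in range(1, 7)})
        row["slope"] = est.beta.slope
        row["nll"] = est.nll
        row["converged"] = est.converged
        rows.append(row)
    return pd.DataFrame(rows)
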