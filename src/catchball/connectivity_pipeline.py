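"""Connectivity-to-behavior association pipeline.

Edges are Fisher-z transformed ROI-to-ROI correlations.  Because the number
of edges (10,585 for 146 ROIs) dwarfs the cohort size, edges predicting a
behavioral parameter are first selected with an L1-penalized linear model
(LASSO) whose penalty is chosen at the minimum mean 10-fold cross-validated
error; the selected edges are then tested individually with Pearson
correlations under a Bonferroni correction whose family size is the number
of selected edges.

Selection and testing deliberately use the same cohort — the pipeline
reproduces that (statistically circular) procedure rather than correcting
it, and the resulting p values should be read accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso, LassoCV

from .synthetic_cohort import ConnectivityMatrix

__all__ = [
    "EdgeSet",
    "LassoSelection",
    "fisher_z",
    "edge_set_from_matrices",
    "edges_from_timeseries",
    "stratified_folds",
    "lasso_select",
    "edge_correlation_tests",
]


def fisher_z(r):
    """Variance-stabilizing Fisher transformation atanh(r); |r| must be < 1."""
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) >= 1):
        raise ValueError("fisher_z requires |r| < 1 (perfect correlations are undefined)")
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) or arr.ndim == 0 else out


@dataclass(frozen=True)
class EdgeSet:
    """Upper-triangle edges (i < j) with a participants x edges value matrix."""

    edges: tuple[tuple[int, int], ...]
    values: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != len(self.edges):
            raise ValueError("values must be (participants x edges)")
        if len(set(self.edges)) != len(self.edges):
            raise ValueError("duplicate edges")
        for i, j in self.edges:
            if not i < j:
                raise ValueError(f"edges must have i < j, got ({i}, {j})")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "edges", tuple(self.edges))

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    def edge_label(self, k: int) -> tuple[str, str]:
        i, j = self.edges[k]
        if self.labels is None:
            return (f"ROI_{i + 1:03d}", f"ROI_{j + 1:03d}")
        return (self.labels[i], self.labels[j])


@dataclass(frozen=True)
class LassoSelection:
    lambda_opt: float
    selected: tuple[int, ...]  # column indices into the edge set
    coefs: np.ndarray
    cv_folds: int
    edge_set: EdgeSet

    def __post_init__(self) -> None:
        if self.lambda_opt <= 0:
            raise ValueError("lambda_opt must be > 0")


def edge_set_from_matrices(matrices: Sequence[ConnectivityMatrix]) -> EdgeSet:
    """Stack each participant's upper triangle into an edge-value matrix."""
    if not matrices:
        raise ValueError("no connectivity matrices supplied")
    n_roi = matrices[0].n_roi
    labels = matrices[0].roi_labels
    iu = np.triu_indices(n_roi, k=1)
    vals = np.stack([m.values[iu] for m in matrices])
    edges = tuple((int(i), int(j)) for i, j in zip(iu[0], iu[1]))
    return EdgeSet(edges=edges, values=vals, labels=labels)


def edges_from_timeseries(
    timeseries: Sequence[np.ndarray], labels: Sequence[str] | None = None
) -> EdgeSet:
    """Pearson correlations between ROI time courses, Fisher-z transformed.

    Each participant array is (timepoints x ROIs) with >= 3 timepoints.  An
    edge touching a constant time series, or a perfect |r| = 1, is flagged
    undefined (NaN) rather than rejected wholesale.
    """
    if not timeseries:
        raise ValueError("no time series supplied")
    n_roi = timeseries[0].shape[1]
    if n_roi < 2:
        raise ValueError("need at least 2 ROIs")
    iu = np.triu_indices(n_roi, k=1)
    rows = []
    for ts in timeseries:
        if ts.shape[0] < 3:
            raise ValueError("need at least 3 timepoints")
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(ts.T)[iu]
            r = np.where(np.abs(r) >= 1, np.nan, r)
            rows.append(np.arctanh(r))
    edges = tuple((int(i), int(j)) for i, j in zip(iu[0], iu[1]))
    return EdgeSet(edges=edges, values=np.stack(rows), labels=tuple(labels) if labels else None)


def stratified_folds(outcome: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Deterministic fold ids, stratified by outcome quantile.

    Participants are sorted by outcome; within each consecutive block of
    ``n_folds`` the fold labels are a seeded permutation, so every fold spans
    the outcome range — important at small n, where fold-to-fold variance
    otherwise dominates the cross-validation curve.
    """
    n = len(outcome)
    if n_folds < 2 or n_folds > n:
        raise ValueError("need n >= folds >= 2")
    rng = np.random.default_rng(seed)
    order = np.argsort(outcome, kind="stable")
    folds = np.empty(n, dtype=int)
    for start in range(0, n, n_folds):
        block = order[start : start + n_folds]
        folds[block] = rng.permutation(n_folds)[: len(block)]
    return folds


def lasso_select(
    edge_set: EdgeSet,
    outcome: np.ndarray,
    folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 100,
    lambda_value: float | None = None,
) -> LassoSelection:
    """LASSO edge selection with the penalty at minimum mean CV error.

    Edges are standardized to unit variance before the penalized fit (the
    coefficients reported are on that standardized scale).  The selected
    edges are those with nonzero coefficients at the optimal penalty.  A
    fixed ``lambda_value`` (must be > 0) bypasses cross-validation; as the
    penalty grows the selection shrinks to the empty set, and as it vanishes
    (with fewer edges than participants) it approaches the OLS support.
    """
    y = np.asarray(outcome, dtype=float)
    if len(y) != edge_set.n_participants:
        raise ValueError("outcome length must match the number of participants")
    if y.std() == 0:
        raise ValueError("zero-variance outcome; nothing to predict")
    X = edge_set.values
    sd = X.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    Xs = (X - X.mean(axis=0)) / sd_safe

    if lambda_value is not None:
        if lambda_value <= 0:
            raise ValueError("lambda_value must be > 0")
        fixed = Lasso(alpha=lambda_value, max_iter=200_000, tol=1e-10)
        fixed.fit(Xs, y)
        coefs, lambda_opt = fixed.coef_.copy(), float(lambda_value)
    else:
        fold_ids = stratified_folds(y, folds, seed)
        cv_splits = [
            (np.where(fold_ids != k)[0], np.where(fold_ids == k)[0]) for k in range(folds)
        ]
        model = LassoCV(cv=cv_splits, alphas=n_lambdas, max_iter=50_000)
        model.fit(Xs, y)
        coefs, lambda_opt = model.coef_.copy(), float(model.alpha_)

    selected = tuple(int(k) for k in np.flatnonzero(coefs))
    return LassoSelection(
        lambda_opt=lambda_opt,
        selected=selected,
        coefs=coefs,
        cv_folds=folds,
        edge_set=edge_set,
    )


def edge_correlation_tests(
    selection: LassoSelection, outcome: np.ndarray
) -> pd.DataFrame:
    """Pearson tests of each selected edge against the behavioral parameter.

    The Bonferroni family is the number of selected edges; an edge passes iff
    its uncorrected p < 0.05 / family.  The table also carries the family
    threshold and, for reference, the conventional 1e-4 uncorrected cutoff.
    """
    if not selection.selected:
        raise ValueError("no selected edges to test")
    y = np.asarray(outcome, dtype=float)
    family = len(selection.selected)
    threshold = 0.05 / family
    rows = []
    for k in selection.selected:
        x = selection.edge_set.values[:, k]
        r, p = stats.pearsonr(x, y)
        li, lj = selection.edge_set.edge_label(k)
        i, j = selection.edge_set.edges[k]
        rows.append(
            {
                "edge_i": i,
                "edge_j": j,
                "label_i": li,
                "label_j": lj,
                "R": float(r),
                "p": float(p),
                "bonferroni_pass": bool(p < threshold),
                "bonferroni_threshold": threshold,
                "p_lt_1e4": bool(p < 1e-4),
            }
        )
    return pd.DataFrame(rows).sort_values("p", ignore_index=True)
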