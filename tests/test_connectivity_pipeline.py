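"""Tests of edge construction, LASSO selection and Bonferroni edge testing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from catchball.connectivity_pipeline import (
    EdgeSet,
    edge_correlation_tests,
    edge_set_from_matrices,
    edges_from_timeseries,
    fisher_z,
    lasso_select,
    stratified_folds,
)
from catchball.synthetic_cohort import (
    PlantedEffect,
    generate_connectivity,
    generate_profiles,
    generate_roi_timeseries,
)


def _planted_edge_set(n, n_noise_edges, r, seed):
    """One planted edge at column 0 among pure-noise edges."""
    rng = np.random.default_rng(seed)
    y = rng.standard_normal(n)
    z = (y - y.mean()) / y.std()
    X = rng.standard_normal((n, n_noise_edges + 1))
    X[:, 0] = r * z + np.sqrt(1 - r * r) * rng.standard_normal(n)
    n_roi = 2
    while n_roi * (n_roi - 1) // 2 < n_noise_edges + 1:
        n_roi += 1
    iu = np.triu_indices(n_roi, k=1)
    edges = tuple((int(a), int(b)) for a, b in zip(*iu))[: n_noise_edges + 1]
    return EdgeSet(edges=edges, values=X), y


class TestFisherZ:
    def test_values_and_symmetry(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)
        assert fisher_z(-0.3) == -fisher_z(0.3)

    @given(st.floats(-0.999, 0.999))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_round_trip(self, r):
        assert np.tanh(fisher_z(r)) == pytest.approx(r, abs=1e-12)

    def test_perfect_correlation_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(1.0)


class TestEdgeConstruction:
    def test_edge_count_combinatorial(self):
        ts = generate_roi_timeseries(3, n_roi=146, n_timepoints=10, seed=1)
        es = edges_from_timeseries(ts)
        assert len(es.edges) == 146 * 145 // 2 == 10_585

    def test_constant_series_flagged_undefined(self):
        ts = [np.column_stack([np.ones(20), np.arange(20.0), np.random.default_rng(0).standard_normal(20)])]
        es = edges_from_timeseries(ts)
        assert np.isnan(es.values[0, 0])  # constant vs linear column

    def test_identical_series_flagged(self):
        x = np.random.default_rng(1).standard_normal(30)
        es = edges_from_timeseries([np.column_stack([x, x])])
        assert np.isnan(es.values[0, 0])

    def test_null_edges_centered_at_zero(self):
        ts = generate_roi_timeseries(40, n_roi=8, n_timepoints=192, seed=2)
        es = edges_from_timeseries(ts)
        assert abs(np.nanmean(es.values)) < 0.01

    def test_from_matrices_matches_upper_triangle(self):
        profiles = generate_profiles(6, seed=3)
        mats = generate_connectivity(profiles, planted=(), n_roi=5, seed=4)
        es = edge_set_from_matrices(mats)
        assert len(es.edges) == 10
        k = es.edges.index((1, 3))
        np.testing.assert_allclose(es.values[:, k], [m.values[1, 3] for m in mats])


class TestStratifiedFolds:
    def test_deterministic_and_balanced(self):
        y = np.random.default_rng(5).standard_normal(43)
        a = stratified_folds(y, 10, seed=7)
        b = stratified_folds(y, 10, seed=7)
        np.testing.assert_array_equal(a, b)
        sizes = np.bincount(a, minlength=10)
        assert sizes.min() >= 4 and sizes.max() <= 5

    def test_every_fold_spans_outcome_range(self):
        y = np.sort(np.random.default_rng(6).standard_normal(50))
        folds = stratified_folds(y, 5, seed=8)
        for k in range(5):
            sel = y[folds == k]
            assert sel.min() < np.percentile(y, 30)
            assert sel.max() > np.percentile(y, 70)


class TestLassoSelect:
    def test_huge_penalty_selects_nothing(self):
        es, y = _planted_edge_set(60, 50, 0.5, seed=9)
        sel = lasso_select(es, y, folds=5, seed=0, lambda_value=1e6)
        assert sel.selected == ()

    def test_tiny_penalty_approaches_ols_support(self):
        # fewer edges than participants: the unpenalized limit is OLS
        rng = np.random.default_rng(10)
        X = rng.standard_normal((40, 5))
        beta = np.array([1.0, 0.0, -2.0, 0.0, 0.5])
        y = X @ beta + 0.1 * rng.standard_normal(40)
        es = EdgeSet(edges=((0, 1), (0, 2), (0, 3), (0, 4), (1, 2)), values=X)
        sel = lasso_select(es, y, folds=5, seed=0, lambda_value=1e-6)
        coef_ols = np.linalg.lstsq(
            np.column_stack([np.ones(40), (X - X.mean(0)) / X.std(0)]), y, rcond=None
        )[0][1:]
        np.testing.assert_allclose(sel.coefs, coef_ols, atol=1e-3)
        assert set(sel.selected) >= {0, 2, 4}

    def test_planted_edge_selected_and_ordering_invariant(self):
        es, y = _planted_edge_set(120, 200, 0.5, seed=11)
        sel = lasso_select(es, y, folds=10, seed=1)
        assert 0 in sel.selected
        perm = np.random.default_rng(12).permutation(120)
        es_p = EdgeSet(edges=es.edges, values=es.values[perm])
        sel_p = lasso_select(es_p, y[perm], folds=10, seed=1)
        assert sel_p.selected == sel.selected
        assert sel_p.lambda_opt == pytest.approx(sel.lambda_opt)

    def test_zero_variance_outcome_rejected(self):
        es, _ = _planted_edge_set(30, 10, 0.3, seed=13)
        with pytest.raises(ValueError, match="variance"):
            lasso_select(es, np.ones(30), folds=5)


class TestEdgeCorrelationTests:
    def test_planted_edge_passes_bonferroni(self):
        es, y = _planted_edge_set(200, 500, 0.5, seed=14)
        sel = lasso_select(es, y, folds=10, seed=2)
        res = edge_correlation_tests(sel, y)
        top = res.iloc[0]
        assert (top["edge_i"], top["edge_j"]) == es.edges[0]
        assert top["bonferroni_pass"]
        assert res["bonferroni_threshold"].iloc[0] == pytest.approx(0.05 / len(sel.selected))

    def test_family_wise_error_controlled(self):
        """Bonferroni over pure-noise selected edges keeps FWER at ~alpha."""
        rng = np.random.default_rng(15)
        n, m = 43, 10
        false_hits = 0
        reps = 1000
        for _ in range(reps):
            X = rng.standard_normal((n, m))
            y = rng.standard_normal(n)
            es = EdgeSet(edges=tuple((0, j + 1) for j in range(m)), values=X)
            sel = lasso_select(es, y, folds=5, seed=0, lambda_value=1e-9)
            res = edge_correlation_tests(sel, y)
            false_hits += int(res["bonferroni_pass"].any())
        assert false_hits / reps == pytest.approx(0.05, abs=0.02)

    def test_report_carries_labels(self):
        profiles = generate_profiles(50, seed=16)
        mats = generate_connectivity(
            profiles, planted=(PlantedEffect((0, 2), "beta6", 0.6),), n_roi=6, seed=17
        )
        es = edge_set_from_matrices(mats)
        y = np.array([p.beta.beta6 for p in profiles])
        sel = lasso_select(es, y, folds=5, seed=3)
        res = edge_correlation_tests(sel, y)
        assert {"label_i", "label_j", "R", "p", "bonferroni_pass"} <= set(res.columns)
        assert "Insula_R" in set(res["label_i"]) | set(res["label_j"])
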