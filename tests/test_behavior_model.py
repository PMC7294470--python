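"""Unit and property tests for the utility model, softmax and likelihood."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from catchball.behavior_model import (
    ACTION_CODES,
    Action,
    BetaVector,
    ContextState,
    ModelOptions,
    ThrowEvent,
    choice_probabilities,
    context_state,
    feature_vector,
    negative_log_likelihood,
    participant_contexts,
    utility,
)

from conftest import toy_record

RAW = ModelOptions(z_normalize_tsb=False, change_mode="record")


# ---------------------------------------------------------------- oracle ---
# Independent re-implementation of the model from the printed case
# definitions: plain dict/loop arithmetic, no shared code with the package.

_ORACLE_F = {
    "N1": dict(f1=-1, f2=-1, f3=0.5, f4=-1, f5=0, f6=-1),
    "N3": dict(f1=-1, f2=-1, f3=0.5, f4=-1, f5=0, f6=-1),
    "N4": dict(f1=-1, f2=-1, f3=-1, f4=-1, f5=0, f6=-1),
    "S1": dict(f1=1, f2=-1, f3=-1, f4=-1, f5=1, f6=1),
    "S3": dict(f1=1, f2=-1, f3=-1, f4=-1, f5=1, f6=1),
    "S4": dict(f1=1, f2=1, f3=1, f4=1, f5=1, f6=-1),
}


def _oracle_code(e):
    return ("S" if e.strength == "strong" else "N") + e.target[1]


def oracle_nll(record, beta, z_normalize=False):
    """Brute-force NLL: every case definition evaluated literally per trial."""
    conf_table = {1: 0, 2: 0, 3: 0, 4: 1, 5: 2, 6: 2, 7: 2, 8: 2}
    p2 = [(i, e) for i, e in enumerate(record.events) if e.thrower == "P2"]
    # participant-level change indicator from the whole record
    pre = any(
        e.thrower == "P2" and e.target == "P4" and e.strength == "strong" and e.session in (4, 5)
        for e in record.events
    )
    man = any(
        e.thrower == "P2" and e.target in ("P1", "P3") and e.strength == "strong" and e.session >= 6
        for e in record.events
    )
    chg_flag = 1 if (pre and man) else 0

    tsbs = []
    for i, e in p2:
        tsbs.append(sum(1 for h in record.events[:i] if h.strength == "strong"))
    if z_normalize:
        mean = sum(tsbs) / len(tsbs)
        sd = math.sqrt(sum((v - mean) ** 2 for v in tsbs) / len(tsbs))
        tsbs = [0.0 if sd == 0 else (v - mean) / sd for v in tsbs]

    total = 0.0
    for (i, e), tsb in zip(p2, tsbs):
        s = e.session
        react = 1 if s == 3 else 0
        conf = conf_table[s]
        message = 1 if s >= 6 else 0
        change = chg_flag if s >= 6 else 0
        utils = {}
        for code, f in _ORACLE_F.items():
            utils[code] = (
                beta.beta0
                + beta.beta1 * f["f1"]
                + beta.beta2 * react * f["f2"]
                + beta.beta3 * conf * f["f3"]
                + beta.beta4 * message * f["f4"]
                + beta.beta5 * tsb * f["f5"]
                + beta.beta6 * change * f["f6"]
            )
        denom = sum(math.exp(beta.slope * u) for u in utils.values())
        total -= math.log(math.exp(beta.slope * utils[_oracle_code(e)]) / denom)
    return total


# ----------------------------------------------------------------- tests ---


class TestActionsAndFeatures:
    def test_six_legal_actions(self):
        assert ACTION_CODES == ("N1", "N3", "N4", "S1", "S3", "S4")
        with pytest.raises(ValueError, match="P2"):
            Action(target="P2", strength="strong")
        with pytest.raises(ValueError, match="X9"):
            feature_vector("X9")

    @pytest.mark.parametrize("code", ACTION_CODES)
    def test_feature_signs_match_case_table(self, code):
        f = feature_vector(code)
        expected = [_ORACLE_F[code][f"f{k}"] for k in range(1, 7)]
        assert f.tolist() == expected

    def test_normal_to_instigator_assists_half(self):
        assert feature_vector("N1")[2] == 0.5
        assert feature_vector("S4").tolist() == [1, 1, 1, 1, 1, -1]
        assert feature_vector("N4")[4] == 0  # normal balls do not accumulate


class TestContextState:
    def test_session_case_definitions(self, example_record):
        by_session = {}
        for i in example_record.p2_indices():
            ctx = context_state(example_record, i, RAW)
            by_session.setdefault(ctx.session, ctx)
        assert [by_session[s].react for s in range(1, 9)] == [0, 0, 1, 0, 0, 0, 0, 0]
        assert [by_session[s].conf for s in range(1, 9)] == [0, 0, 0, 1, 2, 2, 2, 2]
        assert [by_session[s].message for s in range(1, 9)] == [0, 0, 0, 0, 0, 1, 1, 1]

    def test_strong_ball_count_is_strict_history(self, example_record):
        idx = example_record.p2_indices()
        counts = [context_state(example_record, i, RAW).total_strong_balls for i in idx]
        assert counts[0] == 0.0  # no strong balls before the first decision
        assert counts == sorted(counts)  # non-decreasing
        # strictly-before convention: count at trial i excludes the throw at i
        last = idx[-1]
        expected = sum(1 for e in example_record.events[: last - 1] if e.is_strong)
        assert counts[-1] == expected

    def test_rejects_non_decision_points(self, example_record):
        agent_idx = next(
            i + 1 for i, e in enumerate(example_record.events) if e.thrower != "P2"
        )
        with pytest.raises(ValueError, match="not a participant decision"):
            context_state(example_record, agent_idx)
        with pytest.raises(IndexError):
            context_state(example_record, len(example_record.events) + 1)

    def test_change_modes(self):
        # conformed in s4, redirected in s7: record mode sets the gate for all
        # of sessions 6-8, causal mode only after the redirect happened
        rec = toy_record({4: ["S4"], 6: ["N1"], 7: ["S1", "N4"]})
        p2 = rec.p2_indices()
        rec_mode = [context_state(rec, i, RAW).change for i in p2]
        assert rec_mode == [0, 1, 1, 1]
        causal = ModelOptions(z_normalize_tsb=False, change_mode="causal")
        assert [context_state(rec, i, causal).change for i in p2] == [0, 0, 0, 1]
        onset = ModelOptions(z_normalize_tsb=False, change_mode="onset")
        assert [context_state(rec, i, onset).change for i in p2] == [0, 1, 1, 1]

    def test_no_precondition_no_change(self):
        rec = toy_record({5: ["N4"], 7: ["S1"]})
        assert [context_state(rec, i, RAW).change for i in rec.p2_indices()] == [0, 0]


class TestUtilityAndChoice:
    def test_zero_parameters_zero_utility(self):
        ctx = ContextState(1, 0, 0, 0, 0.0, 0)
        beta = BetaVector()
        assert all(utility(c, ctx, beta) == 0 for c in ACTION_CODES)

    def test_baseline_direction(self):
        ctx = ContextState(1, 0, 0, 0, 0.0, 0)
        beta = BetaVector(beta1=1.0)
        assert utility("S4", ctx, beta) == 1.0
        assert utility("N4", ctx, beta) == -1.0

    def test_conformity_hand_value(self):
        # b3 = 2, conf = 2, N1: 2 * 2 * 0.5 = 2
        ctx = ContextState(5, 0, 2, 0, 0.0, 0)
        assert utility("N1", ctx, BetaVector(beta3=2.0)) == pytest.approx(2.0)

    def test_uniform_when_indifferent(self):
        ctx = ContextState(1, 0, 0, 0, 0.0, 0)
        for beta in (BetaVector(), BetaVector(beta1=3.0, beta3=-2.0, slope=0.0)):
            p = choice_probabilities(ctx, beta)
            np.testing.assert_allclose(p, np.full(6, 1 / 6), atol=1e-12)

    def test_strong_dominance(self):
        ctx = ContextState(1, 0, 0, 0, 0.0, 0)
        p = choice_probabilities(ctx, BetaVector(beta1=10.0, slope=1.0))
        assert p[3] + p[4] + p[5] == pytest.approx(1.0, abs=1e-8)

    @given(
        b=st.lists(st.floats(-5, 5), min_size=6, max_size=6),
        slope=st.floats(0.0, 5.0),
        session=st.integers(1, 8),
        tsb=st.integers(0, 100),
        change=st.integers(0, 1),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_normalization_and_ties(self, b, slope, session, tsb, change):
        ctx = ContextState(
            session,
            1 if session == 3 else 0,
            {1: 0, 2: 0, 3: 0, 4: 1}.get(session, 2),
            1 if session >= 6 else 0,
            float(tsb),
            change if session >= 6 else 0,
        )
        beta = BetaVector.from_array(b, slope=slope)
        p = choice_probabilities(ctx, beta)
        assert abs(p.sum() - 1.0) < 1e-12
        # N1 = N3 and S1 = S3: identical feature vectors imply tied probabilities
        assert p[0] == pytest.approx(p[1], rel=1e-12, abs=1e-15)
        assert p[3] == pytest.approx(p[4], rel=1e-12, abs=1e-15)

    @given(
        b=st.lists(st.floats(-3, 3), min_size=6, max_size=6),
        slope=st.floats(0.1, 4.0),
        b0=st.floats(-20, 20),
        k=st.floats(0.1, 10.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_identifiability_invariances(self, b, slope, b0, k):
        """The softmax is blind to the intercept and to (slope*k, beta/k)."""
        ctx = ContextState(6, 0, 2, 1, 7.0, 1)
        base = BetaVector.from_array(b, slope=slope)
        p0 = choice_probabilities(ctx, base)
        shifted = BetaVector.from_array(b, slope=slope, beta0=b0)
        np.testing.assert_allclose(p0, choice_probabilities(ctx, shifted), atol=1e-10)
        rescaled = BetaVector.from_array(
            [v / k for v in b], slope=slope * k, beta0=0.0
        )
        np.testing.assert_allclose(p0, choice_probabilities(ctx, rescaled), atol=1e-10)


class TestNegativeLogLikelihood:
    def test_uniform_model_full_record(self, example_record):
        nll = negative_log_likelihood(example_record, BetaVector(), RAW)
        assert nll == pytest.approx(64 * math.log(6), abs=1e-10)

    def test_single_throw_uniform(self):
        rec = toy_record({1: ["N1"]})
        assert negative_log_likelihood(rec, BetaVector(), RAW) == pytest.approx(
            math.log(6), abs=1e-12
        )

    @pytest.mark.parametrize(
        "actions",
        [
            {1: ["N1", "S4"], 3: ["S3"]},
            {4: ["S4"], 6: ["S1", "N4"]},
            {2: ["N4"], 5: ["S4", "N1"], 8: ["S3", "S1"]},
        ],
    )
    @pytest.mark.parametrize("z_norm", [False, True])
    def test_oracle_equivalence_toy_records(self, actions, z_norm):
        """NLL matches an independent brute-force evaluation to 1e-10."""
        rec = toy_record(actions)
        beta = BetaVector(
            beta1=1.0, beta2=-0.5, beta3=0.8, beta4=-1.2, beta5=0.1, beta6=2.0, slope=1.3
        )
        opts = ModelOptions(z_normalize_tsb=z_norm, change_mode="record")
        assert negative_log_likelihood(rec, beta, opts) == pytest.approx(
            oracle_nll(rec, beta, z_normalize=z_norm), abs=1e-10
        )

    def test_oracle_equivalence_full_record(self, example_record):
        beta = BetaVector(beta1=-1.0, beta3=2.0, beta5=-0.05, beta6=1.5, slope=0.7)
        for z_norm in (False, True):
            opts = ModelOptions(z_normalize_tsb=z_norm, change_mode="record")
            assert negative_log_likelihood(example_record, beta, opts) == pytest.approx(
                oracle_nll(example_record, beta, z_normalize=z_norm), abs=1e-8
            )

    def test_rejects_empty_and_invalid(self):
        rec = toy_record({1: []})
        with pytest.raises(ValueError):
            negative_log_likelihood(rec, BetaVector())
        with pytest.raises(ValueError, match="cannot target itself"):
            ThrowEvent(1, 2, "P2", "P2", "normal")

    def test_z_normalized_contexts_have_unit_scale(self, example_record):
        ctxs = participant_contexts(example_record, ModelOptions(z_normalize_tsb=True))
        tsb = np.array([c.total_strong_balls for c in ctxs])
        assert abs(tsb.mean()) < 1e-10
        assert tsb.std() == pytest.approx(1.0, abs=1e-10)
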