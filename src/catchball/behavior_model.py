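"""Discrete-choice utility model of participant behavior in the catch-ball task.

The catch-ball task is a four-player ball-tossing paradigm (a relative of
Cyberball) in which three scripted computer agents (P1, P3, P4) and one human
participant (P2) take turns throwing a ball that can be *normal* or *strong*
(the strong ball is paired with an unpleasant sound, i.e. it is mildly
aggressive).  Over eight sessions the agents stage an episode of group
aggression against P4, send boost/threat messages to the participant, and the
participant's 64 throws are modeled as draws from a softmax (multinomial
logit) over six actions:

    N1, N3, N4  — normal ball to P1 / P3 / P4
    S1, S3, S4  — strong ball to P1 / P3 / P4

The utility of an action at trial ``t`` is a linear combination of six signed
feature functions, each gated by a session-dependent context regressor:

    U(X_t) = b0 + b1*f1 + b2*react(t)*f2 + b3*conf(t)*f3
           + b4*message(t)*f4 + b5*total_strong_balls(t)*f5
           + b6*change(t)*f6

with b1 the baseline propensity for aggression, b2 reactive revenge (active
only in session 3, when P4 attacks everyone), b3 conformity to the peers'
aggression, b4 capitulation to the threat message, b5 the accumulation effect
of all previously thrown strong balls, and b6 the target-change drive
(redirecting aggression from the victim P4 to the instigators P1/P3).  Choice
probabilities follow a softmax with inverse temperature ``slope``, and the
model is fit per participant by maximum likelihood (see
:mod:`catchball.model_fitting`).

This module houses the action space, the feature/regressor case tables, the
utility, the choice probabilities, and the negative log-likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

__all__ = [
    "PLAYERS",
    "TARGETS",
    "STRENGTHS",
    "ACTION_CODES",
    "ACTIONS",
    "Action",
    "ThrowEvent",
    "TaskRecord",
    "ContextState",
    "BetaVector",
    "ModelOptions",
    "DEFAULT_OPTIONS",
    "feature_vector",
    "context_state",
    "participant_contexts",
    "utility",
    "action_utilities",
    "choice_probabilities",
    "negative_log_likelihood",
    "build_design",
    "nll_from_design",
]

PLAYERS = ("P1", "P2", "P3", "P4")
#: players the participant (P2) may target
TARGETS = ("P1", "P3", "P4")
STRENGTHS = ("normal", "strong")
#: canonical action ordering used by every array in this package
ACTION_CODES = ("N1", "N3", "N4", "S1", "S3", "S4")

N_SESSIONS = 8
THROWS_PER_SESSION = 8
N_TRIALS = N_SESSIONS * THROWS_PER_SESSION  # 64 participant decisions


@dataclass(frozen=True)
class Action:
    """One of the participant's six possible throws (target x strength)."""

    target: str
    strength: str

    def __post_init__(self) -> None:
        if self.target not in TARGETS:
            raise ValueError(
                f"unknown action target {self.target!r}; the participant may "
                f"only target {TARGETS}"
            )
        if self.strength not in STRENGTHS:
            raise ValueError(f"unknown ball strength {self.strength!r}")

    @property
    def code(self) -> str:
        return ("S" if self.strength == "strong" else "N") + self.target[1]

    @classmethod
    def from_code(cls, code: str) -> "Action":
        if code not in ACTION_CODES:
            raise ValueError(f"unknown action code {code!r}; expected one of {ACTION_CODES}")
        return cls(target="P" + code[1], strength="strong" if code[0] == "S" else "normal")


ACTIONS = tuple(Action.from_code(c) for c in ACTION_CODES)
_ACTION_INDEX = {c: i for i, c in enumerate(ACTION_CODES)}

# Feature case table, rows f1..f6, columns in ACTION_CODES order.
#   f1: strong vs normal; f2/f4: strong-to-victim vs everything else;
#   f3: conformity direction (normal balls to the instigators count +0.5 as
#       indirect assistance); f5: strong-ball indicator (accumulation);
#   f6: strong ball redirected at an instigator.
_FEATURES = np.array(
    [
        #  N1    N3    N4    S1    S3    S4
        [-1.0, -1.0, -1.0, 1.0, 1.0, 1.0],  # f1
        [-1.0, -1.0, -1.0, -1.0, -1.0, 1.0],  # f2
        [0.5, 0.5, -1.0, -1.0, -1.0, 1.0],  # f3
        [-1.0, -1.0, -1.0, -1.0, -1.0, 1.0],  # f4
        [0.0, 0.0, 0.0, 1.0, 1.0, 1.0],  # f5
        [-1.0, -1.0, -1.0, 1.0, 1.0, -1.0],  # f6
    ]
)


def feature_vector(action: Action | str) -> np.ndarray:
    """Raw signed feature values ``(f1, ..., f6)`` for one action.

    These are the signs *before* context weighting; e.g. ``f3`` is +0.5 for a
    normal ball to P1 or P3 because such a throw indirectly assists the
    aggression against P4.
    """
    code = action if isinstance(action, str) else action.code
    if code not in _ACTION_INDEX:
        raise ValueError(f"unknown action {code!r}; expected one of {ACTION_CODES}")
    return _FEATURES[:, _ACTION_INDEX[code]].copy()


@dataclass(frozen=True)
class ThrowEvent:
    """A single throw by any player."""

    session: int
    trial_index: int
    thrower: str
    target: str
    strength: str

    def __post_init__(self) -> None:
        if not 1 <= self.session <= N_SESSIONS:
            raise ValueError(f"session must be 1..{N_SESSIONS}, got {self.session}")
        if self.thrower not in PLAYERS or self.target not in PLAYERS:
            raise ValueError(f"unknown player in throw {self!r}")
        if self.thrower == self.target:
            raise ValueError(f"a player cannot target itself: {self!r}")
        if self.strength not in STRENGTHS:
            raise ValueError(f"unknown strength {self.strength!r}")

    @property
    def is_strong(self) -> bool:
        return self.strength == "strong"


@dataclass(frozen=True)
class TaskRecord:
    """Complete event log of one participant's task run.

    ``events`` holds every throw by every player in chronological order;
    ``messages`` maps a session number to the message the participant received
    *before* that session ("boost" or "threat"; sessions 6 and 7 only).
    """

    participant_id: str
    events: tuple[ThrowEvent, ...]
    messages: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))
        object.__setattr__(self, "messages", dict(self.messages))

    def p2_indices(self) -> list[int]:
        """1-based positions (in ``events``) of the participant's decisions."""
        return [i + 1 for i, e in enumerate(self.events) if e.thrower == "P2"]

    def p2_events(self) -> list[ThrowEvent]:
        return [e for e in self.events if e.thrower == "P2"]

    def validate(self) -> None:
        """Check the structural invariants of a complete task run."""
        sessions = [e.session for e in self.events]
        if any(b < a for a, b in zip(sessions, sessions[1:])):
            raise ValueError("sessions must be non-decreasing over the event log")
        p2 = self.p2_events()
        if sorted({e.session for e in self.events}) != list(range(1, N_SESSIONS + 1)):
            raise ValueError(f"a complete record spans sessions 1..{N_SESSIONS}")
        for s in range(1, N_SESSIONS + 1):
            n = sum(1 for e in p2 if e.session == s)
            if n != THROWS_PER_SESSION:
                raise ValueError(
                    f"session {s}: participant threw {n} balls, expected {THROWS_PER_SESSION}"
                )
        if self.messages.get(7) == "threat":
            n_s4 = sum(
                1 for e in p2 if e.session == 6 and e.target == "P4" and e.is_strong
            )
            if n_s4 != 0:
                raise ValueError(
                    "threat message in session 7 requires zero strong balls to P4 "
                    "by the participant in session 6"
                )


@dataclass(frozen=True)
class ContextState:
    """Session-dependent regressors gating the feature functions at one trial.

    ``total_strong_balls`` is a raw count here; z-normalization (when enabled)
    happens across a record's trials in :func:`participant_contexts`.
    """

    session: int
    react: int
    conf: int
    message: int
    total_strong_balls: float
    change: int


ChangeMode = Literal["record", "causal", "onset"]


@dataclass(frozen=True)
class ModelOptions:
    """Configuration of the two deliberately ambiguous model conventions.

    z_normalize_tsb
        Z-score the total_strong_balls regressor across the record's
        participant trials (the only unbounded regressor).  Default on.
    change_mode
        How the target-change gate change(t) is evaluated:

        - ``"record"`` (default): participant-level indicator from the full
          record — 1 on every session 6-8 trial iff the participant threw a
          strong ball to P4 in session 4 or 5 *and* a strong ball to P1/P3
          somewhere in sessions 6-8.  Matches an offline (post hoc) fit.
        - ``"causal"``: same, but the sessions 6-8 clause only counts throws
          strictly before the current trial.
        - ``"onset"``: only the session 4/5 precondition; the gate opens for
          all of sessions 6-8 once the participant joined the aggression.
          This is the generative convention used by the simulator.
    """

    z_normalize_tsb: bool = True
    change_mode: ChangeMode = "record"


DEFAULT_OPTIONS = ModelOptions()


@dataclass(frozen=True)
class BetaVector:
    """Model parameters theta = (b0..b6) plus the softmax inverse temperature."""

    beta0: float = 0.0
    beta1: float = 0.0
    beta2: float = 0.0
    beta3: float = 0.0
    beta4: float = 0.0
    beta5: float = 0.0
    beta6: float = 0.0
    slope: float = 1.0

    def __post_init__(self) -> None:
        vals = self.as_array(include_intercept=True)
        if not np.all(np.isfinite(vals)) or not math.isfinite(self.slope):
            raise ValueError(f"non-finite parameter in {self!r}")
        if self.slope < 0:
            raise ValueError(f"inverse temperature must be >= 0, got {self.slope}")

    def as_array(self, include_intercept: bool = False) -> np.ndarray:
        core = [self.beta1, self.beta2, self.beta3, self.beta4, self.beta5, self.beta6]
        if include_intercept:
            return np.array([self.beta0] + core)
        return np.array(core)

    @classmethod
    def from_array(
        cls, betas: Sequence[float], slope: float = 1.0, beta0: float = 0.0
    ) -> "BetaVector":
        b = list(betas)
        if len(b) != 6:
            raise ValueError(f"expected 6 coefficients beta1..beta6, got {len(b)}")
        return cls(beta0, *b, slope=slope)


def _react(session: int) -> int:
    return 1 if session == 3 else 0


def _conf(session: int) -> int:
    if session <= 3:
        return 0
    return 1 if session == 4 else 2


def _message(session: int) -> int:
    return 1 if session >= 6 else 0


def _change_precondition(events: Iterable[ThrowEvent]) -> bool:
    """Strong ball to P4 by the participant in session 4 or 5."""
    return any(
        e.thrower == "P2" and e.target == "P4" and e.is_strong and e.session in (4, 5)
        for e in events
    )


def _change_manifest(events: Iterable[ThrowEvent]) -> bool:
    """Strong ball to P1 or P3 by the participant in sessions 6-8."""
    return any(
        e.thrower == "P2" and e.target in ("P1", "P3") and e.is_strong and e.session >= 6
        for e in events
    )


def context_state(
    record: TaskRecord, trial_index: int, options: ModelOptions = DEFAULT_OPTIONS
) -> ContextState:
    """Context regressors at one participant decision point.

    ``trial_index`` is the 1-based position of the event in ``record.events``
    and must address a P2 throw.  ``total_strong_balls`` counts strong balls
    by *all* players strictly before the decision (the history available at
    decision time) and is returned un-normalized.
    """
    if not 1 <= trial_index <= len(record.events):
        raise IndexError(
            f"trial_index {trial_index} out of range 1..{len(record.events)}"
        )
    event = record.events[trial_index - 1]
    if event.thrower != "P2":
        raise ValueError(
            f"trial_index {trial_index} is a throw by {event.thrower}, not a "
            "participant decision point"
        )
    history = record.events[: trial_index - 1]
    session = event.session
    tsb = sum(1 for e in history if e.is_strong)

    change = 0
    if session >= 6 and _change_precondition(history):
        if options.change_mode == "record":
            change = int(_change_manifest(record.events))
        elif options.change_mode == "causal":
            change = int(_change_manifest(history))
        elif options.change_mode == "onset":
            change = 1
        else:  # pragma: no cover - guarded by Literal typing
            raise ValueError(f"unknown change_mode {options.change_mode!r}")

    return ContextState(
        session=session,
        react=_react(session),
        conf=_conf(session),
        message=_message(session),
        total_strong_balls=float(tsb),
        change=change,
    )


def participant_contexts(
    record: TaskRecord, options: ModelOptions = DEFAULT_OPTIONS
) -> list[ContextState]:
    """Contexts for every participant decision, with optional z-scored counts.

    When ``options.z_normalize_tsb`` is set, the strong-ball count is z-scored
    across the record's participant trials (population SD); a zero-variance
    count maps to all zeros.
    """
    idx = record.p2_indices()
    if not idx:
        raise ValueError(f"record {record.participant_id!r} contains no participant throws")
    ctxs = [context_state(record, i, options) for i in idx]
    if options.z_normalize_tsb:
        tsb = np.array([c.total_strong_balls for c in ctxs])
        sd = tsb.std()
        z = np.zeros_like(tsb) if sd == 0 else (tsb - tsb.mean()) / sd
        ctxs = [replace(c, total_strong_balls=float(v)) for c, v in zip(ctxs, z)]
    return ctxs


def _context_weights(ctx: ContextState) -> np.ndarray:
    return np.array(
        [1.0, ctx.react, ctx.conf, ctx.message, ctx.total_strong_balls, ctx.change]
    )


def action_utilities(ctx: ContextState, beta: BetaVector) -> np.ndarray:
    """Utilities of the six actions (ACTION_CODES order) in one context."""
    w = _context_weights(ctx)
    u = beta.beta0 + (w * beta.as_array()) @ _FEATURES
    if not np.all(np.isfinite(u)):
        raise ValueError("non-finite utility; check context and parameters")
    return u


def utility(action: Action | str, ctx: ContextState, beta: BetaVector) -> float:
    """U(X_t) for a single action."""
    code = action if isinstance(action, str) else action.code
    if code not in _ACTION_INDEX:
        raise ValueError(f"unknown action {code!r}; expected one of {ACTION_CODES}")
    return float(action_utilities(ctx, beta)[_ACTION_INDEX[code]])


def choice_probabilities(ctx: ContextState, beta: BetaVector) -> np.ndarray:
    """Softmax choice distribution over the six actions.

    P(X) = exp(slope * U(X)) / sum_c exp(slope * U(c)), computed with the usual
    max-subtraction for numerical stability.  Note that N1/N3 (and S1/S3) have
    identical feature vectors, so the model effectively distinguishes four
    action values with the instigator-directed pairs tied.
    """
    z = beta.slope * action_utilities(ctx, beta)
    z = z - z.max()
    p = np.exp(z)
    return p / p.sum()


def build_design(
    record: TaskRecord, options: ModelOptions = DEFAULT_OPTIONS
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial weighted feature tensor for fast likelihood evaluation.

    Returns ``(G, chosen)`` where ``G[t, a, k]`` is the context-weighted value
    of feature k for action a at the participant's t-th decision, so that
    utilities are ``G @ beta`` (plus the likelihood-neutral intercept), and
    ``chosen[t]`` indexes the action actually taken.
    """
    ctxs = participant_contexts(record, options)
    W = np.stack([_context_weights(c) for c in ctxs])  # (T, 6)
    G = W[:, None, :] * _FEATURES.T[None, :, :]  # (T, actions, features)
    chosen = np.array(
        [_ACTION_INDEX[e.code] for e in (Action(t.target, t.strength) for t in record.p2_events())]
    )
    return G, chosen


def nll_from_design(
    G: np.ndarray, chosen: np.ndarray, beta: BetaVector
) -> float:
    """Negative log-likelihood from a precomputed design tensor."""
    u = G @ beta.as_array() + beta.beta0
    z = beta.slope * u
    zmax = z.max(axis=1, keepdims=True)
    logsum = zmax[:, 0] + np.log(np.exp(z - zmax).sum(axis=1))
    ll = z[np.arange(len(chosen)), chosen] - logsum
    return float(-ll.sum())


def negative_log_likelihood(
    record: TaskRecord, beta: BetaVector, options: ModelOptions = DEFAULT_OPTIONS
) -> float:
    """-log P(D | theta): sum of per-trial softmax log-probabilities.

    Contexts are recomputed causally per trial; a uniform model (all betas 0)
    on a full 64-throw record gives 64*log(6).
    """
    G, chosen = build_design(record, options)
    return nll_from_design(G, chosen, beta)
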