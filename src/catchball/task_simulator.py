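"""Simulator of the eight-session catch-ball task.

Three computer agents follow a session script that stages an episode of group
aggression: in session 3 the eventual victim P4 lashes out at everyone, from
session 4 the instigators (P1, then P1+P3) throw strong balls at P4 with 80%
probability, a boost message arrives before session 6, and before session 7
the participant receives either another boost or — if they never joined the
aggression in session 6 — a threat, after which the instigators' strong balls
are split between the participant and P4.

The simulated participant (P2) draws each of its 64 throws from the softmax
choice model under a causally updated context, so records generated here have
a known ground-truth parameter vector and can be used for parameter-recovery
experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .behavior_model import (
    ACTION_CODES,
    ACTIONS,
    N_SESSIONS,
    PLAYERS,
    THROWS_PER_SESSION,
    BetaVector,
    ContextState,
    TaskRecord,
    ThrowEvent,
    _change_precondition,
    _change_manifest,
    _conf,
    _message,
    _react,
    choice_probabilities,
)

__all__ = [
    "AgentRule",
    "SessionScript",
    "SimConfig",
    "default_script",
    "sample_agent_throw",
    "message_logic",
    "simulate_task",
    "simulate_cohort",
]

AGENTS = ("P1", "P3", "P4")


def _uniform(targets: Sequence[str]) -> dict[str, float]:
    return {t: 1.0 / len(targets) for t in targets}


@dataclass(frozen=True)
class AgentRule:
    """One agent's policy within one session."""

    p_strong: float
    strong_targets: Mapping[str, float]
    normal_targets: Mapping[str, float]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_strong <= 1.0:
            raise ValueError(f"p_strong must be in [0, 1], got {self.p_strong}")
        for dist in (self.strong_targets, self.normal_targets):
            if dist and abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"target distribution must sum to 1: {dist}")


@dataclass(frozen=True)
class SessionScript:
    """Per-(session, agent) rules, with a separate arm used after a threat."""

    rules: Mapping[tuple[int, str], AgentRule]
    threat_rules: Mapping[tuple[int, str], AgentRule] = field(default_factory=dict)

    def rule(self, session: int, agent: str, threat_active: bool = False) -> AgentRule:
        if threat_active and (session, agent) in self.threat_rules:
            return self.threat_rules[(session, agent)]
        return self.rules[(session, agent)]


def _others(player: str) -> list[str]:
    return [p for p in PLAYERS if p != player]


def default_script(p_strong: float = 0.8) -> SessionScript:
    """The scripted agent behavior, session by session.

    - Session 1: all agents throw normal balls, targets uniform.
    - Session 2: P1/P3 normal only and never to P4; P4 normal, uniform.
    - Session 3: P4 throws strong balls at the other players uniformly;
      P1/P3 throw normal balls to P2 and P4 only.
    - Session 4: P1 throws strong balls at P4 with probability ``p_strong``;
      P3/P4 normal, uniform.
    - Sessions 5-8: P1 and P3 both target P4 with strong balls at
      ``p_strong``; P4 normal, uniform.
    - Threat arm (sessions 7-8, active only after a threat message): P1/P3
      strong balls are aimed uniformly at P2 and P4.

    When a scripted strong ball is not thrown the agent falls back to a
    normal ball at a uniformly chosen other player.
    """
    rules: dict[tuple[int, str], AgentRule] = {}
    for agent in AGENTS:
        uni = _uniform(_others(agent))
        rules[(1, agent)] = AgentRule(0.0, {}, uni)
    rules[(2, "P1")] = AgentRule(0.0, {}, _uniform(["P2", "P3"]))
    rules[(2, "P3")] = AgentRule(0.0, {}, _uniform(["P1", "P2"]))
    rules[(2, "P4")] = AgentRule(0.0, {}, _uniform(_others("P4")))
    rules[(3, "P1")] = AgentRule(0.0, {}, _uniform(["P2", "P4"]))
    rules[(3, "P3")] = AgentRule(0.0, {}, _uniform(["P2", "P4"]))
    rules[(3, "P4")] = AgentRule(1.0, _uniform(_others("P4")), _uniform(_others("P4")))
    rules[(4, "P1")] = AgentRule(p_strong, {"P4": 1.0}, _uniform(_others("P1")))
    rules[(4, "P3")] = AgentRule(0.0, {}, _uniform(_others("P3")))
    rules[(4, "P4")] = AgentRule(0.0, {}, _uniform(_others("P4")))
    for s in range(5, N_SESSIONS + 1):
        rules[(s, "P1")] = AgentRule(p_strong, {"P4": 1.0}, _uniform(_others("P1")))
        rules[(s, "P3")] = AgentRule(p_strong, {"P4": 1.0}, _uniform(_others("P3")))
        rules[(s, "P4")] = AgentRule(0.0, {}, _uniform(_others("P4")))
    threat_rules = {
        (s, agent): AgentRule(p_strong, _uniform(["P2", "P4"]), _uniform(_others(agent)))
        for s in (7, 8)
        for agent in ("P1", "P3")
    }
    return SessionScript(rules=rules, threat_rules=threat_rules)


@dataclass(frozen=True)
class SimConfig:
    agent_throws_per_session: int = 8
    p_strong: float = 0.8
    seed: int = 0
    threat_arm_enabled: bool = True
    #: generative convention for the change(t) gate; "record" needs the full
    #: record and is therefore not available during simulation
    change_mode: str = "onset"

    def __post_init__(self) -> None:
        if self.agent_throws_per_session < 0:
            raise ValueError("agent_throws_per_session must be >= 0")
        if self.change_mode not in ("onset", "causal"):
            raise ValueError(
                "simulation change_mode must be 'onset' or 'causal' "
                f"(got {self.change_mode!r}); the offline 'record' indicator "
                "cannot be evaluated mid-simulation"
            )


def sample_agent_throw(
    script: SessionScript,
    session: int,
    agent: str,
    rng: np.random.Generator,
    threat_active: bool = False,
) -> tuple[str, str]:
    """Draw (target, strength) for one scripted agent throw."""
    rule = script.rule(session, agent, threat_active)
    if rule.p_strong > 0 and rng.random() < rule.p_strong:
        dist, strength = rule.strong_targets, "strong"
    else:
        dist, strength = rule.normal_targets, "normal"
    targets = sorted(dist)
    probs = np.array([dist[t] for t in targets])
    target = targets[rng.choice(len(targets), p=probs / probs.sum())]
    return target, strength


def message_logic(events: Sequence[ThrowEvent], session: int) -> str | None:
    """Message shown to the participant at a session boundary.

    Before session 6 P3 sends a boost ("Let's throw more strong balls to
    P4").  Before session 7 P1 sends the threat iff the participant threw
    zero strong balls to P4 in session 6, otherwise another boost.  Other
    boundaries carry no message.
    """
    if session == 6:
        return "boost"
    if session == 7:
        joined = any(
            e.thrower == "P2" and e.target == "P4" and e.is_strong and e.session == 6
            for e in events
        )
        return "boost" if joined else "threat"
    return None


def _sim_context(events: list[ThrowEvent], session: int, change_mode: str) -> ContextState:
    tsb = sum(1 for e in events if e.is_strong)
    change = 0
    if session >= 6 and _change_precondition(events):
        if change_mode == "onset":
            change = 1
        else:  # causal
            change = int(_change_manifest(events))
    return ContextState(
        session=session,
        react=_react(session),
        conf=_conf(session),
        message=_message(session),
        total_strong_balls=float(tsb),
        change=change,
    )


def simulate_task(
    beta: BetaVector,
    script: SessionScript | None = None,
    config: SimConfig | None = None,
    rng: np.random.Generator | None = None,
    participant_id: str = "sub-001",
) -> TaskRecord:
    """Simulate one complete task run (bit-reproducible given the seed).

    Turn structure: within each session, repeated rounds of P1, P2, P3, P4
    throws until the participant has thrown 8 balls; agent throws are capped
    at ``agent_throws_per_session`` per agent.  The participant's actions are
    drawn from the softmax choice model under the causally updated context
    (raw strong-ball counts; the change gate per ``config.change_mode``).
    """
    config = config or SimConfig()
    script = script or default_script(config.p_strong)
    if rng is None:
        rng = np.random.default_rng(config.seed)

    events: list[ThrowEvent] = []
    messages: dict[int, str] = {}
    threat_active = False
    trial = 0
    for session in range(1, N_SESSIONS + 1):
        msg = message_logic(events, session)
        if msg is not None:
            messages[session] = msg
            if msg == "threat" and config.threat_arm_enabled:
                threat_active = True
        p2_thrown = 0
        agent_thrown = {a: 0 for a in AGENTS}
        rounds = 0
        while p2_thrown < THROWS_PER_SESSION:
            rounds += 1
            for player in PLAYERS:
                if player == "P2":
                    if p2_thrown >= THROWS_PER_SESSION:
                        continue
                    ctx = _sim_context(events, session, config.change_mode)
                    p = choice_probabilities(ctx, beta)
                    action = ACTIONS[rng.choice(len(ACTION_CODES), p=p)]
                    trial += 1
                    events.append(
                        ThrowEvent(session, trial, "P2", action.target, action.strength)
                    )
                    p2_thrown += 1
                else:
                    if agent_thrown[player] >= config.agent_throws_per_session:
                        continue
                    target, strength = sample_agent_throw(
                        script, session, player, rng, threat_active
                    )
                    trial += 1
                    events.append(ThrowEvent(session, trial, player, target, strength))
                    agent_thrown[player] += 1
            if rounds > 10 * THROWS_PER_SESSION:  # pragma: no cover
                raise RuntimeError("simulation failed to terminate a session")

    record = TaskRecord(participant_id=participant_id, events=tuple(events), messages=messages)
    record.validate()
    return record


def simulate_cohort(
    betas: Sequence[BetaVector],
    script: SessionScript | None = None,
    config: SimConfig | None = None,
) -> list[TaskRecord]:
    """Element-wise :func:`simulate_task` with per-participant spawned seeds."""
    config = config or SimConfig()
    children = np.random.SeedSequence(config.seed).spawn(len(betas))
    return [
        simulate_task(
            beta,
            script=script,
            config=config,
            rng=np.random.default_rng(child),
            participant_id=f"sub-{i + 1:03d}",
        )
        for i, (beta, child) in enumerate(zip(betas, children))
    ]
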