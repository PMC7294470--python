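import numpy as np
import pytest

from catchball.behavior_model import BetaVector, TaskRecord, ThrowEvent
from catchball.task_simulator import SimConfig, simulate_task


@pytest.fixture(scope="session")
def example_record() -> TaskRecord:
    """One complete simulated run with a mildly aggressive participant."""
    beta = BetaVector(beta1=-1.0, beta3=2.0, beta6=3.0, slope=1.0)
    return simulate_task(beta, config=SimConfig(seed=42))


def toy_record(actions_by_session: dict[int, list[str]], participant_id: str = "toy") -> TaskRecord:
    """Hand-built partial record: only P2 throws, given as action codes per session.

    Not a complete 64-throw run; used for oracle checks on tiny inputs.
    """
    events = []
    trial = 0
    for session in sorted(actions_by_session):
        for code in actions_by_session[session]:
            trial += 1
            target = "P" + code[1]
            strength = "strong" if code[0] == "S" else "normal"
            events.append(ThrowEvent(session, trial, "P2", target, strength))
    return TaskRecord(participant_id=participant_id, events=tuple(events))
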