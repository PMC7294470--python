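"""Plain-text I/O: throw-event logs, message flags, parameter tables,
profiles and connectivity matrices."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .behavior_model import TaskRecord, ThrowEvent
from .synthetic_cohort import ConnectivityMatrix

__all__ = [
    "records_to_frame",
    "frame_to_records",
    "write_records",
    "read_records",
    "write_connectivity",
    "read_connectivity",
]

THROW_COLUMNS = ["participant_id", "session", "trial", "thrower", "target", "strength"]
MESSAGE_COLUMNS = ["participant_id", "session", "message_type"]


def records_to_frame(records: Sequence[TaskRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(throws, messages) tables; sessions and trials are 1-based."""
    throw_rows = [
        {
            "participant_id": r.participant_id,
            "session": e.session,
            "trial": e.trial_index,
            "thrower": e.thrower,
            "target": e.target,
            "strength": e.strength,
        }
        for r in records
        for e in r.events
    ]
    msg_rows = [
        {"participant_id": r.participant_id, "session": s, "message_type": m}
        for r in records
        for s, m in sorted(r.messages.items())
    ]
    return (
        pd.DataFrame(throw_rows, columns=THROW_COLUMNS),
        pd.DataFrame(msg_rows, columns=MESSAGE_COLUMNS),
    )


def frame_to_records(
    throws: pd.DataFrame, messages: pd.DataFrame | None = None
) -> list[TaskRecord]:
    missing = set(THROW_COLUMNS) - set(throws.columns)
    if missing:
        raise ValueError(f"throw table missing columns {sorted(missing)}")
    msg_map: dict[str, dict[int, str]] = {}
    if messages is not None and len(messages):
        for pid, grp in messages.groupby("participant_id", sort=False):
            msg_map[pid] = dict(zip(grp["session"].astype(int), grp["message_type"]))
    records = []
    for pid, grp in throws.groupby("participant_id", sort=False):
        grp = grp.sort_values("trial")
        events = tuple(
            ThrowEvent(
                session=int(row.session),
                trial_index=int(row.trial),
                thrower=row.thrower,
                target=row.target,
                strength=row.strength,
            )
            for row in grp.itertuples()
        )
        records.append(TaskRecord(participant_id=pid, events=events, messages=msg_map.get(pid, {})))
    return records


def write_records(records: Sequence[TaskRecord], throws_path, messages_path=None) -> None:
    throws, messages = records_to_frame(records)
    throws.to_csv(throws_path, index=False)
    if messages_path is not None:
        messages.to_csv(messages_path, index=False)


def read_records(throws_path, messages_path=None) -> list[TaskRecord]:
    throws = pd.read_csv(throws_path)
    messages = pd.read_csv(messages_path) if messages_path is not None else None
    return frame_to_records(throws, messages)


def write_connectivity(
    matrices: Sequence[ConnectivityMatrix], directory, labels_file: str = "roi_labels.txt"
) -> None:
    """One whitespace-delimited dense matrix file per participant + labels."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, m in enumerate(matrices):
        np.savetxt(directory / f"connectivity_sub-{i + 1:03d}.txt", m.values, fmt="%.8g")
    (directory / labels_file).write_text("\n".join(matrices[0].roi_labels) + "\n")


def read_connectivity(directory, labels_file: str = "roi_labels.txt") -> list[ConnectivityMatrix]:
    directory = Path(directory)
    labels = tuple((directory / labels_file).read_text().split())
    out = []
    for path in sorted(directory.glob("connectivity_*.txt")):
        out.append(ConnectivityMatrix(values=np.loadtxt(path), roi_labels=labels))
    return out
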