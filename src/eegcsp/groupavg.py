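"""Pooled averaging of task intervals across a group of records.

Two constructions exist: the pooled average of all intervals in the group
(every interval weighted equally, records with more intervals weigh more)
and the average of per-record averages. The pooled construction is the
default throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import EmptyAverageError, SchemaError
from .preprocess import IntervalSpec, task_intervals
from .records import EEGRecord

log = logging.getLogger(__name__)


@dataclass
class GroupAverage:
    """The group/task average interval with its interval bookkeeping."""

    group: str
    task: str
    interval_spec: IntervalSpec
    channel_labels: tuple[str, ...]
    a: np.ndarray  # channels x samples, microvolts
    z_tot: int  # total interval count
    per_record_counts: dict[str, int]

    def __post_init__(self) -> None:
        if self.z_tot != sum(self.per_record_counts.values()):
            raise SchemaError("z_tot must equal the sum of per-record counts")


def record_task_average(
    record: EEGRecord, task: str, spec: IntervalSpec
) -> np.ndarray:
    """Elementwise mean over one record's intervals of one task."""
    intervals = task_intervals(record, task, spec)
    if not intervals:
        raise EmptyAverageError(
            f"{record.subject_id}: no usable {task} intervals to average"
        )
    return np.mean(intervals, axis=0)


def group_pooled_average(
    records: list[EEGRecord],
    task: str,
    spec: IntervalSpec,
    method: str = "pooled",
) -> GroupAverage:
    """Average interval of one group for one task.

    method="pooled" (default): mean over all intervals of all records, so
    every interval carries weight 1/z_tot. method="average_of_averages":
    mean of the per-record average intervals, each record weighted equally.
    Records contributing zero intervals are dropped with a warning.
    """
    if method not in ("pooled", "average_of_averages"):
        raise SchemaError(f"unknown averaging method {method!r}")
    if not records:
        raise EmptyAverageError("no records to average")
    labels = records[0].channel_labels
    groups = {r.group for r in records}
    group = groups.pop() if len(groups) == 1 else "mixed"

    total = None
    per_record_sums: list[np.ndarray] = []
    counts: dict[str, int] = {}
    for record in records:
        if record.channel_labels != labels:
            raise SchemaError(
                f"{record.subject_id}: channel set differs from {records[0].subject_id}"
            )
        intervals = task_intervals(record, task, spec)
        if not intervals:
            log.warning(
                "%s contributes no %s intervals; dropped from the average",
                record.subject_id, task,
            )
            continue
        counts[record.subject_id] = len(intervals)
        s = np.sum(intervals, axis=0)
        total = s if total is None else total + s
        per_record_sums.append(s / len(intervals))

    z_tot = sum(counts.values())
    if z_tot == 0:
        raise EmptyAverageError(f"no {task} intervals in any record of the group")
    if method == "pooled":
        a = total / z_tot
    else:
        a = np.mean(per_record_sums, axis=0)
    return GroupAverage(
        group=group,
        task=task,
        interval_spec=spec,
        channel_labels=labels,
        a=a,
        z_tot=z_tot,
        per_record_counts=counts,
    )
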