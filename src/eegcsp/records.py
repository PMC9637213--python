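"""Core record container shared by the synthetic generator and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SchemaError

#: The three auditory oddball task labels.
TASKS = ("Standard", "Novelty", "Target")

#: Group labels; "pd" is the positive class throughout.
GROUPS = ("control", "pd")


@dataclass(frozen=True)
class Event:
    """A single stimulus onset."""

    task: str
    onset_sample: int


@dataclass
class EEGRecord:
    """One subject-session: labelled multi-channel signal plus its events.

    ``data`` is a (n_channels, n_samples) float array in microvolts; row order
    matches ``channel_labels``. Event onsets are sample indices into ``data``
    and must be strictly increasing.
    """

    subject_id: str
    group: str
    channel_labels: tuple[str, ...]
    fs: float
    data: np.ndarray
    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.channel_labels = tuple(self.channel_labels)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise SchemaError("data must be a 2-D (channels x samples) array")
        if self.data.shape[0] != len(self.channel_labels):
            raise SchemaError(
                f"data has {self.data.shape[0]} rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        if self.fs <= 0:
            raise SchemaError("sampling rate must be positive")
        onsets = [e.onset_sample for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise SchemaError("event onsets must be strictly increasing")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def events_of(self, task: str) -> list[Event]:
        """Events of one task, in onset order."""
        return [e for e in self.events if e.task == task]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise SchemaError(f"channel {label!r} not present in record") from None

    def copy_with(self, data: np.ndarray) -> "EEGRecord":
        """A shallow variant of this record carrying new sample data."""
        return EEGRecord(
            subject_id=self.subject_id,
            group=self.group,
            channel_labels=self.channel_labels,
            fs=self.fs,
            data=data,
            events=list(self.events),
        )
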