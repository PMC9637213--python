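"""Synthetic two-group EEG cohort generator.

Produces labelled records with 1/f-like background noise mixed through a
per-group channel mixing matrix, plus group/task-dependent event-locked
responses, so every downstream stage (filtering, epoching, pooled
averaging, CSP, Laplacian masks, classification) can be exercised and
validated against planted ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, SchedulingError
from .montage import DEFAULT_LABELS
from .preprocess import EPOCH_SECONDS, write_record
from .records import GROUPS, TASKS, EEGRecord, Event


@dataclass(frozen=True)
class ErpTemplate:
    """Event-locked response: per-channel amplitude times a damped cosine.

    The time course is cos(2*pi*f*t) * exp(-decay * t / duration) over
    [0, duration); only the per-channel amplitude structure matters to the
    analysis, the waveform shape is a convention.
    """

    amplitudes: dict[str, float]  # label -> microvolts
    freq_hz: float = 10.0
    duration_ms: float = 300.0
    decay: float = 3.0

    def waveform(self, fs: float) -> np.ndarray:
        n = int(round(self.duration_ms / 1000.0 * fs))
        t = np.arange(n) / fs
        dur_s = self.duration_ms / 1000.0
        return np.cos(2 * np.pi * self.freq_hz * t) * np.exp(-self.decay * t / dur_s)

    def amplitude_vector(self, labels: tuple[str, ...]) -> np.ndarray:
        return np.array([self.amplitudes.get(lbl, 0.0) for lbl in labels])


@dataclass
class SyntheticConfig:
    """Full description of a synthetic cohort; determinism comes from seed."""

    n_subjects_per_group: int = 25
    channel_labels: tuple[str, ...] = DEFAULT_LABELS
    fs: float = 500.0
    record_duration_s: float = 60.0
    events_per_task: dict[str, int] = field(
        default_factory=lambda: {"Standard": 8, "Novelty": 3, "Target": 2}
    )
    min_gap_s: float = 4.0
    erp_templates: dict[tuple[str, str], ErpTemplate] = field(default_factory=dict)
    group_mixing: dict[str, np.ndarray | None] = field(
        default_factory=lambda: {"control": None, "pd": None}
    )
    noise_exponent: float = 1.0
    noise_sigma: float = 1.0
    noise_band: tuple[float, float] = (0.1, 100.0)
    snr: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.channel_labels = tuple(self.channel_labels)
        for group, m in self.group_mixing.items():
            if m is None:
                continue
            m = np.asarray(m, dtype=float)
            n = len(self.channel_labels)
            if m.shape != (n, n):
                raise ConfigurationError(
                    f"mixing matrix for {group!r} must be {n}x{n}, got {m.shape}"
                )
            if np.linalg.matrix_rank(m) < n:
                raise ConfigurationError(f"mixing matrix for {group!r} is rank deficient")
            self.group_mixing[group] = m

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)


def default_config(
    n_subjects_per_group: int = 25,
    seed: int = 0,
    planted_channel: str = "Fz",
    planted_gain_uv: float = 6.0,
    base_amplitude_uv: float = 2.0,
    **overrides,
) -> SyntheticConfig:
    """A cohort whose groups differ by a planted ERP gain on one channel.

    Both groups share a frontal Standard-task response of
    ``base_amplitude_uv``; the pd group additionally carries
    ``planted_gain_uv`` on ``planted_channel``, making the unit vector on
    that channel the planted discriminative direction.
    """
    templates: dict[tuple[str, str], ErpTemplate] = {}
    base = {"Fz": base_amplitude_uv, "FCz": base_amplitude_uv * 0.5}
    for task in TASKS:
        templates[("control", task)] = ErpTemplate(amplitudes=dict(base))
        pd_amp = dict(base)
        if task == "Standard":
            pd_amp[planted_channel] = pd_amp.get(planted_channel, 0.0) + planted_gain_uv
        templates[("pd", task)] = ErpTemplate(amplitudes=pd_amp)
    return SyntheticConfig(
        n_subjects_per_group=n_subjects_per_group,
        erp_templates=templates,
        seed=seed,
        **overrides,
    )


def colored_noise(
    rng: np.random.Generator,
    n_channels: int,
    n_samples: int,
    fs: float,
    exponent: float = 1.0,
    sigma: float = 1.0,
    band: tuple[float, float] = (0.1, 100.0),
) -> np.ndarray:
    """1/f^exponent power-law noise by spectral shaping of white noise.

    Each channel is independently shaped and rescaled to sample standard
    deviation ``sigma``; content outside ``band`` is zeroed.
    """
    if sigma == 0.0:
        return np.zeros((n_channels, n_samples))
    white = rng.standard_normal((n_channels, n_samples))
    spectrum = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    inside = (freqs >= band[0]) & (freqs <= band[1]) & (freqs > 0)
    shape[inside] = freqs[inside] ** (-exponent / 2.0)
    noise = np.fft.irfft(spectrum * shape, n=n_samples, axis=-1)
    std = noise.std(axis=-1, keepdims=True)
    std[std == 0] = 1.0
    return noise / std * sigma


def _schedule_events(
    rng: np.random.Generator, config: SyntheticConfig
) -> list[Event]:
    """Random onsets with >= min_gap_s spacing and full 4-s windows inside."""
    tasks: list[str] = []
    for task, count in config.events_per_task.items():
        tasks.extend([task] * int(count))
    if not tasks:
        return []
    margin = EPOCH_SECONDS / 2.0
    n_ev = len(tasks)
    span = 2 * margin + (n_ev - 1) * config.min_gap_s
    slack = config.record_duration_s - span
    if slack < 0:
        raise SchedulingError(
            f"cannot place {n_ev} events with {config.min_gap_s} s gaps in a "
            f"{config.record_duration_s} s record"
        )
    extras = np.sort(rng.uniform(0.0, slack, size=n_ev))
    onsets_s = margin + np.arange(n_ev) * config.min_gap_s + extras
    rng.shuffle(tasks)
    events = [
        Event(task, int(round(t * config.fs))) for task, t in zip(tasks, onsets_s)
    ]
    events.sort(key=lambda e: e.onset_sample)
    return events


def generate_record(
    config: SyntheticConfig, group: str, subject_id: str, seed: int
) -> EEGRecord:
    """One record: mixed colored noise plus onset-locked ERP templates.

    Bit-identical for identical (config, group, subject_id, seed).
    """
    if group not in GROUPS:
        raise ConfigurationError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    n_samples = int(round(config.record_duration_s * config.fs))
    data = colored_noise(
        rng,
        config.n_channels,
        n_samples,
        config.fs,
        config.noise_exponent,
        config.noise_sigma,
        config.noise_band,
    )
    mixing = config.group_mixing.get(group)
    if mixing is not None:
        data = np.asarray(mixing) @ data
    events = _schedule_events(rng, config)
    for event in events:
        template = config.erp_templates.get((group, event.task))
        if template is None:
            continue
        wave = template.waveform(config.fs) * config.snr
        amps = template.amplitude_vector(config.channel_labels)
        stop = min(event.onset_sample + len(wave), n_samples)
        seg = stop - event.onset_sample
        if seg > 0:
            data[:, event.onset_sample : stop] += np.outer(amps, wave[:seg])
    return EEGRecord(
        subject_id=subject_id,
        group=group,
        channel_labels=config.channel_labels,
        fs=config.fs,
        data=data,
        events=events,
    )


def planted_directions(config: SyntheticConfig) -> dict[str, list[float]]:
    """Unit-norm per-task difference (pd - control) of ERP amplitude maps."""
    out: dict[str, list[float]] = {}
    for task in TASKS:
        ctl = config.erp_templates.get(("control", task))
        pdt = config.erp_templates.get(("pd", task))
        v_ctl = ctl.amplitude_vector(config.channel_labels) if ctl else 0.0
        v_pd = pdt.amplitude_vector(config.channel_labels) if pdt else 0.0
        diff = np.asarray(v_pd) - np.asarray(v_ctl)
        if np.ndim(diff) == 0 or not np.any(diff):
            continue
        out[task] = (diff / np.linalg.norm(diff)).tolist()
    return out


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[list[EEGRecord], dict]:
    """All records of both groups plus a ground-truth manifest."""
    seeds = np.random.SeedSequence(config.seed).generate_state(
        2 * config.n_subjects_per_group
    )
    records: list[EEGRecord] = []
    i = 0
    for group in GROUPS:
        for k in range(config.n_subjects_per_group):
            subject_id = f"{group}_{k:02d}"
            records.append(
                generate_record(config, group, subject_id, int(seeds[i]))
            )
            i += 1
    manifest = {
        "seed": config.seed,
        "fs": config.fs,
        "channel_labels": list(config.channel_labels),
        "records": [{"subject_id": r.subject_id, "group": r.group} for r in records],
        "planted_directions": planted_directions(config),
        "erp_amplitudes": {
            f"{group}/{task}": tpl.amplitudes
            for (group, task), tpl in config.erp_templates.items()
        },
        "group_mixing": {
            group: (None if m is None else np.asarray(m).tolist())
            for group, m in config.group_mixing.items()
        },
    }
    return records, manifest


def write_cohort(
    records: list[EEGRecord], manifest: dict, out_dir: str | Path
) -> None:
    """Write records in the native format plus ``manifest.json``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for record in records:
        write_record(record, out_dir / record.subject_id)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def null_config(config: SyntheticConfig, seed: int) -> SyntheticConfig:
    """Same cohort parameters for both groups (pd copies control templates)."""
    templates = {
        (group, task): config.erp_templates.get(("control", task))
        for group in GROUPS
        for task in TASKS
        if config.erp_templates.get(("control", task)) is not None
    }
    mixing = {g: config.group_mixing.get("control") for g in GROUPS}
    return replace(
        config, erp_templates=templates, group_mixing=mixing, seed=seed
    )
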