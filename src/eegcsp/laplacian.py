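"""Surface-Laplacian masks: center minus a quarter of its four neighbors.

The small mask (d=1) uses immediate grid neighbors, the large mask (d=2)
the cells two steps away. The classification feature for one record/task
is the mean of the Laplacian series over the analysis interval of the
record's average interval; because the operator and the averaging are both
linear this equals the average of per-interval features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, MaskInfeasibleError
from .groupavg import record_task_average
from .montage import MontageGrid, neighbors
from .preprocess import IntervalSpec
from .records import EEGRecord


@dataclass(frozen=True)
class LaplacianMaskSpec:
    """Mask center label and neighbor distance (1 = small, 2 = large)."""

    center: str
    d: int = 1

    def __post_init__(self) -> None:
        if self.d not in (1, 2):
            raise ConfigurationError(f"mask distance must be 1 or 2, got {self.d}")

    def __str__(self) -> str:
        return f"{self.center}" + ("_L" if self.d == 2 else "")


def parse_masks(text: str) -> list[LaplacianMaskSpec]:
    """Parse 'Fz:1,F3:2,F4:2' into mask specs ('Fz' alone means d=1)."""
    masks = []
    for token in text.split(","):
        token = token.strip()
        if not token:
            continue
        if ":" in token:
            center, d = token.split(":", 1)
            masks.append(LaplacianMaskSpec(center.strip(), int(d)))
        else:
            masks.append(LaplacianMaskSpec(token))
    return masks


def _resolve_mask(
    channel_labels: tuple[str, ...], grid: MontageGrid, spec: LaplacianMaskSpec
) -> tuple[int, list[int]]:
    """(center index, four neighbor indices), or raise naming the gaps."""
    index = {lbl: i for i, lbl in enumerate(channel_labels)}
    if spec.center not in index:
        raise MaskInfeasibleError(f"center {spec.center!r} not among the signals")
    report = neighbors(grid, spec.center, spec.d)
    missing = list(report.missing)
    nb_idx: list[int] = []
    for lbl in report.labels:
        if lbl in index:
            nb_idx.append(index[lbl])
        else:
            missing.append(lbl)
    if missing:
        raise MaskInfeasibleError(
            f"mask {spec} infeasible: missing neighbor(s) {', '.join(map(str, missing))}"
        )
    return index[spec.center], nb_idx


def mask_feasible(
    channel_labels: tuple[str, ...], grid: MontageGrid, spec: LaplacianMaskSpec
) -> bool:
    try:
        _resolve_mask(channel_labels, grid, spec)
        return True
    except MaskInfeasibleError:
        return False


def laplacian_signal(
    signals: np.ndarray,
    channel_labels: tuple[str, ...],
    grid: MontageGrid,
    spec: LaplacianMaskSpec,
) -> np.ndarray:
    """y(n) = x_center(n) - 1/4 * sum of the four d-neighbor signals."""
    signals = np.asarray(signals, dtype=float)
    center, nb_idx = _resolve_mask(channel_labels, grid, spec)
    return signals[center] - 0.25 * signals[nb_idx].sum(axis=0)


def laplacian_feature(
    record: EEGRecord,
    task: str,
    interval_spec: IntervalSpec,
    spec: LaplacianMaskSpec,
    grid: MontageGrid,
) -> float:
    """Single value: mean over the interval of the mask applied to the
    record's average task interval."""
    avg = record_task_average(record, task, interval_spec)
    y = laplacian_signal(avg, record.channel_labels, grid, spec)
    return float(y.mean())


def features_from_average(
    avg: np.ndarray,
    channel_labels: tuple[str, ...],
    masks: list[LaplacianMaskSpec],
    grid: MontageGrid,
) -> np.ndarray:
    """One feature per mask from a precomputed average interval."""
    infeasible = [
        str(m) for m in masks if not mask_feasible(channel_labels, grid, m)
    ]
    if infeasible:
        raise MaskInfeasibleError(f"infeasible mask(s): {', '.join(infeasible)}")
    return np.array(
        [
            float(laplacian_signal(avg, channel_labels, grid, m).mean())
            for m in masks
        ]
    )


def feature_set(
    record: EEGRecord,
    task: str,
    interval_spec: IntervalSpec,
    masks: list[LaplacianMaskSpec],
    grid: MontageGrid,
) -> np.ndarray:
    """One feature per mask, in the given order."""
    if not masks:
        return np.array([])
    avg = record_task_average(record, task, interval_spec)
    return features_from_average(avg, record.channel_labels, masks, grid)
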