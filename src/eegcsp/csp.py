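"""Common spatial patterns: fit, projection, log-variance features and
channel informativeness ranking.

The transformation is the classic two-step construction: whiten the
composite (sum of trace-normalized class) covariance, then diagonalize the
whitened pd-class covariance. Rows of W are spatial filters; columns of
W's inverse are the spatial patterns plotted topographically. Components
are ordered by pd-class variance fraction, descending, so the first three
maximize pd variance (MxPMnC) and the last three minimize it (MnPMxC).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DegenerateInputError, FeatureError, SchemaError
from .montage import MontageGrid, neighbors
from .preprocess import IntervalSpec, task_intervals
from .records import EEGRecord

log = logging.getLogger(__name__)

#: Names of the six variance-extremizing components. MxPMnC_l is the l-th
#: largest pd-variance component (index l-1); MnPMxC_l the l-th smallest
#: (index n-l), so MnPMxC1 is the most extreme minimizer.
EXTREME_COMPONENTS = (
    "MxPMnC1", "MxPMnC2", "MxPMnC3", "MnPMxC1", "MnPMxC2", "MnPMxC3",
)

_RIDGE_FACTOR = 1e-10


@dataclass
class CSPModel:
    """Fitted CSP transformation in a fixed channel order."""

    channel_labels: tuple[str, ...]
    W: np.ndarray  # components x channels (spatial filters in rows)
    patterns: np.ndarray  # channels x components (inverse of W)
    ratios: np.ndarray  # per-component pd-class variance fraction, descending

    @property
    def n_components(self) -> int:
        return self.W.shape[0]

    def component_index(self, name: str) -> int:
        n = self.n_components
        if name.startswith("MxPMnC"):
            l = int(name[len("MxPMnC"):])
        elif name.startswith("MnPMxC"):
            l = int(name[len("MnPMxC"):])
        else:
            raise SchemaError(f"unknown component name {name!r}")
        if not 1 <= l <= n:
            raise SchemaError(f"component {name!r} out of range for n={n}")
        return l - 1 if name.startswith("MxPMnC") else n - l

    def save(self, out_dir: str | Path) -> None:
        """JSON metadata plus raw float64 matrix files for W and patterns."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        meta = {
            "channel_labels": list(self.channel_labels),
            "n_components": self.n_components,
            "ratios": self.ratios.tolist(),
        }
        (out_dir / "model.json").write_text(json.dumps(meta, indent=1))
        self.W.astype("<f8").tofile(out_dir / "W.dat")
        self.patterns.astype("<f8").tofile(out_dir / "patterns.dat")

    @classmethod
    def load(cls, in_dir: str | Path) -> "CSPModel":
        in_dir = Path(in_dir)
        meta = json.loads((in_dir / "model.json").read_text())
        n = meta["n_components"]
        n_ch = len(meta["channel_labels"])
        W = np.fromfile(in_dir / "W.dat", dtype="<f8").reshape(n, n_ch)
        patterns = np.fromfile(in_dir / "patterns.dat", dtype="<f8").reshape(n_ch, n)
        return cls(
            channel_labels=tuple(meta["channel_labels"]),
            W=W,
            patterns=patterns,
            ratios=np.asarray(meta["ratios"]),
        )


def normalized_covariance(E: np.ndarray) -> np.ndarray:
    """E @ E.T divided by its trace; symmetric PSD with unit trace."""
    E = np.asarray(E, dtype=float)
    if E.ndim != 2 or E.shape[1] < 2:
        raise DegenerateInputError("need a channels x samples matrix with >= 2 samples")
    C = E @ E.T
    tr = np.trace(C)
    if tr <= 0:
        raise DegenerateInputError("all-zero input: covariance trace is 0")
    return C / tr


def csp_fit(
    avg_control: np.ndarray,
    avg_pd: np.ndarray,
    channel_labels: tuple[str, ...] | None = None,
) -> CSPModel:
    """Fit the CSP transformation from the two group-average intervals.

    Steps: trace-normalized class covariances; eigendecompose their sum;
    whiten with P = Lambda^(-1/2) U^T; diagonalize the whitened pd
    covariance B D B^T; W = B^T P ordered by D descending. The pd/control
    variance fractions sum to 1 per component by construction.
    """
    avg_control = np.asarray(avg_control, dtype=float)
    avg_pd = np.asarray(avg_pd, dtype=float)
    if avg_control.shape[0] != avg_pd.shape[0]:
        raise SchemaError(
            f"channel counts differ: {avg_control.shape[0]} vs {avg_pd.shape[0]}"
        )
    n_ch = avg_control.shape[0]
    if channel_labels is None:
        channel_labels = tuple(f"ch{i}" for i in range(n_ch))
    if len(channel_labels) != n_ch:
        raise SchemaError("channel_labels length does not match the averages")

    C_ctl = normalized_covariance(avg_control)
    C_pd = normalized_covariance(avg_pd)
    C_c = C_ctl + C_pd

    lam, U = np.linalg.eigh(C_c)
    if lam[0] <= 1e-12 * lam[-1]:
        ridge = _RIDGE_FACTOR * np.trace(C_c)
        warnings.warn(
            f"composite covariance is rank deficient; adding ridge {ridge:.3e}",
            RuntimeWarning,
            stacklevel=2,
        )
        lam, U = np.linalg.eigh(C_c + ridge * np.eye(n_ch))
    P = (U / np.sqrt(lam)).T  # Lambda^(-1/2) U^T

    S_pd = P @ C_pd @ P.T
    S_pd = (S_pd + S_pd.T) / 2.0
    d, B = np.linalg.eigh(S_pd)
    order = np.argsort(-d, kind="stable")
    d = np.clip(d[order], 0.0, 1.0)
    B = B[:, order]

    W = B.T @ P
    patterns = U @ (np.sqrt(lam)[:, None] * B)  # inv(W) = U Lambda^(1/2) B

    # Deterministic sign: largest-|weight| pattern entry positive per component.
    for j in range(n_ch):
        k = np.argmax(np.abs(patterns[:, j]))
        if patterns[k, j] < 0:
            patterns[:, j] *= -1.0
            W[j, :] *= -1.0

    return CSPModel(
        channel_labels=tuple(channel_labels), W=W, patterns=patterns, ratios=d
    )


def project(model: CSPModel, signals: np.ndarray) -> np.ndarray:
    """Map a channels x samples matrix into component space: Z = W @ X."""
    signals = np.asarray(signals, dtype=float)
    if signals.shape[0] != len(model.channel_labels):
        raise SchemaError(
            f"signal has {signals.shape[0]} channels, model expects "
            f"{len(model.channel_labels)}"
        )
    return model.W @ signals


def _log_variance(z: np.ndarray) -> np.ndarray:
    v = z.var(axis=-1)  # population variance over the interval samples
    if np.any(v <= 0):
        bad = np.nonzero(v <= 0)[0]
        raise FeatureError(
            f"zero-variance component signal (components {bad.tolist()})"
        )
    return np.log(v)


def features_from_average(
    model: CSPModel,
    avg: np.ndarray,
    components: tuple[str, ...] = EXTREME_COMPONENTS,
) -> np.ndarray:
    """Log-variance features of selected components from a precomputed
    average interval."""
    idx = [model.component_index(name) for name in components]
    return _log_variance(model.W[idx, :] @ np.asarray(avg, dtype=float))


def csp_features(
    model: CSPModel,
    record: EEGRecord,
    task: str,
    spec: IntervalSpec,
    components: tuple[str, ...] = EXTREME_COMPONENTS,
    mode: str = "avg_then_map",
) -> np.ndarray:
    """Log-variance features of the selected components for one record.

    mode="avg_then_map" (default): average the record's task intervals,
    map the average, take log-variance. mode="map_then_avg": per-interval
    log-variance features averaged over the intervals.
    """
    if record.channel_labels != model.channel_labels:
        raise SchemaError(
            f"{record.subject_id}: channel order differs from the fitted model"
        )
    idx = [model.component_index(name) for name in components]
    intervals = task_intervals(record, task, spec)
    if not intervals:
        raise FeatureError(f"{record.subject_id}: no usable {task} intervals")
    W_sel = model.W[idx, :]
    if mode == "avg_then_map":
        z = W_sel @ np.mean(intervals, axis=0)
        return _log_variance(z)
    if mode == "map_then_avg":
        feats = [_log_variance(W_sel @ interval) for interval in intervals]
        return np.mean(feats, axis=0)
    raise SchemaError(f"unknown feature mode {mode!r}")


def spatial_patterns(
    model: CSPModel,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """The channels x 6 pattern sub-matrix of the extreme components."""
    idx = [model.component_index(name) for name in EXTREME_COMPONENTS]
    return model.patterns[:, idx], EXTREME_COMPONENTS


def rank_informative_channels(
    patterns: np.ndarray,
    channel_labels: tuple[str, ...],
    grid: MontageGrid,
) -> list[tuple[str, float]]:
    """Channels ranked by local pattern prominence, scores in [0, 1].

    Per channel and pattern column the raw score is the absolute pattern
    weight plus the mean absolute difference to the weights at its d=1
    montage neighbors (off-grid channels and missing neighbors contribute
    no difference term); the channel score is the max over columns,
    normalized by the largest score. Ties keep channel order.
    """
    patterns = np.atleast_2d(np.asarray(patterns, dtype=float))
    if patterns.shape[0] != len(channel_labels):
        raise SchemaError("pattern rows must match channel_labels")
    index = {lbl: i for i, lbl in enumerate(channel_labels)}
    scores = np.zeros(len(channel_labels))
    for i, lbl in enumerate(channel_labels):
        nb_idx: list[int] = []
        if lbl in grid:
            for nb in neighbors(grid, lbl, 1).labels:
                if nb in index:
                    nb_idx.append(index[nb])
        col_scores = np.abs(patterns[i, :]).astype(float)
        if nb_idx:
            diffs = np.abs(patterns[i, :][None, :] - patterns[nb_idx, :])
            col_scores = col_scores + diffs.mean(axis=0)
        scores[i] = col_scores.max()
    top = scores.max()
    if top > 0:
        scores = scores / top
    ranked = sorted(
        zip(channel_labels, scores), key=lambda pair: -pair[1]
    )
    return [(lbl, float(s)) for lbl, s in ranked]


def export_topomap(
    model: CSPModel, grid: MontageGrid, path: str | Path
) -> None:
    """CSV export of the six extreme pattern columns with grid coordinates."""
    pats, names = spatial_patterns(model)
    lines = ["channel,row,col," + ",".join(names)]
    for i, lbl in enumerate(model.channel_labels):
        cell = grid.label_to_cell.get(lbl, ("", ""))
        values = ",".join(f"{v:.6g}" for v in pats[i])
        lines.append(f"{lbl},{cell[0]},{cell[1]},{values}")
    Path(path).write_text("\n".join(lines) + "\n")
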