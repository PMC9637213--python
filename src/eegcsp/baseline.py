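"""Classical per-band baseline features: sample entropy, RMS, median and
peak frequency, enumerated per band x task x channel as the comparison
feature set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import periodogram

from .errors import DegenerateInputError
from .preprocess import IntervalSpec, bandpass, task_intervals
from .records import TASKS, EEGRecord

log = logging.getLogger(__name__)

FEATURE_NAMES = ("sampen", "rms", "medfreq", "peakfreq")


@dataclass(frozen=True)
class BandScheme:
    """Named frequency bands, ordered, non-overlapping except shared edges."""

    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "delta": (0.1, 4.0),
            "theta": (4.0, 8.0),
            "alpha": (8.0, 13.0),
            "beta": (13.0, 30.0),
            "gamma": (30.0, 100.0),
        }
    )

    def __post_init__(self) -> None:
        prev_high = 0.0
        for name, (low, high) in self.bands.items():
            if not 0 <= low < high:
                raise DegenerateInputError(f"band {name!r} has invalid edges")
            if low < prev_high:
                raise DegenerateInputError(f"band {name!r} overlaps its predecessor")
            prev_high = high

    def names(self) -> tuple[str, ...]:
        return tuple(self.bands)


def rms(x: np.ndarray) -> float:
    """Root mean square: sqrt(mean of squares)."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise DegenerateInputError("RMS of an empty series")
    return float(np.sqrt(np.mean(x * x)))


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """SampEn(m, r): -log(A/B) over template pairs (self-matches excluded).

    B counts pairs of length-m templates within Chebyshev distance r, A the
    same for length m+1; both use the first N-m template start points so
    the counts are comparable. Returns NaN when either count is zero
    (undefined entropy). r defaults to 0.2 * SD(x).
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n <= m + 1:
        raise DegenerateInputError(f"need more than m+1={m + 1} samples, got {n}")
    if r is None:
        r = 0.2 * x.std()
    if r <= 0:
        # constant series: every template matches at distance 0 only if r>0;
        # treat r=0 on a constant series as matching (distance 0 <= 0).
        r = 0.0

    def _count(order: int) -> int:
        emb = sliding_window_view(x, order)[: n - m]  # common template count
        # pairwise Chebyshev distances, upper triangle
        d = np.abs(emb[:, None, :] - emb[None, :, :]).max(axis=-1)
        iu = np.triu_indices(len(emb), k=1)
        return int(np.count_nonzero(d[iu] <= r))

    b = _count(m)
    a = _count(m + 1)
    if a == 0 or b == 0:
        log.warning("sample entropy undefined (A=%d, B=%d); reporting NaN", a, b)
        return float("nan")
    return float(-np.log(a / b))


def _spectrum(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 8:
        raise DegenerateInputError("need at least 8 samples for a spectrum")
    freqs, pxx = periodogram(x, fs=fs, window="hann", detrend=False)
    total = pxx.sum()
    if total <= 0:
        raise DegenerateInputError("zero total spectral power")
    return freqs, pxx


def median_frequency(x: np.ndarray, fs: float) -> float:
    """Frequency splitting the cumulative one-sided power in half.

    The cumulative power is treated as piecewise linear between bins; if it
    plateaus exactly at one half, the midpoint of the crossing set is
    returned.
    """
    freqs, pxx = _spectrum(x, fs)
    cum = np.cumsum(pxx) / pxx.sum()
    half, eps = 0.5, 1e-9  # eps absorbs float noise on an exact-half plateau

    def _cross(target: float) -> float:
        k = int(np.searchsorted(cum, target, side="left"))
        k = min(k, len(cum) - 1)
        if k == 0:
            return float(freqs[0])
        c0, c1 = cum[k - 1], cum[k]
        if c1 <= c0:
            return float(freqs[k])
        frac = np.clip((half - c0) / (c1 - c0), 0.0, 1.0)
        return float(freqs[k - 1] + frac * (freqs[k] - freqs[k - 1]))

    lo = _cross(half - eps)
    hi = _cross(half + eps)
    return (lo + hi) / 2.0


def peak_frequency(x: np.ndarray, fs: float) -> float:
    """Frequency of the maximum-power bin; exact ties go to the lowest."""
    freqs, pxx = _spectrum(x, fs)
    top = pxx.max()
    candidates = np.nonzero(pxx >= top * (1.0 - 1e-9))[0]
    return float(freqs[candidates[0]])


def _interval_features(
    interval: np.ndarray, fs: float, m: int, r_factor: float
) -> np.ndarray:
    """(4, n_channels) feature block for one interval."""
    n_ch = interval.shape[0]
    out = np.empty((len(FEATURE_NAMES), n_ch))
    for c in range(n_ch):
        x = interval[c]
        out[0, c] = sample_entropy(x, m=m, r=r_factor * x.std() if x.std() > 0 else None)
        out[1, c] = rms(x)
        try:
            out[2, c] = median_frequency(x, fs)
            out[3, c] = peak_frequency(x, fs)
        except DegenerateInputError:
            out[2, c] = np.nan
            out[3, c] = np.nan
    return out


def baseline_feature_table(
    records: list[EEGRecord],
    band_scheme: BandScheme | None = None,
    tasks: tuple[str, ...] = TASKS,
    interval_spec: IntervalSpec | None = None,
    m: int = 2,
    r_factor: float = 0.2,
    numtaps: int = 1651,
) -> pd.DataFrame:
    """Wide per-record feature table: {feature}_{band}_{task}_{channel}.

    Each value is the feature computed per interval of the task, then
    averaged over the task's intervals, on the band-filtered record. A
    missing task leaves its columns NaN with a log entry. A 60-channel
    record with the default 5 bands and 3 tasks yields 3600 columns.
    """
    band_scheme = band_scheme or BandScheme()
    interval_spec = interval_spec or IntervalSpec(0.0, 1000.0)
    columns = [
        f"{feat}_{band}_{task}_{ch}"
        for feat in FEATURE_NAMES
        for band in band_scheme.names()
        for task in tasks
        for ch in (records[0].channel_labels if records else ())
    ]
    rows = {}
    for record in records:
        values: dict[str, float] = {}
        for band, (low, high) in band_scheme.bands.items():
            filtered = bandpass(record, low, high, numtaps=numtaps)
            for task in tasks:
                intervals = task_intervals(filtered, task, interval_spec)
                if not intervals:
                    log.warning(
                        "%s: no %s intervals; %s-band features set to NaN",
                        record.subject_id, task, band,
                    )
                    block = np.full(
                        (len(FEATURE_NAMES), record.n_channels), np.nan
                    )
                else:
                    block = np.mean(
                        [
                            _interval_features(iv, record.fs, m, r_factor)
                            for iv in intervals
                        ],
                        axis=0,
                    )
                for fi, feat in enumerate(FEATURE_NAMES):
                    for ci, ch in enumerate(record.channel_labels):
                        values[f"{feat}_{band}_{task}_{ch}"] = block[fi, ci]
        rows[record.subject_id] = values
    return pd.DataFrame.from_dict(rows, orient="index", dtype=float).reindex(
        columns=columns
    )
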