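"""Fixed stratified split, classifier training and PD-positive metrics,
and the parameter-grid runner.

The CSP transformation is always fitted on learning-set records only and
then applied to the validation set; SVMs see z-scored features (statistics
from the learning set), discriminant and Bayes classifiers consume the raw
features.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from . import csp as csp_mod
from . import laplacian as lap_mod
from .errors import ConfigurationError, MaskInfeasibleError, SchemaError
from .groupavg import group_pooled_average, record_task_average
from .montage import CANDIDATE_CENTERS, MontageGrid, default_grid
from .preprocess import IntervalSpec, bandpass
from .records import GROUPS, EEGRecord

log = logging.getLogger(__name__)

#: PD is the positive class everywhere.
POSITIVE = "pd"

CLASSIFIER_KINDS = ("svm_poly", "svm_rbf", "bayes", "lda", "qda", "tree")


# ---------------------------------------------------------------------------
# Split
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    """Disjoint learning/validation record-id lists, fixed once created."""

    learning_ids: tuple[str, ...]
    validation_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        overlap = set(self.learning_ids) & set(self.validation_ids)
        if overlap:
            raise ConfigurationError(f"split overlaps on {sorted(overlap)}")

    @property
    def digest(self) -> str:
        payload = json.dumps(
            [sorted(self.learning_ids), sorted(self.validation_ids)]
        ).encode()
        return hashlib.sha256(payload).hexdigest()

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "learning_ids": list(self.learning_ids),
                    "validation_ids": list(self.validation_ids),
                    "sha256": self.digest,
                },
                indent=1,
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "SplitSpec":
        meta = json.loads(Path(path).read_text())
        split = cls(
            tuple(meta["learning_ids"]), tuple(meta["validation_ids"])
        )
        if meta.get("sha256") and meta["sha256"] != split.digest:
            raise ConfigurationError(f"{path}: split file hash mismatch")
        return split


def stratified_split(
    manifest: list[tuple[str, str]],
    learning_fraction: float = 0.6,
    seed: int = 0,
) -> SplitSpec:
    """Per-group random split, learning size rounded to nearest integer.

    ``manifest`` is a list of (record_id, group). Deterministic in seed.
    """
    if not 0 < learning_fraction < 1:
        raise ConfigurationError(
            f"learning fraction must be in (0, 1), got {learning_fraction}"
        )
    by_group: dict[str, list[str]] = {}
    for record_id, group in manifest:
        by_group.setdefault(group, []).append(record_id)
    rng = np.random.default_rng(seed)
    learning: list[str] = []
    validation: list[str] = []
    for group in sorted(by_group):
        ids = sorted(by_group[group])
        if len(ids) < 2:
            raise ConfigurationError(f"group {group!r} has fewer than 2 records")
        rng.shuffle(ids)
        n_learn = int(round(learning_fraction * len(ids)))
        n_learn = min(max(n_learn, 1), len(ids) - 1)
        learning.extend(ids[:n_learn])
        validation.extend(ids[n_learn:])
    return SplitSpec(tuple(sorted(learning)), tuple(sorted(validation)))


# ---------------------------------------------------------------------------
# Classifiers and metrics
# ---------------------------------------------------------------------------

def make_classifier(kind: str, seed: int = 0):
    """An unfitted sklearn estimator for one of the six classifier kinds."""
    if kind == "svm_poly":
        return Pipeline(
            [("scale", StandardScaler()), ("svc", SVC(kernel="poly", degree=3, C=1.0))]
        )
    if kind == "svm_rbf":
        return Pipeline(
            [("scale", StandardScaler()), ("svc", SVC(kernel="rbf", C=1.0, gamma="scale"))]
        )
    if kind == "bayes":
        return GaussianNB()
    if kind == "lda":
        return LinearDiscriminantAnalysis()
    if kind == "qda":
        # tiny ridge: exactly collinear features otherwise abort the fit
        return QuadraticDiscriminantAnalysis(reg_param=1e-6)
    if kind == "tree":
        return DecisionTreeClassifier(random_state=seed)
    raise ConfigurationError(f"unknown classifier kind {kind!r}")


def train(kind: str, features: np.ndarray, labels: list[str], seed: int = 0):
    """Fit a classifier on (n_records, n_features) data with group labels."""
    features = np.asarray(features, dtype=float)
    labels = list(labels)
    if len(set(labels)) < 2:
        raise SchemaError("training set contains a single class")
    if features.shape[0] != len(labels):
        raise SchemaError("feature rows and labels differ in length")
    model = make_classifier(kind, seed)
    model.fit(features, labels)
    return model


@dataclass
class ClassifierResult:
    """Validation predictions and PD-positive metrics (percent)."""

    classifier: str
    feature_desc: str
    record_ids: tuple[str, ...]
    y_true: tuple[str, ...]
    y_pred: tuple[str, ...]
    extra: dict = field(default_factory=dict)

    @property
    def counts(self) -> tuple[int, int, int, int]:
        """(TP, FN, TN, FP) with PD positive."""
        tp = fn = tn = fp = 0
        for truth, pred in zip(self.y_true, self.y_pred):
            if truth == POSITIVE:
                tp += pred == POSITIVE
                fn += pred != POSITIVE
            else:
                tn += pred != POSITIVE
                fp += pred == POSITIVE
        return tp, fn, tn, fp

    @property
    def accuracy(self) -> float:
        tp, fn, tn, fp = self.counts
        return 100.0 * (tp + tn) / (tp + fn + tn + fp)

    @property
    def sensitivity(self) -> float:
        tp, fn, _, _ = self.counts
        return 100.0 * tp / (tp + fn) if tp + fn else float("nan")

    @property
    def specificity(self) -> float:
        _, _, tn, fp = self.counts
        return 100.0 * tn / (tn + fp) if tn + fp else float("nan")


def metrics_from_counts(
    tp: int, fn: int, tn: int, fp: int
) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) in percent from a confusion
    matrix, by materializing the unique prediction set it describes."""
    y_true = [POSITIVE] * (tp + fn) + ["control"] * (tn + fp)
    y_pred = (
        [POSITIVE] * tp + ["control"] * fn + ["control"] * tn + [POSITIVE] * fp
    )
    result = ClassifierResult(
        classifier="counts",
        feature_desc="counts",
        record_ids=tuple(f"r{i}" for i in range(len(y_true))),
        y_true=tuple(y_true),
        y_pred=tuple(y_pred),
    )
    assert result.counts == (tp, fn, tn, fp)
    return result.accuracy, result.sensitivity, result.specificity


def evaluate_classifier(
    model,
    features: np.ndarray,
    labels: list[str],
    record_ids: list[str] | None = None,
    classifier: str = "",
    feature_desc: str = "",
) -> ClassifierResult:
    """Predict on a validation set and package PD-positive metrics."""
    features = np.asarray(features, dtype=float)
    labels = list(labels)
    unknown = set(labels) - set(GROUPS)
    if unknown:
        raise SchemaError(f"unknown group labels {sorted(unknown)}")
    preds = model.predict(features)
    ids = record_ids or [f"r{i}" for i in range(len(labels))]
    return ClassifierResult(
        classifier=classifier,
        feature_desc=feature_desc,
        record_ids=tuple(ids),
        y_true=tuple(labels),
        y_pred=tuple(preds),
    )


# ---------------------------------------------------------------------------
# Grid runner
# ---------------------------------------------------------------------------

def _default_csp_sets() -> tuple[tuple[str, ...], ...]:
    singles = tuple((name,) for name in csp_mod.EXTREME_COMPONENTS)
    return singles + (
        ("MxPMnC1", "MxPMnC2"),
        ("MxPMnC2", "MxPMnC3"),
        ("MxPMnC1", "MxPMnC2", "MxPMnC3"),
        ("MnPMxC1", "MnPMxC2", "MnPMxC3"),
    )


def _default_mask_sets() -> tuple[tuple[lap_mod.LaplacianMaskSpec, ...], ...]:
    singles = tuple(
        (lap_mod.LaplacianMaskSpec(c, 1),) for c in CANDIDATE_CENTERS
    )
    return singles + (
        (
            lap_mod.LaplacianMaskSpec("Fz", 1),
            lap_mod.LaplacianMaskSpec("F3", 2),
            lap_mod.LaplacianMaskSpec("F4", 2),
        ),
        (
            lap_mod.LaplacianMaskSpec("Fz", 1),
            lap_mod.LaplacianMaskSpec("C3", 2),
        ),
    )


@dataclass
class GridConfig:
    """Axes of the parameter grid."""

    task: str = "Standard"
    low_hz: float = 0.1
    high_hz: tuple[float, ...] = (4.0, 13.0, 20.0, 30.0)
    interval_lengths_ms: tuple[float, ...] = (250.0, 500.0, 1000.0)
    interval_start_ms: float = 0.0
    feature_kinds: tuple[str, ...] = ("csp", "laplacian")
    csp_component_sets: tuple[tuple[str, ...], ...] = field(
        default_factory=_default_csp_sets
    )
    laplacian_mask_sets: tuple[tuple[lap_mod.LaplacianMaskSpec, ...], ...] = field(
        default_factory=_default_mask_sets
    )
    classifiers: tuple[str, ...] = CLASSIFIER_KINDS
    csp_feature_mode: str = "avg_then_map"
    numtaps: int = 1651
    seed: int = 0


def run_grid(
    records: list[EEGRecord],
    split: SplitSpec,
    config: GridConfig | None = None,
    grid: MontageGrid | None = None,
) -> pd.DataFrame:
    """Evaluate every grid cell and return a long-format results table.

    Columns: high_hz, interval_ms, feature_kind, feature_desc, n_features,
    classifier, accuracy, sensitivity, specificity, tp, fn, tn, fp.
    Infeasible Laplacian mask sets are skipped with a log entry.
    """
    config = config or GridConfig()
    grid = grid or default_grid()
    by_id = {r.subject_id: r for r in records}
    missing = [i for i in split.learning_ids + split.validation_ids if i not in by_id]
    if missing:
        raise SchemaError(f"split references unknown records {missing}")

    rows: list[dict] = []
    for high in config.high_hz:
        filtered = {
            rid: bandpass(by_id[rid], config.low_hz, high, numtaps=config.numtaps)
            for rid in split.learning_ids + split.validation_ids
        }
        learn = [filtered[rid] for rid in split.learning_ids]
        valid = [filtered[rid] for rid in split.validation_ids]
        for length in config.interval_lengths_ms:
            spec = IntervalSpec(config.interval_start_ms, length)
            # per-record average intervals, computed once per grid cell
            avg_of = {
                r.subject_id: record_task_average(r, config.task, spec)
                for r in learn + valid
            }
            feature_cells: list[tuple[str, str, np.ndarray, np.ndarray]] = []

            if "csp" in config.feature_kinds:
                avg_ctl = group_pooled_average(
                    [r for r in learn if r.group == "control"], config.task, spec
                )
                avg_pd = group_pooled_average(
                    [r for r in learn if r.group == "pd"], config.task, spec
                )
                model = csp_mod.csp_fit(
                    avg_ctl.a, avg_pd.a, channel_labels=learn[0].channel_labels
                )

                def _csp_feats(r, comps):
                    if config.csp_feature_mode == "avg_then_map":
                        return csp_mod.features_from_average(
                            model, avg_of[r.subject_id], comps
                        )
                    return csp_mod.csp_features(
                        model, r, config.task, spec, comps,
                        mode=config.csp_feature_mode,
                    )

                for comps in config.csp_component_sets:
                    X_learn = np.array([_csp_feats(r, comps) for r in learn])
                    X_valid = np.array([_csp_feats(r, comps) for r in valid])
                    feature_cells.append(
                        ("csp", "+".join(comps), X_learn, X_valid)
                    )

            if "laplacian" in config.feature_kinds:
                for masks in config.laplacian_mask_sets:
                    desc = "+".join(str(m) for m in masks)
                    try:
                        X_learn = np.array(
                            [
                                lap_mod.features_from_average(
                                    avg_of[r.subject_id], r.channel_labels,
                                    list(masks), grid,
                                )
                                for r in learn
                            ]
                        )
                        X_valid = np.array(
                            [
                                lap_mod.features_from_average(
                                    avg_of[r.subject_id], r.channel_labels,
                                    list(masks), grid,
                                )
                                for r in valid
                            ]
                        )
                    except MaskInfeasibleError as exc:
                        log.info("skipping mask set %s: %s", desc, exc)
                        continue
                    feature_cells.append(("laplacian", desc, X_learn, X_valid))

            y_learn = [r.group for r in learn]
            y_valid = [r.group for r in valid]
            for kind, desc, X_learn, X_valid in feature_cells:
                for clf in config.classifiers:
                    try:
                        fitted = train(clf, X_learn, y_learn, seed=config.seed)
                    except np.linalg.LinAlgError as exc:
                        log.info(
                            "skipping %s on %s (%g Hz, %g ms): %s",
                            clf, desc, high, length, exc,
                        )
                        continue
                    result = evaluate_classifier(
                        fitted, X_valid, y_valid,
                        record_ids=list(split.validation_ids),
                        classifier=clf,
                        feature_desc=desc,
                    )
                    tp, fn, tn, fp = result.counts
                    rows.append(
                        {
                            "high_hz": high,
                            "interval_ms": length,
                            "feature_kind": kind,
                            "feature_desc": desc,
                            "n_features": X_learn.shape[1],
                            "classifier": clf,
                            "accuracy": result.accuracy,
                            "sensitivity": result.sensitivity,
                            "specificity": result.specificity,
                            "tp": tp, "fn": fn, "tn": tn, "fp": fp,
                        }
                    )
    return pd.DataFrame(rows)
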