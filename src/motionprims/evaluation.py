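"""Evaluation protocols and metrics: stratified repeated splits,
leave-one-subject-out folds, per-class and overall (micro-pooled) positive
predictive value, row-percent confusion matrices, one-vs-all ROC analysis
with optimal operating points, and a train/test timing harness.

Splitting operates on primitive *segments*, never on individual windows:
all windows of a segment travel together, so near-duplicate overlapping
windows can never leak across the train/test boundary.  Headline metrics
are reported at the primitive level — window predictions within a
ground-truth segment are aggregated by majority vote — with window-level
confusion matrices retained alongside.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc_curve

from .classifiers import ScoreMatrix, fit as fit_classifier
from .core import CLASSES
from .errors import InvalidArgumentError
from .features import feature_matrix

__all__ = [
    "SplitPlan",
    "ConfusionMatrix",
    "RocResult",
    "AlgorithmResult",
    "EvaluationReport",
    "TimingReport",
    "SMALL_DATASET_FRACTIONS",
    "LARGE_DATASET_FRACTIONS",
    "stratified_split",
    "loso_splits",
    "ppv_scores",
    "roc_analysis",
    "evaluate",
    "timing_benchmark",
]

#: Dataset-fraction grid for the original-size timing study (20-100%, 10% steps).
SMALL_DATASET_FRACTIONS: tuple[float, ...] = tuple(
    round(0.1 * i, 10) for i in range(2, 11)
)
#: Dataset-fraction grid for the large simulated-population study (25% steps).
LARGE_DATASET_FRACTIONS: tuple[float, ...] = (0.25, 0.5, 0.75, 1.0)


@dataclass(frozen=True)
class SplitPlan:
    """How to split a feature table for evaluation.

    ``stratified_repeats``: per class, a ``train_fraction`` share of the
    class's segments goes to training, re-drawn ``n_repeats`` times.
    ``loso``: one fold per subject (train on the rest).
    """

    scheme: str = "stratified_repeats"
    train_fraction: float = 0.6
    n_repeats: int = 10
    unit: str = "segment"
    seed: int | None = None

    def __post_init__(self):
        if self.scheme not in ("stratified_repeats", "loso"):
            raise InvalidArgumentError(
                "scheme must be 'stratified_repeats' or 'loso'"
            )
        if not (0 < self.train_fraction < 1):
            raise InvalidArgumentError("train_fraction must be in (0, 1)")
        if self.n_repeats < 1:
            raise InvalidArgumentError("n_repeats must be >= 1")
        if self.unit != "segment":
            raise InvalidArgumentError("only segment-level splitting is supported")
        if self.scheme == "stratified_repeats" and self.seed is None:
            raise InvalidArgumentError("SplitPlan.seed is required (no silent default)")


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------


def _segment_index(meta: pd.DataFrame):
    """Factorize (subject_id, segment_id) pairs; returns per-row segment
    codes, per-segment labels, and per-segment subjects."""
    key = pd.MultiIndex.from_arrays(
        [meta["subject_id"].to_numpy(), meta["segment_id"].to_numpy()]
    )
    codes, uniques = pd.factorize(key, sort=True)
    first_row = np.zeros(len(uniques), dtype=int)
    first_row[codes[::-1]] = np.arange(len(codes))[::-1]
    seg_labels = meta["window_label"].to_numpy()[first_row]
    seg_subjects = meta["subject_id"].to_numpy()[first_row]
    return codes, seg_labels, seg_subjects


def _stratified_train_segments(
    seg_labels: np.ndarray, plan: SplitPlan, repeat_index: int
) -> np.ndarray:
    """Boolean per-segment train membership for one repeat."""
    rng = np.random.default_rng(
        np.random.SeedSequence([int(plan.seed), int(repeat_index)])
    )
    train = np.zeros(len(seg_labels), dtype=bool)
    classes = [c for c in CLASSES if c in seg_labels] + sorted(
        set(seg_labels) - set(CLASSES)
    )
    for c in classes:
        idx = np.flatnonzero(seg_labels == c)
        if len(idx) < 2:
            raise InvalidArgumentError(
                f"class {c!r} has a single segment; cannot stratify"
            )
        n_train = int(round(plan.train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        chosen = rng.permutation(idx)[:n_train]
        train[chosen] = True
    return train


def stratified_split(
    table: pd.DataFrame, plan: SplitPlan, repeat_index: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segment-level stratified split: per class, ``train_fraction`` of the
    segments (within one segment of the exact fraction) go to training.

    Disjoint and exhaustive at the row level; seeded per ``repeat_index``.
    """
    codes, seg_labels, _ = _segment_index(table)
    train_seg = _stratified_train_segments(seg_labels, plan, repeat_index)
    mask = train_seg[codes]
    return table[mask], table[~mask]


def loso_splits(table: pd.DataFrame) -> list[tuple[pd.DataFrame, pd.DataFrame]]:
    """Leave-one-subject-out folds (one per subject, sorted by subject id)."""
    subjects = sorted(pd.unique(table["subject_id"]))
    if len(subjects) < 2:
        raise InvalidArgumentError("leave-one-subject-out requires >= 2 subjects")
    out = []
    for s in subjects:
        mask = (table["subject_id"] == s).to_numpy()
        out.append((table[~mask], table[mask]))
    return out


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclass
class ConfusionMatrix:
    """Counts indexed (true class, predicted class)."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise InvalidArgumentError("counts must be (k, k) for k classes")
        if np.any(self.counts < 0):
            raise InvalidArgumentError("counts must be non-negative")

    @classmethod
    def from_labels(cls, y_true, y_pred, classes=None) -> "ConfusionMatrix":
        if classes is None:
            present = set(np.asarray(y_true)) | set(np.asarray(y_pred))
            classes = tuple(c for c in CLASSES if c in present) + tuple(
                sorted(present - set(CLASSES))
            )
        counts = _sk_confusion(y_true, y_pred, labels=list(classes))
        return cls(tuple(classes), counts)

    @property
    def row_percent(self) -> np.ndarray:
        """Rows normalized to percentages; zero-support rows are NaN."""
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = 100.0 * self.counts / totals
        out[totals[:, 0] == 0] = np.nan
        return out

    def to_frame(self, percent: bool = True) -> pd.DataFrame:
        data = self.row_percent if percent else self.counts
        return pd.DataFrame(data, index=list(self.classes), columns=list(self.classes))

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.classes != other.classes:
            raise InvalidArgumentError("cannot add confusion matrices: class mismatch")
        return ConfusionMatrix(self.classes, self.counts + other.counts)


def ppv_scores(cm: ConfusionMatrix) -> tuple[dict[str, float], float]:
    """Per-class and overall positive predictive value, in percent.

    PPV_c = 100 * TP_c / (TP_c + FP_c) from the one-vs-all reduction; the
    overall PPV micro-pools TP and FP across classes, which for a complete
    multiclass confusion matrix equals overall accuracy.  Classes never
    predicted get NaN.
    """
    counts = cm.counts
    total = counts.sum()
    if total == 0:
        raise InvalidArgumentError("confusion matrix is all zeros")
    tp = np.diag(counts).astype(float)
    predicted = counts.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class = 100.0 * tp / predicted
    per_class[predicted == 0] = np.nan
    overall = 100.0 * tp.sum() / predicted.sum()
    return dict(zip(cm.classes, per_class)), float(overall)


@dataclass
class RocResult:
    """One-vs-all ROC curve for a single class."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    operating_point: dict  # fpr, tpr, threshold at the optimum


def _operating_point(fpr, tpr, thresholds, method: str) -> dict:
    if method == "youden":
        i = int(np.argmax(tpr - fpr))
    elif method == "closest":
        i = int(np.argmin(fpr**2 + (1.0 - tpr) ** 2))
    else:
        raise InvalidArgumentError("operating-point method must be 'youden' or 'closest'")
    return {
        "fpr": float(fpr[i]),
        "tpr": float(tpr[i]),
        "threshold": float(thresholds[i]),
    }


def roc_analysis(
    scores: ScoreMatrix, y_true, *, method: str = "youden"
) -> dict[str, RocResult]:
    """One-vs-all ROC per class: threshold sweep over the class's scores,
    AUC by trapezoidal integration, operating point maximizing Youden's
    J = tpr - fpr (or closest-to-(0,1) with ``method='closest'``).

    Classes absent from ``y_true`` (or with no negatives) are skipped with a
    warning.
    """
    y_true = np.asarray(y_true)
    out: dict[str, RocResult] = {}
    for i, c in enumerate(scores.classes):
        pos = y_true == c
        if not pos.any() or pos.all():
            warnings.warn(
                f"class {c!r} lacks positives or negatives; ROC skipped",
                stacklevel=2,
            )
            continue
        fpr, tpr, thr = _sk_roc_curve(pos, scores.values[:, i])
        auc = float(np.trapezoid(tpr, fpr))
        out[c] = RocResult(
            fpr=fpr,
            tpr=tpr,
            thresholds=thr,
            auc=auc,
            operating_point=_operating_point(fpr, tpr, thr, method),
        )
    return out


# ---------------------------------------------------------------------------
# End-to-end evaluation
# ---------------------------------------------------------------------------


@dataclass
class AlgorithmResult:
    """Cross-repeat metrics for one algorithm (primitive-level headline)."""

    algorithm: str
    classes: tuple[str, ...]
    ppv_per_class_mean: dict[str, float]
    ppv_per_class_sd: dict[str, float]
    overall_ppv_mean: float
    overall_ppv_sd: float
    overall_ppv_per_repeat: list[float]
    confusion: ConfusionMatrix
    window_confusion: ConfusionMatrix
    window_overall_ppv_mean: float
    roc: dict[str, RocResult] | None = None


@dataclass
class EvaluationReport:
    plan: SplitPlan
    classes: tuple[str, ...]
    results: dict[str, AlgorithmResult] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Table layout: one row per algorithm, per-class and overall PPV
        as mean +/- sd over repeats."""
        rows = []
        for name, r in self.results.items():
            row: dict = {"algorithm": name}
            for c in self.classes:
                row[f"{c}_ppv_mean"] = r.ppv_per_class_mean.get(c, np.nan)
                row[f"{c}_ppv_sd"] = r.ppv_per_class_sd.get(c, np.nan)
            row["overall_ppv_mean"] = r.overall_ppv_mean
            row["overall_ppv_sd"] = r.overall_ppv_sd
            rows.append(row)
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        d = {
            "schema": {"kind": "evaluation_report", "version": 1},
            "plan": {
                "scheme": self.plan.scheme,
                "train_fraction": self.plan.train_fraction,
                "n_repeats": self.plan.n_repeats,
                "seed": self.plan.seed,
            },
            "classes": list(self.classes),
            "algorithms": {},
        }
        for name, r in self.results.items():
            d["algorithms"][name] = {
                "ppv_per_class_mean": r.ppv_per_class_mean,
                "ppv_per_class_sd": r.ppv_per_class_sd,
                "overall_ppv_mean": r.overall_ppv_mean,
                "overall_ppv_sd": r.overall_ppv_sd,
                "overall_ppv_per_repeat": r.overall_ppv_per_repeat,
                "confusion_row_percent": r.confusion.row_percent.tolist(),
                "confusion_counts": r.confusion.counts.tolist(),
                "window_overall_ppv_mean": r.window_overall_ppv_mean,
                "roc": {
                    c: {
                        "auc": rr.auc,
                        "operating_point": rr.operating_point,
                    }
                    for c, rr in (r.roc or {}).items()
                },
            }
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _normalize_algorithms(algorithms, hyperparams) -> dict[str, dict]:
    if isinstance(algorithms, str):
        algorithms = [algorithms]
    hp = dict(hyperparams or {})
    return {name: dict(hp.get(name, {})) for name in algorithms}


def _nan_mean_sd(values: np.ndarray) -> tuple[float, float]:
    vals = values[~np.isnan(values)]
    if len(vals) == 0:
        return float("nan"), float("nan")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return mean, sd


def evaluate(
    table: pd.DataFrame,
    algorithms,
    plan: SplitPlan,
    *,
    hyperparams: dict | None = None,
    standardize: bool = True,
    compute_roc: bool = True,
    roc_method: str = "youden",
) -> EvaluationReport:
    """Run the full evaluation protocol on a labeled feature table.

    For every repeat (or LOSO fold): fit each algorithm on the training
    rows, predict and score the test rows, aggregate window predictions to
    primitive-level labels by per-segment majority vote (ties toward the
    earliest class in canonical order), and accumulate confusion counts.
    Feature columns are standardized with training-split statistics when
    ``standardize`` is set.  Per-class and overall PPV are reported as
    mean +/- sample sd across repeats; ROC curves use primitive-level scores
    pooled across repeats.  Fully deterministic given the plan's seed.
    """
    algos = _normalize_algorithms(algorithms, hyperparams)
    X, y, meta = feature_matrix(table)
    if X.shape[0] == 0:
        raise InvalidArgumentError("feature table is empty")
    codes, seg_labels, seg_subjects = _segment_index(meta)
    classes = tuple(c for c in CLASSES if c in seg_labels) + tuple(
        sorted(set(seg_labels) - set(CLASSES))
    )
    class_index = {c: i for i, c in enumerate(classes)}
    seg_label_idx = np.array([class_index[c] for c in seg_labels])

    if plan.scheme == "stratified_repeats":
        folds = [
            _stratified_train_segments(seg_labels, plan, r)
            for r in range(plan.n_repeats)
        ]
    else:
        subjects = sorted(set(seg_subjects))
        if len(subjects) < 2:
            raise InvalidArgumentError("leave-one-subject-out requires >= 2 subjects")
        folds = [seg_subjects != s for s in subjects]

    k = len(classes)
    acc: dict[str, dict] = {
        name: {
            "per_repeat_per_class": [],
            "per_repeat_overall": [],
            "pooled": np.zeros((k, k), dtype=int),
            "pooled_window": np.zeros((k, k), dtype=int),
            "window_overall": [],
            "roc_scores": [],
            "roc_truth": [],
        }
        for name in algos
    }

    for train_seg in folds:
        train_mask = train_seg[codes]
        test_mask = ~train_mask
        # segment-level split => zero window leakage by construction
        assert not np.any(train_seg[codes[test_mask]])
        X_train, y_train = X[train_mask], y[train_mask]
        X_test = X[test_mask]
        if standardize:
            mu = X_train.mean(axis=0)
            sd = X_train.std(axis=0)
            sd[sd < 1e-12] = 1.0
            X_train = (X_train - mu) / sd
            X_test = (X_test - mu) / sd

        test_codes = codes[test_mask]
        local, local_codes = np.unique(test_codes, return_inverse=True)
        n_local = len(local)
        true_idx = seg_label_idx[local]

        for name, hp in algos.items():
            model = fit_classifier(name, X_train, y_train, **hp)
            scores = model.predict_scores(X_test)
            y_pred = model.predict(X_test)

            # map model class order onto report class order
            col = np.array([class_index[c] for c in scores.classes])
            pred_idx = np.array([class_index[c] for c in y_pred])

            # window-level confusion
            wtrue = seg_label_idx[test_codes]
            wcm = np.zeros((k, k), dtype=int)
            np.add.at(wcm, (wtrue, pred_idx), 1)
            acc[name]["pooled_window"] += wcm
            acc[name]["window_overall"].append(
                100.0 * np.trace(wcm) / wcm.sum()
            )

            # primitive level: majority vote + mean scores per segment
            votes = np.zeros((n_local, k))
            np.add.at(votes, (local_codes, pred_idx), 1)
            prim_pred = np.argmax(votes, axis=1)  # first max = canonical order
            mean_scores = np.zeros((n_local, k))
            np.add.at(
                mean_scores,
                (local_codes[:, None], col[None, :]),
                scores.values,
            )
            mean_scores /= np.bincount(local_codes, minlength=n_local)[:, None]

            cm = np.zeros((k, k), dtype=int)
            np.add.at(cm, (true_idx, prim_pred), 1)
            acc[name]["pooled"] += cm
            per_class, overall = ppv_scores(ConfusionMatrix(classes, cm))
            acc[name]["per_repeat_per_class"].append(
                [per_class[c] for c in classes]
            )
            acc[name]["per_repeat_overall"].append(overall)
            if compute_roc:
                acc[name]["roc_scores"].append(mean_scores)
                acc[name]["roc_truth"].append(np.asarray(classes)[true_idx])

    report = EvaluationReport(plan=plan, classes=classes)
    for name in algos:
        a = acc[name]
        per_class_matrix = np.asarray(a["per_repeat_per_class"], dtype=float)
        mean_sd = [_nan_mean_sd(per_class_matrix[:, i]) for i in range(k)]
        overall_arr = np.asarray(a["per_repeat_overall"], dtype=float)
        o_mean, o_sd = _nan_mean_sd(overall_arr)
        roc = None
        if compute_roc:
            pooled_scores = ScoreMatrix(np.vstack(a["roc_scores"]), classes)
            pooled_truth = np.concatenate(a["roc_truth"])
            roc = roc_analysis(pooled_scores, pooled_truth, method=roc_method)
        report.results[name] = AlgorithmResult(
            algorithm=name,
            classes=classes,
            ppv_per_class_mean={c: mean_sd[i][0] for i, c in enumerate(classes)},
            ppv_per_class_sd={c: mean_sd[i][1] for i, c in enumerate(classes)},
            overall_ppv_mean=o_mean,
            overall_ppv_sd=o_sd,
            overall_ppv_per_repeat=[float(v) for v in overall_arr],
            confusion=ConfusionMatrix(classes, a["pooled"]),
            window_confusion=ConfusionMatrix(classes, a["pooled_window"]),
            window_overall_ppv_mean=float(np.mean(a["window_overall"])),
            roc=roc,
        )
    return report


# ---------------------------------------------------------------------------
# Timing harness
# ---------------------------------------------------------------------------


@dataclass
class TimingReport:
    """Wall-clock training/testing times per (algorithm, dataset fraction).

    Absolute values are hardware-dependent; only relative structure (e.g.
    KNN's storage-only training) is meaningful across machines.
    """

    rows: list[dict]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"schema": {"kind": "timing_report", "version": 1}, "rows": self.rows},
                fh,
                indent=2,
            )


def timing_benchmark(
    table: pd.DataFrame,
    algorithms,
    fractions,
    seed: int,
    *,
    hyperparams: dict | None = None,
    probe_size: int = 200,
) -> TimingReport:
    """Measure train time and per-sample test time at increasing dataset
    fractions, training de novo at each fraction.

    ``fractions`` must be strictly increasing within (0, 1].  Test time is
    averaged over a fixed probe set of up to ``probe_size`` rows.
    """
    fractions = list(fractions)
    if not fractions:
        raise InvalidArgumentError("fractions must be non-empty")
    arr = np.asarray(fractions, dtype=float)
    if np.any(arr <= 0) or np.any(arr > 1):
        raise InvalidArgumentError("fractions must lie in (0, 1]")
    if np.any(np.diff(arr) <= 0):
        raise InvalidArgumentError("fractions must be strictly increasing")

    algos = _normalize_algorithms(algorithms, hyperparams)
    X, y, _ = feature_matrix(table)
    n = X.shape[0]
    rng = np.random.default_rng(int(seed))
    probe = rng.choice(n, size=min(probe_size, n), replace=False)
    X_probe = np.ascontiguousarray(X[probe])

    rows = []
    for f in fractions:
        size = max(int(round(f * n)), 2)
        idx = rng.choice(n, size=min(size, n), replace=False)
        X_f = np.ascontiguousarray(X[idx])
        y_f = y[idx]
        if len(np.unique(y_f)) < 2:  # pragma: no cover - tiny-fraction guard
            continue
        for name, hp in algos.items():
            t0 = time.perf_counter()
            model = fit_classifier(name, X_f, y_f, **hp)
            train_s = time.perf_counter() - t0
            t0 = time.perf_counter()
            model.predict(X_probe)
            test_s = (time.perf_counter() - t0) / len(probe)
            rows.append(
                {
                    "algorithm": name,
                    "fraction": float(f),
                    "n_train": int(len(idx)),
                    "train_seconds": train_s,
                    "test_seconds_per_sample": test_s,
                }
            )
    return TimingReport(rows)
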