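"""Exhaustive search over sensor-site subsets and sensor types.

Every non-empty subset of the instrumented sites is evaluated with the same
split seeds (so between-configuration differences are paired, not split
noise), ranked by mean overall PPV, and summarized as the best configuration
per sensor count.  The IMU-vs-accelerometer comparison evaluates each
configuration twice — all 10 channels per site vs the 3 acceleration
channels — on identical splits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.linalg

from . import core
from .core import CLASSES
from .errors import InvalidArgumentError, MotionPrimsError
from .evaluation import (
    SplitPlan,
    _segment_index,
    _stratified_train_segments,
    evaluate,
    ppv_scores,
    ConfusionMatrix,
)
from .features import (
    SensorConfig,
    feature_columns,
    feature_matrix,
    select_channels,
    table_sites,
)

__all__ = [
    "SearchEntry",
    "SensorSearchResult",
    "enumerate_configs",
    "exhaustive_search",
    "compare_sensor_types",
]

MAX_SEARCH_SITES = 20


def enumerate_configs(sites, sensor_type: str = "imu") -> list[SensorConfig]:
    """All 2^n - 1 non-empty site subsets, ordered by size then
    lexicographically."""
    sites = list(sites)
    if not sites:
        raise InvalidArgumentError("sites must be non-empty")
    if len(set(sites)) != len(sites):
        raise InvalidArgumentError("sites contains duplicates")
    if len(sites) > MAX_SEARCH_SITES:
        raise InvalidArgumentError(
            f"{len(sites)} sites would require {2 ** len(sites) - 1} "
            f"configurations; restrict to at most {MAX_SEARCH_SITES} sites"
        )
    ordered = sorted(sites)
    return [
        SensorConfig(sites=combo, sensor_type=sensor_type)
        for size in range(1, len(ordered) + 1)
        for combo in combinations(ordered, size)
    ]


@dataclass
class SearchEntry:
    config: SensorConfig
    n_sites: int
    overall_ppv_mean: float
    overall_ppv_sd: float
    ppv_per_class: dict[str, float]
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None


@dataclass
class SensorSearchResult:
    classifier: str
    sensor_type: str
    plan: SplitPlan
    entries: list[SearchEntry] = field(default_factory=list)

    @property
    def best_per_count(self) -> dict[int, SearchEntry]:
        """Best entry for each sensor count (ties -> lexicographically
        smallest site set)."""
        out: dict[int, SearchEntry] = {}
        counts = sorted({e.n_sites for e in self.entries})
        for k in counts:
            candidates = [e for e in self.entries if e.n_sites == k and e.ok]
            if not candidates:
                continue
            out[k] = min(
                candidates, key=lambda e: (-e.overall_ppv_mean, e.config.sites)
            )
        return out

    def to_frame(self) -> pd.DataFrame:
        all_sites = sorted({s for e in self.entries for s in e.config.sites})
        rows = []
        for e in self.entries:
            row: dict = {
                "sites": "+".join(e.config.sites),
                "n_sites": e.n_sites,
                "sensor_type": e.config.sensor_type,
                "overall_ppv_mean": e.overall_ppv_mean,
                "overall_ppv_sd": e.overall_ppv_sd,
                "error": e.error or "",
            }
            for s in all_sites:
                row[f"has_{s}"] = int(s in e.config.sites)
            rows.append(row)
        return pd.DataFrame(rows)

    def best_to_dict(self) -> dict:
        return {
            "schema": {"kind": "sensor_search_best", "version": 1},
            "classifier": self.classifier,
            "sensor_type": self.sensor_type,
            "best_per_count": {
                str(k): {
                    "sites": list(e.config.sites),
                    "overall_ppv_mean": e.overall_ppv_mean,
                    "overall_ppv_sd": e.overall_ppv_sd,
                }
                for k, e in self.best_per_count.items()
            },
        }

    def best_to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.best_to_dict(), fh, indent=2)


def _evaluate_config(
    table, config, classifier, plan, hyperparams
) -> SearchEntry:
    try:
        sub = select_channels(table, config)
        report = evaluate(
            sub,
            [classifier],
            plan,
            hyperparams={classifier: hyperparams or {}},
            compute_roc=False,
        )
        r = report.results[classifier]
        return SearchEntry(
            config=config,
            n_sites=config.n_sites,
            overall_ppv_mean=r.overall_ppv_mean,
            overall_ppv_sd=r.overall_ppv_sd,
            ppv_per_class=dict(r.ppv_per_class_mean),
        )
    except MotionPrimsError as exc:  # record and continue
        return SearchEntry(
            config=config,
            n_sites=config.n_sites,
            overall_ppv_mean=float("nan"),
            overall_ppv_sd=float("nan"),
            ppv_per_class={},
            error=str(exc),
        )


def _lda_paired_entries(
    table: pd.DataFrame,
    configs: list[SensorConfig],
    plan: SplitPlan,
    ridge: float = 1e-6,
) -> list[SearchEntry]:
    """Evaluate many configurations with LDA on identical splits.

    Mathematically identical to ``select_channels -> evaluate`` per config
    (same splits, same training-split standardization, same regularized
    pooled-covariance discriminant, same primitive-level majority vote), but
    the pooled within-class scatter of a column subset is read off as a
    submatrix of the full-feature scatter, computed once per split.
    """
    X, _y, meta = feature_matrix(table)
    cols = feature_columns(table)
    codes, seg_labels, seg_subjects = _segment_index(meta)
    classes = tuple(c for c in CLASSES if c in seg_labels) + tuple(
        sorted(set(seg_labels) - set(CLASSES))
    )
    class_index = {c: i for i, c in enumerate(classes)}
    seg_label_idx = np.array([class_index[c] for c in seg_labels])
    y_idx = seg_label_idx[codes]
    k = len(classes)

    if plan.scheme == "stratified_repeats":
        folds = [
            _stratified_train_segments(seg_labels, plan, r)
            for r in range(plan.n_repeats)
        ]
    else:
        subjects = sorted(set(seg_subjects))
        if len(subjects) < 2:
            raise InvalidArgumentError(
                "leave-one-subject-out requires >= 2 subjects"
            )
        folds = [seg_subjects != s for s in subjects]

    col_site = np.array([c.split(".")[0] for c in cols])
    col_mod = np.array([c.split(".")[1] for c in cols])
    config_cols = []
    for cfg in configs:
        mods = set(core.sensor_modalities(cfg.sensor_type))
        mask = np.isin(col_site, list(cfg.sites)) & np.isin(col_mod, list(mods))
        config_cols.append(np.flatnonzero(mask))

    per_class = [[] for _ in configs]
    overall = [[] for _ in configs]
    errors: dict[int, str] = {}

    for train_seg in folds:
        train_mask = train_seg[codes]
        test_mask = ~train_mask
        X_train, X_test = X[train_mask], X[test_mask]
        mu = X_train.mean(axis=0)
        sd = X_train.std(axis=0)
        sd[sd < 1e-12] = 1.0
        X_train = (X_train - mu) / sd
        X_test = (X_test - mu) / sd
        y_train = y_idx[train_mask]
        counts = np.bincount(y_train, minlength=k)
        n_train = len(y_train)
        means = np.vstack([X_train[y_train == ci].mean(axis=0) for ci in range(k)])
        gram = X_train.T @ X_train
        scatter_full = gram - (means * counts[:, None]).T @ means
        dof = max(n_train - k, 1)
        log_priors = np.log(counts / n_train)

        test_codes = codes[test_mask]
        local, local_codes = np.unique(test_codes, return_inverse=True)
        true_idx = seg_label_idx[local]

        for ci, idx in enumerate(config_cols):
            if ci in errors:
                continue
            try:
                cov = scatter_full[np.ix_(idx, idx)] / dof
                p = len(idx)
                tr = np.trace(cov)
                cov[np.diag_indices_from(cov)] += ridge * (tr / p if tr > 0 else 1.0)
                cho = scipy.linalg.cho_factor(cov, check_finite=False)
                m = means[:, idx]
                w = scipy.linalg.cho_solve(cho, m.T, check_finite=False)
                b = -0.5 * np.einsum("kp,pk->k", m, w) + log_priors
                pred = np.argmax(X_test[:, idx] @ w + b, axis=1)
                votes = np.zeros((len(local), k))
                np.add.at(votes, (local_codes, pred), 1)
                prim_pred = np.argmax(votes, axis=1)
                cm = np.zeros((k, k), dtype=int)
                np.add.at(cm, (true_idx, prim_pred), 1)
                pc, ov = ppv_scores(ConfusionMatrix(classes, cm))
                per_class[ci].append([pc[c] for c in classes])
                overall[ci].append(ov)
            except (scipy.linalg.LinAlgError, MotionPrimsError) as exc:
                errors[ci] = str(exc)

    entries = []
    for ci, cfg in enumerate(configs):
        if ci in errors or not overall[ci]:
            entries.append(
                SearchEntry(
                    config=cfg,
                    n_sites=cfg.n_sites,
                    overall_ppv_mean=float("nan"),
                    overall_ppv_sd=float("nan"),
                    ppv_per_class={},
                    error=errors.get(ci, "no successful repeats"),
                )
            )
            continue
        arr = np.asarray(overall[ci], dtype=float)
        pc = np.asarray(per_class[ci], dtype=float)
        with np.errstate(invalid="ignore"):
            pc_mean = np.nanmean(pc, axis=0)
        entries.append(
            SearchEntry(
                config=cfg,
                n_sites=cfg.n_sites,
                overall_ppv_mean=float(arr.mean()),
                overall_ppv_sd=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
                ppv_per_class=dict(zip(classes, pc_mean)),
            )
        )
    return entries


def exhaustive_search(
    table: pd.DataFrame,
    classifier: str = "lda",
    plan: SplitPlan | None = None,
    *,
    sites=None,
    sensor_type: str = "imu",
    hyperparams: dict | None = None,
    progress=None,
) -> SensorSearchResult:
    """Evaluate every non-empty site subset with identical split seeds.

    A ``plan`` (with seed) is required; LDA is the default classifier and is
    evaluated through a shared-scatter fast path (identical results to the
    generic route).  A configuration whose evaluation fails is recorded with
    its error and the search continues.
    """
    if plan is None:
        raise InvalidArgumentError("a SplitPlan (with seed) is required")
    if sites is None:
        sites = table_sites(table)
    configs = enumerate_configs(sites, sensor_type)
    result = SensorSearchResult(
        classifier=classifier, sensor_type=sensor_type, plan=plan
    )
    hp = dict(hyperparams or {})
    if classifier == "lda" and set(hp) <= {"ridge"}:
        result.entries = _lda_paired_entries(table, configs, plan, **hp)
        if progress is not None:
            progress(len(configs), len(configs))
        return result
    for i, config in enumerate(configs):
        result.entries.append(
            _evaluate_config(table, config, classifier, plan, hyperparams)
        )
        if progress is not None:
            progress(i + 1, len(configs))
    return result


def compare_sensor_types(
    table: pd.DataFrame,
    configs,
    classifier: str = "lda",
    plan: SplitPlan | None = None,
    *,
    hyperparams: dict | None = None,
) -> pd.DataFrame:
    """Paired IMU vs accelerometer PPVs for each configuration.

    ``table`` must be a full-IMU feature table; each configuration is
    evaluated once with all 10 channels per site and once with the 3
    acceleration channels, on identical splits.
    """
    if plan is None:
        raise InvalidArgumentError("a SplitPlan (with seed) is required")
    rows = []
    for config in configs:
        sites = config.sites if isinstance(config, SensorConfig) else tuple(config)
        imu = _evaluate_config(
            table, SensorConfig(sites, "imu"), classifier, plan, hyperparams
        )
        acc = _evaluate_config(
            table,
            SensorConfig(sites, "accelerometer"),
            classifier,
            plan,
            hyperparams,
        )
        rows.append(
            {
                "sites": "+".join(sites),
                "n_sites": len(sites),
                "imu_ppv_mean": imu.overall_ppv_mean,
                "imu_ppv_sd": imu.overall_ppv_sd,
                "accelerometer_ppv_mean": acc.overall_ppv_mean,
                "accelerometer_ppv_sd": acc.overall_ppv_sd,
            }
        )
    return pd.DataFrame(rows)


def plot_ppv_vs_count(results, path=None, ax=None):
    """Best-per-count PPV vs sensor count, one line per sensor type.

    ``results`` is an iterable of :class:`SensorSearchResult`.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for result in np.atleast_1d(results):
        best = result.best_per_count
        counts = sorted(best)
        ax.plot(
            counts,
            [best[k].overall_ppv_mean for k in counts],
            marker="o",
            label=result.sensor_type,
        )
    ax.set_xlabel("number of sensors")
    ax.set_ylabel("overall PPV (%)")
    ax.legend()
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
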