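"""Normalization, sliding windows, and the five per-channel statistical
features (mean, sd, min, max, rms) that feed the classifiers.

A feature table is a :class:`pandas.DataFrame` whose first columns are the
metadata ``subject_id, segment_id, window_label, window_start_s`` and whose
remaining columns are features named ``<site>.<modality>.<axis>.<stat>`` in
deterministic site-major order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from . import core
from .core import FEATURE_STATS, METADATA_COLUMNS
from .errors import InvalidArgumentError
from .synth import Recording, SegmentLabels

__all__ = [
    "WindowSpec",
    "SensorConfig",
    "Window",
    "zscore_normalize",
    "segment_windows",
    "extract_features",
    "feature_names",
    "featurize_recording",
    "featurize_cohort",
    "select_channels",
    "feature_columns",
    "feature_matrix",
    "table_sites",
]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding analysis window (seconds); defaults 0.25 s width, 0.1 s stride."""

    width_s: float = 0.25
    stride_s: float = 0.1

    def __post_init__(self):
        if not (0 < self.stride_s <= self.width_s):
            raise InvalidArgumentError(
                "require 0 < stride_s <= width_s "
                f"(got stride={self.stride_s}, width={self.width_s})"
            )


@dataclass(frozen=True)
class SensorConfig:
    """A sensor placement: a subset of body sites plus the sensor type.

    ``imu`` keeps all 10 channels per site; ``accelerometer`` keeps the 3
    linear-acceleration channels.
    """

    sites: tuple[str, ...]
    sensor_type: str = "imu"

    def __post_init__(self):
        if len(self.sites) == 0:
            raise InvalidArgumentError("SensorConfig.sites must be non-empty")
        object.__setattr__(self, "sites", tuple(sorted(set(self.sites))))
        if self.sensor_type not in core.SENSOR_TYPES:
            raise InvalidArgumentError(
                f"sensor_type must be one of {core.SENSOR_TYPES}"
            )

    @property
    def n_sites(self) -> int:
        return len(self.sites)


@dataclass(frozen=True)
class Window:
    """One labeled analysis window (sample index half-open range)."""

    start_s: float
    start_idx: int
    stop_idx: int
    label: str
    segment_id: int


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def zscore_normalize(
    rec: Recording, stats: pd.DataFrame | None = None
) -> tuple[Recording, pd.DataFrame]:
    """Z-score every channel; returns the transformed recording and the
    per-channel statistics used.

    If ``stats`` (a frame indexed by channel name with columns ``mean`` and
    ``sd``) is supplied — e.g. computed on training data — it is applied;
    otherwise statistics are computed from ``rec`` itself (population sd),
    in which case transformed channels have mean 0 and sd 1 within 1e-9.
    Channels with ~zero variance are passed through as all-zeros after mean
    removal, with a warning.
    """
    names = rec.channel_names
    if stats is None:
        mean = rec.values.mean(axis=0)
        sd = rec.values.std(axis=0)
        stats = pd.DataFrame({"mean": mean, "sd": sd}, index=names)
    else:
        if set(stats.index) != set(names):
            raise InvalidArgumentError(
                "normalization stats channels do not match the recording"
            )
        stats = stats.loc[names]
        mean = stats["mean"].to_numpy(dtype=float)
        sd = stats["sd"].to_numpy(dtype=float)

    degenerate = sd < 1e-12
    if degenerate.any():
        bad = [names[i] for i in np.flatnonzero(degenerate)]
        warnings.warn(
            f"channel(s) with ~zero variance passed through as zeros: {bad}",
            stacklevel=2,
        )
    safe_sd = np.where(degenerate, 1.0, sd)
    values = (rec.values - mean) / safe_sd
    out = Recording(
        sample_rate=rec.sample_rate,
        channels=list(rec.channels),
        values=values,
        subject_id=rec.subject_id,
    )
    return out, stats


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------


def _window_geometry(rec: Recording, spec: WindowSpec) -> tuple[int, int]:
    width_n = max(int(round(spec.width_s * rec.sample_rate)), 1)
    stride_n = max(int(round(spec.stride_s * rec.sample_rate)), 1)
    return width_n, stride_n


def segment_windows(
    rec: Recording, labels: SegmentLabels, spec: WindowSpec
) -> list[Window]:
    """Slide windows over the recording and label each by the primitive
    owning the majority of its samples (ties toward the earlier segment).

    Windows start at multiples of the stride and are emitted only when fully
    inside the recording; over a contiguous span of T seconds this yields
    floor((T - width) / stride) + 1 windows.  Windows containing no labeled
    samples (possible only if the protocol leaves gaps) are dropped.
    """
    width_n, stride_n = _window_geometry(rec, spec)
    n = rec.n_samples
    if n < width_n:
        warnings.warn(
            "recording shorter than one analysis window; no windows emitted",
            stacklevel=2,
        )
        return []

    # per-sample segment ownership (-1 = unlabeled)
    owner = np.full(n, -1, dtype=int)
    for k, seg in enumerate(labels):
        i0 = int(np.ceil(seg.start_s * rec.sample_rate - 1e-9))
        i1 = int(np.ceil(seg.end_s * rec.sample_rate - 1e-9))
        owner[i0 : min(i1, n)] = k

    segments = list(labels)
    out: list[Window] = []
    n_windows = (n - width_n) // stride_n + 1
    for w in range(n_windows):
        a = w * stride_n
        b = a + width_n
        counts = np.bincount(owner[a:b][owner[a:b] >= 0], minlength=len(segments))
        if counts.sum() == 0:
            continue
        k = int(np.argmax(counts))  # first max -> earlier segment on ties
        seg = segments[k]
        out.append(
            Window(
                start_s=a / rec.sample_rate,
                start_idx=a,
                stop_idx=b,
                label=seg.label,
                segment_id=seg.segment_id,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------


def extract_features(window: np.ndarray) -> np.ndarray:
    """Five statistics per channel for one window (samples x channels).

    Returns a vector of length ``5 * n_channels`` ordered channel-major:
    (mean, sd, min, max, rms) per channel.  sd and rms use population
    normalization (divide by n); rms = sqrt(mean(x^2)).
    """
    window = np.asarray(window, dtype=float)
    if window.ndim == 1:
        window = window[:, None]
    if window.size == 0:
        raise InvalidArgumentError("window must be non-empty")
    if not np.isfinite(window).all():
        raise InvalidArgumentError("window contains non-finite samples")
    return _stack_stats(window).ravel()


def _stack_stats(block: np.ndarray) -> np.ndarray:
    """(..., samples, channels) -> (..., channels, 5) statistics array."""
    mean = block.mean(axis=-2)
    sd = block.std(axis=-2)
    mn = block.min(axis=-2)
    mx = block.max(axis=-2)
    rms = np.sqrt(np.mean(block**2, axis=-2))
    return np.stack([mean, sd, mn, mx, rms], axis=-1)


def feature_names(channels) -> list[str]:
    """Deterministic feature-column names for an ordered channel list."""
    return [
        f"{core.channel_name(*ch)}.{stat}"
        for ch in channels
        for stat in FEATURE_STATS
    ]


def featurize_recording(
    rec: Recording,
    labels: SegmentLabels,
    spec: WindowSpec = WindowSpec(),
    *,
    normalize: bool = True,
    stats: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Normalize (optional), window, and featurize one labeled recording."""
    if normalize:
        rec, _ = zscore_normalize(rec, stats)
    windows = segment_windows(rec, labels, spec)
    cols = feature_names(rec.channels)
    if not windows:
        meta = pd.DataFrame(columns=list(METADATA_COLUMNS))
        return pd.concat([meta, pd.DataFrame(columns=cols)], axis=1)

    if not np.isfinite(rec.values).all():
        raise InvalidArgumentError("recording contains non-finite samples")

    width_n, stride_n = _window_geometry(rec, spec)
    # (n_windows_full, channels, width) view; stride over window starts
    view = sliding_window_view(rec.values, width_n, axis=0)
    starts = np.array([w.start_idx for w in windows])
    block = view[starts].transpose(0, 2, 1)  # (n_windows, width, channels)
    feats = _stack_stats(block).reshape(len(windows), -1)

    df = pd.DataFrame(feats, columns=cols)
    df.insert(0, "window_start_s", [w.start_s for w in windows])
    df.insert(0, "window_label", [w.label for w in windows])
    df.insert(0, "segment_id", [w.segment_id for w in windows])
    df.insert(0, "subject_id", rec.subject_id)
    return df


def featurize_cohort(
    cohort,
    spec: WindowSpec = WindowSpec(),
    *,
    normalize: bool = True,
) -> pd.DataFrame:
    """Featurize a list of ``(Recording, SegmentLabels)`` pairs into one table."""
    frames = [
        featurize_recording(rec, labels, spec, normalize=normalize)
        for rec, labels in cohort
    ]
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Channel selection and table utilities
# ---------------------------------------------------------------------------


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in METADATA_COLUMNS]


def table_sites(table: pd.DataFrame) -> tuple[str, ...]:
    """Sites present in a feature table, canonical order."""
    sites = {c.split(".", 1)[0] for c in feature_columns(table)}
    return core.canonical_site_order(sites)


def select_channels(table: pd.DataFrame, config: SensorConfig) -> pd.DataFrame:
    """Restrict a feature table to ``config.sites`` under ``config.sensor_type``.

    Metadata columns are untouched; feature-column order is preserved, so
    the operation is idempotent and the accelerometer output is always a
    column subset of the IMU output for the same sites.
    """
    available = set(table_sites(table))
    unknown = [s for s in config.sites if s not in available]
    if unknown:
        raise InvalidArgumentError(
            f"unknown site(s) {unknown}; valid sites: "
            f"{list(core.canonical_site_order(available))}"
        )
    mods = set(core.sensor_modalities(config.sensor_type))
    keep = []
    for c in feature_columns(table):
        site, modality = c.split(".")[:2]
        if site in config.sites and modality in mods:
            keep.append(c)
    meta = [c for c in METADATA_COLUMNS if c in table.columns]
    return table[meta + keep].copy()


def feature_matrix(
    table: pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Split a feature table into (X, y, metadata)."""
    cols = feature_columns(table)
    X = table[cols].to_numpy(dtype=float)
    y = table["window_label"].to_numpy()
    meta = table[[c for c in METADATA_COLUMNS if c in table.columns]]
    return X, y, meta
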