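"""Readers and writers for recordings, segment labels, feature tables, and
the run configuration.

All tabular artifacts are plain CSV with a leading versioned schema comment
(``# motionprims-<kind> v<major>``); readers reject unknown major versions.
Recording files are wide CSV: column 0 is ``time_s``, remaining columns are
named ``<site>.<modality>.<axis>``.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import core
from .errors import ConfigError, InvalidArgumentError, ParseError
from .synth import Recording, Segment, SegmentLabels

__all__ = [
    "read_recording",
    "write_recording",
    "read_segments",
    "write_segments",
    "read_feature_table",
    "write_feature_table",
    "RunConfig",
    "load_config",
]

_SCHEMAS = {
    "recording": 1,
    "segments": 1,
    "features": 1,
}


def _schema_line(kind: str) -> str:
    return f"# motionprims-{kind} v{_SCHEMAS[kind]}"


def _check_schema(path, first_line: str, kind: str) -> None:
    prefix = f"# motionprims-{kind} v"
    if not first_line.startswith(prefix):
        raise ParseError(
            f"missing or wrong schema header; expected '{prefix}<major>'",
            path=path,
            line=1,
        )
    try:
        major = int(first_line[len(prefix):].strip().split(".")[0])
    except ValueError:
        raise ParseError("unparseable schema version", path=path, line=1) from None
    if major != _SCHEMAS[kind]:
        raise ParseError(
            f"unsupported {kind} schema major version {major} "
            f"(supported: {_SCHEMAS[kind]})",
            path=path,
            line=1,
        )


def _read_header(path) -> tuple[dict, int]:
    """Read leading '#' comment lines as key: value metadata; returns the
    metadata dict and the number of comment lines."""
    meta: dict[str, str] = {}
    n = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n += 1
            body = line[1:].strip()
            if n == 1:
                meta["_schema"] = body
            elif ":" in body:
                key, value = body.split(":", 1)
                meta[key.strip()] = value.strip()
    if n == 0:
        raise ParseError("file has no schema header", path=path, line=1)
    return meta, n


# ---------------------------------------------------------------------------
# Recordings
# ---------------------------------------------------------------------------


def write_recording(rec: Recording, path) -> None:
    path = Path(path)
    df = rec.to_frame()
    with open(path, "w", newline="") as fh:
        fh.write(_schema_line("recording") + "\n")
        fh.write(f"# subject_id: {rec.subject_id}\n")
        fh.write(f"# sample_rate_hz: {rec.sample_rate:.10g}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def read_recording(path) -> Recording:
    """Read a recording CSV written by :func:`write_recording`.

    Raises :class:`ParseError` (with a line number) on a malformed header,
    a non-monotonic time column, or ragged rows.
    """
    path = Path(path)
    meta, n_comments = _read_header(path)
    _check_schema(path, "# " + meta["_schema"], "recording")
    if "subject_id" not in meta or "sample_rate_hz" not in meta:
        raise ParseError(
            "header must carry 'subject_id' and 'sample_rate_hz'",
            path=path,
            line=n_comments,
        )
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.ParserError as exc:
        line = _parser_error_line(exc)
        raise ParseError(f"malformed CSV body: {exc}", path=path, line=line) from exc
    if df.columns[0] != "time_s":
        raise ParseError(
            f"first column must be 'time_s', got {df.columns[0]!r}",
            path=path,
            line=n_comments + 1,
        )
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) > 1:
        bad = np.flatnonzero(np.diff(t) <= 0)
        if len(bad):
            raise ParseError(
                "time_s is not strictly increasing",
                path=path,
                line=n_comments + 1 + int(bad[0]) + 2,
            )
    channel_cols = list(df.columns[1:])
    channels = []
    for name in channel_cols:
        try:
            channels.append(core.split_channel_name(name))
        except InvalidArgumentError as exc:
            raise ParseError(str(exc), path=path, line=n_comments + 1) from exc
    values = df[channel_cols].to_numpy(dtype=float)
    return Recording(
        sample_rate=float(meta["sample_rate_hz"]),
        channels=channels,
        values=values,
        subject_id=meta["subject_id"],
    )


def _parser_error_line(exc) -> int | None:
    import re

    m = re.search(r"line (\d+)", str(exc))
    return int(m.group(1)) if m else None


# ---------------------------------------------------------------------------
# Segment labels
# ---------------------------------------------------------------------------


def write_segments(labels: SegmentLabels, path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(_schema_line("segments") + "\n")
        labels.to_frame().to_csv(fh, index=False, float_format="%.10g")


def read_segments(path) -> SegmentLabels:
    path = Path(path)
    meta, _ = _read_header(path)
    _check_schema(path, "# " + meta["_schema"], "segments")
    df = pd.read_csv(path, comment="#")
    required = {"segment_id", "start_s", "end_s", "label"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"segments file must have columns {sorted(required)}", path=path, line=2
        )
    segs = [
        Segment(
            start_s=float(r.start_s),
            end_s=float(r.end_s),
            label=str(r.label),
            segment_id=int(r.segment_id),
        )
        for r in df.itertuples()
    ]
    return SegmentLabels(segs)


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------


def write_feature_table(table: pd.DataFrame, path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(_schema_line("features") + "\n")
        table.to_csv(fh, index=False, float_format="%.10g")


def read_feature_table(path) -> pd.DataFrame:
    path = Path(path)
    meta, _ = _read_header(path)
    _check_schema(path, "# " + meta["_schema"], "features")
    df = pd.read_csv(path, comment="#")
    missing = [c for c in core.METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(
            f"feature table lacks metadata columns {missing}", path=path, line=2
        )
    return df


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_GENERATOR_KEYS = {
    "n_subjects",
    "sample_rate_hz",
    "n_trials",
    "n_targets",
    "target_distance_cm",
    "objects",
    "primitive_sequence_per_move",
    "noise_sd",
    "class_separation",
    "active_side",
    "movement_speed_scale",
    "duration_mean_s",
    "duration_cv",
    "offset_scale",
}
_WINDOW_KEYS = {"width_s", "stride_s"}
_SPLIT_KEYS = {"scheme", "train_fraction", "n_repeats"}
_SEARCH_KEYS = {"classifier", "sensor_type", "n_repeats", "train_fraction", "sites"}
_TOP_KEYS = {
    "seed",
    "generator",
    "window",
    "algorithms",
    "hyperparams",
    "split",
    "search",
    "output_dir",
    "log_level",
}


@dataclass
class RunConfig:
    """Resolved run configuration; every seed is explicit."""

    seed: int
    generator: dict = dc_field(default_factory=dict)
    window: dict = dc_field(default_factory=dict)
    algorithms: list[str] = dc_field(default_factory=lambda: ["lda", "nbc", "svm", "knn"])
    hyperparams: dict = dc_field(default_factory=dict)
    split: dict = dc_field(default_factory=dict)
    search: dict = dc_field(default_factory=dict)
    output_dir: str = "out"
    log_level: str = "INFO"

    def resolved(self) -> dict:
        return {
            "seed": self.seed,
            "generator": self.generator,
            "window": self.window,
            "algorithms": self.algorithms,
            "hyperparams": self.hyperparams,
            "split": self.split,
            "search": self.search,
            "output_dir": self.output_dir,
            "log_level": self.log_level,
        }


def _reject_unknown(mapping: dict, allowed: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in {where}; allowed: {sorted(allowed)}"
        )


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    A missing ``seed`` is an error (seeds are never defaulted silently);
    unknown keys are rejected at every level.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _reject_unknown(raw, _TOP_KEYS, "config root")
    if "seed" not in raw:
        raise ConfigError("config must set an explicit 'seed'")
    _reject_unknown(raw.get("generator") or {}, _GENERATOR_KEYS, "generator")
    _reject_unknown(raw.get("window") or {}, _WINDOW_KEYS, "window")
    _reject_unknown(raw.get("split") or {}, _SPLIT_KEYS, "split")
    _reject_unknown(raw.get("search") or {}, _SEARCH_KEYS, "search")
    algorithms = raw.get("algorithms") or ["lda", "nbc", "svm", "knn"]
    from .classifiers import ALGORITHMS

    bad = [a for a in algorithms if a not in ALGORITHMS]
    if bad:
        raise ConfigError(f"unknown algorithm(s) {bad}; valid: {list(ALGORITHMS)}")
    return RunConfig(
        seed=int(raw["seed"]),
        generator=dict(raw.get("generator") or {}),
        window=dict(raw.get("window") or {}),
        algorithms=list(algorithms),
        hyperparams=dict(raw.get("hyperparams") or {}),
        split=dict(raw.get("split") or {}),
        search=dict(raw.get("search") or {}),
        output_dir=str(raw.get("output_dir", "out")),
        log_level=str(raw.get("log_level", "INFO")),
    )
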