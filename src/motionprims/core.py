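"""Shared vocabulary of the domain: primitive classes, body sites, channel
layout, feature statistics, and deterministic seed derivation.

A full inertial measurement unit (IMU) at one body site contributes ten
channels: three linear accelerations, three angular velocities, and a
four-component orientation quaternion.  An accelerometer-only sensor
contributes the three acceleration channels.
"""

from __future__ import annotations

import hashlib

import numpy as np

from .errors import InvalidArgumentError

#: Canonical order of the four functional primitive classes.
CLASSES: tuple[str, ...] = ("reach", "transport", "reposition", "idle")

#: The eleven instrumented body sites, in canonical (site-major) order.
SITES: tuple[str, ...] = (
    "head",
    "sternum",
    "pelvis",
    "l_scapula",
    "r_scapula",
    "l_arm",
    "r_arm",
    "l_forearm",
    "r_forearm",
    "l_hand",
    "r_hand",
)

MODALITY_AXES: dict[str, tuple[str, ...]] = {
    "acc": ("x", "y", "z"),
    "gyr": ("x", "y", "z"),
    "quat": ("w", "x", "y", "z"),
}
MODALITIES: tuple[str, ...] = ("acc", "gyr", "quat")
SENSOR_TYPES: tuple[str, ...] = ("imu", "accelerometer")

#: Per-channel statistics computed on every analysis window.
FEATURE_STATS: tuple[str, ...] = ("mean", "sd", "min", "max", "rms")

#: Leading non-feature columns of every feature table.
METADATA_COLUMNS: tuple[str, ...] = (
    "subject_id",
    "segment_id",
    "window_label",
    "window_start_s",
)

#: Channels contributed by one full IMU (3 acc + 3 gyr + 4 quat).
CHANNELS_PER_IMU = 10
#: Channels contributed by an accelerometer-only sensor.
CHANNELS_PER_ACCELEROMETER = 3


def sensor_modalities(sensor_type: str) -> tuple[str, ...]:
    """Modalities retained for a sensor type (``imu`` or ``accelerometer``)."""
    if sensor_type == "imu":
        return MODALITIES
    if sensor_type == "accelerometer":
        return ("acc",)
    raise InvalidArgumentError(
        f"unknown sensor_type {sensor_type!r}; expected one of {SENSOR_TYPES}"
    )


def iter_channels(
    sites=SITES, sensor_type: str = "imu"
) -> list[tuple[str, str, str]]:
    """Ordered ``(site, modality, axis)`` triples, site-major."""
    mods = sensor_modalities(sensor_type)
    return [
        (site, mod, axis)
        for site in sites
        for mod in mods
        for axis in MODALITY_AXES[mod]
    ]


def channel_name(site: str, modality: str, axis: str) -> str:
    return f"{site}.{modality}.{axis}"


def split_channel_name(name: str) -> tuple[str, str, str]:
    """Parse ``site.modality.axis`` into its parts.

    Raises :class:`InvalidArgumentError` on malformed names.
    """
    parts = name.split(".")
    if len(parts) != 3:
        raise InvalidArgumentError(
            f"channel name {name!r} is not of the form site.modality.axis"
        )
    site, modality, axis = parts
    if modality not in MODALITY_AXES:
        raise InvalidArgumentError(
            f"unknown modality {modality!r} in channel {name!r}"
        )
    if axis not in MODALITY_AXES[modality]:
        raise InvalidArgumentError(
            f"axis {axis!r} invalid for modality {modality!r} in channel {name!r}"
        )
    return site, modality, axis


def canonical_site_order(sites) -> tuple[str, ...]:
    """Sort sites into the canonical anatomical order (unknown sites last,
    alphabetically)."""
    index = {s: i for i, s in enumerate(SITES)}
    return tuple(sorted(sites, key=lambda s: (index.get(s, len(SITES)), s)))


def stable_int(text: str) -> int:
    """Stable 31-bit integer derived from a string (run-independent, unlike
    the builtin ``hash``)."""
    digest = hashlib.sha256(text.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministically derive a per-stage seed (< 2**31) from a global seed.

    Every pipeline stage gets an independent, reproducible stream so stages
    can be re-run in isolation.
    """
    ss = np.random.SeedSequence([int(global_seed), stable_int(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


def rng_for(seed: int, *key: int) -> np.random.Generator:
    """Generator seeded from ``seed`` plus an optional integer key path."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))
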