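"""Synthetic labeled inertial recordings of a structured tabletop task.

The generator emulates the study conditions under which upper-extremity
functional primitives (reach, transport, reposition, idle) are recorded
with body-worn IMUs: a subject repeatedly moves an object between a center
target and radially arrayed targets, wearing 11 sensors (head, sternum,
pelvis, and bilateral hand / forearm / upper arm / scapula), each streaming
3D linear acceleration, 3D angular velocity, and a unit quaternion.

Kinematic model
---------------
* Moving primitives carry a minimum-jerk linear-acceleration burst on the
  active-side arm chain (strongest distally) and, attenuated, on the trunk
  and head.  The burst's direction sign separates reach/reposition (+) from
  transport (-).
* Reach additionally carries a forearm angular-velocity "grasp rotation"
  burst (pronation/supination to grasp) that is absent in reposition —
  so reach and reposition are separable only through gyroscope/quaternion
  channels, never through acceleration alone.
* Idle carries no class-specific kinematics.
* A latent postural-sway component (smoothed Gaussian noise) is shared by
  the trunk, head, and active-arm sites, inducing strong cross-channel
  correlation; the resting arm drifts with its own independent latent, and
  every site additionally carries a small independent "fidget" sway.
* Quaternions are obtained by integrating each site's volitional angular
  velocity from the identity orientation (renormalized each step), matching
  the drift-corrected orientation output of commercial sensor-fusion IMUs;
  sensor noise is added after integration.
* Independent Gaussian sensor noise (``SubjectParams.noise_sd``) is added to
  every channel.

``class_separation`` scales every class-specific kinematic term; at 0 the
four class-conditional signal distributions coincide exactly, providing a
null calibration in which any classifier's expected accuracy is chance.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from . import core
from .core import CLASSES, SITES
from .errors import InvalidArgumentError

__all__ = [
    "TaskProtocol",
    "SubjectParams",
    "Recording",
    "Segment",
    "SegmentLabels",
    "ClassMoments",
    "DEFAULT_CLASS_COUNTS",
    "default_class_proportions",
    "default_protocol",
    "desk_protocol",
    "default_subjects",
    "simulate_recording",
    "simulate_cohort",
    "simulate_feature_population",
]

#: Published composition of the motivating dataset: number of primitives per
#: class across all six subjects.
DEFAULT_CLASS_COUNTS: dict[str, int] = {
    "reach": 810,
    "transport": 708,
    "reposition": 781,
    "idle": 582,
}


def default_class_proportions() -> np.ndarray:
    """Class proportions (reach, transport, reposition, idle), summing to 1."""
    counts = np.array([DEFAULT_CLASS_COUNTS[c] for c in CLASSES], dtype=float)
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# Protocol and subject descriptions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TaskProtocol:
    """Structured tabletop protocol: trials x radial targets x objects.

    Each center<->target move produces ``primitive_sequence_per_move``
    (default idle -> reach -> transport -> reposition).
    """

    n_trials: int = 5
    n_targets: int = 8
    target_distance_cm: float = 20.0
    objects: tuple[str, ...] = ("paper_roll", "aluminum_can")
    primitive_sequence_per_move: tuple[str, ...] = (
        "idle",
        "reach",
        "transport",
        "reposition",
    )

    def __post_init__(self):
        if self.n_trials < 1:
            raise InvalidArgumentError("n_trials must be >= 1")
        if self.n_targets < 1:
            raise InvalidArgumentError("n_targets must be >= 1")
        if self.target_distance_cm <= 0:
            raise InvalidArgumentError("target_distance_cm must be > 0")
        if len(self.objects) < 1:
            raise InvalidArgumentError("protocol needs at least one object")
        if len(self.primitive_sequence_per_move) < 1:
            raise InvalidArgumentError("primitive_sequence_per_move is empty")
        bad = set(self.primitive_sequence_per_move) - set(CLASSES)
        if bad:
            raise InvalidArgumentError(
                f"unknown primitive classes {sorted(bad)}; valid: {CLASSES}"
            )

    @property
    def n_moves(self) -> int:
        return self.n_trials * self.n_targets * len(self.objects)

    @property
    def n_segments(self) -> int:
        return self.n_moves * len(self.primitive_sequence_per_move)


def default_protocol() -> TaskProtocol:
    """Full-fidelity protocol: 5 trials x 8 targets x 2 objects."""
    return TaskProtocol()


def desk_protocol(n_trials: int = 2, n_targets: int = 3) -> TaskProtocol:
    """Reduced protocol for fast desk-scale experiments (pairs with the
    60 Hz generator mode); 2 x 3 x 2 objects -> 48 primitives per subject."""
    return TaskProtocol(n_trials=n_trials, n_targets=n_targets)


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject generation parameters.

    ``offset_scale`` controls a deterministic, subject-specific kinematic
    idiosyncrasy (amplitude and direction perturbations derived from a hash
    of ``subject_id``); set it to 0 to make subjects exchangeable.
    """

    subject_id: str
    movement_speed_scale: float = 1.0
    noise_sd: float = 0.2
    duration_mean_s: float = 1.0
    duration_cv: float = 0.25
    active_side: str = "right"
    offset_scale: float = 0.3

    def __post_init__(self):
        if self.movement_speed_scale <= 0:
            raise InvalidArgumentError("movement_speed_scale must be > 0")
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be >= 0")
        if self.duration_mean_s <= 0:
            raise InvalidArgumentError("duration_mean_s must be > 0")
        if self.duration_cv < 0:
            raise InvalidArgumentError("duration_cv must be >= 0")
        if self.active_side not in ("left", "right"):
            raise InvalidArgumentError("active_side must be 'left' or 'right'")
        if self.offset_scale < 0:
            raise InvalidArgumentError("offset_scale must be >= 0")


def default_subjects(n_subjects: int = 6, **overrides) -> list[SubjectParams]:
    """The default virtual cohort: ``n_subjects`` right-active subjects."""
    if n_subjects < 1:
        raise InvalidArgumentError("n_subjects must be >= 1")
    return [
        SubjectParams(subject_id=f"s{i + 1:02d}", **overrides)
        for i in range(n_subjects)
    ]


# ---------------------------------------------------------------------------
# Recordings and labels
# ---------------------------------------------------------------------------


@dataclass
class Recording:
    """A multi-channel inertial time series.

    ``values`` is a (samples x channels) float array; ``channels`` is the
    ordered list of ``(site, modality, axis)`` triples naming each column.
    """

    sample_rate: float
    channels: list[tuple[str, str, str]]
    values: np.ndarray
    subject_id: str

    def __post_init__(self):
        if self.sample_rate <= 0:
            raise InvalidArgumentError("sample_rate must be > 0")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.channels):
            raise InvalidArgumentError(
                "values must be (n_samples, n_channels) matching `channels`"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def channel_names(self) -> list[str]:
        return [core.channel_name(*c) for c in self.channels]

    @property
    def sites(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for site, _, _ in self.channels:
            seen.setdefault(site, None)
        return tuple(seen)

    def to_frame(self) -> pd.DataFrame:
        t = np.arange(self.n_samples) / self.sample_rate
        df = pd.DataFrame(self.values, columns=self.channel_names)
        df.insert(0, "time_s", t)
        return df


@dataclass(frozen=True)
class Segment:
    start_s: float
    end_s: float
    label: str
    segment_id: int


@dataclass
class SegmentLabels:
    """Ordered, non-overlapping ground-truth primitive intervals."""

    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self):
        prev_end = -np.inf
        for seg in self.segments:
            if seg.end_s <= seg.start_s:
                raise InvalidArgumentError(
                    f"segment {seg.segment_id}: end_s must exceed start_s"
                )
            if seg.start_s < prev_end - 1e-12:
                raise InvalidArgumentError(
                    f"segment {seg.segment_id} overlaps its predecessor"
                )
            if seg.label not in CLASSES:
                raise InvalidArgumentError(
                    f"segment {seg.segment_id}: unknown class {seg.label!r}"
                )
            prev_end = seg.end_s

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.segments]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "segment_id": [s.segment_id for s in self.segments],
                "start_s": [s.start_s for s in self.segments],
                "end_s": [s.end_s for s in self.segments],
                "label": [s.label for s in self.segments],
            }
        )


# ---------------------------------------------------------------------------
# Kinematic building blocks
# ---------------------------------------------------------------------------

# Class-signal site weights for the *active* arm chain, trunk, and head
# (the trunk and head lean with the move; weights decay proximally).
# Inactive-side limb sites carry no class signal; together with the trunk
# and head this makes exactly seven informative sites.
_ACTIVE_CHAIN_WEIGHTS = {"hand": 1.0, "forearm": 0.9, "arm": 0.8, "scapula": 0.7}
_TRUNK_WEIGHTS = {"sternum": 0.7, "pelvis": 0.7, "head": 0.6}

#: Acceleration-burst sign per class: reach/reposition vs transport.
_CLASS_SIGN = {"reach": 1.0, "reposition": 1.0, "transport": -1.0, "idle": 0.0}

#: Peak grasp-rotation angular velocity (rad/s) on the active forearm in reach.
_GRASP_GYR_AMP = 2.0
#: Peak movement-accompanying arm rotation (rad/s) on the active arm chain.
_ARM_GYR_AMP = 1.5
#: Peak-acceleration factor: a minimum-jerk move covering the target
#: distance within the central part of a segment of duration T has peak
#: acceleration ~ _BURST_PEAK_FACTOR * distance / T^2.
_BURST_PEAK_FACTOR = 16.0
#: Lognormal sigma of the per-site, per-segment execution-gain jitter: each
#: body site realizes the movement with independent amplitude variability,
#: so every informative site carries non-redundant class evidence.
_SITE_GAIN_SIGMA = 0.0
#: Standard deviation (per axis) of the shared latent trunk-sway component
#: (common to all sites; induces the cross-channel correlation that a
#: feature-independence assumption cannot absorb).
_LATENT_ACC_SD = 0.8
#: Standard deviation of the site-specific independent "fidget" sway
#: (irreducible local motion that no other site can act as a reference for).
_FIDGET_ACC_SD = 0.2
#: Scale of latent/fidget components on angular-velocity channels.
_LATENT_GYR_SCALE = 0.3
#: Smoothing time constant (s) of latent/fidget components.
_LATENT_SMOOTH_S = 0.2


def _class_signal_weights(active_side: str) -> dict[str, float]:
    side = "r" if active_side == "right" else "l"
    weights = {f"{side}_{part}": w for part, w in _ACTIVE_CHAIN_WEIGHTS.items()}
    weights.update(_TRUNK_WEIGHTS)
    return weights


def _make_site_rotations() -> dict[str, np.ndarray]:
    """Fixed per-site rotations of the movement signature: each body segment
    realizes the move along its own characteristic direction (the head
    pitches, the pelvis rolls, the hand translates), so each site carries a
    distinct projection of the class signal.

    Deterministic (hash-seeded per site name, in canonical site order) with
    signature directions kept >= 30 degrees apart so no two sites are
    kinematically redundant.
    """
    from scipy.spatial.transform import Rotation

    ez = np.array([0.0, 0.0, 1.0])
    rotations: dict[str, np.ndarray] = {}
    taken: list[np.ndarray] = []
    for site in SITES:
        h = int.from_bytes(
            hashlib.sha256(("site:" + site).encode("utf-8")).digest()[:8], "big"
        ) % (2**31)
        rng = np.random.default_rng(h)
        for _ in range(200):
            rot = Rotation.from_rotvec(0.8 * rng.normal(size=3)).as_matrix()
            direction = rot @ ez
            if all(
                np.degrees(np.arccos(np.clip(direction @ d, -1, 1))) >= 30.0
                for d in taken
            ):
                break
        rotations[site] = rot
        taken.append(rot @ ez)
    return rotations


_SITE_ROTATIONS = _make_site_rotations()

def _make_site_styles() -> dict[str, tuple[np.ndarray, dict[str, float]]]:
    """Fixed per-site rotation styles: every body segment rotates about its
    own characteristic axis with a class-specific amplitude during a move
    (the head orients toward the target in reach, the pelvis counter-rotates
    in transport, ...).  This gives each signal-carrying site class evidence
    through its own gyroscope channels that no other site duplicates.
    Deterministic per site name; idle has no style."""
    styles: dict[str, tuple[np.ndarray, dict[str, float]]] = {}
    for site in SITES:
        h = int.from_bytes(
            hashlib.sha256(("style:" + site).encode("utf-8")).digest()[:8], "big"
        ) % (2**31)
        rng = np.random.default_rng(h)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        # normalize the class contrast so every site's style is equally
        # strong (no site is weakly informative by hash luck)
        raw = rng.normal(size=3)
        raw = raw - raw.mean()
        raw = raw / max(raw.std(), 1e-9)
        amps = dict(zip(("reach", "transport", "reposition"), map(float, raw)))
        amps["idle"] = 0.0
        styles[site] = (axis, amps)
    return styles


_SITE_STYLES = _make_site_styles()


def informative_sites(active_side: str = "right") -> tuple[str, ...]:
    """The sites that carry class-discriminative signal at default settings
    (trunk + head + the active arm chain: seven sites)."""
    return core.canonical_site_order(_class_signal_weights(active_side))


def _min_jerk_bell(tau: np.ndarray) -> np.ndarray:
    """Bell-shaped minimum-jerk speed profile on normalized time tau in
    [0, 1], normalized to unit peak (peak at tau = 0.5).

    The single-signed bell (rather than the biphasic acceleration trace) is
    used as the burst envelope so that the class-coding direction sign is
    present in every analysis window of a moving primitive.
    """
    return 16.0 * tau**2 * (1.0 - tau) ** 2


def _subject_idiosyncrasy(
    subject: SubjectParams,
) -> tuple[float, np.ndarray, float, float]:
    """Deterministic per-subject idiosyncrasy derived from the subject id:
    (movement amplitude multiplier, 3D posture rotation matrix applied to
    movement directions and rotation axes, grasp-rotation multiplier,
    postural-sway multiplier).  All effects scale with ``offset_scale``."""
    from scipy.spatial.transform import Rotation

    h = int.from_bytes(
        hashlib.sha256(subject.subject_id.encode("utf-8")).digest()[:8], "big"
    ) % (2**31)
    rng = np.random.default_rng(h)
    s = subject.offset_scale
    amp = float(np.exp(1.0 * s * rng.normal()))
    rotation = Rotation.from_rotvec(2.2 * s * rng.normal(size=3)).as_matrix()
    gyr = float(np.exp(1.0 * s * rng.normal()))
    sway = float(np.exp(1.0 * s * rng.normal()))
    return amp, rotation, gyr, sway


def _smoothed_noise(rng: np.random.Generator, n: int, k: int, sigma: float,
                    sd: float) -> np.ndarray:
    """k columns of unit-sd smoothed Gaussian noise scaled to ``sd``."""
    raw = rng.normal(size=(n, k))
    sm = gaussian_filter1d(raw, sigma=max(sigma, 1e-9), axis=0, mode="wrap")
    std = sm.std(axis=0)
    std[std < 1e-12] = 1.0
    return sm / std * sd


def _integrate_quaternions(omega: np.ndarray, dt: float) -> np.ndarray:
    """Integrate per-site angular velocity (n, S, 3) from identity, returning
    unit quaternions (n, S, 4) in (w, x, y, z) order.

    Exact for piecewise-constant angular velocity over each sample interval.
    """
    n, n_sites, _ = omega.shape
    half = 0.5 * dt * omega
    theta = np.linalg.norm(half, axis=2)  # (n, S)
    sinc = np.where(theta > 1e-12, np.sin(theta) / np.where(theta > 0, theta, 1.0), 1.0)
    dq = np.empty((n, n_sites, 4))
    dq[..., 0] = np.cos(theta)
    dq[..., 1:] = half * sinc[..., None]

    out = np.empty((n, n_sites, 4))
    cur = np.zeros((n_sites, 4))
    cur[:, 0] = 1.0
    for t in range(n):
        out[t] = cur
        if t == n - 1:
            break
        w1, x1, y1, z1 = cur[:, 0], cur[:, 1], cur[:, 2], cur[:, 3]
        w2, x2, y2, z2 = dq[t, :, 0], dq[t, :, 1], dq[t, :, 2], dq[t, :, 3]
        nxt = np.stack(
            [
                w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
                w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
                w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
                w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
            ],
            axis=1,
        )
        nxt /= np.linalg.norm(nxt, axis=1, keepdims=True)
        cur = nxt
    return out


# ---------------------------------------------------------------------------
# Recording simulation
# ---------------------------------------------------------------------------


def simulate_recording(
    protocol: TaskProtocol,
    subject: SubjectParams,
    seed: int,
    *,
    sample_rate: float = 240.0,
    class_separation: float = 1.0,
    site_gain_sigma: float = _SITE_GAIN_SIGMA,
    site_engagement_prob: float = 1.0,
    site_style_amp: float = 0.0,
) -> tuple[Recording, SegmentLabels]:
    """Simulate one subject performing the tabletop protocol.

    Returns a full 11-site IMU :class:`Recording` (110 channels) and the
    ground-truth :class:`SegmentLabels`.  Identical arguments reproduce
    bit-identical output.

    Parameters
    ----------
    sample_rate:
        240 Hz by default; 60 Hz is the documented desk-scale mode (window
        and stride are specified in seconds, so features are rate-robust).
    class_separation:
        Scales all class-specific kinematics; 0 makes the four
        class-conditional signal distributions coincide (null calibration).
    site_gain_sigma:
        Lognormal sigma of per-site, per-segment execution-gain jitter.  At
        0 (default) every informative site realizes the same burst amplitude;
        at larger values each site is an independently unreliable witness of
        the movement, which is the regime in which adding sensors genuinely
        improves classification (used by sensor-redundancy studies).
    site_engagement_prob:
        Probability that a signal-carrying site expresses a given segment's
        movement at all (independent per site and segment).  Below 1 this
        emulates compensatory movement variability — different repetitions
        recruit different body segments — making each additional sensor
        genuinely indispensable for the segments few sites express.
        Default 1 (every informative site expresses every move).
    site_style_amp:
        Peak amplitude (rad/s) of the per-site rotation "style": each body
        segment rotates about its own characteristic axis with a
        class-specific amplitude during a move, giving each site class
        evidence through its own gyroscope channels that no other site
        duplicates.  Default 0 (off); used together with
        ``site_engagement_prob`` in sensor-redundancy studies.
    """
    if sample_rate <= 0:
        raise InvalidArgumentError("sample_rate must be > 0")
    if class_separation < 0:
        raise InvalidArgumentError("class_separation must be >= 0")
    if site_gain_sigma < 0:
        raise InvalidArgumentError("site_gain_sigma must be >= 0")
    if not (0 < site_engagement_prob <= 1):
        raise InvalidArgumentError("site_engagement_prob must be in (0, 1]")
    if site_style_amp < 0:
        raise InvalidArgumentError("site_style_amp must be >= 0")
    if seed is None:
        raise InvalidArgumentError("seed is required")

    rng = np.random.default_rng(int(seed))
    fs = float(sample_rate)
    dt = 1.0 / fs

    # --- schedule of primitive segments -----------------------------------
    plan: list[tuple[str, int]] = []  # (class, target index)
    for _obj in protocol.objects:
        for _trial in range(protocol.n_trials):
            for target in range(protocol.n_targets):
                for prim in protocol.primitive_sequence_per_move:
                    plan.append((prim, target))

    mean = subject.duration_mean_s / subject.movement_speed_scale
    cv = subject.duration_cv
    if cv > 0:
        sigma2 = np.log1p(cv**2)
        mu = np.log(mean) - 0.5 * sigma2
        durations = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=len(plan))
    else:
        durations = np.full(len(plan), mean)
    durations = np.maximum(durations, 4.0 * dt)  # a segment spans >= 4 samples

    bounds = np.concatenate([[0.0], np.cumsum(durations)])
    n = int(round(bounds[-1] * fs))
    segments = [
        Segment(start_s=float(bounds[i]), end_s=float(bounds[i + 1]),
                label=plan[i][0], segment_id=i)
        for i in range(len(plan))
    ]
    labels = SegmentLabels(segments)

    # --- per-site signal components ---------------------------------------
    acc = {site: np.zeros((n, 3)) for site in SITES}
    gyr = {site: np.zeros((n, 3)) for site in SITES}

    amp_mult, posture_rot, gyr_mult, sway_mult = _subject_idiosyncrasy(subject)

    latent_acc = _smoothed_noise(
        rng, n, 3, _LATENT_SMOOTH_S * fs, sway_mult * _LATENT_ACC_SD
    )
    latent_gyr = _smoothed_noise(
        rng, n, 3, _LATENT_SMOOTH_S * fs,
        sway_mult * _LATENT_ACC_SD * _LATENT_GYR_SCALE,
    )
    # The trunk/head/active-arm group shares the postural-sway latent; the
    # resting (inactive) arm hangs loose and drifts with its own independent
    # latent, so its sites carry no information about the active group.
    latent2_acc = _smoothed_noise(
        rng, n, 3, _LATENT_SMOOTH_S * fs, sway_mult * _LATENT_ACC_SD
    )
    latent2_gyr = _smoothed_noise(
        rng, n, 3, _LATENT_SMOOTH_S * fs,
        sway_mult * _LATENT_ACC_SD * _LATENT_GYR_SCALE,
    )
    active_group = set(_class_signal_weights(subject.active_side))
    gyr_sway: dict[str, np.ndarray] = {}
    for site in SITES:
        fidget = _smoothed_noise(
            rng, n, 3, _LATENT_SMOOTH_S * fs, sway_mult * _FIDGET_ACC_SD
        )
        la = latent_acc if site in active_group else latent2_acc
        lg = latent_gyr if site in active_group else latent2_gyr
        gyr_sway[site] = lg + _LATENT_GYR_SCALE * fidget
        acc[site] += la + fidget
        gyr[site] += gyr_sway[site]
    weights = _class_signal_weights(subject.active_side)
    side = "r_" if subject.active_side == "right" else "l_"
    forearm = side + "forearm"
    _arm_chain = {side + "hand", side + "forearm", side + "arm"}
    distance_m = protocol.target_distance_cm / 100.0

    for (prim, target), seg in zip(plan, segments):
        if prim == "idle":
            continue
        i0 = int(round(seg.start_s * fs))
        i1 = min(int(round(seg.end_s * fs)), n)
        if i1 - i0 < 2:
            continue
        tau = (np.arange(i1 - i0) + 0.5) / (i1 - i0)
        duration = seg.end_s - seg.start_s
        # dominant vertical (object lift/lower) component plus a planar
        # component toward the radial target; the constant vertical part is
        # what makes the class-coding sign linearly recoverable across
        # targets.  The whole frame is rotated by the subject's posture.
        theta = 2.0 * np.pi * target / protocol.n_targets
        direction = posture_rot @ np.array(
            [0.5 * np.cos(theta), 0.5 * np.sin(theta), 1.0]
        )
        # peak acceleration of a minimum-jerk move covering the target
        # distance within the central part of the segment
        peak = _BURST_PEAK_FACTOR * distance_m / duration**2
        # movement burst plus a sustained postural (gravity-projection)
        # shift while the arm is off the support, so moving primitives are
        # distinguishable from idle in every window, not just mid-burst
        envelope = _min_jerk_bell(tau) + 0.4 * np.sin(np.pi * tau) ** 0.25
        burst = (
            class_separation * _CLASS_SIGN[prim] * amp_mult * peak * envelope
        )
        wave = burst[:, None] * direction[None, :]
        site_gain = {
            site: rng.lognormal(mean=0.0, sigma=site_gain_sigma)
            if site_gain_sigma > 0
            else 1.0
            for site in weights
        }
        if site_engagement_prob < 1.0:
            for site in weights:
                if rng.random() >= site_engagement_prob:
                    site_gain[site] = 0.0
        for site, w in weights.items():
            acc[site][i0:i1] += (
                w * site_gain[site] * wave @ _SITE_ROTATIONS[site].T
            )
        # arm rotation accompanying any move (shoulder/elbow yaw), also
        # sign-coded; carried by the active-chain gyroscopes only
        arm_rot = (
            class_separation
            * _CLASS_SIGN[prim]
            * amp_mult
            * _ARM_GYR_AMP
            * envelope
        )
        arm_axis = posture_rot @ np.array([0.0, 0.0, 1.0])
        for site, w in weights.items():
            if site in _arm_chain:
                gyr[site][i0:i1] += (
                    w
                    * site_gain[site]
                    * arm_rot[:, None]
                    * (_SITE_ROTATIONS[site] @ arm_axis)[None, :]
                )
            # site-specific rotation style: class evidence exclusive to this
            # site's gyroscope channels
            style_axis, style_amps = _SITE_STYLES[site]
            style = (
                class_separation
                * w
                * site_gain[site]
                * site_style_amp
                * style_amps[prim]
            )
            if style != 0.0:
                gyr[site][i0:i1] += (
                    style * envelope[:, None] * (posture_rot @ style_axis)[None, :]
                )
        if prim == "reach":
            grasp = (
                class_separation
                * gyr_mult
                * _GRASP_GYR_AMP
                * np.sin(np.pi * tau) ** 0.5
            )
            # grasp (pronation/supination) axis in the subject's frame
            grasp_axis = posture_rot @ np.array([1.0, 0.0, 0.0])
            gyr[forearm][i0:i1] += (
                site_gain[forearm] * grasp[:, None] * grasp_axis[None, :]
            )

    # --- quaternions from volitional angular velocity, then assembly -------
    # Orientation integrates the volitional (class-driven) rotation only:
    # commercial IMUs emit drift-corrected sensor-fusion orientation, so the
    # slow postural sway must not accumulate into an orientation random walk
    # (which would encode elapsed time rather than motion content).
    omega = np.stack(
        [gyr[site] - gyr_sway[site] for site in SITES], axis=1
    )  # (n, S, 3)
    quat = _integrate_quaternions(omega, dt)  # (n, S, 4)

    channels = core.iter_channels(SITES, "imu")
    values = np.empty((n, len(channels)))
    col = 0
    for si, site in enumerate(SITES):
        values[:, col : col + 3] = acc[site]
        values[:, col + 3 : col + 6] = gyr[site]
        values[:, col + 6 : col + 10] = quat[:, si, :]
        col += 10

    if subject.noise_sd > 0:
        values = values + rng.normal(0.0, subject.noise_sd, size=values.shape)

    rec = Recording(
        sample_rate=fs,
        channels=channels,
        values=values,
        subject_id=subject.subject_id,
    )
    return rec, labels


def simulate_cohort(
    protocol: TaskProtocol,
    subjects: list[SubjectParams],
    seed: int,
    *,
    sample_rate: float = 240.0,
    class_separation: float = 1.0,
    site_gain_sigma: float = _SITE_GAIN_SIGMA,
    site_engagement_prob: float = 1.0,
    site_style_amp: float = 0.0,
) -> list[tuple[Recording, SegmentLabels]]:
    """Simulate one recording per subject, with per-subject seeds derived
    deterministically from ``seed``."""
    out = []
    for i, subject in enumerate(subjects):
        sub_seed = int(
            np.random.SeedSequence([int(seed), i]).generate_state(1)[0] % (2**31)
        )
        out.append(
            simulate_recording(
                protocol,
                subject,
                sub_seed,
                sample_rate=sample_rate,
                class_separation=class_separation,
                site_gain_sigma=site_gain_sigma,
                site_engagement_prob=site_engagement_prob,
                site_style_amp=site_style_amp,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Moment-matched feature populations (for scaling studies)
# ---------------------------------------------------------------------------


@dataclass
class ClassMoments:
    """Per-class feature means/variances plus class proportions; the
    sufficient description for generating a moment-matched population."""

    classes: tuple[str, ...]
    feature_names: list[str]
    means: np.ndarray  # (n_classes, n_features)
    variances: np.ndarray  # (n_classes, n_features)
    proportions: np.ndarray  # (n_classes,)

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        self.proportions = np.asarray(self.proportions, dtype=float)
        k, p = self.means.shape
        if self.variances.shape != (k, p):
            raise InvalidArgumentError("means/variances shape mismatch")
        if len(self.classes) != k or len(self.feature_names) != p:
            raise InvalidArgumentError("classes/feature_names length mismatch")
        if np.any(self.variances < 0):
            raise InvalidArgumentError("variances must be >= 0")
        if abs(float(self.proportions.sum()) - 1.0) > 1e-9:
            raise InvalidArgumentError("proportions must sum to 1 (within 1e-9)")

    @classmethod
    def from_feature_table(cls, table: pd.DataFrame) -> "ClassMoments":
        """Estimate moments (and proportions) from a labeled feature table."""
        feature_cols = [
            c for c in table.columns if c not in core.METADATA_COLUMNS
        ]
        present = [c for c in CLASSES if (table["window_label"] == c).any()]
        means, variances, counts = [], [], []
        for c in present:
            block = table.loc[table["window_label"] == c, feature_cols].to_numpy(
                dtype=float
            )
            means.append(block.mean(axis=0))
            variances.append(block.var(axis=0))
            counts.append(block.shape[0])
        counts = np.asarray(counts, dtype=float)
        return cls(
            classes=tuple(present),
            feature_names=feature_cols,
            means=np.vstack(means),
            variances=np.vstack(variances),
            proportions=counts / counts.sum(),
        )


def simulate_feature_population(
    moments: ClassMoments, n: int, seed: int
) -> pd.DataFrame:
    """Draw a labeled feature population matched to ``moments``.

    Class counts follow a multinomial over ``moments.proportions``; within a
    class, features are independent Gaussians with that class's means and
    variances.  Rows are shuffled; output follows the feature-table layout.
    """
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    rng = np.random.default_rng(int(seed))
    counts = rng.multinomial(n, moments.proportions)
    blocks, labels = [], []
    for ci, c in enumerate(moments.classes):
        if counts[ci] == 0:
            continue
        block = rng.normal(
            loc=moments.means[ci],
            scale=np.sqrt(moments.variances[ci]),
            size=(counts[ci], moments.means.shape[1]),
        )
        blocks.append(block)
        labels.extend([c] * counts[ci])
    X = np.vstack(blocks)
    order = rng.permutation(n)
    X = X[order]
    labels = np.asarray(labels, dtype=object)[order]

    df = pd.DataFrame(X, columns=moments.feature_names)
    df.insert(0, "window_start_s", 0.0)
    df.insert(0, "window_label", labels)
    df.insert(0, "segment_id", np.arange(n))
    df.insert(0, "subject_id", "population")
    return df


def null_cohort_moments(moments: ClassMoments) -> ClassMoments:
    """Moments with all class means/variances replaced by their pooled
    values (class-separation zero in feature space)."""
    w = moments.proportions[:, None]
    pooled_mean = (moments.means * w).sum(axis=0)
    pooled_var = (
        (moments.variances + (moments.means - pooled_mean) ** 2) * w
    ).sum(axis=0)
    k = len(moments.classes)
    return replace(
        moments,
        means=np.tile(pooled_mean, (k, 1)),
        variances=np.tile(pooled_var, (k, 1)),
    )
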