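"""Synthetic generator: determinism, structure, moments, and the
class-separability dial."""

import numpy as np
import pandas as pd
import pytest

import motionprims as mp
from motionprims.synth import (
    _integrate_quaternions,
    informative_sites,
    null_cohort_moments,
)


class TestProtocolAndSubjects:
    def test_default_protocol_dimensions(self):
        p = mp.default_protocol()
        assert (p.n_trials, p.n_targets, len(p.objects)) == (5, 8, 2)
        assert p.n_segments == 5 * 8 * 2 * 4

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_trials": 0},
            {"n_targets": 0},
            {"objects": ()},
            {"primitive_sequence_per_move": ("reach", "jump")},
        ],
    )
    def test_invalid_protocol_rejected(self, kwargs):
        with pytest.raises(mp.InvalidArgumentError):
            mp.TaskProtocol(**kwargs)

    def test_invalid_subject_rejected(self):
        with pytest.raises(mp.InvalidArgumentError):
            mp.SubjectParams("s", noise_sd=-1)
        with pytest.raises(mp.InvalidArgumentError):
            mp.SubjectParams("s", active_side="up")


class TestClassProportions:
    def test_counts_sum_to_published_total(self):
        assert sum(mp.DEFAULT_CLASS_COUNTS.values()) == 2881

    def test_proportions_normalized_and_ordered(self):
        p = mp.default_class_proportions()
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert p[mp.CLASSES.index("reach")] == pytest.approx(810 / 2881, abs=1e-9)
        assert p[mp.CLASSES.index("idle")] == pytest.approx(582 / 2881, abs=1e-9)


class TestSimulateRecording:
    def test_seeded_reproducibility_is_bit_identical(self, tiny_recording):
        protocol = mp.TaskProtocol(n_trials=1, n_targets=1, objects=("can",))
        rec2, labels2 = mp.simulate_recording(
            protocol, mp.SubjectParams("s01"), seed=7, sample_rate=60
        )
        rec1, labels1 = tiny_recording
        assert np.array_equal(rec1.values, rec2.values)
        assert labels1.to_frame().equals(labels2.to_frame())

    def test_full_imu_recording_has_110_channels(self, tiny_recording):
        rec, _ = tiny_recording
        assert len(rec.channels) == 11 * 10
        per_site = pd.Series([c[0] for c in rec.channels]).value_counts()
        assert (per_site == 10).all()

    def test_prescribed_primitive_sequence(self, tiny_recording):
        _, labels = tiny_recording
        assert labels.labels == ["idle", "reach", "transport", "reposition"]
        assert [s.segment_id for s in labels] == [0, 1, 2, 3]

    def test_segments_sorted_nonoverlapping_cover_recording(self, tiny_recording):
        rec, labels = tiny_recording
        segs = list(labels)
        assert segs[0].start_s == 0.0
        for a, b in zip(segs, segs[1:]):
            assert a.end_s == b.start_s  # no gaps in the default protocol
        assert segs[-1].end_s == pytest.approx(rec.duration_s, abs=1 / rec.sample_rate)

    def test_invalid_arguments_rejected(self):
        protocol = mp.default_protocol()
        with pytest.raises(mp.InvalidArgumentError):
            mp.simulate_recording(
                protocol, mp.SubjectParams("s"), seed=1, sample_rate=0
            )
        with pytest.raises(mp.InvalidArgumentError):
            mp.simulate_recording(
                protocol, mp.SubjectParams("s"), seed=1, class_separation=-1
            )

    def test_quaternions_unit_norm_before_noise(self):
        protocol = mp.TaskProtocol(n_trials=1, n_targets=2, objects=("can",))
        rec, _ = mp.simulate_recording(
            protocol,
            mp.SubjectParams("s01", noise_sd=0.0),
            seed=3,
            sample_rate=60,
        )
        quat_cols = [
            i for i, (s, m, a) in enumerate(rec.channels) if m == "quat"
        ]
        q = rec.values[:, quat_cols].reshape(rec.n_samples, 11, 4)
        norms = np.linalg.norm(q, axis=2)
        assert np.allclose(norms, 1.0, atol=1e-6)

    def test_idle_is_near_silent_on_distal_channels_without_sway(self):
        # per-segment execution gains jitter single segments; compare class
        # means over many segments
        protocol = mp.TaskProtocol(n_trials=4, n_targets=2, objects=("can",))
        subject = mp.SubjectParams("s01", noise_sd=0.0)
        rec, labels = mp.simulate_recording(protocol, subject, seed=3, sample_rate=60)
        hand = rec.channel_names.index("r_hand.acc.z")
        fs = rec.sample_rate
        rms = {}
        for seg in labels:
            sl = slice(int(seg.start_s * fs) + 2, int(seg.end_s * fs) - 2)
            rms.setdefault(seg.label, []).append(
                float(np.sqrt(np.mean(rec.values[sl, hand] ** 2)))
            )
        idle = np.mean(rms["idle"])
        for c in ("reach", "transport", "reposition"):
            assert np.mean(rms[c]) > 1.5 * idle

    def test_grasp_rotation_separates_reach_from_reposition(self):
        protocol = mp.TaskProtocol(n_trials=4, n_targets=2, objects=("can",))
        subject = mp.SubjectParams("s01", noise_sd=0.0, offset_scale=0.0)
        rec, labels = mp.simulate_recording(protocol, subject, seed=3, sample_rate=60)
        gyr_cols = [
            i
            for i, (s, m, a) in enumerate(rec.channels)
            if s == "r_forearm" and m == "gyr"
        ]
        fs = rec.sample_rate
        by_class = {"reach": [], "reposition": []}
        for seg in labels:
            if seg.label not in by_class:
                continue
            sl = slice(int(seg.start_s * fs), int(seg.end_s * fs))
            by_class[seg.label].append(
                np.sqrt(np.mean(rec.values[sl, gyr_cols] ** 2))
            )
        assert np.mean(by_class["reach"]) > 1.5 * np.mean(by_class["reposition"])

    def test_adjacent_site_channels_are_correlated(self, desk_cohort):
        # the shared postural sway couples adjacent sites; measure it during
        # idle (class bursts, which have site-specific directions, are absent)
        rec, labels = desk_cohort[0]
        names = rec.channel_names
        fs = rec.sample_rate
        idle = np.zeros(rec.n_samples, dtype=bool)
        for seg in labels:
            if seg.label == "idle":
                idle[int(seg.start_s * fs) : int(seg.end_s * fs)] = True
        pairs = [
            ("sternum.acc.x", "pelvis.acc.x"),
            ("r_forearm.acc.y", "r_hand.acc.y"),
            ("l_forearm.acc.z", "l_hand.acc.z"),
        ]
        for a, b in pairs:
            r = np.corrcoef(
                rec.values[idle, names.index(a)], rec.values[idle, names.index(b)]
            )[0, 1]
            assert r > 0.3, (a, b, r)

    def test_informative_sites_are_trunk_head_and_active_arm(self):
        assert set(informative_sites("right")) == {
            "head",
            "sternum",
            "pelvis",
            "r_scapula",
            "r_arm",
            "r_forearm",
            "r_hand",
        }
        assert "l_hand" in informative_sites("left")

    def test_separation_zero_collapses_class_signal(self):
        protocol = mp.TaskProtocol(n_trials=4, n_targets=3, objects=("can",))
        subject = mp.SubjectParams("s01", noise_sd=0.0)
        rec, labels = mp.simulate_recording(
            protocol, subject, seed=3, sample_rate=60, class_separation=0.0
        )
        hand = rec.channel_names.index("r_hand.acc.z")
        fs = rec.sample_rate
        rms = {}
        for seg in labels:
            sl = slice(int(seg.start_s * fs), int(seg.end_s * fs))
            rms.setdefault(seg.label, []).append(
                float(np.sqrt(np.mean(rec.values[sl, hand] ** 2)))
            )
        means = {k: np.mean(v) for k, v in rms.items()}
        # only sway remains: no class stands out
        assert max(means.values()) < 2.0 * min(means.values())


class TestQuaternionIntegration:
    def test_constant_rotation_rate_gives_expected_angle(self):
        # rotate about x at 1 rad/s for 1 s at 100 Hz -> quat angle ~1 rad
        omega = np.tile([1.0, 0.0, 0.0], (101, 1, 1))
        q = _integrate_quaternions(omega, 0.01)
        w = q[-1, 0, 0]
        angle = 2 * np.arccos(np.clip(w, -1, 1))
        assert angle == pytest.approx(1.0, abs=1e-6)

    def test_zero_rotation_stays_identity(self):
        q = _integrate_quaternions(np.zeros((50, 2, 3)), 0.01)
        assert np.allclose(q[..., 0], 1.0)
        assert np.allclose(q[..., 1:], 0.0)


class TestFeaturePopulation:
    def _moments(self, p=4):
        means = np.arange(4 * p, dtype=float).reshape(4, p)
        variances = np.full((4, p), 2.0)
        return mp.ClassMoments(
            classes=mp.CLASSES,
            feature_names=[f"f{i}" for i in range(p)],
            means=means,
            variances=variances,
            proportions=mp.default_class_proportions(),
        )

    def test_multinomial_class_counts_within_three_se(self):
        n = 300_000
        table = mp.simulate_feature_population(self._moments(), n, seed=5)
        counts = table["window_label"].value_counts()
        for c, p in zip(mp.CLASSES, mp.default_class_proportions()):
            se = np.sqrt(n * p * (1 - p))
            assert abs(counts[c] - n * p) <= 3 * se

    def test_zero_variance_feature_is_constant_at_class_mean(self):
        m = self._moments()
        m.variances[:, 0] = 0.0
        table = mp.simulate_feature_population(m, 500, seed=5)
        for ci, c in enumerate(mp.CLASSES):
            vals = table.loc[table["window_label"] == c, "f0"]
            assert np.allclose(vals, m.means[ci, 0])

    def test_empirical_means_within_clt_bound(self):
        m = self._moments()
        table = mp.simulate_feature_population(m, 10_000, seed=5)
        for ci, c in enumerate(mp.CLASSES):
            block = table.loc[table["window_label"] == c]
            n_c = len(block)
            bound = 4 * np.sqrt(m.variances[ci]) / np.sqrt(n_c)
            assert (
                np.abs(block[m.feature_names].mean(axis=0) - m.means[ci]) <= bound
            ).all()

    def test_seeded_and_reproducible(self):
        a = mp.simulate_feature_population(self._moments(), 1000, seed=9)
        b = mp.simulate_feature_population(self._moments(), 1000, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_negative_variance_rejected(self):
        m = self._moments()
        with pytest.raises(mp.InvalidArgumentError):
            mp.ClassMoments(
                classes=m.classes,
                feature_names=m.feature_names,
                means=m.means,
                variances=-np.ones_like(m.variances),
                proportions=m.proportions,
            )

    def test_moments_round_trip_from_table(self, desk_table):
        m = mp.ClassMoments.from_feature_table(desk_table)
        assert set(m.classes) == set(mp.CLASSES)
        assert m.proportions.sum() == pytest.approx(1.0, abs=1e-9)
        pop = mp.simulate_feature_population(m, 2000, seed=2)
        assert set(pop.columns) == set(desk_table.columns)

    def test_null_moments_coincide_across_classes(self, desk_table):
        m = null_cohort_moments(mp.ClassMoments.from_feature_table(desk_table))
        assert np.allclose(m.means, m.means[0])
        assert np.allclose(m.variances, m.variances[0])
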