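"""Mirror, alignment, per-frame CoM estimators and the full path pipeline."""

import numpy as np
import pytest

from swaykit import synthetic_data as syn
from swaykit.com_pipeline import (
    DEFAULT_SEGMENT_TABLE,
    Segment,
    SegmentTable,
    align_to_first,
    com_path,
    com_three_joint,
    com_tbcm,
    flip_ml,
    interpolate_gaps,
    read_com_path,
    write_com_path,
)
from swaykit.skeleton_io import ML, JointName, TrackingState

from conftest import make_standing_sequence


class TestFlipML:
    def test_negates_ml_only(self, jittered_seq):
        flipped = flip_ml(jittered_seq)
        np.testing.assert_array_equal(flipped.positions[:, :, ML],
                                      -jittered_seq.positions[:, :, ML])
        np.testing.assert_array_equal(flipped.positions[:, :, 1:],
                                      jittered_seq.positions[:, :, 1:])

    def test_involution(self, jittered_seq):
        twice = flip_ml(flip_ml(jittered_seq))
        np.testing.assert_array_equal(twice.positions, jittered_seq.positions)

    def test_zero_ml_is_fixed_point(self, standing_seq):
        seq = standing_seq
        seq.positions[:, :, ML] = 0.0
        np.testing.assert_array_equal(flip_ml(seq).positions, seq.positions)


class TestAlignToFirst:
    def test_frame0_centroid_maps_to_origin(self, jittered_seq):
        aligned = align_to_first(jittered_seq)
        idx = [JointName.index(j) for j in ("hip_left", "hip_right", "spine_mid")]
        np.testing.assert_allclose(aligned.positions[0, idx].mean(axis=0),
                                   0.0, atol=1e-12)

    def test_static_sequence_all_centroids_at_origin(self, standing_seq):
        aligned = align_to_first(standing_seq)
        idx = [JointName.index(j) for j in ("hip_left", "hip_right", "spine_mid")]
        np.testing.assert_allclose(aligned.positions[:, idx].mean(axis=1),
                                   0.0, atol=1e-12)

    def test_pairwise_distances_preserved(self, jittered_seq):
        before = jittered_seq.positions
        after = align_to_first(jittered_seq).positions
        for frame in (0, 17, 59):
            d_before = np.linalg.norm(before[frame, :, None] - before[frame, None], axis=-1)
            d_after = np.linalg.norm(after[frame, :, None] - after[frame, None], axis=-1)
            np.testing.assert_allclose(d_after, d_before, atol=1e-12)

    def test_idempotent(self, jittered_seq):
        once = align_to_first(jittered_seq)
        twice = align_to_first(once)
        np.testing.assert_allclose(twice.positions, once.positions, atol=1e-15)

    def test_untracked_core_joint_in_frame0_is_an_error(self, standing_seq):
        standing_seq.states[0, JointName.index("spine_mid")] = TrackingState.not_tracked
        with pytest.raises(ValueError, match="spine_mid"):
            align_to_first(standing_seq)


class TestComThreeJoint:
    def test_identical_joints_return_that_point(self, standing_seq):
        f = standing_seq.frame(0)
        p = np.array([0.2, 0.9, -0.1])
        for j in ("hip_left", "hip_right", "spine_mid"):
            f.positions[JointName.index(j)] = p
        np.testing.assert_allclose(com_three_joint(f), p)

    def test_component_wise_mean(self, standing_seq):
        f = standing_seq.frame(0)
        pts = {"hip_left": (0, 0, 0), "hip_right": (0.3, 0, 0), "spine_mid": (0, 0.3, 0.3)}
        for j, p in pts.items():
            f.positions[JointName.index(j)] = p
        np.testing.assert_allclose(com_three_joint(f), [0.1, 0.1, 0.1])

    def test_untracked_joint_is_an_error(self, standing_seq):
        f = standing_seq.frame(0)
        f.states[JointName.index("hip_right")] = TrackingState.not_tracked
        with pytest.raises(ValueError, match="hip_right"):
            com_three_joint(f)

    def test_commutes_with_rigid_translation(self, jittered_seq):
        from swaykit.skeleton_io import SkeletonFrame

        f = jittered_seq.frame(3)
        shift = np.array([0.5, -0.2, 1.0])
        shifted = SkeletonFrame(
            timestamp=f.timestamp,
            positions=f.positions + shift,
            states=f.states.copy(),
        )
        np.testing.assert_allclose(
            com_three_joint(shifted), com_three_joint(f) + shift, atol=1e-12
        )

    def test_equals_degenerate_three_segment_tbcm(self, jittered_seq):
        # equal point-masses concentrated at the three joints
        table = SegmentTable(tuple(
            Segment(j, 1.0 / 3.0, JointName(j), JointName(j), 0.0)
            for j in ("hip_left", "hip_right", "spine_mid")
        ))
        f = jittered_seq.frame(5)
        np.testing.assert_allclose(com_tbcm(f, table), com_three_joint(f), atol=1e-12)


class TestComTbcm:
    def test_single_segment_midpoint(self, standing_seq):
        f = standing_seq.frame(0)
        f.positions[JointName.index("hip_left")] = (0, 0, 0)
        f.positions[JointName.index("knee_left")] = (1, 0, 0)
        table = SegmentTable((Segment("thigh", 1.0, JointName.hip_left,
                                      JointName.knee_left, 0.5),))
        np.testing.assert_allclose(com_tbcm(f, table), [0.5, 0, 0])

    def test_two_equal_point_masses(self, standing_seq):
        f = standing_seq.frame(0)
        f.positions[JointName.index("head")] = (0, 0, 0)
        f.positions[JointName.index("foot_left")] = (2, 2, 2)
        table = SegmentTable((
            Segment("a", 0.5, JointName.head, JointName.head, 0.0),
            Segment("b", 0.5, JointName.foot_left, JointName.foot_left, 0.0),
        ))
        np.testing.assert_allclose(com_tbcm(f, table), [1, 1, 1])

    def test_matches_brute_force_weighted_sum(self, jittered_seq):
        f = jittered_seq.frame(9)
        # independent oracle: explicit sum(m_i * segment_com_i) / sum(m_i)
        num = np.zeros(3)
        total = 0.0
        for s in DEFAULT_SEGMENT_TABLE:
            p = f.positions[JointName.index(s.proximal)]
            d = f.positions[JointName.index(s.distal)]
            seg_com = (1 - s.com_fraction) * p + s.com_fraction * d
            num += s.mass_fraction * seg_com
            total += s.mass_fraction
        np.testing.assert_allclose(com_tbcm(f, DEFAULT_SEGMENT_TABLE),
                                   num / total, atol=1e-12)

    def test_bad_mass_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            SegmentTable((Segment("x", 0.9, JointName.head, JointName.neck, 0.5),))


class TestComPath:
    def test_static_standing_gives_zero_path(self, standing_seq):
        path = com_path(standing_seq, "three_joint", validate=False)
        np.testing.assert_allclose(path.ml_mm, 0.0, atol=1e-9)
        np.testing.assert_allclose(path.ap_mm, 0.0, atol=1e-9)
        assert path.method == "three_joint"
        assert len(path) == len(standing_seq)

    def test_known_trajectory_recovered(self, subject):
        preset = syn.SotPreset("a", 3.0, bandwidth_hz=0.3, joint_noise_mm=0.0)
        truth = syn.generate_com_process(preset, 99)
        seq = syn.synthesize_skeleton(truth, preset, subject, 1)
        path = com_path(seq, "three_joint")
        rel = truth.xy30_mm - truth.xy30_mm[0]
        np.testing.assert_allclose(path.ml_mm, rel[:, 0], atol=1e-9)
        np.testing.assert_allclose(path.ap_mm, rel[:, 1], atol=1e-9)

    def test_camera_side_mirroring_symmetry(self, subject):
        preset = syn.SotPreset("a", 3.0, joint_noise_mm=0.0)
        truth = syn.generate_com_process(preset, 5)
        mirrored = syn.GroundTruth(
            condition=truth.condition, t30=truth.t30,
            xy30_mm=truth.xy30_mm * np.array([-1.0, 1.0]),
            t100=truth.t100, xy100_mm=truth.xy100_mm * np.array([-1.0, 1.0]),
            target_rms_mm=truth.target_rms_mm, theta=truth.theta,
            axis_sd_mm=truth.axis_sd_mm,
        )
        p1 = com_path(syn.synthesize_skeleton(truth, preset, subject, 1), "three_joint")
        p2 = com_path(syn.synthesize_skeleton(mirrored, preset, subject, 1), "three_joint")
        np.testing.assert_allclose(p2.ml_mm, -p1.ml_mm, atol=1e-9)
        np.testing.assert_allclose(p2.ap_mm, p1.ap_mm, atol=1e-9)

    def test_invariant_to_constant_whole_body_offset(self, jittered_seq):
        base = com_path(jittered_seq, "three_joint", validate=False)
        shifted_seq = jittered_seq.with_positions(
            jittered_seq.positions + np.array([0.3, -0.1, 0.7])
        )
        shifted = com_path(shifted_seq, "three_joint", validate=False)
        np.testing.assert_allclose(shifted.ml_mm, base.ml_mm, atol=1e-9)
        np.testing.assert_allclose(shifted.ap_mm, base.ap_mm, atol=1e-9)

    def test_short_dropout_is_interpolated(self, jittered_seq):
        jittered_seq.states[10, JointName.index("hip_left")] = TrackingState.not_tracked
        path = com_path(jittered_seq, "three_joint", validate=False)
        assert np.all(np.isfinite(path.ml_mm))

    def test_tbcm_method_runs_and_differs_from_three_joint(self, jittered_seq):
        p3 = com_path(jittered_seq, "three_joint", validate=False)
        pt = com_path(jittered_seq, "tbcm", validate=False)
        assert pt.method == "tbcm"
        assert len(pt) == len(p3)
        assert not np.allclose(pt.ap_mm, p3.ap_mm)


def test_path_csv_round_trip(jittered_seq):
    path = com_path(jittered_seq, "three_joint", validate=False)
    back = read_com_path(write_com_path(path), method=path.method)
    np.testing.assert_allclose(back.ml_mm, path.ml_mm, atol=1e-6)
    np.testing.assert_allclose(back.ap_mm, path.ap_mm, atol=1e-6)
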