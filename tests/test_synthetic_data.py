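"""The paired-recording simulator: determinism, calibration, recovery."""

import numpy as np
import pandas as pd
import pytest

from swaykit import agreement as agr
from swaykit import synthetic_data as syn
from swaykit.com_pipeline import com_path
from swaykit.forceplate_model import cof_to_com
from swaykit.sway_metrics import sway_from_path


class TestComProcess:
    def test_same_seed_identical_output(self):
        p = syn.default_presets()["b"]
        t1 = syn.generate_com_process(p, 42)
        t2 = syn.generate_com_process(p, 42)
        np.testing.assert_array_equal(t1.xy30_mm, t2.xy30_mm)
        np.testing.assert_array_equal(t1.xy100_mm, t2.xy100_mm)

    def test_zero_diffusion_gives_constant_path(self):
        p = syn.default_presets()["a"]
        t = syn.generate_com_process(p, 1, diffusion_scale=0.0)
        assert np.all(t.xy30_mm == 0.0)
        assert t.true_rms_30hz_mm == 0.0

    def test_long_horizon_rms_approaches_target(self):
        p = syn.SotPreset("a", 5.0, bandwidth_hz=0.3, duration_s=200.0)
        rms = [syn.generate_com_process(p, s).true_rms_30hz_mm for s in range(8)]
        assert abs(np.mean(rms) - 5.0) / 5.0 < 0.10

    def test_both_grids_sample_one_path(self):
        p = syn.default_presets()["c"]
        t = syn.generate_com_process(p, 3)
        # grids coincide every 0.1 s: xy30[3j] and xy100[10j] hit the same
        # base-grid sample
        np.testing.assert_array_equal(t.xy30_mm[::3], t.xy100_mm[::10])


class TestSkeletonChannel:
    def test_noise_free_pipeline_inversion(self, subject):
        preset = syn.SotPreset("a", 3.0, joint_noise_mm=0.0)
        truth = syn.generate_com_process(preset, 11)
        path = com_path(syn.synthesize_skeleton(truth, preset, subject, 1), "three_joint")
        rel = truth.xy30_mm - truth.xy30_mm[0]
        assert np.max(np.abs(path.ml_mm - rel[:, 0])) < 1e-6
        assert np.max(np.abs(path.ap_mm - rel[:, 1])) < 1e-6

    def test_noise_free_inversion_under_hip_strategy(self, subject):
        preset = syn.SotPreset("e", 17.1, hip_mix=0.7, joint_noise_mm=0.0)
        truth = syn.generate_com_process(preset, 12)
        path = com_path(syn.synthesize_skeleton(truth, preset, subject, 1), "three_joint")
        rel = truth.xy30_mm - truth.xy30_mm[0]
        assert np.max(np.abs(path.ml_mm - rel[:, 0])) < 1e-6

    def test_omitting_mirror_negates_ml(self, subject):
        from swaykit.com_pipeline import align_to_first
        from swaykit.skeleton_io import CORE_JOINT_IDX, ML

        preset = syn.SotPreset("a", 3.0, joint_noise_mm=0.0)
        truth = syn.generate_com_process(preset, 2)
        seq = syn.synthesize_skeleton(truth, preset, subject, 1)
        aligned = align_to_first(seq)  # no flip_ml
        ml = aligned.positions[:, CORE_JOINT_IDX, ML].mean(axis=1) * 1000
        rel = truth.xy30_mm - truth.xy30_mm[0]
        np.testing.assert_allclose(ml, -rel[:, 0], atol=1e-6)

    def test_noisy_recovery_within_5pct_at_high_sway(self, subject):
        # joint noise inflates measured RMS by ~2/3*sigma^2 per axis; at a
        # perturbed-condition amplitude that is well under 5%
        preset = syn.SotPreset("e", 17.1, bandwidth_hz=0.7)
        ratios = []
        for s in range(60):
            truth = syn.generate_com_process(preset, 1000 + s)
            skel = syn.synthesize_skeleton(truth, preset, subject, 2000 + s)
            measured = sway_from_path(com_path(skel, "three_joint")).sway_rms_mm
            ratios.append(measured / truth.true_rms_30hz_mm)
        assert abs(np.mean(ratios) - 1.0) < 0.05

    def test_same_seed_reproducible(self, subject):
        preset = syn.default_presets()["d"]
        truth = syn.generate_com_process(preset, 5)
        s1 = syn.synthesize_skeleton(truth, preset, subject, 9)
        s2 = syn.synthesize_skeleton(truth, preset, subject, 9)
        np.testing.assert_array_equal(s1.positions, s2.positions)

    def test_nonpositive_height_rejected(self):
        preset = syn.default_presets()["a"]
        truth = syn.generate_com_process(preset, 1)
        bad = syn.SubjectMeta("S0", 0.0, 70.0)
        with pytest.raises(ValueError, match="height"):
            syn.synthesize_skeleton(truth, preset, bad, 1)


class TestCofChannel:
    def test_noise_free_exact_recovery(self, subject):
        preset = syn.SotPreset("b", 4.2, cof_noise_mm=0.0)
        truth = syn.generate_com_process(preset, 21)
        path = cof_to_com(syn.synthesize_cof(truth, preset, subject, 1))
        assert np.max(np.abs(path.ml_mm - truth.xy100_mm[:, 0])) < 1e-9
        assert np.max(np.abs(path.ap_mm - truth.xy100_mm[:, 1])) < 1e-9

    def test_noisy_recovery_within_5pct(self, subject):
        preset = syn.SotPreset("e", 17.1, bandwidth_hz=0.7)
        ratios = []
        for s in range(60):
            truth = syn.generate_com_process(preset, 3000 + s)
            cof = syn.synthesize_cof(truth, preset, subject, 4000 + s)
            measured = sway_from_path(cof_to_com(cof)).sway_rms_mm
            c = truth.xy100_mm - truth.xy100_mm.mean(axis=0)
            true_rms = np.sqrt(np.mean(c[:, 0] ** 2) + np.mean(c[:, 1] ** 2))
            ratios.append(measured / true_rms)
        assert abs(np.mean(ratios) - 1.0) < 0.05


class TestMeasurementModel:
    def test_expected_rms_matches_empirical_means(self, null_study):
        # closed-form channel model vs the measured study, per condition
        presets = syn.default_presets()
        g = null_study.long.groupby(["condition", "method"])["sway_rms_mm"].mean()
        scales = {c: syn.calibrate_channel_scale(presets[c]) for c in "abcdef"}
        for c in "abcdef":
            for method, chan, scale in (
                ("pendulum", "plate", 1.0),
                ("three_joint", "camera", scales[c]),
            ):
                expected = syn.expected_measured_rms(presets[c], chan, scale)
                assert g[c, method] == pytest.approx(expected, rel=0.05)

    def test_calibration_below_noise_floor_rejected(self):
        preset = syn.default_presets()["a"]
        with pytest.raises(ValueError, match="noise floor"):
            syn.calibrate_channel_scale(preset, additive_mm=2.9)

    def test_window_shrinkage_limits(self):
        # uncorrelated samples lose exactly the 1/n mean share; a frozen
        # path keeps nothing
        assert syn.window_shrinkage(100, 0.0) == pytest.approx(1 - 1 / 100)
        assert syn.window_shrinkage(100, 1.0) == pytest.approx(0.0, abs=1e-12)


class TestStudy:
    def test_factorial_shape_and_determinism(self):
        s1 = syn.generate_study(3, repeats=2, seed=77, conditions=list("ab"))
        s2 = syn.generate_study(3, repeats=2, seed=77, conditions=list("ab"))
        assert len(s1.long) == 3 * 2 * 2 * 2  # subjects x cond x repeats x methods
        pd.testing.assert_frame_equal(s1.long, s2.long)

    def test_zero_injected_bias_recovered_as_null(self, null_study):
        pairs = agr.PairedSwaySet.from_long(null_study.long)
        for c in "abcdef":
            e = agr.bland_altman(pairs, c)
            se = e.sd_diff / np.sqrt(e.n)
            assert abs(e.bias) < 3 * se, f"condition {c}: bias {e.bias:.3f}"

    def test_injected_additive_bias_recovered(self):
        # a perturbed-condition bias of 1.6 mm, the scale of the largest
        # between-method disagreement
        study = syn.generate_study(
            30, repeats=2, seed=123, conditions=["e"],
            bias=syn.BiasModel(additive_mm={"e": 1.6}),
        )
        pairs = agr.PairedSwaySet.from_long(study.long)
        e = agr.bland_altman(pairs, "e")
        se = e.sd_diff / np.sqrt(e.n)
        assert abs(e.bias - 1.6) < 3 * se

    def test_multiplicative_bias_recovered(self):
        study = syn.generate_study(
            30, repeats=2, seed=9, conditions=["d"],
            bias=syn.BiasModel(multiplicative={"d": 0.9}),
        )
        pairs = agr.PairedSwaySet.from_long(study.long)
        e = agr.bland_altman(pairs, "d")
        expected = 0.1 * e.mean_a  # (1 - m) * E[plate sway]
        se = e.sd_diff / np.sqrt(e.n)
        assert abs(e.bias - expected) < 3 * se + 0.02 * expected

    def test_shared_truth_repeatability_is_noise_driven(self):
        presets = syn.default_presets()
        study = syn.generate_study(
            80, repeats=2, seed=31, conditions=["a"],
            share_truth_across_repeats=True,
        )
        pairs = agr.PairedSwaySet.from_long(study.long)
        scale = study.truth["channel_scale"].iloc[0]
        for method, chan, s in (("pendulum", "plate", 1.0),
                                ("three_joint", "camera", scale)):
            r = agr.repeatability(pairs, "a", method)
            predicted = syn.predicted_repeat_sd(presets["a"], chan, channel_scale=s)
            assert r.sd_within == pytest.approx(predicted, rel=0.30)
            assert r.cr == pytest.approx(agr.CR_FACTOR * r.sd_within, abs=1e-12)

    def test_keep_recordings_round_trip(self):
        study = syn.generate_study(1, repeats=1, seed=2, conditions=["a"],
                                   keep_recordings=True)
        rec = study.recordings[0]
        measured = sway_from_path(com_path(rec.skeleton, "three_joint")).sway_rms_mm
        row = study.long[(study.long.trial_id == rec.trial_id)
                         & (study.long.method == "three_joint")]
        assert measured == pytest.approx(float(row.sway_rms_mm.iloc[0]))
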