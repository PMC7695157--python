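"""Feature extraction, slow-eye-movement detection and the staging rules."""

import numpy as np
import pandas as pd
import pytest

import vigistate as vg
from vigistate.recording import Recording


def feature_row(**kw):
    base = dict(alpha_power_anterior=0.0, alpha_power_posterior=0.0,
                slowwave_power=0.0, sem_flag=False, marker_flag="none",
                artifact=False)
    base.update(kw)
    return pd.Series(base)


class TestDetectSem:
    fs = 200.0

    def _eog(self, amp, freq=0.3, phase="anti", duration=10.0, noise=2.0, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(int(duration * self.fs)) / self.fs
        wave = amp * np.sin(2 * np.pi * freq * t)
        left = wave + rng.normal(0, noise, t.size)
        sign = -1.0 if phase == "anti" else 1.0
        right = sign * wave + rng.normal(0, noise, t.size)
        return left, right

    def test_anti_phase_slow_deflection_detected(self):
        left, right = self._eog(80.0)
        flags = vg.detect_sem(left, right, self.fs)
        assert flags.mean() > 0.9

    def test_in_phase_drift_not_detected(self):
        left, right = self._eog(80.0, phase="in")
        assert not vg.detect_sem(left, right, self.fs).any()

    def test_small_deflections_ignored(self):
        left, right = self._eog(5.0)
        assert not vg.detect_sem(left, right, self.fs).any()

    def test_sensitivity_and_specificity_on_planted_epochs(self):
        """200 SEM seconds vs 200 clean seconds at default synthesis SNR."""
        sem_course = vg.block_course([("B1", 200)])
        clean_course = vg.block_course([("0", 200)])
        rec_sem, _ = vg.simulate_recording(sem_course, seed=21)
        rec_clean, _ = vg.simulate_recording(clean_course, seed=22)
        sens = vg.detect_sem(rec_sem.channel("EOGh-L"),
                             rec_sem.channel("EOGh-R"), rec_sem.fs).mean()
        spec = 1.0 - vg.detect_sem(rec_clean.channel("EOGh-L"),
                                   rec_clean.channel("EOGh-R"),
                                   rec_clean.fs).mean()
        assert sens >= 0.9
        assert spec >= 0.9


class TestClassifyEpoch:
    def test_marker_forces_stage_c_regardless_of_powers(self, calib):
        row = feature_row(marker_flag="spindle",
                          alpha_power_posterior=10 * calib.alpha_threshold)
        assert vg.classify_epoch(row, calib) == "C"

    def test_slow_wave_dominance_gives_b23(self, calib):
        row = feature_row(slowwave_power=2 * calib.slowwave_threshold)
        assert vg.classify_epoch(row, calib) == "B23"

    def test_alpha_takes_precedence_over_slow_when_both_high(self, calib):
        row = feature_row(slowwave_power=2 * calib.slowwave_threshold,
                          alpha_power_posterior=2 * calib.alpha_threshold)
        assert vg.classify_epoch(row, calib) == "A1"

    @pytest.mark.parametrize("ratio,expected",
                             [(0.2, "A1"), (0.7, "A2"), (1.5, "A3")])
    def test_frontalization_ratio_selects_a_substage(self, calib, ratio, expected):
        post = 3 * calib.alpha_threshold
        row = feature_row(alpha_power_posterior=post,
                          alpha_power_anterior=ratio * post)
        assert vg.classify_epoch(row, calib) == expected

    def test_sem_without_alpha_gives_b1(self, calib):
        assert vg.classify_epoch(feature_row(sem_flag=True), calib) == "B1"

    def test_featureless_epoch_is_stage_0(self, calib):
        assert vg.classify_epoch(feature_row(), calib) == "0"

    def test_artifact_epoch_rejected(self, calib):
        with pytest.raises(ValueError, match="artifact"):
            vg.classify_epoch(feature_row(artifact=True), calib)


class TestExtractFeatures:
    def test_occipital_tone_loads_posterior_alpha(self, calib):
        fs = 200.0
        t = np.arange(int(10 * fs)) / fs
        labels = ("Fp1", "Fz", "O1", "O2") + vg.EOG_PAIR
        data = np.zeros((6, t.size))
        data[2] = data[3] = 40 * np.sin(2 * np.pi * 10 * t)
        rec = Recording(data, fs, labels)
        grid = vg.segment_epochs(rec)
        feats = vg.extract_features(
            rec, grid,
            rois={"anterior": ("Fp1", "Fz"), "posterior": ("O1", "O2"),
                  "global": ("Fp1", "Fz", "O1", "O2")})
        assert (feats.alpha_power_posterior > 50 * feats.alpha_power_anterior
                + 1e-12).all()

    def test_white_noise_band_powers_scale_with_bandwidth(self):
        fs = 200.0
        rng = np.random.default_rng(8)
        labels = ("O1",) + vg.EOG_PAIR
        sigma = 20.0
        rec = Recording(rng.normal(0, sigma, (3, int(60 * fs))), fs, labels)
        grid = vg.segment_epochs(rec)
        feats = vg.extract_features(
            rec, grid, rois={"anterior": ("O1",), "posterior": ("O1",),
                             "global": ("O1",)})
        # flat spectrum: band power ≈ σ² × bandwidth / nyquist
        for col, (lo, hi) in (("alpha_power_posterior", (8, 12)),
                              ("slowwave_power", (2, 7))):
            expect = sigma ** 2 * (hi - lo + 1) / (fs / 2)
            mean_power = feats[col].mean()
            assert expect / 3 < mean_power < expect * 3

    def test_marker_sample_maps_to_its_epoch(self, calib):
        rec, _ = vg.simulate_recording(vg.block_course([("0", 5)]), seed=3)
        grid = vg.segment_epochs(rec)
        feats = vg.extract_features(rec, grid, markers=[(2 * 200 + 17, "SPINDLE")])
        assert feats.marker_flag.tolist() == ["none", "none", "spindle",
                                              "none", "none"]


class TestClassifyRecording:
    def test_planted_a1_recording_recovered(self, calib):
        course = vg.block_course([("A1", 60)])
        rec, markers = vg.simulate_recording(course, seed=31)
        pred = vg.classify_recording(rec, calib, markers=markers)
        assert (np.array(pred.labels) == "A1").mean() >= 0.95

    def test_hyperstable_signal_chain_reaches_ass_14(self, calib):
        course = vg.simulate_stage_course("hyperstable", duration_min=4, seed=7)
        rec, markers = vg.simulate_recording(course, seed=32)
        pred = vg.classify_recording(rec, calib, markers=markers)
        assert vg.arousal_stability_score(pred).score == 14

    def test_scaling_with_recalibration_preserves_stages(self):
        """Common gain changes cancel when thresholds are recalibrated from
        the equally scaled calibration segment."""
        seg = vg.simulate_calibration_segment(20, seed=55)
        course = vg.block_course([("A1", 20), ("A3", 20), ("B23", 20)])
        rec, markers = vg.simulate_recording(course, seed=56)
        base = vg.classify_recording(rec, vg.calibrate(seg), markers=markers)
        scale = 1.3  # stays within the artifact amplitude limit
        rec2 = rec.copy_with(rec.samples * scale)
        seg2 = seg.copy_with(seg.samples * scale)
        scaled = vg.classify_recording(rec2, vg.calibrate(seg2), markers=markers)
        same = ~(base.artifact_mask | scaled.artifact_mask)
        assert np.array_equal(base.scores[same], scaled.scores[same])

    def test_low_voltage_subject_rejected(self, calib):
        import dataclasses
        low = dataclasses.replace(calib, low_voltage_flag=True)
        rec, _ = vg.simulate_recording(vg.block_course([("A1", 5)]), seed=1)
        with pytest.raises(ValueError, match="low-voltage"):
            vg.classify_recording(rec, low)

    def test_all_artifact_recording_blocks_metrics(self, calib):
        rec, _ = vg.simulate_recording(vg.block_course([("A1", 10)]), seed=2)
        t = np.arange(rec.n_samples) / rec.fs
        # huge in-band oscillation: every epoch exceeds the amplitude limit
        rec.samples[0] += 1e4 * np.sin(2 * np.pi * 5 * t)
        pred = vg.classify_recording(rec, calib)
        assert pred.artifact_mask.all()
        with pytest.raises(ValueError, match="artifact"):
            vg.mean_vigilance_value(pred)

    def test_auto_event_detector_finds_planted_events(self, calib):
        labels = ["B23"] * 60
        labels[10] = labels[40] = "C"
        course = vg.StageSequence.from_labels(labels)
        rec, markers = vg.simulate_recording(course, seed=33)
        found = vg.detect_events_auto(rec)
        found_epochs = {s // 200 for s, _ in found}
        assert {10, 40} <= found_epochs
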