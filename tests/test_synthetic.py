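"""Ground-truth behavior of the stage-course, signal and cohort generators."""

import numpy as np
import pytest

import vigistate as vg
from vigistate.preprocess import band_power_epochs
from vigistate.stages import SCORE_OF
from vigistate.synthetic import DEFAULT_COURSE_PARAMS


class TestStageCourse:
    def test_fixed_seed_reproduces_course_exactly(self):
        a = vg.simulate_stage_course("adaptive", seed=3)
        b = vg.simulate_stage_course("adaptive", seed=3)
        assert np.array_equal(a.scores, b.scores)
        c = vg.simulate_stage_course("adaptive", seed=4)
        assert not np.array_equal(a.scores, c.scores)

    @pytest.mark.parametrize("reg_type", vg.REGULATION_TYPES)
    def test_length_is_duration_times_60(self, reg_type):
        course = vg.simulate_stage_course(reg_type, duration_min=8, seed=0)
        assert course.n_seconds == 480
        assert not course.artifact_mask.any()

    def test_hyperstable_contains_only_0_and_a1_and_scores_14(self):
        course = vg.simulate_stage_course("hyperstable", seed=1)
        assert set(course.scores.tolist()) <= {SCORE_OF["0"], SCORE_OF["A1"]}
        assert vg.arousal_stability_score(course).score == 14

    def test_stable_never_reaches_b23_or_c(self):
        for seed in range(30):
            course = vg.simulate_stage_course("stable", seed=seed)
            assert course.scores.min() >= SCORE_OF["A3"]

    def test_unknown_regulation_type_rejected(self):
        with pytest.raises(ValueError, match="unknown regulation type"):
            vg.simulate_stage_course("langorous", seed=0)

    def test_too_short_duration_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            vg.simulate_stage_course("adaptive", duration_min=0, seed=0)

    def test_unstable_first_c_quartile_matches_chain_enumeration(self):
        """Fraction of unstable courses whose first C falls in quartile 1
        agrees with exact minute-resolution enumeration of the chain."""
        p = DEFAULT_COURSE_PARAMS["unstable"]
        # exact forward pass: distribution over scores, tracking the
        # probability that no C event fired during the first 5 minutes
        dist = {p.start: 1.0}
        no_fire = 0.0
        for _ in range(5):
            # weight current states by their per-minute no-fire probability
            new = {}
            for s, w in dist.items():
                w_keep = w * (1 - p.c_entry if s == SCORE_OF["B23"] else 1.0)
                down = s - 1 if s > p.floor else s
                up = s + 1 if s < p.ceiling else s
                stay = 1.0 - p.descend - p.ascend
                for s2, q in ((down, p.descend), (up, p.ascend), (s, stay)):
                    new[s2] = new.get(s2, 0.0) + w_keep * q
            dist = new
        no_fire = sum(dist.values())
        expected = 1.0 - no_fire
        n = 500
        hits = 0
        for seed in range(n):
            course = vg.simulate_stage_course("unstable", seed=seed)
            c_idx = np.flatnonzero(course.scores == SCORE_OF["C"])
            hits += c_idx.size > 0 and c_idx[0] < 300
        assert abs(hits / n - expected) <= 0.03


class TestRecordingSynthesis:
    def test_a1_course_has_occipital_alpha_dominance(self):
        course = vg.block_course([("A1", 60)])
        rec, _ = vg.simulate_recording(course, seed=11)
        post = rec.channels(("O1", "O2", "Pz"))
        front = rec.channels(("Fp1", "Fz", "F4"))
        p_post = band_power_epochs(post, rec.fs, (8, 12)).mean(axis=0)
        p_front = band_power_epochs(front, rec.fs, (8, 12)).mean(axis=0)
        assert (p_post > p_front).mean() >= 0.95

    def test_activated_wake_has_no_alpha_dominance(self, calib):
        course = vg.block_course([("0", 60)])
        rec, _ = vg.simulate_recording(course, seed=12)
        post = rec.channels(("O1", "O2", "Pz"))
        p_post = band_power_epochs(post, rec.fs, (8, 12)).mean(axis=0)
        assert (p_post < calib.alpha_threshold).all()

    def test_one_marker_per_c_second(self):
        labels = ["B23"] * 120
        labels[45] = "C"
        course = vg.StageSequence.from_labels(labels)
        _, markers = vg.simulate_recording(course, seed=13)
        assert len(markers) == 1
        sample, kind = markers[0]
        assert 45 * 200 <= sample < 46 * 200
        assert kind in ("SPINDLE", "KCOMPLEX")

    def test_missing_eog_rejected(self):
        course = vg.block_course([("A1", 10)])
        with pytest.raises(ValueError, match="EOG"):
            vg.simulate_recording(course, layout=vg.EEG_1020, seed=0)

    def test_empty_course_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            vg.simulate_recording(vg.StageSequence(scores=np.array([], dtype=int)),
                                  seed=0)


class TestCohort:
    def test_fixed_seed_reproduces_cohort_table(self):
        spec = vg.CohortSpec(n_per_group={"patient": 4, "control": 4},
                             duration_min=8, seed=5)
        a = vg.simulate_cohort(spec).table
        b = vg.simulate_cohort(spec).table
        assert a.equals(b)

    def test_group_sizes_and_ground_truth_recorded(self):
        spec = vg.CohortSpec(n_per_group={"patient": 6, "control": 3},
                             duration_min=8, seed=2)
        res = vg.simulate_cohort(spec)
        assert (res.table.group == "patient").sum() == 6
        assert set(res.table.true_type) <= set(vg.REGULATION_TYPES)
        assert len(res.courses) == 9

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="at least one subject"):
            vg.CohortSpec(n_per_group={"patient": 0, "control": 5})

    def test_mixture_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sums to"):
            vg.CohortSpec(group_mixtures={
                "patient": {"adaptive": 0.6, "stable": 0.6},
                "control": {"adaptive": 1.0},
            }, n_per_group={"patient": 3, "control": 3})

    def test_zero_noise_covariate_warns(self):
        with pytest.warns(UserWarning, match="zero noise"):
            vg.CohortSpec(covariate_model={
                "sleep_efficiency": vg.CovariateSpec(90.0, -2.0, 0.0)})

    def test_zero_slope_covariate_is_null_correlated(self):
        """With a flat covariate model the sample ASS-covariate correlation
        stays inside the permutation null band."""
        spec = vg.CohortSpec(
            n_per_group={"patient": 20, "control": 1},
            covariate_model={"flat": vg.CovariateSpec(50.0, 0.0, 5.0)},
            duration_min=8, seed=7)
        t = vg.simulate_cohort(spec).table
        t = t[t.group == "patient"]
        rho = vg.spearman(t.ass, t.flat, method="approx").statistic
        # permutation null band for n=20
        rng = np.random.default_rng(0)
        ranks_a = np.argsort(np.argsort(t.ass.to_numpy()))
        ranks_b = np.argsort(np.argsort(t.flat.to_numpy()))
        null = []
        a_c = ranks_a - ranks_a.mean()
        b_c = ranks_b - ranks_b.mean()
        denom = np.sqrt((a_c ** 2).sum() * (b_c ** 2).sum())
        for _ in range(2000):
            null.append(a_c @ rng.permutation(b_c) / denom)
        lo, hi = np.quantile(null, [0.025, 0.975])
        assert lo <= rho <= hi

    def test_strong_negative_slope_is_recovered(self):
        """A strong planted ASS->sleep-efficiency slope yields a negative
        Spearman correlation with one-sided p<0.05 in >=80% of replicates."""
        wins = 0
        n_rep = 200
        for r in range(n_rep):
            spec = vg.CohortSpec(
                n_per_group={"patient": 17, "control": 1},
                group_mixtures={
                    "patient": {"adaptive": 0.25, "unstable": 0.25,
                                "stable": 0.25, "hyperstable": 0.25},
                    "control": {"adaptive": 1.0},
                },
                covariate_model={
                    "sleep_efficiency": vg.CovariateSpec(95.0, -2.0, 5.0, 0, 100)},
                duration_min=8, seed=1000 + r)
            t = vg.simulate_cohort(spec).table
            t = t[t.group == "patient"]
            res = vg.spearman(t.ass, t.sleep_efficiency, tail="less",
                              method="approx")
            wins += (res.statistic < 0) and (res.p_value < 0.05)
        assert wins / n_rep >= 0.8
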