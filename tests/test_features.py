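"""Feature extraction: segmentation, normalization, excursions, assembly."""

import numpy as np
import pandas as pd
import pytest

from liftkin import features
from liftkin.errors import ConfigurationError, InputError, SegmentationError
from liftkin.records import kinematics_frame


def _kin_from_truth(truth):
    return kinematics_frame(truth.t, truth.joints_deg, truth.pt_mm)


class TestSegmentTask:
    def test_boundaries_within_3_samples(self, zero_noise_cohort):
        trial = zero_noise_cohort.trials[0]
        kin = _kin_from_truth(trial.truth)
        start, end = features.segment_task(kin)
        fs = 40.0
        true_start = trial.truth.events["start_s"] * fs
        true_end = trial.truth.events["end_s"] * fs
        assert abs(start - true_start) <= 3
        assert abs(end - true_end) <= 3

    def test_constant_series_rejected(self):
        t = np.arange(100) / 40.0
        joints = {j: np.zeros(100) for j in ("sacr", "hip_l", "hip_r", "knee_l", "knee_r", "ankle_l", "ankle_r")}
        kin = kinematics_frame(t, joints, np.zeros((100, 3)))
        with pytest.raises(SegmentationError):
            features.segment_task(kin)

    def test_marker_override_returned_verbatim(self, zero_noise_cohort):
        kin = _kin_from_truth(zero_noise_cohort.trials[0].truth)
        start, end = features.segment_task(kin, markers=(0.5, 4.5))
        assert (start, end) == (20, 180)


class TestTimeNormalize:
    def test_linear_ramp_preserved(self):
        x = np.linspace(0.0, 10.0, 81)
        y = features.time_normalize(x, 0, 80, n=101)
        assert y.shape == (101,)
        np.testing.assert_allclose(y, np.linspace(0.0, 10.0, 101), atol=1e-12)
        assert y[0] == x[0] and y[-1] == x[-1]

    def test_identity_when_lengths_match(self):
        x = np.sin(np.linspace(0, 3, 50))
        np.testing.assert_allclose(features.time_normalize(x, 0, 49, n=50), x, atol=1e-12)

    def test_sine_interpolation_error_small(self):
        t = np.linspace(0.0, 1.0, 161)
        x = np.sin(2 * np.pi * 2 * t)
        y = features.time_normalize(x, 0, 160, n=101)
        exact = np.sin(2 * np.pi * 2 * np.linspace(0, 1, 101))
        assert np.max(np.abs(y - exact)) < 0.005  # < 0.5% of unit amplitude

    def test_degenerate_window_rejected(self):
        with pytest.raises(InputError):
            features.time_normalize(np.arange(10.0), 4, 5)


class TestExcursionRange:
    def test_enumerated(self):
        assert features.excursion_range(np.array([1.0, 3.0, 2.0])) == 2.0
        assert features.excursion_range(np.full(7, 4.2)) == 0.0

    def test_full_period_sine(self):
        x = 3.5 * np.sin(np.linspace(0, 2 * np.pi, 101))
        assert features.excursion_range(x) == pytest.approx(7.0, rel=1e-3)

    def test_offset_invariance(self, rng):
        x = rng.normal(size=64)
        assert features.excursion_range(x + 123.4) == pytest.approx(features.excursion_range(x), abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            features.excursion_range(np.array([]))


class TestAssembly:
    @staticmethod
    def _toy_features(n_subjects=1, reps=1):
        rows = []
        rng = np.random.default_rng(0)
        for s in range(n_subjects):
            for posture in ("correct", "incorrect"):
                for load in (1.0,):
                    for rep in range(1, reps + 1):
                        row = {"subject": f"S{s}", "task": "LL", "posture": posture, "load": load, "rep": rep}
                        row.update({f: float(rng.uniform(1, 10)) for f in features.T_LL_FEATURES})
                        rows.append(row)
        return features.feature_table(rows)

    def test_row_counts_and_views(self):
        table = self._toy_features(n_subjects=1, reps=1)
        subs = features.assemble(table)
        (key, sub), = subs.items()
        assert key == ("LL", 1.0)
        assert len(sub) == 2  # 1 subject x 1 rep x 2 postures
        assert len(features.FEATURE_SETS["T-Ll"]) == 10
        assert len(features.FEATURE_SETS["UpB"]) == 4
        assert set(features.UPB_FEATURES) == {"pt_ap_exc", "pt_ml_exc", "pt_v_exc", "rom_sacr"}

    def test_assemble_partitions_trials(self, default_result):
        feats = default_result.features
        subs = features.assemble(feats)
        assert sum(len(s) for s in subs.values()) == len(feats)
        assert len(subs) == 6  # 2 tasks x 3 loads
        for (task, load), sub in subs.items():
            assert len(sub) == 26 * 3 * 2  # subjects x reps x postures
            assert set(sub["y"]) == {0, 1}

    def test_unknown_feature_set_rejected(self):
        with pytest.raises(ConfigurationError):
            features.assemble(self._toy_features(), feature_set="bogus")


class TestConditionMeans:
    def test_rep_average(self):
        rows = []
        for rep, val in zip((1, 2, 3), (10.0, 20.0, 30.0)):
            row = {"subject": "S1", "task": "LL", "posture": "correct", "load": 1.0, "rep": rep}
            row.update({f: val for f in features.T_LL_FEATURES})
            rows.append(row)
        cm = features.condition_means(features.feature_table(rows))
        assert len(cm) == 1
        assert cm["rom_knee_l"].iloc[0] == pytest.approx(20.0)

    def test_single_rep_passthrough(self):
        row = {"subject": "S1", "task": "LL", "posture": "correct", "load": 1.0, "rep": 1}
        row.update({f: 7.5 for f in features.T_LL_FEATURES})
        cm = features.condition_means(features.feature_table([row]))
        assert cm["rom_sacr"].iloc[0] == 7.5

    def test_cohort_knee_mean_near_commanded(self, default_result):
        """Subject-level mean under the correct posture tracks the commanded
        condition mean within 3 standard errors."""
        from liftkin.synth import CONDITION_TARGETS

        cond = default_result.condition_means
        sel = cond[(cond.task == "LL") & (cond.posture == "correct") & (cond.load == 1.0)]
        mean, sd = CONDITION_TARGETS[("LL", "correct")]["knee"]
        se = sd / np.sqrt(len(sel))
        assert abs(sel["rom_knee_r"].mean() - mean) < 3 * se


class TestZscore:
    def test_train_standardized(self, rng):
        x = pd.DataFrame(rng.normal(5, 3, size=(40, 4)), columns=list("abcd"))
        xt, xa, mean, sd = features.zscore(x)
        np.testing.assert_allclose(xt.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(xt.std(axis=0), 1.0, atol=1e-12)
        np.testing.assert_allclose(xt, xa)

    def test_apply_row_at_train_mean_is_zero(self, rng):
        x = rng.normal(size=(30, 3))
        _, xa, _, _ = features.zscore(x, apply=x.mean(axis=0, keepdims=True))
        np.testing.assert_allclose(xa, 0.0, atol=1e-12)

    def test_shift_invariance(self, rng):
        x = rng.normal(size=(30, 3))
        xt1, *_ = features.zscore(x)
        xt2, *_ = features.zscore(x + np.array([10.0, -3.0, 0.5]))
        np.testing.assert_allclose(xt1, xt2, atol=1e-9)

    def test_zero_variance_feature_named(self):
        x = pd.DataFrame({"good": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(ConfigurationError, match="flat"):
            features.zscore(x)


def test_reparameterization_invariance(zero_noise_cohort):
    """RoM/excursion features depend on extrema only, so a uniform time
    re-parameterization of the trial leaves the features unchanged."""
    trial = zero_noise_cohort.trials[0]
    kin = _kin_from_truth(trial.truth)
    f1 = features.build_features(kin)
    slow = kin.iloc[np.repeat(np.arange(len(kin)), 2)].reset_index(drop=True)
    slow["time_s"] = np.arange(len(slow)) / 40.0
    f2 = features.build_features(slow)
    for name in features.T_LL_FEATURES:
        assert f2[name] == pytest.approx(f1[name], rel=0.02, abs=0.5)
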