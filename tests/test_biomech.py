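"""Biomechanical model: filter contract, calibration, angles, displacement."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from liftkin import biomech, synth
from liftkin.errors import CalibrationError, ConfigurationError, InputError
from liftkin.frames import SEGMENTS, nominal_mounting, rot_ml, rotation_angle_deg
from liftkin.records import SegmentPose


def _tone_gain(f, fs, method="fft", fc=10.0, seconds=8.0):
    t = np.arange(int(seconds * fs)) / fs
    x = np.sin(2 * np.pi * f * t)
    y = biomech.lowpass(x, fs, fc=fc, method=method)
    mid = slice(len(t) // 4, 3 * len(t) // 4)  # avoid edge transients
    return np.max(np.abs(y[mid]))


class TestLowpass:
    def test_dc_gain_unity(self):
        x = np.full(400, 3.7)
        assert np.max(np.abs(biomech.lowpass(x, 40.0) - 3.7)) < 1e-9

    def test_minus_3db_at_cutoff(self):
        assert _tone_gain(10.0, 40.0) == pytest.approx(1 / np.sqrt(2), rel=0.05)

    def test_second_order_rolloff_at_twice_cutoff(self):
        # analog Butterworth magnitude 1/sqrt(1+(f/fc)^4) at f = 2 fc
        assert _tone_gain(20.0, 80.0) == pytest.approx(1 / np.sqrt(17), rel=0.10)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ConfigurationError):
            biomech.lowpass(np.zeros(100), fs=15.0, fc=10.0)

    def test_filtfilt_variant_runs_and_preserves_dc(self):
        x = np.full(400, -2.0)
        y = biomech.lowpass(x, 40.0, method="filtfilt")
        assert np.max(np.abs(y + 2.0)) < 1e-9


class TestDisplacement:
    def test_identity_rotation(self):
        pt = biomech.trunk_pelvis_displacement(Rotation.identity(), 500.0)
        np.testing.assert_allclose(pt, [[0.0, 0.0, 1000.0]], atol=1e-12)

    def test_90deg_flexion_matches_homogeneous_oracle(self):
        r = rot_ml(90.0)
        pt = biomech.trunk_pelvis_displacement(r, 500.0)[0]
        np.testing.assert_allclose(pt, [500.0, 0.0, 500.0], atol=1e-9)
        # brute-force 4x4 homogeneous-transform arithmetic
        R = r.as_matrix()[0]
        o = np.array([0.0, 0.0, 500.0])
        T = np.eye(4)
        T[:3, :3], T[:3, 3] = R, o
        Tinv = np.linalg.inv(T)
        expected = o - Tinv[:3, 3]  # PT = o − (translation of the inverse transform)
        np.testing.assert_allclose(pt, [expected[1], expected[0], expected[2]], atol=1e-9)

    @pytest.mark.parametrize("angle", [-80.0, -15.0, 10.0, 45.0, 120.0])
    def test_homogeneity_in_trunk_length(self, angle):
        r = rot_ml(np.array([angle, angle / 2]))
        a = biomech.trunk_pelvis_displacement(r, 250.0)
        b = biomech.trunk_pelvis_displacement(r, 500.0)
        np.testing.assert_allclose(b, 2.0 * a, rtol=1e-12, atol=1e-9)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ConfigurationError):
            biomech.trunk_pelvis_displacement(Rotation.identity(), 0.0)


class TestJointAngles:
    @staticmethod
    def _poses(n, rotations):
        t = np.arange(n) / 40.0
        return SegmentPose(t=t, rotations=rotations)

    def test_identity_gives_zero(self):
        r = Rotation.identity(5)
        poses = self._poses(5, {seg: r for seg in SEGMENTS})
        angles = biomech.joint_angles(poses)
        for v in angles.values():
            np.testing.assert_allclose(v, 0.0, atol=1e-12)

    def test_pure_sagittal_rotation_recovered(self):
        base = {seg: Rotation.identity(1) for seg in SEGMENTS}
        base["trunk"] = rot_ml(30.0)  # lumbosacral flexion of 30 deg
        angles = biomech.joint_angles(self._poses(1, base))
        assert angles["sacr"][0] == pytest.approx(30.0, abs=1e-9)

    def test_invariance_under_common_world_rotation(self, rng):
        world = Rotation.from_rotvec(rng.normal(size=3))
        phi = rng.uniform(-60, 60, size=len(SEGMENTS))
        base = {seg: rot_ml(np.full(3, p)) for seg, p in zip(SEGMENTS, phi)}
        rotated = {seg: world * r for seg, r in base.items()}
        a = biomech.joint_angles(self._poses(3, base))
        b = biomech.joint_angles(self._poses(3, rotated))
        for j in a:
            np.testing.assert_allclose(a[j], b[j], atol=1e-9)

    def test_missing_segment_rejected(self):
        poses = self._poses(1, {"pelvis": Rotation.identity(1)})
        with pytest.raises(InputError):
            biomech.joint_angles(poses)


class TestCalibration:
    def test_exact_nominal_mounting_recovered(self, zero_noise_fmap):
        nominal = nominal_mounting()
        for seg in SEGMENTS:
            err = rotation_angle_deg(zero_noise_fmap.maps[seg] * nominal[seg].inv())[0]
            assert err < 1e-6

    def test_injected_misalignment_recovered_within_1deg(self):
        spec = synth.CohortSpec.noise_free(n_subjects=1, misalignment_deg=5.0, seed=11)
        rng = np.random.default_rng(11)
        subj = synth.draw_subject(spec, rng)
        standing, sitting = synth.simulate_calibration(subj, rng)
        fmap = biomech.functional_calibration(standing, sitting)
        nominal = nominal_mounting()
        for seg in SEGMENTS:
            true = nominal[seg] * subj.misalignment[seg]
            err = rotation_angle_deg(fmap.maps[seg] * true.inv())[0]
            assert err < 1.0, f"{seg}: {err:.2f} deg"

    def test_tilted_standing_capture_flagged(self, zero_noise_cohort):
        subj = zero_noise_cohort.subjects[0]
        standing, sitting = synth.simulate_calibration(subj, np.random.default_rng(0))
        tilt = rot_ml(30.0)
        tilted = {
            seg: type(s)(s.sensor_id, s.t, (tilt * s.rotations()).as_quat(scalar_first=True), s.fs_hz)
            for seg, s in standing.streams.items()
        }
        standing_tilted = type(standing)(pose="standing", streams=tilted)
        with pytest.warns(UserWarning, match="nominal mounting"):
            fmap = biomech.functional_calibration(standing_tilted, sitting, nominal=nominal_mounting())
        assert fmap.warnings

    def test_motion_during_capture_rejected(self, zero_noise_cohort):
        subj = zero_noise_cohort.subjects[0]
        standing, sitting = synth.simulate_calibration(subj, np.random.default_rng(0))
        s = standing.streams["pelvis"]
        wobble = rot_ml(np.linspace(0, 20, len(s)))
        moved = type(s)(s.sensor_id, s.t, (wobble * s.rotations()).as_quat(scalar_first=True), s.fs_hz)
        bad = type(standing)(pose="standing", streams={**standing.streams, "pelvis": moved})
        with pytest.raises(CalibrationError):
            biomech.functional_calibration(bad, sitting)


class TestRoundTrip:
    def test_zero_noise_end_to_end(self, zero_noise_cohort, zero_noise_fmap):
        """Calibration → poses → angles reproduces ground truth to <0.5 deg."""
        for trial in zero_noise_cohort.trials[:6]:
            kin = biomech.process_trial(trial.recording, zero_noise_fmap)
            for joint, truth in trial.truth.joints_deg.items():
                err = np.max(np.abs(kin[f"{joint}_deg"].to_numpy() - truth))
                assert err < 0.5, f"{joint}: {err:.3f} deg"
                rom_err = abs(np.ptp(kin[f"{joint}_deg"].to_numpy()) - np.ptp(truth))
                assert rom_err < 0.5
            pt = kin[["pt_ap_mm", "pt_ml_mm", "pt_v_mm"]].to_numpy()
            exc_err = np.abs(np.ptp(pt, axis=0) - np.ptp(trial.truth.pt_mm, axis=0))
            assert np.max(exc_err) < 1.0

    def test_poses_orthonormal(self, zero_noise_cohort, zero_noise_fmap):
        rec = zero_noise_cohort.trials[0].recording
        poses = biomech.segment_poses(rec, zero_noise_fmap)
        for r in poses.rotations.values():
            dets = np.linalg.det(r.as_matrix())
            np.testing.assert_allclose(dets, 1.0, atol=1e-9)
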