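"""Wavelet denoising, EKF fusion, diameter extraction and rectification."""

import numpy as np
import pytest

from cocorod import EKFConfig, SensorTrace, SynthSpec, TrunkGeometry, \
    diameter_from_ultrasonic, ekf_fuse, extract_tree_parameters, \
    process_trace, rectify_anomalies, synth_climber_trace, wavelet_denoise
from cocorod.sensor_pipeline import PoseTrace, sure_threshold


class TestWaveletDenoise:
    def test_zero_signal_stays_zero(self):
        out = wavelet_denoise(np.zeros(256))
        np.testing.assert_allclose(out, 0.0, atol=1e-14)

    def test_lossless_roundtrip_without_thresholding(self, rng):
        sig = rng.normal(size=1000)
        out = wavelet_denoise(sig, threshold=False)
        np.testing.assert_allclose(out, sig, atol=1e-10)

    def test_sure_shrinkage_reduces_noise_on_ramp(self):
        rng = np.random.default_rng(42)
        clean = np.linspace(0.0, 10.0, 1024)
        noisy = clean + rng.normal(0.0, 0.1, 1024)
        out = wavelet_denoise(noisy)
        rmse_in = np.sqrt(np.mean((noisy - clean) ** 2))
        rmse_out = np.sqrt(np.mean((out - clean) ** 2))
        assert rmse_out <= rmse_in

    def test_sure_threshold_zero_for_zero_sigma(self):
        assert sure_threshold(np.arange(16.0), 0.0) == 0.0

    def test_rejects_short_signal(self):
        with pytest.raises(ValueError):
            wavelet_denoise(np.zeros(4))


def _static_trace(n=500, rate=50.0, heading=0.3, g=9.8, sigma=0.0, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(n) / rate
    accel = rng.normal(0.0, sigma, (n, 3))
    accel[:, 2] += g
    gyro = rng.normal(0.0, sigma / 10 if sigma else 0.0, (n, 3))
    mag = rng.normal(0.0, sigma / 5 if sigma else 0.0, (n, 3))
    mag[:, 0] += np.cos(heading)
    mag[:, 1] += np.sin(heading)
    return SensorTrace(t=t, accel=accel, gyro=gyro, mag=mag,
                       us_left=np.full(n, 0.2), us_right=np.full(n, 0.2))


class TestEkfFuse:
    def test_static_pose_drift_bounded(self):
        pose = ekf_fuse(_static_trace(sigma=0.05, seed=1))
        # at rest the position drift must stay inside the filter's own
        # 3-sigma envelope (consistency of the reported covariance)
        sigma_h = np.sqrt(pose.covariances[-1][0, 0])
        sigma_x = np.sqrt(pose.covariances[-1][4, 4])
        assert abs(pose.height[-1]) < 3.0 * sigma_h
        assert abs(pose.horizontal[-1]) < 3.0 * sigma_x
        np.testing.assert_allclose(pose.heading, 0.3, atol=0.05)

    def test_constant_velocity_ascent_recovers_height(self, wct_geometry):
        spec = SynthSpec(seed=11, n_slips=0, n_scars=0, climb_height=12.0)
        trace, truth = synth_climber_trace(spec, wct_geometry)
        cfg = EKFConfig(nominal_climb_speed=spec.climb_speed)
        pose = ekf_fuse(trace, cfg)
        assert pose.height[-1] == pytest.approx(truth.total_height, rel=0.05)

    def test_covariances_remain_symmetric_psd(self):
        pose = ekf_fuse(_static_trace(n=200, sigma=0.05, seed=2))
        for P in pose.covariances[::20]:
            np.testing.assert_allclose(P, P.T, atol=1e-9)
            assert np.linalg.eigvalsh(P).min() > -1e-9

    def test_innovations_zero_mean_on_matched_data(self, wct_geometry):
        spec = SynthSpec(seed=5, n_slips=0, n_scars=0)
        trace, _ = synth_climber_trace(spec, wct_geometry)
        pose = ekf_fuse(trace)
        innov = pose.innovations[250:]  # drop the launch-ramp transient
        for j in range(innov.shape[1]):
            se = innov[:, j].std() / np.sqrt(innov.shape[0])
            assert abs(innov[:, j].mean()) < 2.0 * se + 1e-6

    def test_rejects_bad_covariance_config(self):
        with pytest.raises(ValueError):
            ekf_fuse(_static_trace(n=50), EKFConfig(r_accel=0.0))


class TestDiameterFromUltrasonic:
    def test_trunk_filling_frame(self):
        d, bad = diameter_from_ultrasonic([0.0], [0.0], 0.6)
        assert d[0] == 0.6 and not bad[0]

    def test_forced_arithmetic(self):
        d, bad = diameter_from_ultrasonic([0.2], [0.2], 0.6)
        assert d[0] == pytest.approx(0.2, abs=1e-15)

    def test_inconsistent_geometry_flagged_not_fatal(self):
        d, bad = diameter_from_ultrasonic([0.4], [0.3], 0.6)
        assert bad[0] and d[0] < 0

    def test_taper_slope_recovered_from_descent(self, wct_geometry):
        spec = SynthSpec(seed=7, n_slips=0, n_scars=0, climb_height=10.0)
        trace, truth = synth_climber_trace(spec, wct_geometry)
        d, _ = diameter_from_ultrasonic(trace.us_left, trace.us_right,
                                        spec.frame_span)
        # taper slope: fit diameter against true height, compare to truth
        slope_est = np.polyfit(truth.height, d, 1)[0]
        slope_true = np.polyfit(truth.height, truth.diameter, 1)[0]
        assert slope_est == pytest.approx(slope_true, rel=0.10)


class TestRectifyAnomalies:
    def test_clean_monotone_input_unchanged(self):
        h = np.linspace(0.0, 5.0, 200)
        d = np.full(200, 0.2)
        h2, d2, flagged = rectify_anomalies(h, d)
        np.testing.assert_allclose(h2, h, atol=1e-12)
        np.testing.assert_allclose(d2, d, atol=1e-12)
        assert flagged == 0

    def test_scar_spike_replaced(self):
        d = np.full(200, 0.2)
        d[77] += 1.0
        h = np.linspace(0.0, 5.0, 200)
        _, d2, flagged = rectify_anomalies(h, d)
        assert abs(d2[77] - 0.2) < 1e-3
        assert flagged >= 1

    def test_height_dip_matches_pava_oracle(self):
        # brute-force pool-adjacent-violators as the independent oracle
        def pava(y):
            y = list(map(float, y))
            w = [1.0] * len(y)
            blocks = [[v, wt] for v, wt in zip(y, w)]
            i = 0
            while i < len(blocks) - 1:
                if blocks[i][0] > blocks[i + 1][0] + 1e-15:
                    v = (blocks[i][0] * blocks[i][1]
                         + blocks[i + 1][0] * blocks[i + 1][1])
                    wt = blocks[i][1] + blocks[i + 1][1]
                    blocks[i] = [v / wt, wt]
                    del blocks[i + 1]
                    i = max(i - 1, 0)
                else:
                    i += 1
            out = []
            for v, wt in blocks:
                out.extend([v] * int(round(wt)))
            return np.array(out)

        h = np.array([0.0, 0.5, 1.0, 0.6, 1.2, 1.1, 1.5, 2.0])
        d = np.full(8, 0.2)
        h2, _, _ = rectify_anomalies(h, d)
        np.testing.assert_allclose(h2, pava(h), atol=1e-12)
        assert np.all(np.diff(h2) >= 0)

    def test_rectified_height_always_monotone(self, rng):
        h = np.cumsum(rng.normal(0.05, 0.1, 500))
        h2, _, _ = rectify_anomalies(h, np.full(500, 0.2))
        assert np.all(np.diff(h2) >= -1e-12)


class TestExtractTreeParameters:
    def test_vertical_climb_recovers_height_and_taper(self, wct_geometry):
        spec = SynthSpec(seed=13, climb_height=10.0)
        trace, truth = synth_climber_trace(spec, wct_geometry)
        meas = process_trace(trace, frame_span=spec.frame_span,
                             climb_speed=spec.climb_speed)
        assert meas.total_height == pytest.approx(truth.total_height,
                                                  rel=0.05)
        # denoised + rectified diameter profile must slope downward
        slope = np.polyfit(meas.heights, meas.diameters, 1)[0]
        assert slope < 0

    def test_heading_constant_within_noise(self, wct_geometry):
        spec = SynthSpec(seed=17, n_slips=0, n_scars=0)
        trace, truth = synth_climber_trace(spec, wct_geometry)
        meas = process_trace(trace, frame_span=spec.frame_span,
                             climb_speed=spec.climb_speed)
        np.testing.assert_allclose(meas.heading, truth.heading, atol=0.05)

    def test_zero_motion_trace_gives_zero_height(self):
        trace = _static_trace(n=300)
        pose = ekf_fuse(trace)
        d, _ = diameter_from_ultrasonic(trace.us_left, trace.us_right, 0.6)
        meas = extract_tree_parameters(pose, d)
        assert meas.total_height == pytest.approx(0.0, abs=1e-6)
        assert meas.heights.size == 1

    def test_mismatched_time_base_rejected(self):
        pose = PoseTrace(t=np.arange(5.0), height=np.zeros(5),
                         horizontal=np.zeros(5), heading=np.zeros(5),
                         innovations=np.zeros((5, 4)))
        with pytest.raises(ValueError):
            extract_tree_parameters(pose, np.zeros(4))


class TestTraceIO:
    def test_csv_roundtrip(self, tmp_path, wct_geometry):
        spec = SynthSpec(seed=3, climb_height=2.0)
        trace, _ = synth_climber_trace(spec, wct_geometry)
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        back = SensorTrace.from_csv(path)
        np.testing.assert_allclose(back.accel, trace.accel, atol=1e-12)
        np.testing.assert_allclose(back.us_left, trace.us_left, atol=1e-12)

    def test_rejects_wrong_columns(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("a,b\n1,2\n")
        with pytest.raises(ValueError):
            SensorTrace.from_csv(p)

    def test_rejects_non_increasing_timestamps(self):
        with pytest.raises(ValueError):
            SensorTrace(t=np.array([0.0, 0.0, 1.0]),
                        accel=np.zeros((3, 3)), gyro=np.zeros((3, 3)),
                        mag=np.zeros((3, 3)), us_left=np.zeros(3),
                        us_right=np.zeros(3))
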