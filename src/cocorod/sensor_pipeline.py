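"""Climber sensor processing: from raw logs to tree parameters.

A tree-climbing robot logs a 9-axis IMU (accelerometer, gyroscope,
magnetometer) and two ultrasonic range sensors facing the trunk from
opposite sides of a rigid frame.  The processing chain mirrors standard
robot-odometry practice:

1. wavelet denoising of each channel (Daubechies family, per-level soft
   thresholds chosen by Stein's Unbiased Risk Estimate, noise scale from
   the median absolute deviation of the finest detail coefficients);
2. sensor fusion with an extended Kalman filter whose state transition is
   a degree-3 polynomial (constant-jerk) kinematic model per axis, with
   heading observed by the magnetometer and its rate by the gyroscope;
3. trunk diameter from the frame span minus the two ultrasonic distances;
4. rectification of slip/scar artifacts: Hampel outlier replacement on the
   diameter stream and isotonic projection of the height stream (heights
   must increase steadily during an ascent);
5. resampling everything onto the height axis to emit the tree
   measurement (height, horizontal shift, heading, diameter profile).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import pywt
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "SensorTrace",
    "TreeMeasurement",
    "EKFConfig",
    "wavelet_denoise",
    "sure_threshold",
    "ekf_fuse",
    "diameter_from_ultrasonic",
    "rectify_anomalies",
    "extract_tree_parameters",
    "process_trace",
]

TRACE_COLUMNS = ["t_s", "ax", "ay", "az", "gx", "gy", "gz",
                 "mx", "my", "mz", "us_left_m", "us_right_m"]
MEASUREMENT_COLUMNS = ["height_m", "horizontal_shift_m", "heading_rad",
                       "diameter_m"]
_MAD_TO_SIGMA = 0.6745


@dataclass
class SensorTrace:
    """Raw climber log: timestamps, IMU channels and ultrasonic ranges."""

    t: np.ndarray
    accel: np.ndarray    # (n, 3) m/s^2, gravity included on the climb axis
    gyro: np.ndarray     # (n, 3) rad/s
    mag: np.ndarray      # (n, 3) normalized
    us_left: np.ndarray  # (n,) m
    us_right: np.ndarray  # (n,) m

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(self.us_left < 0) or np.any(self.us_right < 0):
            raise ValueError("ultrasonic distances must be non-negative")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({
            "t_s": self.t,
            "ax": self.accel[:, 0], "ay": self.accel[:, 1],
            "az": self.accel[:, 2],
            "gx": self.gyro[:, 0], "gy": self.gyro[:, 1],
            "gz": self.gyro[:, 2],
            "mx": self.mag[:, 0], "my": self.mag[:, 1],
            "mz": self.mag[:, 2],
            "us_left_m": self.us_left, "us_right_m": self.us_right,
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SensorTrace":
        df = pd.read_csv(path)
        if list(df.columns) != TRACE_COLUMNS:
            raise ValueError(
                f"sensor log must have columns {TRACE_COLUMNS}, "
                f"got {list(df.columns)}")
        return cls(
            t=df["t_s"].to_numpy(),
            accel=df[["ax", "ay", "az"]].to_numpy(),
            gyro=df[["gx", "gy", "gz"]].to_numpy(),
            mag=df[["mx", "my", "mz"]].to_numpy(),
            us_left=df["us_left_m"].to_numpy(),
            us_right=df["us_right_m"].to_numpy(),
        )


@dataclass
class TreeMeasurement:
    """Extracted tree parameters on a common height axis."""

    heights: np.ndarray           # m, non-decreasing
    horizontal_shift: np.ndarray  # m
    heading: np.ndarray           # rad
    diameters: np.ndarray         # m

    @property
    def total_height(self) -> float:
        return float(self.heights.max()) if self.heights.size else 0.0

    def diameter_at(self, height: float) -> float:
        return float(np.interp(height, self.heights, self.diameters))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({
            "height_m": self.heights,
            "horizontal_shift_m": self.horizontal_shift,
            "heading_rad": self.heading,
            "diameter_m": self.diameters,
        }).to_csv(path, index=False)


def sure_threshold(coeffs: np.ndarray, sigma: float) -> float:
    """Soft threshold minimizing Stein's unbiased risk estimate.

    Works on one detail-coefficient band; candidate thresholds are the
    sorted coefficient magnitudes (in sigma units).
    """
    n = coeffs.size
    if n == 0 or sigma == 0:
        return 0.0
    x2 = np.sort((coeffs / sigma) ** 2)
    cum = np.concatenate([[0.0], np.cumsum(x2)])
    ks = np.arange(n + 1)
    # risk of thresholding at t^2 = x2[k-1] (0 for k = 0)
    t2 = np.concatenate([[0.0], x2])
    risk = (n - 2.0 * ks + cum + (n - ks) * t2) / n
    return float(sigma * np.sqrt(t2[np.argmin(risk)]))


def wavelet_denoise(signal: np.ndarray, wavelet: str = "db4",
                    level: int = 4, threshold: bool = True) -> np.ndarray:
    """Denoise one channel by SURE-thresholded Daubechies shrinkage.

    The noise scale is estimated once from the finest detail band as
    MAD/0.6745; each detail band is then soft-thresholded at its own SURE
    threshold and the signal rebuilt by the inverse transform.  With
    ``threshold=False`` the transform round-trips unchanged (perfect
    reconstruction).
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1 or signal.size < 8:
        raise ValueError("signal must be 1-D with at least 8 samples")
    level = min(level, pywt.dwt_max_level(signal.size,
                                          pywt.Wavelet(wavelet).dec_len))
    coeffs = pywt.wavedec(signal, wavelet, level=level)
    if threshold:
        finest = coeffs[-1]
        sigma = float(np.median(np.abs(finest))) / _MAD_TO_SIGMA
        if sigma > 0:
            coeffs = [coeffs[0]] + [
                pywt.threshold(c, sure_threshold(c, sigma), mode="soft")
                for c in coeffs[1:]
            ]
    out = pywt.waverec(coeffs, wavelet)
    return out[: signal.size]


@dataclass
class EKFConfig:
    """Noise configuration of the fusion filter.

    ``q_jerk`` is the white jerk-rate process intensity per kinematic axis
    ((m/s^3)^2 s^-1-like discrete intensity); measurement variances are
    per denoised channel.  Initial variances follow the diagonal
    position/orientation initialization convention.
    """

    q_jerk: float = 0.05
    q_heading: float = 1e-4
    r_accel: float = 0.05**2
    r_gyro: float = 0.01**2
    r_mag: float = 0.02**2
    p0_pos: float = 1e-4
    p0_kin: float = 0.01
    p0_heading: float = 1e-2
    gravity: float = 9.8
    # optional motion-model constraint: the commanded ascent speed of the
    # climb controller, applied as a weak per-sample velocity
    # pseudo-measurement.  Pure accelerometer dead reckoning accumulates a
    # position random walk; constraining the velocity to the commanded
    # speed (loosely, so slips and ramps are still tracked through the
    # accelerometer) bounds that drift.  None disables the constraint.
    nominal_climb_speed: float | None = None
    r_climb_speed: float = 0.05**2

    def validate(self) -> None:
        vals = [self.q_jerk, self.q_heading, self.r_accel, self.r_gyro,
                self.r_mag, self.p0_pos, self.p0_kin, self.p0_heading]
        if any(v <= 0 for v in vals):
            raise ValueError("all covariance configuration values must be "
                             "positive")


@dataclass
class PoseTrace:
    """Fused pose estimate per sample, with filter diagnostics."""

    t: np.ndarray
    height: np.ndarray            # m, vertical displacement since start
    horizontal: np.ndarray        # m
    heading: np.ndarray           # rad
    innovations: np.ndarray       # (n, n_meas)
    covariances: np.ndarray = field(repr=False, default=None)  # (n, 10, 10)


def _kinematic_blocks(dt: float, q: float) -> tuple[np.ndarray, np.ndarray]:
    """Constant-jerk (degree-3 polynomial) transition and process noise."""
    F = np.array([
        [1.0, dt, dt**2 / 2.0, dt**3 / 6.0],
        [0.0, 1.0, dt, dt**2 / 2.0],
        [0.0, 0.0, 1.0, dt],
        [0.0, 0.0, 0.0, 1.0],
    ])
    g = np.array([dt**4 / 24.0, dt**3 / 6.0, dt**2 / 2.0, dt])
    return F, q * np.outer(g, g)


def ekf_fuse(trace: SensorTrace, config: EKFConfig | None = None,
             denoise: bool = True) -> PoseTrace:
    """Fuse IMU channels into a pose trace (height, horizontal, heading).

    State (10): [h, vh, ah, jh, x, vx, ax, jx, psi, psi_dot] — two
    constant-jerk kinematic chains (vertical and horizontal) plus heading.
    Measurements per sample: vertical specific force minus gravity,
    horizontal acceleration, magnetometer heading atan2(my, mx), and
    gyro heading rate.  The covariance update uses the Joseph form so the
    covariance stays symmetric positive semi-definite.
    """
    cfg = config or EKFConfig()
    cfg.validate()
    t = trace.t
    n = t.size
    az = trace.accel[:, 2]
    axh = trace.accel[:, 0]
    gz = trace.gyro[:, 2]
    mx, my = trace.mag[:, 0], trace.mag[:, 1]
    if denoise and n >= 8:
        az = wavelet_denoise(az)
        axh = wavelet_denoise(axh)
        gz = wavelet_denoise(gz)
        mx = wavelet_denoise(mx)
        my = wavelet_denoise(my)
    psi_meas = np.unwrap(np.arctan2(my, mx))

    x = np.zeros(10)
    x[8] = psi_meas[0]
    P = np.diag([cfg.p0_pos, cfg.p0_kin, cfg.p0_kin, cfg.p0_kin,
                 cfg.p0_pos, cfg.p0_kin, cfg.p0_kin, cfg.p0_kin,
                 cfg.p0_heading, cfg.p0_heading])
    H = np.zeros((4, 10))
    H[0, 2] = 1.0   # vertical acceleration
    H[1, 6] = 1.0   # horizontal acceleration
    H[2, 8] = 1.0   # heading
    H[3, 9] = 1.0   # heading rate
    R = np.diag([cfg.r_accel, cfg.r_accel, cfg.r_mag, cfg.r_gyro])
    I10 = np.eye(10)

    height = np.zeros(n)
    horiz = np.zeros(n)
    heading = np.zeros(n)
    innov = np.zeros((n, 4))
    covs = np.zeros((n, 10, 10))
    heading[0] = x[8]
    covs[0] = P

    for i in range(1, n):
        dt = t[i] - t[i - 1]
        Fk, Qk = _kinematic_blocks(dt, cfg.q_jerk)
        F = np.zeros((10, 10))
        F[:4, :4] = Fk
        F[4:8, 4:8] = Fk
        F[8:, 8:] = np.array([[1.0, dt], [0.0, 1.0]])
        Q = np.zeros((10, 10))
        Q[:4, :4] = Qk
        Q[4:8, 4:8] = Qk
        gh = np.array([dt**2 / 2.0, dt])
        Q[8:, 8:] = cfg.q_heading * np.outer(gh, gh)

        x = F @ x
        P = F @ P @ F.T + Q

        z = np.array([az[i] - cfg.gravity, axh[i], psi_meas[i], gz[i]])
        y = z - H @ x
        S = H @ P @ H.T + R
        K = P @ H.T @ np.linalg.solve(S, np.eye(4))
        x = x + K @ y
        KH = I10 - K @ H
        P = KH @ P @ KH.T + K @ R @ K.T  # Joseph form

        if cfg.nominal_climb_speed is not None and \
                x[1] > 0.5 * cfg.nominal_climb_speed:
            # scalar update on the vertical velocity: while the estimate is
            # in the cruise regime the commanded climb speed bounds the
            # dead-reckoning drift; outside it (launch ramp, slip stalls —
            # both brief) the accelerometer evidence rules alone, so the
            # constraint never fights a genuine stall.
            y_v = cfg.nominal_climb_speed - x[1]
            S_v = P[1, 1] + cfg.r_climb_speed
            K_v = P[:, 1] / S_v
            x = x + K_v * y_v
            KHv = I10 - np.outer(K_v, np.eye(10)[1])
            P = KHv @ P @ KHv.T + cfg.r_climb_speed * np.outer(K_v, K_v)

        height[i] = x[0]
        horiz[i] = x[4]
        heading[i] = x[8]
        innov[i] = y
        covs[i] = P

    return PoseTrace(t=t, height=height, horizontal=horiz, heading=heading,
                     innovations=innov, covariances=covs)


def diameter_from_ultrasonic(us_left, us_right, frame_span: float
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Trunk diameter from two opposed range sensors on a rigid frame.

    diameter = frame_span - us_left - us_right.  Samples where the
    geometry is inconsistent (negative diameter) are flagged, not fatal:
    they are handed to rectification.

    Returns ``(diameter, invalid_mask)``.
    """
    us_left = np.asarray(us_left, dtype=float)
    us_right = np.asarray(us_right, dtype=float)
    if frame_span <= 0:
        raise ValueError("frame span must be positive")
    d = frame_span - us_left - us_right
    return d, d < 0


def _pava_isotonic(y: np.ndarray) -> np.ndarray:
    ir = IsotonicRegression(increasing=True, out_of_bounds="clip")
    return ir.fit_transform(np.arange(y.size), y)


def rectify_anomalies(height: np.ndarray, diameter: np.ndarray,
                      window: int = 11, n_mad: float = 3.0
                      ) -> tuple[np.ndarray, np.ndarray, int]:
    """Rectify slip/scar artifacts in the measurement streams.

    Diameter: Hampel filter — a sample farther than ``n_mad`` scaled MADs
    from its centred rolling median (window 11) is replaced by that
    median.  Height: isotonic projection enforcing a steady increase over
    time.  Returns ``(height_rectified, diameter_rectified, n_flagged)``.
    """
    height = np.asarray(height, dtype=float)
    diameter = np.asarray(diameter, dtype=float)
    d = diameter.copy()
    n = d.size
    if n >= window:
        med = pd.Series(d).rolling(window, center=True, min_periods=1)\
            .median().to_numpy()
        mad = pd.Series(np.abs(d - med)).rolling(
            window, center=True, min_periods=1).median().to_numpy()
        sigma = mad / _MAD_TO_SIGMA
        floor = 1e-12
        bad = np.abs(d - med) > n_mad * np.maximum(sigma, floor)
        d[bad] = med[bad]
        n_flagged = int(bad.sum())
    else:
        n_flagged = 0
    h = _pava_isotonic(height)
    n_flagged += int(np.sum(~np.isclose(h, height)))
    return h, d, n_flagged


def extract_tree_parameters(pose: PoseTrace, diameter: np.ndarray,
                            start_height: float = 0.0,
                            height_step: float = 0.1) -> TreeMeasurement:
    """Resample rectified streams onto the height axis.

    ``pose`` and ``diameter`` must share the trace's time base.  Heights
    are offset by the climb's known start height (0 for a ground start).
    """
    if pose.t.size != np.asarray(diameter).size:
        raise ValueError("pose trace and diameter stream must share one "
                         "time base")
    h = np.asarray(pose.height, dtype=float) + start_height
    if h.size == 0 or np.ptp(h) <= 0:
        return TreeMeasurement(heights=np.array([start_height]),
                               horizontal_shift=np.array([0.0]),
                               heading=np.array([pose.heading[0] if
                                                 pose.heading.size else 0.0]),
                               diameters=np.asarray(diameter[:1], dtype=float))
    h_mono = np.maximum.accumulate(h)
    grid = np.arange(h_mono[0], h_mono[-1] + height_step / 2, height_step)
    if grid[-1] < h_mono[-1] - 1e-9:
        grid = np.append(grid, h_mono[-1])
    return TreeMeasurement(
        heights=grid,
        horizontal_shift=np.interp(grid, h_mono, pose.horizontal),
        heading=np.interp(grid, h_mono, pose.heading),
        diameters=np.interp(grid, h_mono, np.asarray(diameter, dtype=float)),
    )


def process_trace(trace: SensorTrace, frame_span: float,
                  config: EKFConfig | None = None,
                  start_height: float = 0.0,
                  climb_speed: float | None = None) -> TreeMeasurement:
    """Full pipeline: denoise + fuse + diameter + rectify + extract.

    ``climb_speed``, when given, is the commanded ascent speed of the
    climb controller, used as a weak velocity constraint in the fusion
    filter (see :class:`EKFConfig`).  The diameter stream is rectified
    (Hampel) on the raw samples first so isolated scar spikes are excised
    before the wavelet smoother can smear them, then denoised.
    """
    cfg = config or EKFConfig()
    if climb_speed is not None:
        cfg = replace(cfg, nominal_climb_speed=climb_speed)
    pose = ekf_fuse(trace, config=cfg)
    diam, _ = diameter_from_ultrasonic(trace.us_left, trace.us_right,
                                       frame_span)
    h_rect, d_rect, _ = rectify_anomalies(pose.height, diam)
    if d_rect.size >= 8:
        d_rect = wavelet_denoise(d_rect)
    pose_rect = PoseTrace(t=pose.t, height=h_rect,
                          horizontal=pose.horizontal, heading=pose.heading,
                          innovations=pose.innovations,
                          covariances=pose.covariances)
    return extract_tree_parameters(pose_rect, d_rect,
                                   start_height=start_height)
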