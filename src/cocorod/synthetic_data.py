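"""Synthetic test inputs: noisy growth observations and climber traces.

No public dataset of coconut-palm growth or climber logs exists, so every
pipeline stage is exercised on synthetic data with known ground truth.
Two generators are provided:

* :func:`synth_growth_observations` — i.i.d. Gaussian observation noise on
  a simulated growth series, standing in for field measurements of
  height/DBH/diameter curves.

* :func:`synth_climber_trace` — a kinematically consistent sensor log of a
  robot ascending a tapered (frustum) trunk: trapezoidal velocity profile
  (ramp-up, cruise), accelerometer = gravity + true vertical acceleration
  + noise, gyro/magnetometer consistent with a constant heading, and
  ultrasonic ranges derived from the frame span and the trunk radius at
  the instantaneous height.  Artifacts emulate real climbs: *slips*
  (transient stalls of the ascent, visible to the IMU) and *scars*
  (isolated ultrasonic outliers where bark scars or wedges catch the
  beam).  The paired ground truth enables recovery tests.

All randomness flows from a single seed fanned out to per-channel
substreams, so each channel is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .secondary_growth import TrunkGeometry, radius_at_height
from .sensor_pipeline import SensorTrace
from .simulator import GrowthSeries

__all__ = ["SynthSpec", "ClimbTruth", "synth_growth_observations",
           "synth_climber_trace"]


@dataclass
class SynthSpec:
    """Conditions of one synthetic climb."""

    climb_speed: float = 0.2     # m/s
    rate_hz: float = 50.0        # trace rate
    climb_height: float = 12.0   # m of ascent
    accel_ramp: float = 0.5      # m/s^2 start/stop ramp
    frame_span: float = 0.6      # m between the two ultrasonic sensors
    heading: float = 0.3         # rad, constant robot heading
    sigma_accel: float = 0.05    # m/s^2
    sigma_gyro: float = 0.005    # rad/s
    sigma_mag: float = 0.01      # on normalized components
    sigma_us: float = 0.005      # m
    n_slips: int = 2             # transient stalls per climb
    slip_duration: float = 0.5   # s
    n_scars: int = 3             # ultrasonic spike artifacts per climb
    scar_magnitude: float = 0.08  # m spike on one range channel
    gravity: float = 9.8         # N/kg
    seed: int = 0

    def __post_init__(self) -> None:
        if self.climb_speed <= 0:
            raise ValueError("climb speed must be positive")
        if self.rate_hz <= 0:
            raise ValueError("trace rate must be positive")
        sigmas = [self.sigma_accel, self.sigma_gyro, self.sigma_mag,
                  self.sigma_us]
        if any(s < 0 for s in sigmas):
            raise ValueError("noise sigmas must be non-negative")

    def replace(self, **kw) -> "SynthSpec":
        return replace(self, **kw)


@dataclass
class ClimbTruth:
    """Ground truth paired with a synthetic trace."""

    t: np.ndarray
    height: np.ndarray
    velocity: np.ndarray
    heading: float
    diameter: np.ndarray
    dbh: float
    total_height: float
    slip_times: np.ndarray
    scar_indices: np.ndarray


def synth_growth_observations(series: GrowthSeries, sigma: float,
                              seed: int) -> GrowthSeries:
    """Add i.i.d. Gaussian noise to the observable growth quantities.

    Heights, DBH and diameters each draw from an independent substream of
    ``seed``; abscissae (times, profile heights) are left exact.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    streams = [np.random.default_rng(s)
               for s in np.random.SeedSequence(seed).spawn(3)]
    return GrowthSeries(
        times=series.times.copy(),
        heights=series.heights + streams[0].normal(0, sigma,
                                                   series.heights.size),
        dbh=series.dbh + streams[1].normal(0, sigma, series.dbh.size),
        profile_heights=series.profile_heights.copy(),
        diameters=series.diameters + streams[2].normal(
            0, sigma, series.diameters.size),
        direction_angle=series.direction_angle.copy(),
        horizontal_shift=series.horizontal_shift.copy(),
    )


def _ascent_profile(spec: SynthSpec, rng: np.random.Generator
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                               np.ndarray, np.ndarray]:
    """Piecewise-linear velocity profile with ramp-up and slip stalls.

    Returns (t, height, velocity, acceleration, slip_times).  The profile
    is integrated exactly (trapezoid on the piecewise-linear velocity), so
    the ground truth is kinematically consistent with the acceleration
    channel to machine precision of the trapezoid rule.
    """
    dt = 1.0 / spec.rate_hz
    v, a0 = spec.climb_speed, spec.accel_ramp
    ramp = v / a0
    cruise = spec.climb_height / v  # generous horizon; clipped below
    stall_cost = spec.slip_duration + v / a0  # extra time per slip
    total = ramp + cruise + spec.n_slips * (stall_cost + ramp) + 2.0
    t = np.arange(0.0, total, dt)

    if spec.n_slips > 0:
        lo, hi = 0.15 * total, 0.75 * total
        slip_times = np.sort(rng.uniform(lo, hi, spec.n_slips))
    else:
        slip_times = np.array([])

    vel = np.full_like(t, v)
    vel[t < ramp] = a0 * t[t < ramp]
    for ts in slip_times:
        # decelerate, stall, re-accelerate
        dec = v / a0
        for i, ti in enumerate(t):
            if ts <= ti < ts + dec:
                vel[i] = min(vel[i], v - a0 * (ti - ts))
            elif ts + dec <= ti < ts + dec + spec.slip_duration:
                vel[i] = 0.0
            elif ts + dec + spec.slip_duration <= ti < ts + 2 * dec + \
                    spec.slip_duration:
                vel[i] = min(vel[i], a0 * (ti - ts - dec - spec.slip_duration))
    height = np.concatenate([[0.0], np.cumsum(
        0.5 * (vel[1:] + vel[:-1]) * dt)])
    # clip the climb at the requested height
    idx = np.searchsorted(height, spec.climb_height)
    idx = min(idx, t.size - 1)
    t, vel, height = t[:idx + 1], vel[:idx + 1], height[:idx + 1]
    accel = np.gradient(vel, t)
    return t, height, vel, accel, slip_times


def synth_climber_trace(spec: SynthSpec, tree: TrunkGeometry
                        ) -> tuple[SensorTrace, ClimbTruth]:
    """Generate a climber sensor log on a tapered trunk with ground truth.

    The accelerometer's third axis carries gravity plus the true vertical
    acceleration; the first two axes are pure noise (no lateral motion).
    Ultrasonic ranges split ``frame_span - diameter`` between the two
    sensors with a fixed mounting offset; scars add isolated spikes to the
    left channel at known sample indices.
    """
    streams = np.random.SeedSequence(spec.seed).spawn(6)
    rng_kin, rng_acc, rng_gyr, rng_mag, rng_us, rng_scar = (
        np.random.default_rng(s) for s in streams)

    t, height, vel, accel, slip_times = _ascent_profile(spec, rng_kin)
    n = t.size

    acc = rng_acc.normal(0.0, spec.sigma_accel, (n, 3))
    acc[:, 2] += spec.gravity + accel
    gyro = rng_gyr.normal(0.0, spec.sigma_gyro, (n, 3))
    mag = rng_mag.normal(0.0, spec.sigma_mag, (n, 3))
    mag[:, 0] += np.cos(spec.heading)
    mag[:, 1] += np.sin(spec.heading)
    mag[:, 2] += 0.5  # constant inclination component

    diameter = 2.0 * radius_at_height(height, tree)
    gap = spec.frame_span - diameter
    offset = 0.02  # rigid mounting asymmetry, cancels in the sum
    us_left = gap / 2.0 + offset + rng_us.normal(0, spec.sigma_us, n)
    us_right = gap / 2.0 - offset + rng_us.normal(0, spec.sigma_us, n)
    if spec.n_scars > 0 and n > 20:
        scar_idx = np.sort(rng_scar.choice(
            np.arange(10, n - 10), size=spec.n_scars, replace=False))
        us_left[scar_idx] += spec.scar_magnitude
    else:
        scar_idx = np.array([], dtype=int)
    us_left = np.clip(us_left, 0.0, None)
    us_right = np.clip(us_right, 0.0, None)

    trace = SensorTrace(t=t, accel=acc, gyro=gyro, mag=mag,
                        us_left=us_left, us_right=us_right)
    truth = ClimbTruth(
        t=t, height=height, velocity=vel, heading=spec.heading,
        diameter=diameter, dbh=float(2.0 * radius_at_height(
            min(1.4, height[-1]), tree)),
        total_height=float(height[-1]), slip_times=slip_times,
        scar_indices=scar_idx)
    return trace, truth
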