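"""Growth simulation driver and model-vs-observation comparison metrics.

``simulate`` couples the modules: each time step extends the trunk by
``a_v dt``, seeds freshly appeared material with tropism-driven strains
toward the environment-adjusted preferred direction, advances the planar
apical system (couple -> relaxed curvature -> angle -> base curve), and
reads trunk radii off the calibrated exponential taper.  It emits temporal
series (height and DBH vs time, sampled yearly) and spatial profiles
(diameter, growth direction and horizontal shift vs height, sampled every
0.1 m from breast height upward), the two views the model is judged on.

``compare_series`` computes the comparison metrics used throughout:
variance of the prediction-observation error (population form, reported in
squared units), MAE, RMSE and R^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import TreeParams
from .environment import frustum_second_moment, wind_deflection
from .primary_growth import ApicalState, apical_step
from .rod_kinematics import GrowthSchedule
from .secondary_growth import radius_at_height

__all__ = ["GrowthSeries", "ComparisonMetrics", "simulate", "compare_series"]

TEMPORAL_COLUMNS = ["time_y", "height_m", "dbh_m"]
PROFILE_COLUMNS = ["height_m", "diameter_m", "direction_rad",
                   "horizontal_shift_m"]


@dataclass
class GrowthSeries:
    """Temporal and spatial growth characteristics of one simulated tree."""

    times: np.ndarray             # y
    heights: np.ndarray           # m
    dbh: np.ndarray               # m
    profile_heights: np.ndarray   # m
    diameters: np.ndarray         # m
    direction_angle: np.ndarray   # rad
    horizontal_shift: np.ndarray  # m

    def validate(self) -> None:
        if np.any(np.diff(self.heights) < -1e-12):
            raise ValueError("heights must be non-decreasing")
        if np.any(self.diameters <= 0):
            raise ValueError("diameters must be positive")
        if self.times.shape != self.heights.shape or \
                self.times.shape != self.dbh.shape:
            raise ValueError("temporal arrays must be length-consistent")
        if not (self.profile_heights.shape == self.diameters.shape
                == self.direction_angle.shape == self.horizontal_shift.shape):
            raise ValueError("profile arrays must be length-consistent")

    def temporal_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_y": self.times, "height_m": self.heights,
                             "dbh_m": self.dbh})

    def profile_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "height_m": self.profile_heights,
            "diameter_m": self.diameters,
            "direction_rad": self.direction_angle,
            "horizontal_shift_m": self.horizontal_shift,
        })

    def to_csv(self, temporal_path: str | Path,
               profile_path: str | Path | None = None) -> None:
        self.temporal_frame().to_csv(temporal_path, index=False)
        if profile_path is not None:
            self.profile_frame().to_csv(profile_path, index=False)

    @classmethod
    def from_csv(cls, temporal_path: str | Path,
                 profile_path: str | Path | None = None) -> "GrowthSeries":
        tf = pd.read_csv(temporal_path)
        if list(tf.columns) != TEMPORAL_COLUMNS:
            raise ValueError(f"temporal CSV must have columns "
                             f"{TEMPORAL_COLUMNS}, got {list(tf.columns)}")
        if profile_path is not None:
            pf = pd.read_csv(profile_path)
            if list(pf.columns) != PROFILE_COLUMNS:
                raise ValueError(f"profile CSV must have columns "
                                 f"{PROFILE_COLUMNS}, got {list(pf.columns)}")
        else:
            pf = pd.DataFrame({c: np.array([]) for c in PROFILE_COLUMNS})
        return cls(
            times=tf["time_y"].to_numpy(),
            heights=tf["height_m"].to_numpy(),
            dbh=tf["dbh_m"].to_numpy(),
            profile_heights=pf["height_m"].to_numpy(),
            diameters=pf["diameter_m"].to_numpy(),
            direction_angle=pf["direction_rad"].to_numpy(),
            horizontal_shift=pf["horizontal_shift_m"].to_numpy(),
        )


@dataclass
class ComparisonMetrics:
    """Error metrics between a predicted and an observed series."""

    variance: float  # population variance of the error, squared units
    mae: float
    rmse: float
    r2: float


def _frustum_moment_vec(x_top: np.ndarray, x_base: float, k: float,
                        rho_prime: float, min_gap: float = 1e-6
                        ) -> np.ndarray:
    """Vectorized frustum second moment with a floor on |x_top - x_base|.

    Near the base the printed formula is singular (radii coincide); the
    floor keeps the rigidity finite and very large there, which damps the
    couple's effect at the clamped end without changing the physics
    elsewhere.
    """
    x_top = np.minimum(np.asarray(x_top, dtype=float), x_base - min_gap)
    num = np.abs(x_top**5 - x_base**4 * x_top + x_base**5)
    den = np.abs(x_top - x_base)
    return rho_prime * np.pi * k / 10.0 * num / den


def simulate(params: TreeParams, years: float, dt: float = 0.05,
             dr: float = 0.01, profile_step: float = 0.1) -> GrowthSeries:
    """Run the coupled primary/secondary growth model.

    Parameters
    ----------
    params : TreeParams — calibrated parameter set (taper anchors included).
    years : simulated horizon (y); temporal output is sampled yearly.
    dt, dr : time step (y) and material grid spacing (m).

    The run is deterministic: identical parameters give bit-identical
    output.
    """
    if years <= 0 or dt <= 0 or dr <= 0:
        raise ValueError("years, dt and dr must be positive")
    geom = params.trunk_geometry()
    sched = GrowthSchedule(a_v=params.a_v)
    k_final = sched.length(years)

    n_steps = int(round(years / dt))
    r_full = np.arange(0.0, k_final + dr / 2, dr)
    if r_full[-1] < k_final - 1e-12:
        r_full = np.append(r_full, k_final)
    n_full = r_full.size

    beta_star_init = params.beta_max * np.sin(
        (params.theta_p_f - params.theta_0) / 2.0)
    q = np.zeros(n_full)
    beta_star = np.full(n_full, beta_star_init)
    theta = np.full(n_full, params.theta_0)
    s = np.zeros((n_full, 2))

    record_every = max(1, int(round(1.0 / dt)))
    times, heights, dbh_series = [0.0], [0.0], [2.0 * geom.x_dbh]

    n_active = 1
    for step in range(1, n_steps + 1):
        t = step * dt
        k = sched.length(t)
        n_active = int(np.searchsorted(r_full, k + 1e-12, side="right"))
        r_act = r_full[:n_active]

        if n_active >= 2:
            # heights of material points from the current base curve
            h_of_r = np.maximum.accumulate(np.clip(s[:n_active, 0], 0.0, None))
            x_h = radius_at_height(np.clip(h_of_r, 0.0, None), geom)
            I = _frustum_moment_vec(x_h, geom.x_base, k, params.rho_prime)
            YI = params.Y * I
            dYI_dt = YI * params.a_v / k
            rho3 = params.rho_prime * np.pi * x_h**2
            # transverse load: projected self-weight plus optional wind line
            p_y = rho3 * params.g * np.sin(theta[:n_active]) \
                + params.wind_line_load

            state = ApicalState(r_grid=r_act, q=q[:n_active],
                                beta_star=beta_star[:n_active],
                                theta=theta[:n_active], s=s[:n_active],
                                theta_0=params.theta_0)
            state = apical_step(state, YI, dt, p_y=p_y,
                                rigidity_rate=dYI_dt)
            q[:n_active] = state.q
            beta_star[:n_active] = state.beta_star
            theta[:n_active] = state.theta
            s[:n_active] = state.s

        if step % record_every == 0:
            times.append(t)
            heights.append(float(s[n_active - 1, 0]))
            dbh_series.append(2.0 * geom.x_dbh)

    # spatial profile at the final time, breast height upward
    s1 = s[:n_active, 0]
    tip_height = float(s1[-1])
    h0 = min(params.breast_height, tip_height)
    profile_h = np.arange(h0, tip_height + profile_step / 2, profile_step)
    profile_h = profile_h[profile_h <= tip_height + 1e-12]
    if profile_h.size == 0:
        profile_h = np.array([tip_height])
    # invert the (monotone) height-along-rod map to sample angle and shift
    s1_mono = np.maximum.accumulate(s1)
    r_of_h = np.interp(profile_h, s1_mono, r_full[:n_active])
    direction = np.interp(r_of_h, r_full[:n_active], theta[:n_active])
    shift = np.interp(r_of_h, r_full[:n_active], s[:n_active, 1])
    diam = 2.0 * radius_at_height(profile_h, geom)
    diam = np.atleast_1d(diam)

    series = GrowthSeries(
        times=np.asarray(times), heights=np.asarray(heights),
        dbh=np.asarray(dbh_series), profile_heights=profile_h,
        diameters=diam, direction_angle=direction,
        horizontal_shift=shift)
    series.validate()
    return series


def wind_state(params: TreeParams, k: float) -> tuple[float, float]:
    """Tip deflection and wind angle for the current trunk, as diagnostics.

    Uses the frustum second moment at the tip radius and the configured
    tip force ``F_wind``.
    """
    geom = params.trunk_geometry()
    x_top = radius_at_height(k, geom)
    I = frustum_second_moment(x_top, geom.x_base, k, params.rho_prime)
    return wind_deflection(params.F_wind, k, params.Y, I, x_top)


def compare_series(pred_x, pred_y, obs_x, obs_y,
                   unit_scale: float = 1.0) -> ComparisonMetrics:
    """Compare a predicted series against observations.

    The prediction is resampled onto the observation abscissa by linear
    interpolation when the grids differ.  ``unit_scale`` rescales both
    series first (e.g. 100 to report metre data in centimetres, so the
    variance comes out in cm^2).

    Metrics: MAE = mean|e|, RMSE = sqrt(mean e^2), variance =
    mean((e - mean e)^2), R^2 = 1 - SSE/SST about the observation mean,
    with e = pred - obs.
    """
    pred_x = np.asarray(pred_x, dtype=float)
    pred_y = np.asarray(pred_y, dtype=float) * unit_scale
    obs_x = np.asarray(obs_x, dtype=float)
    obs_y = np.asarray(obs_y, dtype=float) * unit_scale
    if obs_x.size < 2:
        raise ValueError("need at least 2 observations to compare")
    if pred_x.size != pred_y.size or obs_x.size != obs_y.size:
        raise ValueError("abscissa/ordinate length mismatch")
    if pred_x.size == obs_x.size and np.allclose(pred_x, obs_x):
        pred = pred_y
    else:
        pred = np.interp(obs_x, pred_x, pred_y)
    e = pred - obs_y
    mae = float(np.mean(np.abs(e)))
    rmse = float(np.sqrt(np.mean(e**2)))
    variance = float(np.mean((e - np.mean(e)) ** 2))
    sst = float(np.sum((obs_y - np.mean(obs_y)) ** 2))
    if sst == 0.0:
        raise ValueError("observations have zero variance: R^2 undefined")
    r2 = 1.0 - float(np.sum(e**2)) / sst
    return ComparisonMetrics(variance=variance, mae=mae, rmse=rmse, r2=r2)
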