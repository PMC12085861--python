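"""Primary (apical) growth: tropism-seeded strains and the small-deflection
apical system.

The growth direction of a palm trunk is steered by gravitropism, sunlight
and wind.  New material at the apex is laid down with an initial curvature
``beta0`` and twist ``gamma0`` chosen so that, after a look-ahead length
``delta`` of further growth, the growth director ``f3`` points along a
preferred target direction.  Expanding ``f3(r + delta)`` to second order and
projecting onto the current directors gives the closed forms

    beta0      = sgn(c1) * (beta_max / 2) * sqrt(2 (1 - c3))
    dbeta0/dr  = (beta_max^2 / 2) * (c1 - sgn(c1) * sqrt(2 (1 - c3)))
    gamma0     = sgn(c1) * beta_max * c2 / sqrt(2 (1 - c3))   (0 if beta0 = 0)

with ``c_i = f_target . f_i`` and ``beta_max`` the physiological maximum
curvature (1/m).  When ``beta_max = 2 / delta`` these seeds solve the
projected Taylor system exactly; for smaller ``beta_max`` the trunk curves
toward the target as fast as the tissue allows.

The apical system itself is the planar small-deflection balance

    d q / dr      = -p_y cos(theta)          (contact couple, tip-free)
    d beta*/ dt   = d(YI)/dt * q / (YI)^2    (relaxation by new wood)
    d theta / dr  = beta* + q / (YI)
    d s / dr      = cos(theta0) i + (sin(theta0) + (theta - theta0) cos(theta0)) j

with ``q(k(t), t) = 0`` at the free tip, ``theta(0, t) = theta0`` and
``s(0, t) = 0`` clamped at the base, and newly appeared material receiving
``beta* = beta_max sin((theta_p_f - theta0) / 2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .rod_kinematics import MaterialFrame

__all__ = [
    "TropismTargets",
    "ApicalState",
    "env_adjusted_direction",
    "tropism_strains",
    "dms_curvature_rate",
    "apical_step",
    "taylor_truncation_residual",
]

_DEGENERATE_TOL = 1e-12


def _sgn(x: float) -> float:
    """Sign with the tie-break sgn(0) = +1."""
    return 1.0 if x >= 0 else -1.0


def _unit(v: np.ndarray, name: str, tol: float = 1e-8) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if abs(np.linalg.norm(v) - 1.0) > tol:
        raise ValueError(f"{name} must be a unit vector")
    return v


@dataclass
class TropismTargets:
    """Preferred growth directions and deflection angles.

    ``f_p`` is the gravitropism-only preferred direction, ``f_p_star`` the
    preferred direction once sunlight and wind are folded in; the
    orthogonal pair (``f_p_gamma``, ``f_p_beta``) spans the rotation plane
    and ``f_p_F`` is the final target handed to the strain seeding.
    """

    f_p: np.ndarray
    f_p_star: np.ndarray
    theta: float = 0.0
    theta_0: float = 0.0
    theta_S: float = 0.0
    theta_w: float = 0.0
    theta_p: float = 0.0
    theta_p_f: float = 0.0
    beta_max: float = 0.0
    f_p_gamma: np.ndarray = field(init=False)
    f_p_beta: np.ndarray = field(init=False)
    f_p_F: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.f_p = _unit(self.f_p, "f_p")
        self.f_p_star = _unit(self.f_p_star, "f_p_star")
        cross = np.cross(self.f_p, self.f_p_star)
        norm = np.linalg.norm(cross)
        if norm < _DEGENERATE_TOL:
            raise ValueError(
                "f_p and f_p_star are parallel: the normal to the "
                "preferential-growth plane is undefined"
            )
        self.f_p_gamma = cross / norm
        self.f_p_beta = np.cross(self.f_p_gamma, self.f_p_star)
        self.f_p_F = env_adjusted_direction(self.f_p, self.f_p_star, self.theta)


def env_adjusted_direction(f_p: np.ndarray, f_p_star: np.ndarray,
                           theta: float, *, strict_literal: bool = False
                           ) -> np.ndarray:
    """Final preferred growth direction under sunlight and wind.

    Rotates ``f_p`` by ``theta`` toward ``f_p_beta`` (the in-plane normal
    built from ``f_p x f_p_star``):

        f_p_F = normalize(f_p cos(theta) + f_p_beta sin(theta)).

    With ``strict_literal=True`` the raw cross product
    ``(f_p cos theta) x (f_p_beta sin theta)`` is returned instead — a
    direction perpendicular to the rotation plane that vanishes at
    theta in {0, pi/2}; it is provided for inspection only.
    """
    f_p = _unit(f_p, "f_p")
    f_p_star = _unit(f_p_star, "f_p_star")
    cross = np.cross(f_p, f_p_star)
    norm = np.linalg.norm(cross)
    if norm < _DEGENERATE_TOL:
        raise ValueError(
            "f_p and f_p_star are parallel: adjusted direction undefined"
        )
    f_p_gamma = cross / norm
    f_p_beta = np.cross(f_p_gamma, f_p_star)
    if strict_literal:
        return np.cross(f_p * np.cos(theta), f_p_beta * np.sin(theta))
    v = f_p * np.cos(theta) + f_p_beta * np.sin(theta)
    return v / np.linalg.norm(v)


def tropism_strains(f_target: np.ndarray, frame: MaterialFrame,
                    beta_max: float, delta: float = 0.1
                    ) -> tuple[float, float, float]:
    """Strain seeds steering the growth director toward ``f_target``.

    Returns ``(beta0, dbeta0_dr, gamma0)``; see the module docstring for
    the closed forms.  ``beta_max = 0`` (straight growth) returns zeros for
    any target.  The square-root argument is clamped at 0 against rounding
    when ``|f_target . f3|`` exceeds 1.
    """
    if beta_max < 0:
        raise ValueError("beta_max must be non-negative")
    f_target = _unit(f_target, "f_target")
    frame.validate(tol=1e-8)
    c1 = float(f_target @ frame.f1)
    c2 = float(f_target @ frame.f2)
    c3 = float(f_target @ frame.f3)
    arg = np.clip(2.0 * (1.0 - c3), 0.0, None)
    root = float(np.sqrt(arg))
    sg = _sgn(c1)
    beta0 = sg * 0.5 * beta_max * root
    dbeta0_dr = 0.5 * beta_max**2 * (c1 - sg * root)
    if beta0 == 0.0:
        gamma0 = 0.0
    else:
        gamma0 = sg * beta_max * c2 / root
    return beta0, dbeta0_dr, gamma0


def taylor_truncation_residual(f_targets: np.ndarray, frames: np.ndarray,
                               beta_max: float, delta: float,
                               n_sub: int = 32) -> np.ndarray:
    """Residual of the quadratic projection construction, per target.

    The projection relations equate components of the degree-2 Taylor
    polynomial of ``f3(r + delta)`` under the seeded strain field
    ``y(r) = (0, beta0 + dbeta0_dr * r, gamma0)``.  This routine propagates
    the director triad exactly (batched RK4 with ``n_sub`` substeps) and
    returns ``|f3_exact(delta) - Taylor2(delta)|`` (Euclidean norm), the
    truncation residual, for each target/frame pair.  It decays at third
    order in ``delta``.

    Parameters
    ----------
    f_targets : (n, 3) unit target directions.
    frames : (n, 3, 3) director triads, rows (f1, f2, f3).
    """
    f_targets = np.asarray(f_targets, dtype=float)
    F0 = np.asarray(frames, dtype=float)
    n = f_targets.shape[0]
    c1 = np.einsum("ij,ij->i", f_targets, F0[:, 0])
    c2 = np.einsum("ij,ij->i", f_targets, F0[:, 1])
    c3 = np.einsum("ij,ij->i", f_targets, F0[:, 2])
    root = np.sqrt(np.clip(2.0 * (1.0 - c3), 0.0, None))
    sg = np.where(c1 >= 0, 1.0, -1.0)
    beta0 = sg * 0.5 * beta_max * root
    dbeta0 = 0.5 * beta_max**2 * (c1 - sg * root)
    gamma0 = np.where(beta0 != 0.0, sg * beta_max * c2 / np.where(root == 0, 1.0, root), 0.0)

    # degree-2 Taylor polynomial of f3 in the initial frame
    taylor = (F0[:, 2]
              + delta * beta0[:, None] * F0[:, 0]
              + 0.5 * delta**2 * (dbeta0[:, None] * F0[:, 0]
                                  + (beta0 * gamma0)[:, None] * F0[:, 1]
                                  - (beta0**2)[:, None] * F0[:, 2]))

    # exact propagation of dF_i/dr = y(r) x F_i, batched RK4
    def rhs(r, F):
        y_body = np.stack([np.zeros(n), beta0 + dbeta0 * r,
                           np.full(n, 1.0) * gamma0], axis=1)
        y_world = np.einsum("nij,ni->nj", F, y_body)
        return np.cross(y_world[:, None, :], F)

    F = F0.copy()
    h = delta / n_sub
    r = 0.0
    for _ in range(n_sub):
        k1 = rhs(r, F)
        k2 = rhs(r + h / 2, F + h / 2 * k1)
        k3 = rhs(r + h / 2, F + h / 2 * k2)
        k4 = rhs(r + h, F + h * k3)
        F = F + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        # renormalize rows (batched Gram-Schmidt)
        f1 = F[:, 0] / np.linalg.norm(F[:, 0], axis=1, keepdims=True)
        f2 = F[:, 1] - np.einsum("ij,ij->i", F[:, 1], f1)[:, None] * f1
        f2 /= np.linalg.norm(f2, axis=1, keepdims=True)
        F = np.stack([f1, f2, np.cross(f1, f2)], axis=1)
        r += h
    return np.linalg.norm(F[:, 2] - taylor, axis=1)


def dms_curvature_rate(v_gamma: float, s_param: float, alpha: float,
                       theta_p_f: float, theta: float) -> float:
    """Curvature change rate from differential maturation strain.

        p = (2 v_gamma / s^2) * alpha * sin(theta_p_f - theta)

    ``v_gamma`` is the maturation (radial growth) velocity (m/y),
    ``s_param`` the cross-section scale (m), ``alpha`` the maximum
    differential maturation strain (m/m).  ``p`` has units 1/(m y) and its
    sign follows the misalignment ``sin(theta_p_f - theta)``.
    """
    if s_param <= 0:
        raise ValueError("cross-section scale s must be positive")
    return 2.0 * v_gamma / s_param**2 * alpha * np.sin(theta_p_f - theta)


@dataclass
class ApicalState:
    """Fields of the planar apical system on a material grid.

    ``r_grid`` spans the trunk (0 at the base, k(t) at the tip);
    ``q`` is the contact couple (N m), ``beta_star`` the relaxed curvature
    (1/m), ``theta`` the trunk angle (rad) and ``s`` the planar base curve
    ((n, 2), first column along the initial growth direction, second the
    transverse drift).
    """

    r_grid: np.ndarray
    q: np.ndarray
    beta_star: np.ndarray
    theta: np.ndarray
    s: np.ndarray
    theta_0: float = 0.0

    @classmethod
    def initial(cls, r_grid: np.ndarray, theta_0: float,
                beta_star_init: float) -> "ApicalState":
        r_grid = np.asarray(r_grid, dtype=float)
        n = r_grid.size
        state = cls(
            r_grid=r_grid,
            q=np.zeros(n),
            beta_star=np.full(n, float(beta_star_init)),
            theta=np.full(n, float(theta_0)),
            s=np.zeros((n, 2)),
            theta_0=float(theta_0),
        )
        state._integrate_theta_s(np.ones(n))  # consistent theta/s for YI=1
        return state

    def _integrate_theta_s(self, YI: np.ndarray) -> None:
        dtheta = self.beta_star + self.q / YI
        self.theta = self.theta_0 + cumulative_trapezoid(
            dtheta, self.r_grid, initial=0.0)
        th0 = self.theta_0
        ds1 = np.full_like(self.r_grid, np.cos(th0))
        ds2 = np.sin(th0) + (self.theta - th0) * np.cos(th0)
        s1 = cumulative_trapezoid(ds1, self.r_grid, initial=0.0)
        s2 = cumulative_trapezoid(ds2, self.r_grid, initial=0.0)
        self.s = np.stack([s1, s2], axis=1)


def apical_step(state: ApicalState, rigidity: np.ndarray, dt: float,
                p_y: np.ndarray | float = 0.0,
                rigidity_rate: np.ndarray | float = 0.0) -> ApicalState:
    """Advance the apical system one explicit-Euler time step.

    Parameters
    ----------
    state : ApicalState on the current material grid.
    rigidity : flexural rigidity ``YI(r)`` on the grid (must be > 0).
    dt : time step (years).
    p_y : transverse distributed load on the grid (N/m); the couple obeys
        ``dq/dr = -p_y cos(theta)`` integrated inward from the free tip.
    rigidity_rate : ``d(YI)/dt`` on the grid, driving relaxation of the
        curvature ``beta*`` as new wood matures.

    Order of operations per step: (i) couple ``q`` from the tip condition,
    (ii) ``beta*`` relaxation, (iii) ``theta`` outward from the clamped
    base, (iv) base curve ``s`` by the linearized direction rule.
    """
    r = state.r_grid
    YI = np.broadcast_to(np.asarray(rigidity, dtype=float), r.shape)
    if np.any(YI <= 0):
        raise ValueError("flexural rigidity YI must be positive on the grid")
    p_y = np.broadcast_to(np.asarray(p_y, dtype=float), r.shape)
    dYI = np.broadcast_to(np.asarray(rigidity_rate, dtype=float), r.shape)

    new = ApicalState(r_grid=r, q=state.q.copy(),
                      beta_star=state.beta_star.copy(),
                      theta=state.theta.copy(), s=state.s.copy(),
                      theta_0=state.theta_0)
    # (i) dq/dr = -p_y cos(theta), q(k) = 0: integrate from the tip inward
    integrand = p_y * np.cos(state.theta)
    total = cumulative_trapezoid(integrand, r, initial=0.0)
    new.q = total[-1] - total
    # (ii) relaxation of the unloaded curvature
    new.beta_star = state.beta_star + dt * dYI * new.q / YI**2
    # (iii, iv) theta outward from theta(0) = theta0, then the base curve
    new._integrate_theta_s(YI)
    return new
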