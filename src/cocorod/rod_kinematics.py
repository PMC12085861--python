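"""Rod kinematics: director frames, strain fields, and the growth schedule.

A growing palm trunk is described as a space curve ``s(r)`` carrying an
orthonormal director triad ``(f1, f2, f3)`` at every material coordinate
``r`` (arc length of deposited material, in metres).  The directors evolve
along the rod by the Serret–Frenet-type relations

    d f_i / dr = y x f_i,        d s / dr = w1 f1 + w2 f2 + w3 f3,

where ``y = (y1, y2, y3)`` collects curvature and twist (1/m) and
``w = (w1, w2, w3)`` the stretch/shear strains (dimensionless; the
unsheared, inextensible reference is ``w = (0, 0, 1)``, i.e. the curve
advances along ``f3``).  Both strain vectors are expressed in the moving
(body) frame.

Primary growth enters through the trunk-length schedule ``k(t)``: material
``r`` exists for ``0 <= r <= k(t)``, and the appearance map gives the date
at which material ``r`` was laid down.  For a constant apical growth
velocity ``a_v`` (m/y) the schedule is simply ``k(t) = a_v t`` with
appearance time ``r / a_v``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MaterialFrame",
    "StrainVectors",
    "GrowthSchedule",
    "growth_schedule",
    "integrate_frame",
]

_ORTHO_TOL = 1e-9


@dataclass
class MaterialFrame:
    """Position and orthonormal director triad at one material point.

    ``f3`` is the tangent-like director (growth direction); the triad is
    right-handed, ``f3 = f1 x f2``.
    """

    s: np.ndarray
    f1: np.ndarray
    f2: np.ndarray
    f3: np.ndarray
    f0: np.ndarray | None = None  # directors at r = 0, rows (f1, f2, f3)

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.f1 = np.asarray(self.f1, dtype=float)
        self.f2 = np.asarray(self.f2, dtype=float)
        self.f3 = np.asarray(self.f3, dtype=float)

    @classmethod
    def identity(cls) -> "MaterialFrame":
        """Frame at the origin with directors along the lab axes."""
        return cls(
            s=np.zeros(3),
            f1=np.array([1.0, 0.0, 0.0]),
            f2=np.array([0.0, 1.0, 0.0]),
            f3=np.array([0.0, 0.0, 1.0]),
        )

    @property
    def directors(self) -> np.ndarray:
        """Directors stacked as rows of a 3x3 rotation matrix."""
        return np.vstack([self.f1, self.f2, self.f3])

    def is_orthonormal(self, tol: float = _ORTHO_TOL) -> bool:
        F = self.directors
        if not np.allclose(F @ F.T, np.eye(3), atol=tol):
            return False
        # right-handedness: f3 = f1 x f2
        return bool(np.allclose(np.cross(self.f1, self.f2), self.f3, atol=tol))

    def validate(self, tol: float = 1e-8) -> None:
        if not self.is_orthonormal(tol):
            raise ValueError(
                "director triad is not a right-handed orthonormal frame"
            )


@dataclass
class StrainVectors:
    """Curvature/twist and stretch strains of the rod.

    ``y0 = (0, beta0, gamma0)`` and ``w0 = (0, 0, 1)`` are the reference
    strains of freshly deposited material: bending about f2 with curvature
    ``beta0`` and twist ``gamma0`` about the growth axis.
    """

    beta0: float = 0.0
    gamma0: float = 0.0
    beta_star: float = 0.0  # relaxed (external-force-free) curvature
    beta: float = 0.0       # current (loaded) curvature
    y: np.ndarray = field(default_factory=lambda: np.zeros(3))
    w: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    @property
    def y0(self) -> np.ndarray:
        return np.array([0.0, self.beta0, self.gamma0])

    @property
    def w0(self) -> np.ndarray:
        return np.array([0.0, 0.0, 1.0])


class GrowthSchedule:
    """Trunk length ``k(t)`` and the appearance map of material coordinates.

    Two constructions are supported: the constant-velocity analytic form
    ``k(t) = a_v t`` and a user-supplied monotone table ``(t_i, k_i)``
    interpolated linearly.
    """

    def __init__(self, a_v: float | None = None,
                 table: tuple[np.ndarray, np.ndarray] | None = None):
        if (a_v is None) == (table is None):
            raise ValueError("provide exactly one of a_v or table")
        if a_v is not None:
            if a_v <= 0:
                raise ValueError("apical growth velocity a_v must be > 0")
            self.a_v = float(a_v)
            self._table = None
        else:
            ts = np.asarray(table[0], dtype=float)
            ks = np.asarray(table[1], dtype=float)
            if ts.ndim != 1 or ts.shape != ks.shape or ts.size < 2:
                raise ValueError("table must be two equal-length 1-D arrays")
            if np.any(np.diff(ts) <= 0):
                raise ValueError("table times must be strictly increasing")
            if np.any(np.diff(ks) < 0):
                raise ValueError("trunk length k(t) must be non-decreasing")
            self.a_v = None
            self._table = (ts, ks)

    def length(self, t: float) -> float:
        """Trunk length k(t) in metres."""
        if t < 0:
            raise ValueError("time must be non-negative")
        if self._table is None:
            return self.a_v * t
        ts, ks = self._table
        return float(np.interp(t, ts, ks))

    def appearance_time(self, r) -> np.ndarray | float:
        """Date (years) at which material coordinate ``r`` appeared.

        The inverse of ``k``; for the constant-velocity schedule this is
        ``r / a_v``.
        """
        r = np.asarray(r, dtype=float)
        if np.any(r < 0):
            raise ValueError("material coordinate must be non-negative")
        if self._table is None:
            out = r / self.a_v
        else:
            ts, ks = self._table
            out = np.interp(r, ks, ts)
        return float(out) if out.ndim == 0 else out

    # admissibility of a (r, t) pair: 0 <= r <= k(t)
    def admissible(self, r: float, t: float) -> bool:
        return 0.0 <= r <= self.length(t)


def growth_schedule(t: float, a_v: float) -> tuple[float, GrowthSchedule]:
    """Trunk length at time ``t`` under constant apical velocity ``a_v``.

    Returns ``(k, schedule)`` where ``k = a_v * t`` and ``schedule``
    carries the appearance map ``f(r) = r / a_v``.
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    sched = GrowthSchedule(a_v=a_v)
    return sched.length(t), sched


def _gram_schmidt(F: np.ndarray) -> np.ndarray:
    """Re-orthonormalize the director rows, preserving right-handedness."""
    f1 = F[0] / np.linalg.norm(F[0])
    f2 = F[1] - (F[1] @ f1) * f1
    f2 /= np.linalg.norm(f2)
    f3 = np.cross(f1, f2)
    return np.vstack([f1, f2, f3])


def integrate_frame(strain_fn, frame0: MaterialFrame,
                    r_grid: np.ndarray) -> list[MaterialFrame]:
    """Integrate the director/base-curve ODEs along the material coordinate.

    Parameters
    ----------
    strain_fn : callable
        ``r -> (y, w)`` returning the body-frame curvature/twist vector and
        stretch vector at material coordinate ``r``.
    frame0 : MaterialFrame
        Orthonormal frame at ``r_grid[0]`` (must be 0).
    r_grid : array
        Strictly increasing material coordinates starting at 0; each grid
        interval is one fixed step of the classical 4th-order Runge–Kutta
        scheme, followed by Gram–Schmidt renormalization of the directors.

    Returns
    -------
    list of MaterialFrame, one per grid point, with ``s(0)`` at the origin
    of ``frame0``.
    """
    frame0.validate()
    r_grid = np.asarray(r_grid, dtype=float)
    if r_grid.ndim != 1 or r_grid.size < 1:
        raise ValueError("r_grid must be a 1-D array")
    if abs(r_grid[0]) > 1e-15:
        raise ValueError("r_grid must start at 0")
    if r_grid.size > 1 and np.any(np.diff(r_grid) <= 0):
        raise ValueError("r_grid must be strictly increasing")

    def rhs(r, s, F):
        y, w = strain_fn(r)
        y = np.asarray(y, dtype=float)
        w = np.asarray(w, dtype=float)
        y_world = F.T @ y
        dF = np.cross(np.broadcast_to(y_world, (3, 3)), F)
        ds = F.T @ w
        return ds, dF

    s = frame0.s.copy()
    F = frame0.directors.copy()
    f0 = F.copy()
    frames = [MaterialFrame(s.copy(), *F.copy(), f0=f0)]
    for i in range(r_grid.size - 1):
        r, h = r_grid[i], r_grid[i + 1] - r_grid[i]
        k1s, k1F = rhs(r, s, F)
        k2s, k2F = rhs(r + h / 2, s + h / 2 * k1s, F + h / 2 * k1F)
        k3s, k3F = rhs(r + h / 2, s + h / 2 * k2s, F + h / 2 * k2F)
        k4s, k4F = rhs(r + h, s + h * k3s, F + h * k3F)
        s = s + h / 6 * (k1s + 2 * k2s + 2 * k3s + k4s)
        F = _gram_schmidt(F + h / 6 * (k1F + 2 * k2F + 2 * k3F + k4F))
        frames.append(MaterialFrame(s.copy(), *F.copy(), f0=f0))
    return frames
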