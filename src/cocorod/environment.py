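"""Abiotic-factor submodels: sunlight availability and wind loading.

Sunlight is handled as an additive budget — the total available sunlight is
the sum of the overall mean, the percentage of full sunlight, the variation
with height and an error term — feeding a sunlight deflection angle
``theta_S`` that composes with the wind deflection ``theta_w`` into the
final preferred angle ``theta_p_f = theta + theta_S + theta_w``.

Wind acts through a cantilever model of the trunk idealized as a conical
frustum of base radius ``x_base`` and top radius ``x_top``.  The
mass-weighted second moment used throughout is

    I = (rho' pi k / 10) * |x_top^5 - x_base^4 x_top + x_base^5| / |x_top - x_base|

(the absolute values keep I positive for tapered trunks), the tip
deflection under a tip force F is ``D = F k^3 / (3 Y I)`` and the wind
deflection angle ``theta_w = arccos(k / (D + x_top))`` with the argument
clamped to [-1, 1].  Note I carries the wood density rho', so Y*I is a
mass-weighted rigidity rather than the SI flexural rigidity; the package
is internally consistent in that convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SunlightComponents",
    "WindLoad",
    "total_available_sunlight",
    "compose_final_angle",
    "frustum_second_moment",
    "wind_deflection",
    "wind_adjusted_curvature",
    "wind_adjusted_curvature_frustum",
]

_SINGULAR_TOL = 1e-9


@dataclass
class SunlightComponents:
    """Additive sunlight budget (irradiance-proportional units)."""

    OMS: float = 0.0   # overall mean sunlight
    PFS: float = 0.0   # percentage of full sunlight
    VS_H: float = 0.0  # variation of sunlight with height
    E: float = 0.0     # error term

    @property
    def TAS(self) -> float:
        """Total available sunlight: exact sum of the components."""
        return total_available_sunlight(self.OMS, self.PFS, self.VS_H, self.E)


@dataclass
class WindLoad:
    """Result of the cantilever wind model at the trunk tip."""

    F: float          # tip wind force (N)
    D: float          # tip deflection (m)
    I: float          # frustum second moment (rho'-weighted)
    Y: float          # elastic modulus (Pa)
    k: float          # trunk length / lever arm (m)
    theta_w: float    # wind deflection angle (rad)

    @property
    def B_moment(self) -> float:
        """Base bending moment of the tip-loaded cantilever, F * k."""
        return self.F * self.k


def total_available_sunlight(OMS: float, PFS: float, VS_H: float,
                             E: float) -> float:
    """TAS = OMS + PFS + VS(H) + E, an exact sum."""
    return OMS + PFS + VS_H + E


def compose_final_angle(theta: float, theta_S: float, theta_w: float) -> float:
    """Final deflection angle: theta_p_f = theta + theta_S + theta_w."""
    return theta + theta_S + theta_w


def frustum_second_moment(x_top: float, x_base: float, k: float,
                          rho_prime: float) -> float:
    """Mass-weighted second moment of the conical-frustum trunk.

    Singular when the two radii coincide; callers should perturb one
    radius slightly for a cylinder-like trunk.
    """
    if x_top <= 0 or x_base <= 0:
        raise ValueError("frustum radii must be positive")
    if k <= 0:
        raise ValueError("trunk length k must be positive")
    if abs(x_top - x_base) < _SINGULAR_TOL:
        raise ValueError(
            "frustum second moment is singular for equal radii; "
            "perturb x_top or x_base slightly"
        )
    num = abs(x_top**5 - x_base**4 * x_top + x_base**5)
    den = abs(x_top - x_base)
    return rho_prime * np.pi * k / 10.0 * num / den


def wind_deflection(F: float, k: float, Y: float, I: float,
                    x_top: float) -> tuple[float, float]:
    """Tip deflection and wind angle of the cantilevered trunk.

    D = F k^3 / (3 Y I);  theta_w = arccos(clip(k / (D + x_top), -1, 1)).
    For k > D + x_top (clipped argument 1) the angle is 0.
    """
    if Y <= 0 or I <= 0 or k <= 0:
        raise ValueError("Y, I and k must be positive")
    D = F * k**3 / (3.0 * Y * I)
    theta_w = float(np.arccos(np.clip(k / (D + x_top), -1.0, 1.0)))
    return D, theta_w


def wind_adjusted_curvature(beta_star: float, q: float, Y: float,
                            I: float) -> float:
    """Loaded curvature from the linear elastic constitutive relation.

    beta = beta* + q / (Y I).
    """
    YI = Y * I
    if YI == 0:
        raise ValueError("flexural rigidity Y*I must be non-zero")
    return beta_star + q / YI


def wind_adjusted_curvature_frustum(beta_star: float, q: float, Y: float,
                                    x_top: float, x_base: float, k: float,
                                    rho_prime: float) -> float:
    """Loaded curvature with the frustum second moment substituted in.

    Identical to :func:`wind_adjusted_curvature` with
    ``I = frustum_second_moment(x_top, x_base, k, rho_prime)``.
    """
    I = frustum_second_moment(x_top, x_base, k, rho_prime)
    return wind_adjusted_curvature(beta_star, q, Y, I)
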