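"""Secondary (diffuse) growth: exponential trunk taper anchored at DBH.

Palms thicken by parenchyma expansion rather than a cambium; the model
captures the outcome as an exponential taper of the trunk radius with
height.  Writing ``a = rho' g / B`` (1/m, with B the bulk modulus of the
trunk tissue) and ``lam = (-rho' g / (B pi)) c'`` (m^2, with c' the
integration constant), the radius at height ``k_h`` is

    x(k_h) = sqrt(lam * exp(-a k_h)),

so the base radius is ``sqrt(lam)`` and the diameter at breast height
(DBH, 1.4 m above ground by cultivation convention) is ``2 x(1.4)``.
Neither B nor c' is observable directly; :func:`calibrate_taper` fits both
from two measured radii (base and breast height), which is how cultivation
practice enters the model.  Only the composites ``a`` and ``lam`` affect
the geometry, so admissibility is ``lam > 0`` (c' and B may carry either
sign convention individually).

The radial growth velocity is the time derivative of the radius carried by
the apical elongation ``k(t) = a_v t``:

    V_r = dx/dk * a_v = -(a / 2) x(k_h) a_v,

negative for a tapered trunk (a material point finds itself on an ever
longer trunk).  The cross-section area is ``A_r = pi x^2`` and the areal
(line) mass density ``rho''' = rho' A_r``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TrunkGeometry",
    "radius_at_height",
    "calibrate_taper",
    "radial_velocity",
    "radial_velocity_substituted",
    "trunk_area_and_density",
    "dbh",
]

BREAST_HEIGHT = 1.4  # m above ground


@dataclass(frozen=True)
class TrunkGeometry:
    """Taper parameters of one trunk.

    Attributes
    ----------
    rho_prime : wood density (kg/m^3)
    g : gravitational field (N/kg)
    B : bulk modulus (Pa); sign is conventional, see module docstring
    c_prime : integration constant of the taper law
    breast_height : DBH reference height (m), 1.4 by default
    """

    rho_prime: float
    g: float
    B: float
    c_prime: float
    breast_height: float = BREAST_HEIGHT

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError(
                "taper constant lam = (-rho' g / (B pi)) c' must be positive"
            )

    @property
    def decay(self) -> float:
        """Taper decay rate a = rho' g / B (1/m)."""
        return self.rho_prime * self.g / self.B

    @property
    def lam(self) -> float:
        """Squared base radius lam = (-rho' g / (B pi)) c' (m^2)."""
        return -self.rho_prime * self.g / (self.B * np.pi) * self.c_prime

    @property
    def x_base(self) -> float:
        return float(np.sqrt(self.lam))

    @property
    def x_dbh(self) -> float:
        return radius_at_height(self.breast_height, self)

    @property
    def DBH(self) -> float:
        return 2.0 * self.x_dbh

    @classmethod
    def from_anchors(cls, x_base_obs: float, x_at_h_obs: float,
                     h: float = BREAST_HEIGHT, rho_prime: float = 600.0,
                     g: float = 9.8) -> "TrunkGeometry":
        c_prime, B = calibrate_taper(x_base_obs, x_at_h_obs, h, rho_prime, g)
        return cls(rho_prime=rho_prime, g=g, B=B, c_prime=c_prime,
                   breast_height=h)


def radius_at_height(k_h, params: TrunkGeometry):
    """Trunk radius (m) at height ``k_h`` (m) above ground.

    ``x = sqrt(lam * exp(-a k_h))``; at ``k_h = 0`` this is the base
    radius ``sqrt(lam)``.
    """
    k_h = np.asarray(k_h, dtype=float)
    if np.any(k_h < 0):
        raise ValueError("height must be non-negative")
    out = np.sqrt(params.lam * np.exp(-params.decay * k_h))
    return float(out) if out.ndim == 0 else out


def calibrate_taper(x_base_obs: float, x_at_h_obs: float,
                    h: float = BREAST_HEIGHT, rho_prime: float = 600.0,
                    g: float = 9.8) -> tuple[float, float]:
    """Fit (c', B) so the taper law reproduces two observed radii exactly.

    ``a = (2 / h) ln(x_base / x_at_h)``, ``B = rho' g / a``,
    ``c' = -(B pi / (rho' g)) x_base^2``.  The fit is exact at both
    anchors by construction.
    """
    if h <= 0:
        raise ValueError("anchor height must be positive")
    if not 0 < x_at_h_obs < x_base_obs:
        raise ValueError(
            "calibration requires 0 < x_at_h_obs < x_base_obs (tapered trunk)"
        )
    a = 2.0 / h * np.log(x_base_obs / x_at_h_obs)
    B = rho_prime * g / a
    c_prime = -(B * np.pi / (rho_prime * g)) * x_base_obs**2
    return float(c_prime), float(B)


def radial_velocity(k_h, a_v: float, params: TrunkGeometry):
    """Radial growth velocity V_r = d x / d t (m/y) at height ``k_h``.

    Direct closed form carried by the apical elongation:

        V_r = ((rho' g)^2 / (B^2 pi)) c' exp(-a k_h) a_v
              / (2 sqrt(lam exp(-a k_h)))

    which equals the chain-rule derivative -(a/2) x a_v; negative for a
    tapered trunk.
    """
    if a_v < 0:
        raise ValueError("a_v must be non-negative")
    k_h = np.asarray(k_h, dtype=float)
    p = params
    gam = np.exp(-p.decay * k_h)
    num = (p.rho_prime * p.g) ** 2 / (p.B**2 * np.pi) * p.c_prime * gam * a_v
    out = num / (2.0 * np.sqrt(p.lam * gam))
    return float(out) if out.ndim == 0 else out


def radial_velocity_substituted(k_h, a_v: float, params: TrunkGeometry):
    """Radial growth velocity via the substitutions Gamma = exp(-a k),
    zeta = (-rho' g / (B pi)) c':

        V_r = -(rho' g / B) zeta Gamma a_v / (2 sqrt(zeta Gamma)).

    Algebraically identical to :func:`radial_velocity`.
    """
    k_h = np.asarray(k_h, dtype=float)
    p = params
    gamma = np.exp(-p.decay * k_h)
    zeta = p.lam
    out = -(p.rho_prime * p.g / p.B) * zeta * gamma * a_v \
        / (2.0 * np.sqrt(zeta * gamma))
    return float(out) if out.ndim == 0 else out


def trunk_area_and_density(k_h, params: TrunkGeometry):
    """Cross-section area A_r = pi x^2 (m^2) and line density rho''' =
    rho' A_r (kg/m) at height ``k_h``."""
    x = radius_at_height(k_h, params)
    A = np.pi * np.asarray(x) ** 2
    rho3 = params.rho_prime * A
    if np.ndim(k_h) == 0:
        return float(A), float(rho3)
    return A, rho3


def dbh(params: TrunkGeometry, breast_height: float | None = None) -> float:
    """Diameter at breast height: 2 x(breast_height)."""
    h = params.breast_height if breast_height is None else breast_height
    return 2.0 * radius_at_height(h, params)
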