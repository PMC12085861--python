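"""Parameter configuration: flat key/value files and cultivar presets.

Configs are flat YAML mappings whose keys mirror the model symbols
(``rho_prime``, ``Y``, ``a_v``, ``beta_max`` ...).  Unknown keys are
rejected so typos fail loudly.  Two presets ship with the package: ``wct``
(West Coast Tall) and ``cgd`` (Chowghat Green Dwarf).  Their printed
physical constants are shared; the cultivars differ in apical velocity and
taper anchors (the shipped anchor radii are synthetic representative
values — see each preset file).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .secondary_growth import TrunkGeometry

__all__ = ["TreeParams", "load_config", "load_preset", "PRESETS"]

PRESETS = ("wct", "cgd")


@dataclass
class TreeParams:
    """Full parameter set of one simulated tree.

    Units: SI with time in years for growth quantities; angles in rad.
    """

    # material & field constants
    rho_prime: float = 600.0        # wood density, kg/m^3
    g: float = 9.8                  # gravitational field, N/kg
    Y: float = 1.14e10              # elastic modulus, Pa
    # growth velocities & apical-system constants
    a_v: float = 0.46               # apical growth velocity, m/y
    V_r: float = 0.01               # nominal radial growth velocity, m/y
    alpha: float = 0.001            # max differential maturation strain, m/m
    s0: float = 0.01                # position offset constant, m
    s: float = 0.01                 # cross-section scale parameter, m
    # tropism angles & curvature bound
    theta_0: float = 0.0            # initial trunk angle, rad
    theta_p: float = float(np.pi / 2)   # trunk movement angle, rad
    theta_p_f: float = 0.61 * float(np.pi)  # final deflection angle, rad
    theta_S: float = 0.0            # sunlight deflection angle, rad
    beta_max: float = 0.0           # maximum curvature, 1/m
    # environment
    F_wind: float = 0.0             # tip wind force, N
    wind_line_load: float = 0.0     # extra transverse line load, N/m
    OMS: float = 0.0
    PFS: float = 0.0
    VS_H: float = 0.0
    E_sun: float = 0.0
    # taper anchors (calibrate c', B) and DBH convention
    x_base: float = 0.16            # base radius, m
    x_dbh: float = 0.14             # radius at breast height, m
    breast_height: float = 1.4      # m

    def trunk_geometry(self) -> TrunkGeometry:
        """Calibrated taper parameters from the anchor radii."""
        return TrunkGeometry.from_anchors(
            self.x_base, self.x_dbh, h=self.breast_height,
            rho_prime=self.rho_prime, g=self.g)

    def replace(self, **kw) -> "TreeParams":
        return replace(self, **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "TreeParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(
                f"unknown config keys: {sorted(unknown)}; "
                f"known keys: {sorted(known)}"
            )
        return cls(**{k: float(v) for k, v in d.items()})

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def load_config(path: str | Path) -> TreeParams:
    """Load a flat YAML config, rejecting unknown keys."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a flat key/value mapping")
    return TreeParams.from_dict(data)


def load_preset(name: str) -> TreeParams:
    """Load a shipped cultivar preset ('wct' or 'cgd')."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {PRESETS}")
    ref = resources.files("cocorod") / "presets" / f"{name}.yaml"
    data = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return TreeParams.from_dict(data)
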