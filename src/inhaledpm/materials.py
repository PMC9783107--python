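"""Material and fluid parameter sets for particle–wall adhesion modelling.

The default profile describes micronised drug particles (solid lipid
microparticle density) impacting the polymer wall of an inhaler, with the
silicon–silicon work of adhesion commonly used for dry van-der-Waals
contact. Values are shipped as a YAML profile alongside the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "MaterialParameters",
    "FluidProperties",
    "default_materials",
    "default_fluid",
    "load_profile",
    "dump_profile",
]


@dataclass(frozen=True)
class MaterialParameters:
    """Mechanical and adhesion constants of the particle/surface pair.

    Attributes
    ----------
    Es, Ep : float
        Young's moduli of the wall surface and the particle material (Pa).
    nu_s, nu_p : float
        Poisson ratios of surface and particle (dimensionless, in [0, 0.5)).
    WA : float
        Work of adhesion of the dry van-der-Waals contact (J/m^2).
    ks : float
        Static friction coefficient between particle and wall.
    f : float
        Near-wall drag correction factor applied to Stokes drag on a
        particle resting on the wall.
    Cu : float
        Cunningham slip correction factor (1 for the spherical
        micro-particles considered here).
    rho_p : float
        Particle material density (kg/m^3).
    """

    Es: float = 4.1e9
    Ep: float = 1e9
    nu_s: float = 0.35
    nu_p: float = 0.4
    WA: float = 0.039
    ks: float = 0.5
    f: float = 1.7
    Cu: float = 1.0
    rho_p: float = 1230.0

    def __post_init__(self) -> None:
        for name in ("Es", "Ep", "WA", "rho_p"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0 < self.ks <= 2):
            raise ValueError("ks must lie in (0, 2]")
        if self.f < 1:
            raise ValueError("near-wall correction f must be >= 1")
        if self.Cu < 1:
            raise ValueError("Cunningham factor Cu must be >= 1")
        for name in ("nu_s", "nu_p"):
            nu = getattr(self, name)
            if not (0 <= nu < 0.5):
                raise ValueError(f"{name} must lie in [0, 0.5)")


@dataclass(frozen=True)
class FluidProperties:
    """Carrier-gas properties: air at 1013.25 hPa and 15 degC by default.

    ``rho_M`` is the mixture density used in the wall-function identity;
    under the dilute one-way-coupling assumption it defaults to the fluid
    density itself.
    """

    rho: float = 1.225
    mu: float = 1.7894e-5
    rho_M: float = field(default=1.225)

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.mu <= 0 or self.rho_M <= 0:
            raise ValueError("fluid densities and viscosity must be positive")


def default_materials() -> MaterialParameters:
    """Material constants of the shipped default profile."""
    return MaterialParameters()


def default_fluid() -> FluidProperties:
    """Air at standard conditions (dilute mixture: rho_M = rho)."""
    return FluidProperties()


def load_profile(path: str | Path | None = None) -> tuple[MaterialParameters, FluidProperties]:
    """Load a material/fluid profile from YAML.

    With no argument, loads the packaged default profile
    (``profiles/table1_default.yaml``).
    """
    if path is None:
        ref = resources.files("inhaledpm").joinpath("profiles/table1_default.yaml")
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    # YAML 1.1 reads exponent forms like 4.1e9 as strings; coerce
    mat = MaterialParameters(**{k: float(v) for k, v in
                                doc.get("materials", {}).items()})
    fl = {k: float(v) for k, v in doc.get("fluid", {}).items()}
    if "rho_M" not in fl and "rho" in fl:
        fl = dict(fl, rho_M=fl["rho"])
    fluid = FluidProperties(**fl)
    return mat, fluid


def dump_profile(mat: MaterialParameters, fluid: FluidProperties, path: str | Path) -> None:
    """Write a profile YAML readable by :func:`load_profile`."""
    doc = {"materials": asdict(mat), "fluid": asdict(fluid)}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
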