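"""Particle–wall adhesion, capture, bounce and detachment physics.

Pure functions of particle diameter, material constants and local flow
quantities. The model chain is:

* van-der-Waals sticking force ``Fst = (3/4) pi WA dp`` of a dry contact;
* Dahneke/Brach–Dunn capture velocity ``vcr = (2 E / dp)^(10/7)`` with the
  El-Batsh composite material parameter ``E``: a particle impacting a wall
  with normal speed below ``vcr`` adheres, otherwise it rebounds with its
  velocity components scaled by the normal/tangential coefficients of
  restitution;
* for a particle stuck to the wall, the fluid drag evaluated at the
  particle centre inside the linear viscous sublayer
  (``V = rho dp u*^2 / (2 mu)``, Stokes drag with near-wall correction
  ``f``) is compared against the adhesion resistance: a moment balance
  around the contact edge for rolling detachment
  (``FD dp/2 >= Fst a``, with ``a`` the JKR-like contact radius) and a
  friction balance for sliding (``FD >= ks Fst``). Lift and the normal
  flattening of the contact are neglected (both are small for elastic
  micro-particles). Solving each balance for the wall friction velocity
  gives the critical wall shear velocities ``uR*`` (rolling) and ``uS*``
  (sliding); a deposited particle resuspends only when the local ``u*``
  exceeds them.

All functions broadcast over numpy arrays in their ``dp``/velocity
arguments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .materials import FluidProperties, MaterialParameters

__all__ = [
    "AdhesionDerived",
    "RestitutionPair",
    "DetachmentAssessment",
    "DetachmentOutcome",
    "adhesion_force",
    "compliances",
    "elbatsh_parameter",
    "capture_velocity",
    "sticking_decision",
    "bounce_velocity",
    "composite_young",
    "contact_radius",
    "stokes_drag",
    "sublayer_velocity",
    "wall_drag_force",
    "rolling_check",
    "sliding_check",
    "critical_shear_rolling",
    "critical_shear_sliding",
    "detachment_decision",
    "derive_adhesion",
]

_TEN_SEVENTHS = 10.0 / 7.0


@dataclass(frozen=True)
class RestitutionPair:
    """Normal/tangential coefficients of restitution of a wall bounce."""

    e_n: float
    e_t: float

    def __post_init__(self) -> None:
        if not (0 < self.e_n <= 1) or not (0 < self.e_t <= 1):
            raise ValueError("coefficients of restitution must lie in (0, 1]")


class DetachmentOutcome(str, Enum):
    REMAIN_STUCK = "remain_stuck"
    DETACH_ROLLING = "detach_rolling"
    DETACH_SLIDING = "detach_sliding"


@dataclass(frozen=True)
class AdhesionDerived:
    """Adhesion quantities evaluated for one particle diameter."""

    dp: float
    Fst: float
    k1: float
    k2: float
    E_cap: float
    KC: float
    a: float
    vcr: float


@dataclass(frozen=True)
class DetachmentAssessment:
    """Force/moment diagnostics for one stuck particle.

    ``rolling`` / ``sliding`` are the raw criterion flags; ``outcome``
    applies the rolling-first precedence (rolling is the more likely
    detachment mode for spherical particles, so a particle satisfying both
    criteria is recorded as detaching by rolling).
    """

    FD: float
    drag_moment: float
    adhesion_moment: float
    sliding_resistance: float
    u_star: float
    uR_star: float
    uS_star: float
    rolling: bool
    sliding: bool
    outcome: DetachmentOutcome


def adhesion_force(dp, mat: MaterialParameters):
    """van-der-Waals sticking force ``(3/4) pi WA dp`` (N)."""
    dp = np.asarray(dp, dtype=float)
    if np.any(dp < 0):
        raise ValueError("particle diameter must be non-negative")
    out = 0.75 * math.pi * mat.WA * dp
    return out if out.ndim else float(out)


def compliances(mat: MaterialParameters) -> tuple[float, float]:
    """Surface and particle elastic compliances ``(1-nu^2)/(pi E)`` (1/Pa)."""
    k1 = (1.0 - mat.nu_s**2) / (math.pi * mat.Es)
    k2 = (1.0 - mat.nu_p**2) / (math.pi * mat.Ep)
    return k1, k2


def elbatsh_parameter(k1: float, k2: float, rho_p: float) -> float:
    """El-Batsh composite capture parameter.

    ``E = 0.51 [5 pi^2 (k1+k2) / (4 rho_p^(3/2))]^(2/5)`` — the material
    composite that makes the capture-velocity power law return m/s when the
    diameter is in metres.
    """
    if k1 <= 0 or k2 <= 0 or rho_p <= 0:
        raise ValueError("compliances and density must be positive")
    return 0.51 * (5.0 * math.pi**2 * (k1 + k2) / (4.0 * rho_p**1.5)) ** 0.4


def capture_velocity(dp, E_cap: float):
    """Capture velocity ``vcr = (2 E / dp)^(10/7)`` (m/s).

    Impacts with normal speed below ``vcr`` adhere; ``vcr`` decreases with
    diameter, so fine particles are captured at almost any impact speed.
    """
    dp = np.asarray(dp, dtype=float)
    if np.any(dp <= 0):
        raise ValueError("particle diameter must be strictly positive")
    out = (2.0 * E_cap / dp) ** _TEN_SEVENTHS
    return out if out.ndim else float(out)


def sticking_decision(vn, vcr):
    """Stick/bounce decision for a wall impact.

    Returns ``True`` for stick (``vn <= vcr``; the measure-zero tie counts
    as capture), ``False`` for bounce. Broadcasts.
    """
    vn = np.asarray(vn, dtype=float)
    if np.any(vn < 0):
        raise ValueError("normal impact speed must be non-negative")
    out = vn <= vcr
    return out if out.ndim else bool(out)


def bounce_velocity(v_in: np.ndarray, n: np.ndarray, cor: RestitutionPair) -> np.ndarray:
    """Rebound velocity of a bouncing particle.

    ``n`` is the unit inward wall normal; the approach requires
    ``v_in . n < 0``. The normal component is reversed and scaled by
    ``e_n``, the tangential component scaled by ``e_t``.
    """
    v_in = np.asarray(v_in, dtype=float)
    n = np.asarray(n, dtype=float)
    if not math.isclose(float(np.linalg.norm(n)), 1.0, rel_tol=1e-9):
        raise ValueError("wall normal must be a unit vector")
    vn = float(v_in @ n)
    if vn >= 0:
        raise ValueError("particle is not approaching the wall (v.n >= 0)")
    v_t = v_in - vn * n
    return cor.e_t * v_t - cor.e_n * vn * n


def composite_young(mat: MaterialParameters) -> float:
    """Composite Young's modulus ``KC`` (Pa) of the contact pair."""
    return (4.0 / 3.0) / ((1.0 - mat.nu_s**2) / mat.Es + (1.0 - mat.nu_p**2) / mat.Ep)


def contact_radius(dp, mat: MaterialParameters):
    """Contact deformation radius ``a = [3 pi WA dp^2 / (2 KC)]^(1/3)`` (m).

    The lateral extent of the adhesive flattening: the moment arm of the
    sticking force in the rolling balance.
    """
    dp = np.asarray(dp, dtype=float)
    KC = composite_young(mat)
    out = (3.0 * math.pi * mat.WA * dp**2 / (2.0 * KC)) ** (1.0 / 3.0)
    return out if out.ndim else float(out)


def stokes_drag(dp, V_rel, fluid: FluidProperties, f: float = 1.0, Cu: float = 1.0):
    """Stokes drag ``3 pi mu dp V f / Cu`` (N) on a sphere.

    Written from the standard-drag form ``(1/2) C_D rho V^2 (pi dp^2/4)``
    with ``C_D = 24/Re_p``; the Reynolds number cancels so V = 0 gives
    exactly zero force.
    """
    dp = np.asarray(dp, dtype=float)
    V_rel = np.asarray(V_rel, dtype=float)
    if np.any(dp < 0) or np.any(V_rel < 0):
        raise ValueError("diameter and relative speed must be non-negative")
    out = 3.0 * math.pi * fluid.mu * dp * V_rel * f / Cu
    return out if out.ndim else float(out)


def sublayer_velocity(dp, u_star, fluid: FluidProperties):
    """Fluid speed at the centre of a wall-resting particle (m/s).

    Linear law of the wall evaluated at height ``dp/2``:
    ``V = rho dp u*^2 / (2 mu)``.
    """
    dp = np.asarray(dp, dtype=float)
    u_star = np.asarray(u_star, dtype=float)
    out = fluid.rho * dp * u_star**2 / (2.0 * fluid.mu)
    return out if out.ndim else float(out)


def wall_drag_force(dp, u_star, fluid: FluidProperties, f: float = 1.7, Cu: float = 1.0):
    """Drag on a wall-deposited particle, ``FD = (3 f / Cu) (pi/2) dp^2 rho u*^2``.

    Algebraically the composition of Stokes drag with the sublayer
    velocity; with the default near-wall correction f = 1.7 the prefactor
    is the familiar 5.1 pi / 2.
    """
    dp = np.asarray(dp, dtype=float)
    u_star = np.asarray(u_star, dtype=float)
    out = (3.0 * f / Cu) * (math.pi / 2.0) * dp**2 * fluid.rho * u_star**2
    return out if out.ndim else float(out)


def rolling_check(FD, dp, Fst, a):
    """Rolling detachment criterion: drag moment >= adhesion moment."""
    out = np.asarray(FD) * np.asarray(dp) / 2.0 >= np.asarray(Fst) * np.asarray(a)
    return out if out.ndim else bool(out)


def sliding_check(FD, ks, Fst):
    """Sliding detachment criterion: drag >= static friction ks * Fst."""
    out = np.asarray(FD) >= ks * np.asarray(Fst)
    return out if out.ndim else bool(out)


def critical_shear_rolling(dp, mat: MaterialParameters, fluid: FluidProperties,
                           variant: str = "force_balance"):
    """Critical wall friction velocity for rolling detachment (m/s).

    ``force_balance`` (default): the u* root of
    ``wall_drag_force(dp, u*) * dp/2 = Fst * a``, in closed form
    ``sqrt(3 WA a / (5.1 rho dp^2))`` (f = 1.7).

    ``as_printed``: the literal published expression
    ``(1/rho)(1/KC)^(1/3)(WA/dp)^(4/3)`` — dimensionally m^2/s^2, retained
    for audit only; its square root differs from the force-balance root by
    a constant factor ~0.99.
    """
    dp = np.asarray(dp, dtype=float)
    if np.any(dp <= 0):
        raise ValueError("particle diameter must be strictly positive")
    if variant == "force_balance":
        a = contact_radius(dp, mat)
        out = np.sqrt(mat.WA * a * mat.Cu / (mat.f * fluid.rho * dp**2))
    elif variant == "as_printed":
        KC = composite_young(mat)
        out = (1.0 / fluid.rho) * KC ** (-1.0 / 3.0) * (mat.WA / dp) ** (4.0 / 3.0)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return out if out.ndim else float(out)


def critical_shear_sliding(dp, mat: MaterialParameters, fluid: FluidProperties,
                           variant: str = "force_balance"):
    """Critical wall friction velocity for sliding detachment (m/s).

    ``force_balance`` (default): the u* root of
    ``wall_drag_force(dp, u*) = ks * Fst``, in closed form
    ``sqrt(ks WA / (2 f rho dp))``.

    ``as_printed``: the literal published expression
    ``0.5 ks WA / (rho_p dp)`` (m^2/s^2, particle density), audit only.
    """
    dp = np.asarray(dp, dtype=float)
    if np.any(dp <= 0):
        raise ValueError("particle diameter must be strictly positive")
    if variant == "force_balance":
        out = np.sqrt(mat.ks * mat.WA * mat.Cu / (2.0 * mat.f * fluid.rho * dp))
    elif variant == "as_printed":
        out = 0.5 * mat.ks * mat.WA / (mat.rho_p * dp)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return out if out.ndim else float(out)


def derive_adhesion(dp: float, mat: MaterialParameters) -> AdhesionDerived:
    """Evaluate the full adhesion parameter chain for one diameter."""
    k1, k2 = compliances(mat)
    E_cap = elbatsh_parameter(k1, k2, mat.rho_p)
    return AdhesionDerived(
        dp=float(dp),
        Fst=adhesion_force(dp, mat),
        k1=k1,
        k2=k2,
        E_cap=E_cap,
        KC=composite_young(mat),
        a=contact_radius(dp, mat),
        vcr=capture_velocity(dp, E_cap),
    )


def detachment_decision(dp: float, u_star: float, mat: MaterialParameters,
                        fluid: FluidProperties) -> DetachmentAssessment:
    """Assess whether a stuck particle detaches at local friction velocity u*.

    Evaluates the rolling moment balance and the sliding friction balance;
    when both hold, rolling takes precedence.
    """
    if u_star < 0:
        raise ValueError("u_star must be non-negative")
    Fst = adhesion_force(dp, mat)
    a = contact_radius(dp, mat)
    FD = wall_drag_force(dp, u_star, fluid, f=mat.f, Cu=mat.Cu)
    rolls = rolling_check(FD, dp, Fst, a)
    slides = sliding_check(FD, mat.ks, Fst)
    if rolls:
        outcome = DetachmentOutcome.DETACH_ROLLING
    elif slides:
        outcome = DetachmentOutcome.DETACH_SLIDING
    else:
        outcome = DetachmentOutcome.REMAIN_STUCK
    return DetachmentAssessment(
        FD=float(FD),
        drag_moment=float(FD) * dp / 2.0,
        adhesion_moment=float(Fst) * float(a),
        sliding_resistance=mat.ks * float(Fst),
        u_star=float(u_star),
        uR_star=critical_shear_rolling(dp, mat, fluid),
        uS_star=critical_shear_sliding(dp, mat, fluid),
        rolling=bool(rolls),
        sliding=bool(slides),
        outcome=outcome,
    )
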