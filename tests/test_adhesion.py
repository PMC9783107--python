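"""Adhesion/detachment physics: frozen reference values, algebraic
identities, independent bisection oracles and monotonicity properties.

Reference numbers were computed by direct hand arithmetic of the model
formulas and by bisection on the raw force/moment balances, independently
of the implementation.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from inhaledpm import adhesion as ad
from inhaledpm.adhesion import DetachmentOutcome, RestitutionPair

PI = math.pi


# ---------------------------------------------------------------------------
# frozen reference values (independent hand/bisection computation)

def test_adhesion_force_reference(mat):
    assert ad.adhesion_force(1e-6, mat) == pytest.approx(9.189159e-8, rel=1e-6)
    assert ad.adhesion_force(0.0, mat) == 0.0
    with pytest.raises(ValueError):
        ad.adhesion_force(-1e-6, mat)


def test_compliances_reference(mat):
    k1, k2 = ad.compliances(mat)
    assert k1 == pytest.approx(6.812608e-11, rel=1e-6)
    assert k2 == pytest.approx(2.673803e-10, rel=1e-6)


def test_compliances_identical_materials_are_equal():
    from inhaledpm import MaterialParameters
    m = MaterialParameters(Es=PI, Ep=PI, nu_s=0.0, nu_p=0.0)
    k1, k2 = ad.compliances(m)
    assert k1 == k2


def test_elbatsh_parameter_reference(mat):
    k1, k2 = ad.compliances(mat)
    E = ad.elbatsh_parameter(k1, k2, mat.rho_p)
    assert E == pytest.approx(3.165128e-6, rel=1e-6)


def test_elbatsh_parameter_scaling(mat):
    k1, k2 = ad.compliances(mat)
    E1 = ad.elbatsh_parameter(k1, k2, mat.rho_p)
    E32 = ad.elbatsh_parameter(32 * k1, 32 * k2, mat.rho_p)
    assert E32 / E1 == pytest.approx(4.0, rel=1e-12)   # 32^(2/5) = 4
    assert ad.elbatsh_parameter(k1, k2, 2 * mat.rho_p) < E1


def test_capture_velocity_reference(mat):
    k1, k2 = ad.compliances(mat)
    E = ad.elbatsh_parameter(k1, k2, mat.rho_p)
    assert ad.capture_velocity(5e-6, E) == pytest.approx(1.400745, rel=1e-6)
    # power law: doubling dp scales vcr by 2^(-10/7)
    r = ad.capture_velocity(2e-6, E) / ad.capture_velocity(1e-6, E)
    assert r == pytest.approx(2 ** (-10 / 7), rel=1e-12)
    with pytest.raises(ValueError):
        ad.capture_velocity(0.0, E)


def test_composite_young_reference_and_symmetry(mat):
    assert ad.composite_young(mat) == pytest.approx(1.264993e9, rel=1e-6)
    from inhaledpm import MaterialParameters
    swapped = MaterialParameters(Es=mat.Ep, Ep=mat.Es, nu_s=mat.nu_p, nu_p=mat.nu_s)
    assert ad.composite_young(swapped) == pytest.approx(ad.composite_young(mat), rel=1e-12)


def test_contact_radius_reference_and_power_law(mat):
    assert ad.contact_radius(1e-6, mat) == pytest.approx(5.257015e-8, rel=1e-6)
    r = ad.contact_radius(8e-6, mat) / ad.contact_radius(1e-6, mat)
    assert r == pytest.approx(4.0, rel=1e-12)          # dp^(2/3)
    # contact flattening stays small: justifies neglecting the normal
    # deformation in the rolling moment balance
    dp = np.linspace(0.5e-6, 5e-6, 50)
    assert np.all(ad.contact_radius(dp, mat) < dp / 10)


# ---------------------------------------------------------------------------
# stick / bounce decisions

def test_sticking_decision_basic_and_boundary():
    assert ad.sticking_decision(0.0, 1.0) is True
    assert ad.sticking_decision(2.0, 1.0) is False
    vcr = 3.7
    eps = 1e-12 * vcr
    assert ad.sticking_decision(vcr - eps, vcr) is True
    assert ad.sticking_decision(vcr + eps, vcr) is False
    assert ad.sticking_decision(vcr, vcr) is True      # tie counts as capture
    with pytest.raises(ValueError):
        ad.sticking_decision(-0.1, vcr)


@pytest.mark.parametrize("e", [0.2, 0.25, 0.5, 0.75, 0.85])
def test_bounce_velocity_componentwise(e):
    n = np.array([1.0, 0.0, 0.0])
    v_in = np.array([-1.0, 0.0, 2.0])
    v_out = ad.bounce_velocity(v_in, n, RestitutionPair(e, e))
    assert v_out == pytest.approx([e * 1.0, 0.0, e * 2.0])
    assert v_out @ n >= 0


def test_bounce_velocity_elastic_preserves_speed():
    n = np.array([0.0, 0.0, 1.0])
    v_in = np.array([0.3, -0.4, -1.2])
    v_out = ad.bounce_velocity(v_in, n, RestitutionPair(1.0, 1.0))
    assert np.linalg.norm(v_out) == pytest.approx(np.linalg.norm(v_in))


def test_bounce_velocity_requires_approach():
    n = np.array([1.0, 0.0, 0.0])
    with pytest.raises(ValueError):
        ad.bounce_velocity(np.array([0.5, 0.0, 0.0]), n, RestitutionPair(0.5, 0.5))


def test_restitution_pair_bounds():
    with pytest.raises(ValueError):
        RestitutionPair(0.0, 0.5)
    with pytest.raises(ValueError):
        RestitutionPair(0.5, 1.1)


# ---------------------------------------------------------------------------
# near-wall drag chain

def test_stokes_drag_linear_and_zero(mat, fluid):
    assert ad.stokes_drag(1e-6, 0.0, fluid) == 0.0
    F1 = ad.stokes_drag(1e-6, 1.0, fluid, f=mat.f, Cu=mat.Cu)
    assert ad.stokes_drag(1e-6, 2.0, fluid, f=mat.f, Cu=mat.Cu) == pytest.approx(2 * F1)
    assert ad.stokes_drag(2e-6, 1.0, fluid, f=mat.f, Cu=mat.Cu) == pytest.approx(2 * F1)


def test_sublayer_velocity_quadratic(fluid):
    assert ad.sublayer_velocity(1e-6, 0.0, fluid) == 0.0
    v1 = ad.sublayer_velocity(1e-6, 1.0, fluid)
    assert ad.sublayer_velocity(1e-6, 3.0, fluid) == pytest.approx(9 * v1)


def test_wall_drag_equals_composed_chain(mat, fluid):
    """Closed-form wall drag == Stokes drag at the sublayer velocity."""
    dp = np.linspace(0.5e-6, 5e-6, 20)[:, None]
    us = np.linspace(0.1, 5.0, 20)[None, :]
    direct = ad.wall_drag_force(dp, us, fluid, f=mat.f, Cu=mat.Cu)
    composed = ad.stokes_drag(dp * np.ones_like(us),
                              ad.sublayer_velocity(dp, us, fluid),
                              fluid, f=mat.f, Cu=mat.Cu)
    assert np.max(np.abs(direct - composed) / composed) < 1e-9


def test_wall_drag_coefficient_is_5_1_pi_over_2(fluid):
    dp, us = 2e-6, 1.3
    expected = 5.1 * PI / 2 * dp**2 * fluid.rho * us**2
    assert ad.wall_drag_force(dp, us, fluid, f=1.7, Cu=1.0) == pytest.approx(expected, rel=1e-12)


# ---------------------------------------------------------------------------
# detachment thresholds: bisection oracle equivalence

def _uR_bisect(dp, mat, fluid):
    Fst = ad.adhesion_force(dp, mat)
    a = ad.contact_radius(dp, mat)
    return brentq(lambda u: ad.wall_drag_force(dp, u, fluid, f=mat.f, Cu=mat.Cu)
                  * dp / 2 - Fst * a, 1e-8, 1e5)


def _uS_bisect(dp, mat, fluid):
    Fst = ad.adhesion_force(dp, mat)
    return brentq(lambda u: ad.wall_drag_force(dp, u, fluid, f=mat.f, Cu=mat.Cu)
                  - mat.ks * Fst, 1e-8, 1e5)


def test_critical_shear_reference_values(mat, fluid):
    assert ad.critical_shear_rolling(1e-6, mat, fluid) == pytest.approx(31.376855, rel=1e-6)
    assert ad.critical_shear_rolling(5e-6, mat, fluid) == pytest.approx(10.730733, rel=1e-6)
    assert ad.critical_shear_sliding(5e-6, mat, fluid) == pytest.approx(30.600238, rel=1e-6)


def test_critical_shear_closed_forms_match_bisection(mat, fluid):
    for dp in np.geomspace(0.1e-6, 10e-6, 15):
        uR = ad.critical_shear_rolling(dp, mat, fluid)
        uS = ad.critical_shear_sliding(dp, mat, fluid)
        assert abs(uR - _uR_bisect(dp, mat, fluid)) / uR < 0.02
        assert abs(uS - _uS_bisect(dp, mat, fluid)) / uS < 0.02


def test_sliding_root_defining_property(mat, fluid):
    dp = 3e-6
    uS = ad.critical_shear_sliding(dp, mat, fluid)
    FD = ad.wall_drag_force(dp, uS, fluid, f=mat.f, Cu=mat.Cu)
    assert FD == pytest.approx(mat.ks * ad.adhesion_force(dp, mat), rel=1e-12)


def test_sliding_root_power_law(mat, fluid):
    r = ad.critical_shear_sliding(4e-6, mat, fluid) / ad.critical_shear_sliding(1e-6, mat, fluid)
    assert r == pytest.approx(0.5, rel=1e-12)          # dp^(-1/2)


def test_as_printed_variants(mat, fluid):
    # literal published expressions, retained for audit (units m^2/s^2)
    dp = 1e-6
    KC = ad.composite_young(mat)
    expected = (1 / fluid.rho) * KC ** (-1 / 3) * (mat.WA / dp) ** (4 / 3)
    assert ad.critical_shear_rolling(dp, mat, fluid, variant="as_printed") == \
        pytest.approx(expected, rel=1e-12)
    dp = 5e-6
    assert ad.critical_shear_sliding(dp, mat, fluid, variant="as_printed") == \
        pytest.approx(0.5 * mat.ks * mat.WA / (mat.rho_p * dp), rel=1e-12)
    with pytest.raises(ValueError):
        ad.critical_shear_rolling(dp, mat, fluid, variant="bogus")


def test_rolling_and_sliding_checks_inclusive_boundary():
    assert ad.rolling_check(0.0, 1e-6, 1e-7, 5e-8) is False
    # FD*dp/2 == Fst*a exactly -> detaches (inclusive >=)
    assert ad.rolling_check(2e-7 * 5e-8 / (0.5e-6), 1e-6, 2e-7, 5e-8) is True
    assert ad.sliding_check(0.0, 0.5, 1e-7) is False
    assert ad.sliding_check(5e-8, 0.5, 1e-7) is True


# ---------------------------------------------------------------------------
# detachment decision

def test_detachment_decision_quiescent_and_low_shear(mat, fluid):
    assert ad.detachment_decision(1e-6, 0.0, mat, fluid).outcome is \
        DetachmentOutcome.REMAIN_STUCK
    for dp in np.linspace(0.5e-6, 5e-6, 10):
        for us in (0.1, 0.5, 1.0):
            assert ad.detachment_decision(dp, us, mat, fluid).outcome is \
                DetachmentOutcome.REMAIN_STUCK


def test_detachment_outcome_flips_at_rolling_threshold(mat, fluid):
    dp = 2e-6
    uR = ad.critical_shear_rolling(dp, mat, fluid)
    below = ad.detachment_decision(dp, uR * (1 - 1e-9), mat, fluid)
    above = ad.detachment_decision(dp, uR * (1 + 1e-9), mat, fluid)
    assert below.outcome is DetachmentOutcome.REMAIN_STUCK
    assert above.outcome is DetachmentOutcome.DETACH_ROLLING


def test_detachment_rolling_takes_precedence_over_sliding(mat, fluid):
    dp = 2e-6
    uS = ad.critical_shear_sliding(dp, mat, fluid)
    res = ad.detachment_decision(dp, 2 * uS, mat, fluid)
    assert res.rolling and res.sliding
    assert res.outcome is DetachmentOutcome.DETACH_ROLLING


def test_detachment_outcome_consistent_with_thresholds(mat, fluid):
    for dp in (0.7e-6, 2e-6, 4.5e-6):
        for us in (0.2, 5.0, 15.0, 40.0, 120.0):
            r = ad.detachment_decision(dp, us, mat, fluid)
            assert r.rolling == (us >= r.uR_star * (1 - 1e-12))
            assert r.sliding == (us >= r.uS_star * (1 - 1e-12))


# ---------------------------------------------------------------------------
# monotonicity properties

@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.floats(min_value=0.1e-6, max_value=9e-6),
       st.floats(min_value=1.05, max_value=2.0))
def test_size_monotonicity(dp, factor):
    """vcr, uR*, uS* decrease with diameter; Fst, a increase."""
    from inhaledpm import FluidProperties, MaterialParameters
    mat, fluid = MaterialParameters(), FluidProperties()
    d2 = dp * factor
    k1, k2 = ad.compliances(mat)
    E = ad.elbatsh_parameter(k1, k2, mat.rho_p)
    assert ad.capture_velocity(d2, E) < ad.capture_velocity(dp, E)
    assert ad.critical_shear_rolling(d2, mat, fluid) < ad.critical_shear_rolling(dp, mat, fluid)
    assert ad.critical_shear_sliding(d2, mat, fluid) < ad.critical_shear_sliding(dp, mat, fluid)
    assert ad.adhesion_force(d2, mat) > ad.adhesion_force(dp, mat)
    assert ad.contact_radius(d2, mat) > ad.contact_radius(dp, mat)
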