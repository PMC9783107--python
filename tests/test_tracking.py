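"""Particle tracking: injection protocol, integrator accuracy, impact
handling and run-level bookkeeping invariants."""

import math
from dataclasses import replace

import numpy as np
import pytest

from inhaledpm import (CallableField, RestitutionPair, SimulationConfig,
                       SizeDistribution, handle_impact, inject,
                       relaxation_time, run, step)
from inhaledpm.adhesion import DetachmentOutcome
from inhaledpm.geometry import WallHit
from inhaledpm.tracking import ParticleState, ParticleStatus


def small_config(**kw):
    defaults = dict(n_particles=60, seed=7)
    defaults.update(kw)
    return SimulationConfig(**defaults)


def still_fluid():
    return CallableField(lambda p: np.zeros_like(p))


# ---------------------------------------------------------------------------
# injection

def test_inject_is_deterministic_per_seed(geometry, default_field):
    cfg = small_config()
    a = inject(cfg, geometry, default_field, np.random.default_rng(cfg.seed))
    b = inject(cfg, geometry, default_field, np.random.default_rng(cfg.seed))
    assert all(np.array_equal(p.x, q.x) and np.array_equal(p.v, q.v)
               and p.dp == q.dp for p, q in zip(a, b))


def test_inject_protocol_defaults(geometry, default_field, rng):
    cfg = SimulationConfig()
    assert cfg.n_particles == 500
    assert cfg.release_height == pytest.approx(12.5e-3)
    assert cfg.flow_rate_lpm == 60.0
    parts = inject(cfg, geometry, default_field, rng)
    assert len(parts) == 500
    # release plane, inside the capsule chamber
    assert all(p.x[2] == pytest.approx(12.5e-3) for p in parts)
    # initial slip velocity is zero: particle starts with the fluid velocity
    X = np.stack([p.x for p in parts])
    U = default_field.velocity(X)
    V = np.stack([p.v for p in parts])
    assert np.allclose(V, U)
    # diameters respect the truncation window
    dps = np.array([p.dp for p in parts])
    assert dps.min() >= 0.5e-6 and dps.max() <= 5e-6


def test_inject_release_plane_outside_domain(geometry, default_field, rng):
    cfg = small_config(release_height=1.0)
    with pytest.raises(ValueError):
        inject(cfg, geometry, default_field, rng)


def test_random_injection_mode(geometry, default_field):
    cfg = small_config(injection_mode="random")
    a = inject(cfg, geometry, default_field, np.random.default_rng(3))
    b = inject(cfg, geometry, default_field, np.random.default_rng(3))
    assert all(np.array_equal(p.x, q.x) for p, q in zip(a, b))
    dps = np.array([p.dp for p in a])
    assert dps.min() >= 0.5e-6 and dps.max() <= 5e-6


def test_size_distribution_quantiles_monotone():
    d = SizeDistribution()
    q = np.linspace(0.01, 0.99, 50)
    vals = d.quantiles(q)
    assert np.all(np.diff(vals) > 0)
    assert vals[0] >= d.lo and vals[-1] <= d.hi


# ---------------------------------------------------------------------------
# integrator

def test_relaxation_time_reference(mat, fluid):
    assert relaxation_time(5e-6, mat, fluid) == pytest.approx(9.546962e-5, rel=1e-6)


def test_uniform_field_advection_is_exact(mat, fluid):
    u0 = np.array([1.0, -2.0, 0.5])
    field = CallableField(lambda p: np.tile(u0, (len(p), 1)))
    p = ParticleState(id=0, dp=2e-6, x=np.zeros(3), v=u0.copy())
    for _ in range(20):
        p = step(p, field, fluid, 1e-5, mat=mat)
    assert np.allclose(p.v, u0, rtol=0, atol=0)
    assert np.allclose(p.x, u0 * p.t, rtol=1e-12)


def test_still_fluid_velocity_relaxation(mat, fluid):
    """Speed decays as exp(-t/tau_p) within 1% at dt = tau_p/10."""
    dp = 2e-6
    tau = relaxation_time(dp, mat, fluid)
    p = ParticleState(id=0, dp=dp, x=np.zeros(3), v=np.array([1.0, 0.0, 0.0]))
    field = still_fluid()
    dt = tau / 10
    for _ in range(30):
        p = step(p, field, fluid, dt, mat=mat)
    expected = math.exp(-p.t / tau)
    assert abs(p.v[0] - expected) / expected < 0.01


def test_step_rejects_bad_dt(mat, fluid):
    p = ParticleState(id=0, dp=1e-6, x=np.zeros(3), v=np.zeros(3))
    with pytest.raises(ValueError):
        step(p, still_fluid(), fluid, 0.0, mat=mat)


# ---------------------------------------------------------------------------
# impact handling

def _wall_hit(normal=(1.0, 0.0, 0.0), kind="wall"):
    return WallHit(point=np.array([0.01, 0.0, 0.01]),
                   normal=np.array(normal), region="capsule_chamber",
                   kind=kind, s=0.5)


def test_grazing_impact_sticks(mat):
    p = ParticleState(id=1, dp=2e-6, x=np.zeros(3),
                      v=np.array([-1e-6, 0.0, 1.0]))
    p2, ev = handle_impact(p, _wall_hit(), mat, RestitutionPair(0.5, 0.5))
    assert p2.status is ParticleStatus.STUCK
    assert ev.outcome == "stick" and ev.vn < ev.vcr
    assert p2.stuck_region == "capsule_chamber"


def test_supercritical_impact_bounces_with_cor(mat):
    vn_in = 30.0                       # above vcr for any dp in range
    p = ParticleState(id=2, dp=5e-6, x=np.zeros(3),
                      v=np.array([-vn_in, 0.0, 2.0]))
    cor = RestitutionPair(0.5, 0.75)
    p2, ev = handle_impact(p, _wall_hit(), mat, cor)
    assert p2.status is ParticleStatus.IN_FLOW
    assert ev.outcome == "bounce" and ev.vn > ev.vcr
    assert p2.v[0] == pytest.approx(cor.e_n * vn_in)
    assert p2.v[2] == pytest.approx(cor.e_t * 2.0)


def test_outlet_hit_emits_without_event(mat):
    p = ParticleState(id=3, dp=2e-6, x=np.zeros(3),
                      v=np.array([0.0, 0.0, 5.0]))
    p2, ev = handle_impact(p, _wall_hit(normal=(0, 0, -1.0), kind="outlet"),
                           mat, RestitutionPair(0.5, 0.5))
    assert p2.status is ParticleStatus.EMITTED
    assert ev is None


# ---------------------------------------------------------------------------
# full runs

def test_run_conserves_particles_and_event_invariants(geometry, default_field,
                                                      fluid, mat):
    cfg = small_config()
    res = run(cfg, geometry, default_field, fluid, mat)
    c = res.counts()
    assert c["in_flow"] == 0
    assert sum(c.values()) == cfg.n_particles
    for ev in res.impacts:
        if ev.outcome == "stick":
            assert ev.vn <= ev.vcr
        else:
            assert ev.vn > ev.vcr
    # one detachment assessment per deposition event
    stick_events = [e for e in res.impacts if e.outcome == "stick"]
    assert len(res.detachments) >= len(
        [p for p in res.states if p.status is ParticleStatus.STUCK])
    assert len(stick_events) == len(res.detachments)


def test_run_seed_determinism(geometry, default_field, fluid, mat):
    cfg = small_config()
    r1 = run(cfg, geometry, default_field, fluid, mat)
    r2 = run(cfg, geometry, default_field, fluid, mat)
    assert len(r1.impacts) == len(r2.impacts)
    for a, b in zip(r1.impacts, r2.impacts):
        assert a.particle_id == b.particle_id and a.outcome == b.outcome
        assert a.vn == b.vn and a.time == b.time
    assert [p.status for p in r1.states] == [p.status for p in r2.states]


def test_zero_flow_emits_nothing(geometry, fluid, mat):
    cfg = small_config(max_transit_time=5e-3)
    res = run(cfg, geometry, still_fluid(), fluid, mat)
    c = res.counts()
    assert c["emitted"] == 0
    assert c["in_domain_timeout"] + c["stuck"] == cfg.n_particles


def test_detachment_assessments_match_thresholds(geometry, default_field,
                                                 fluid, mat):
    """Outcome of every assessment agrees with an independent u* comparison."""
    from inhaledpm import critical_shear_rolling, critical_shear_sliding
    cfg = small_config(n_particles=120)
    res = run(cfg, geometry, default_field, fluid, mat)
    assert res.detachments, "expected some deposition in the default setup"
    for d in res.detachments:
        a = d.assessment
        uR = critical_shear_rolling(d.dp, mat, fluid)
        uS = critical_shear_sliding(d.dp, mat, fluid)
        assert a.uR_star == pytest.approx(uR, rel=1e-12)
        assert a.uS_star == pytest.approx(uS, rel=1e-12)
        expect_roll = a.u_star >= uR
        expect_slide = a.u_star >= uS
        if expect_roll:
            assert a.outcome is DetachmentOutcome.DETACH_ROLLING
        elif expect_slide:
            assert a.outcome is DetachmentOutcome.DETACH_SLIDING
        else:
            assert a.outcome is DetachmentOutcome.REMAIN_STUCK
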