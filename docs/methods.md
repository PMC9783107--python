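# Methods

## Scope and modelling stance

The package simulates the fate of respirable microparticles
(0.5–5 µm) released inside a capsule-type dry powder inhaler during one
inhalation: transport by the airflow, wall impact, adhesion or rebound,
and possible resuspension of deposited particles. Two deliberate
simplifications define the stance:

1. **The carrier flow is prescribed, not solved.** At the nominal
   operating point (60 L/min, set in the real device by a ~2800 Pa
   pressure drop) the instantaneous flow rate sits near its peak for
   most of the inhalation, so a steady field is a good approximation,
   and the particle physics consumes only local velocities and
   near-wall shear. Analytic surrogate fields stand in for a CFD
   solution; gridded fields from any external solver can be loaded
   instead (CSV point dialect or legacy-VTK structured points).
2. **One-way coupling.** The powder phase is dilute; particles do not
   modify the flow and do not interact with each other. No turbulent
   dispersion is added: the tracker is deterministic given the field
   (an eddy-interaction model is a natural extension hook).

## Adhesion and detachment model

Sticking is van-der-Waals only (dry conditions): `F_st = (3/4)π W_A d_p`
with the silicon–silicon work of adhesion `W_A = 0.039 J/m²` as the
default contact pair. Impacts are classified by the Dahneke capture
criterion using the Brach–Dunn/El-Batsh capture velocity
`v_cr = (2E/d_p)^{10/7}`; the composite parameter `E` is treated as the
SI composite that makes `v_cr` come out in m/s for `d_p` in metres.
Rebounds scale the normal and tangential velocity components by the
restitution pair `(e_n, e_t)`; ties `v_n = v_cr` count as capture (a
measure-zero case; the inclusive choice mirrors the inclusive `≥` of
the detachment balances).

Deposited particles feel the wall-parallel drag of the viscous
sublayer, evaluated at the particle centre height `d_p/2`:
`V = ρ d_p u*²/(2μ)`, `F_D = 3πμ d_p V f/C_u` with the near-wall
correction `f = 1.7`. Two failure modes are assessed:

- rolling, a moment balance about the contact edge:
  `F_D d_p/2 ≥ F_st a`, contact radius `a = [3π W_A d_p²/(2 K_C)]^{1/3}`;
- sliding, a friction balance: `F_D ≥ k_s F_st`.

Lift and the normal flattening `b` of the contact are neglected — both
are small for elastic microparticles (`a < d_p/10` across the whole
size range, verified in the tests) — so neither appears in the data
model. When both criteria hold, the outcome is recorded as rolling,
the more likely mode for spheres; both raw flags are kept in the
assessment record.

**Critical wall shear velocities.** The published closed forms for the
rolling/sliding thresholds are dimensionally inconsistent as printed
(m²/s²; the sliding form also carries the particle density where the
force balance implies the fluid density). The default `force_balance`
variant therefore defines `u_R*` and `u_S*` as the exact roots of the
two balances above — closed forms
`u_R* = sqrt(W_A a C_u/(f ρ d_p²))` and
`u_S* = sqrt(k_s W_A C_u/(2 f ρ d_p))` — which the tests verify against
independent bisection to better than 2% over 0.1–10 µm (the rolling
closed form is ~0.99× the square root of the printed expression). The
literal printed expressions remain available as `variant="as_printed"`
for audit, including the particle-density sliding form.

Because the flow is steady, each deposited particle is assessed once,
at its deposition point, using the friction velocity sampled from the
local field (`u* = sqrt(μ|u_t|/(ρ ds))` at offset `ds` along the inward
normal; `ds` defaults to 50 µm, a first-grid-point distance consistent
with a `y+ ≈ 2.5` near-wall resolution, and is configurable). A
detached particle re-enters the flow from rest at the wall — the
conservative choice; it immediately re-accelerates by drag — and is
re-tracked, up to five rounds.

## Surrogate geometry and flow

The real device geometry is proprietary CAD, so the domain is an
idealised axisymmetric body of revolution preserving the four-region
topology: capsule chamber (R 10 mm × 20 mm), conical transition,
central chamber (R 8 mm × 16 mm), grid zone (R 6 mm) holding a
perforated screen, and mouthpiece (R 5.15 mm × 30 mm). The mouthpiece
bore is sized so 60 L/min gives a ~12 m/s mean outlet speed. The
release plane sits 12.5 mm above the base — the capsule position. The
screen is an axial plane with a periodic square-opening mask (pitch
1.2 mm, open-area fraction 0.6, both configurable) rather than resolved
3-D bars. Two tangential inlet patches are marked on the capsule-chamber
wall for labelling; dynamically they behave as walls.

Three analytic field kinds are provided, all exactly flux-calibrated at
the outlet: a generalised Poiseuille duct (parabolic axial profile on
the local radius `R(z)` plus the continuity-consistent radial
component), the same plus a Rankine swirl confined to the capsule and
central chambers, and the default grid-jet composite that additionally
steers flow toward the nearest screen opening and accelerates it
through by the inverse open fraction within 1.5 pitches of the screen.

**Calibration (one-time).** The surrogate has two free intensity
parameters with no counterpart in the printed formulas: the swirl peak
speed and the grid steering coefficient. They were set once — swirl
7.0 m/s (core at half radius), steering 0.3 — so that total deposition
of the default protocol falls in the 13–18% range reported for this
class of capsule device at 60 L/min, and were not adjusted thereafter.
All other defaults (materials, flow rate, release height, particle
count, size window) are the study conditions themselves.

## Injection

The default injection is a deterministic stratified surface release,
emulating the cell-centre surface injection of CFD solvers: positions
on a sunflower-spiral covering of the release disc (95% of the local
radius), diameters at the quantiles of the size distribution, paired to
positions by a Fibonacci-stride permutation. This makes the injected
ensemble — and hence the deposition statistics — nearly independent of
particle count, which is what allows a 100-vs-5000-particle comparison
to agree within a few tenths of a percentage point; a pure
pseudo-random mode (`injection_mode="random"`) is available, at the
cost of ~4-point binomial noise at n = 100. Initial particle velocity
equals the local fluid velocity (zero slip). The default size
distribution is lognormal, median 2 µm, GSD 1.8, truncated to the
0.5–5 µm respirable window; the true formulation distribution is not
published, so this is a configurable assumption.

## Numerical integration

The drag ODE `dv/dt = (u − v)/τ_p`, `τ_p = ρ_p d_p² C_u/(18 μ)`, is
linear, so each step applies its exact constant-field solution for both
velocity and position, with the field sampled at the step midpoint
(second order in field variation, exact in uniform flow, and
unconditionally stable — no stiffness constraint from the smallest
particles, whose `τ_p` is below a microsecond). Free-stream drag uses
`f = 1`; the near-wall correction applies only to the stuck-particle
assessment. The step is limited by a spatial cell-crossing bound
(`dx_max = 0.4 mm`, `dt_max = 50 µs`); results are insensitive to
halving it. Every step segment is intersected analytically with the
boundary (cylinder/cone lateral surface, base, screen plane with mask,
outlet), so impacts are resolved exactly; a bounced particle restarts
10 nm inside the wall along the inward normal. Particles exceeding a
0.25 s transit budget are reported as timed out (none do under the
default conditions). Gravity is off by default — transit times are far
below settling times at these sizes — with a config flag to enable the
drift-corrected update.

The fine-particle fraction is reported as emitted particles with
`d_p` below a configurable cutoff (default 5 µm) over injected — the
quantity is named but not uniquely defined in the DPI literature, so
the definition is explicit here.

## Default experiment sizes

The reference protocol injects 500 particles; the restitution sweep
runs the 4×4 grid (normal ∈ {0.20, 0.25, 0.50, 0.75}, tangential ∈
{0.25, 0.50, 0.75, 0.80}; the full 5×5 candidate set {0.2, 0.25, 0.5,
0.75, 0.85}² is available via config) with identical injection per
cell; the count-independence check uses 100/500/5000. A full sweep
takes about a minute on one CPU.

## What the surrogate does and does not show

Passing tests demonstrate the adhesion/detachment physics is
implemented exactly (closed forms vs independent roots, identities to
1e-9), and that on a flux-calibrated swirling surrogate the *mechanism*
conclusions hold: deposition happens at grazing sub-critical impacts,
and no deposited particle approaches the rolling or sliding threshold
(`u*` is one to two orders of magnitude below `u_R*`, `u_S*`). They do
not validate device-specific quantities: region-by-region percentages,
the spatial impact pattern, and the sensitivity to the restitution
coefficients all depend on the real geometry's jets and recirculation,
which the surrogate only caricatures. In particular the restitution
coefficients move total deposition by only ~0.2 points here (nearly all
capture events are first-contact grazing impacts), whereas a real
device shows a few points of spread; both are consistent with the
qualitative finding that restitution has no large effect. Humidity and
temperature effects, electrostatics, liquid bridges, particle breakage
and agglomeration are outside the model, as is any JKR/DMT
contact-mechanics refinement.
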