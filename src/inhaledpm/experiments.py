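"""Numerical experiments: COR sweep, count independence, reporting.

The headline experiment is a 4x4 sweep over normal/tangential restitution
coefficient pairs with identical seed and injection in every cell,
reporting region-wise deposition percentages and total rolling/sliding
detachment counts per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from .adhesion import DetachmentOutcome, RestitutionPair
from .geometry import REGIONS, SurrogateGeometry
from .tracking import ParticleStatus, RunResult, SimulationConfig, run

__all__ = [
    "DepositionReport",
    "SweepResult",
    "NORMAL_COR_GRID",
    "TANGENTIAL_COR_GRID",
    "deposition_report",
    "cor_sweep",
    "particle_count_independence",
    "diagnostics_tables",
    "write_event_logs",
]

# Default sweep grid: 4 normal x 4 tangential restitution values.
NORMAL_COR_GRID = (0.20, 0.25, 0.50, 0.75)
TANGENTIAL_COR_GRID = (0.25, 0.50, 0.75, 0.80)
# Full candidate list from the impact literature (available via config).
COR_CANDIDATES = (0.2, 0.25, 0.5, 0.75, 0.85)


@dataclass(frozen=True)
class DepositionReport:
    """Region-wise deposition outcome of one simulation.

    Percentages are of injected particles. The dispersion chamber is the
    capsule chamber plus the central chamber. FPF is the emitted fraction
    with diameter below the cutoff (the fraction fine enough to be lung-
    available); the cutoff is configurable and not uniquely standardised.
    """

    n_injected: int
    region_counts: dict[str, int]
    region_pct: dict[str, float]
    dispersion_chamber_pct: float
    total_deposition_pct: float
    emitted_pct: float
    timeout_pct: float
    fpf_pct: float
    fpf_cutoff: float

    def to_dict(self) -> dict:
        return {
            "n_injected": self.n_injected,
            "region_counts": dict(self.region_counts),
            "region_pct": dict(self.region_pct),
            "dispersion_chamber_pct": self.dispersion_chamber_pct,
            "total_deposition_pct": self.total_deposition_pct,
            "emitted_pct": self.emitted_pct,
            "timeout_pct": self.timeout_pct,
            "fpf_pct": self.fpf_pct,
            "fpf_cutoff": self.fpf_cutoff,
        }


def deposition_report(result: RunResult, geometry: SurrogateGeometry,
                      fpf_cutoff: float = 5.0e-6) -> DepositionReport:
    """Aggregate terminal particle states into a deposition report."""
    states = result.states
    n = len(states)
    counts = {r: 0 for r in REGIONS}
    emitted = timeout = 0
    fine_emitted = 0
    for p in states:
        if p.status is ParticleStatus.STUCK:
            counts[p.stuck_region] += 1
        elif p.status is ParticleStatus.EMITTED:
            emitted += 1
            if p.dp < fpf_cutoff:
                fine_emitted += 1
        elif p.status is ParticleStatus.TIMEOUT:
            timeout += 1
    pct = {r: 100.0 * c / n for r, c in counts.items()}
    total_dep = sum(pct.values())
    return DepositionReport(
        n_injected=n,
        region_counts=counts,
        region_pct=pct,
        dispersion_chamber_pct=pct["capsule_chamber"] + pct["central_chamber"],
        total_deposition_pct=total_dep,
        emitted_pct=100.0 * emitted / n,
        timeout_pct=100.0 * timeout / n,
        fpf_pct=100.0 * fine_emitted / n,
        fpf_cutoff=fpf_cutoff,
    )


@dataclass
class SweepResult:
    """COR sweep output: one report + detachment count per grid cell."""

    reports: dict[tuple[float, float], DepositionReport]
    detachment_counts: dict[tuple[float, float], int]

    @property
    def total_detachments(self) -> int:
        return sum(self.detachment_counts.values())

    @property
    def max_total_deposition(self) -> float:
        return max(r.total_deposition_pct for r in self.reports.values())

    @property
    def min_total_deposition(self) -> float:
        return min(r.total_deposition_pct for r in self.reports.values())

    def to_dataframe(self) -> pd.DataFrame:
        """Total deposition (%) table: rows tangential COR, cols normal COR."""
        e_ns = sorted({k[0] for k in self.reports})
        e_ts = sorted({k[1] for k in self.reports})
        data = [[self.reports[(en, et)].total_deposition_pct for en in e_ns]
                for et in e_ts]
        return pd.DataFrame(data, index=pd.Index(e_ts, name="cor_tangential"),
                            columns=pd.Index(e_ns, name="cor_normal"))


def cor_sweep(base_config: SimulationConfig, geometry: SurrogateGeometry, field,
              fluid, mat, normal_values=NORMAL_COR_GRID,
              tangential_values=TANGENTIAL_COR_GRID,
              keep_results: bool = False):
    """Run one simulation per (normal, tangential) COR combination.

    Seed and therefore injection are identical across cells, so cells
    differ only in the rebound treatment.
    """
    reports: dict[tuple[float, float], DepositionReport] = {}
    detach: dict[tuple[float, float], int] = {}
    results: dict[tuple[float, float], RunResult] = {}
    for en in normal_values:
        for et in tangential_values:
            cfg = replace(base_config, cor=RestitutionPair(e_n=en, e_t=et))
            res = run(cfg, geometry, field, fluid, mat)
            key = (en, et)
            reports[key] = deposition_report(res, geometry)
            detach[key] = sum(
                1 for d in res.detachments
                if d.assessment.outcome is not DetachmentOutcome.REMAIN_STUCK)
            if keep_results:
                results[key] = res
    sweep = SweepResult(reports=reports, detachment_counts=detach)
    return (sweep, results) if keep_results else sweep


def particle_count_independence(base_config: SimulationConfig,
                                geometry: SurrogateGeometry, field, fluid, mat,
                                counts=(100, 500, 5000),
                                tolerance_pp: float = 3.0) -> pd.DataFrame:
    """Total deposition vs injected particle count.

    Flags any pairwise difference above ``tolerance_pp`` percentage
    points; at least two counts are required for a comparison.
    """
    counts = list(counts)
    if len(counts) < 2:
        raise ValueError("particle-count independence needs at least two counts")
    rows = []
    for n in counts:
        cfg = replace(base_config, n_particles=int(n))
        res = run(cfg, geometry, field, fluid, mat)
        rep = deposition_report(res, geometry)
        rows.append({"n_particles": int(n),
                     "total_deposition_pct": rep.total_deposition_pct,
                     "emitted_pct": rep.emitted_pct})
    df = pd.DataFrame(rows)
    spread = df["total_deposition_pct"].max() - df["total_deposition_pct"].min()
    df.attrs["max_pairwise_difference_pp"] = float(spread)
    df.attrs["within_tolerance"] = bool(spread <= tolerance_pp)
    df.attrs["tolerance_pp"] = float(tolerance_pp)
    return df


def diagnostics_tables(result: RunResult) -> dict[str, pd.DataFrame]:
    """Per-particle diagnostic tables behind the standard result plots.

    ``moments``: drag vs adhesion moment per stuck particle;
    ``stick_velocities``: normal impact vs capture velocity per stick;
    ``impacts_z``: vn/vcr of every impact against its axial coordinate;
    ``stick_diameters``: vn/vcr of sticks against particle diameter;
    ``wall_shear``: local u* vs rolling/sliding critical values per
    stuck particle.
    """
    stick = [ev for ev in result.impacts if ev.outcome == "stick"]
    moments = pd.DataFrame(
        [{"particle_id": d.particle_id, "dp": d.dp,
          "drag_moment": d.assessment.drag_moment,
          "adhesion_moment": d.assessment.adhesion_moment}
         for d in result.detachments])
    stick_vel = pd.DataFrame(
        [{"particle_id": ev.particle_id, "vn": ev.vn, "vcr": ev.vcr}
         for ev in stick])
    impacts_z = pd.DataFrame(
        [{"particle_id": ev.particle_id, "z": float(ev.position[2]),
          "vn": ev.vn, "vcr": ev.vcr, "outcome": ev.outcome}
         for ev in result.impacts])
    stick_dp = pd.DataFrame(
        [{"particle_id": ev.particle_id, "dp": ev.dp, "vn": ev.vn, "vcr": ev.vcr}
         for ev in stick])
    shear = pd.DataFrame(
        [{"particle_id": d.particle_id, "dp": d.dp,
          "u_star": d.assessment.u_star, "uR_star": d.assessment.uR_star,
          "uS_star": d.assessment.uS_star}
         for d in result.detachments])
    tables = {"moments": moments, "stick_velocities": stick_vel,
              "impacts_z": impacts_z, "stick_diameters": stick_dp,
              "wall_shear": shear}
    if not result.impacts:
        import warnings
        warnings.warn("no impact events: diagnostic tables are empty")
    return tables


def write_event_logs(result: RunResult, outdir) -> dict[str, Path]:
    """Write the stick/impact/detachment event logs as CSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    ev_cols = ["particle_id", "time", "x", "y", "z", "region", "dp", "vn",
               "vcr", "outcome"]

    def ev_row(ev):
        return {"particle_id": ev.particle_id, "time": ev.time,
                "x": ev.position[0], "y": ev.position[1], "z": ev.position[2],
                "region": ev.region, "dp": ev.dp, "vn": ev.vn, "vcr": ev.vcr,
                "outcome": ev.outcome}

    impact_df = pd.DataFrame([ev_row(ev) for ev in result.impacts],
                             columns=ev_cols)
    stick_df = impact_df[impact_df["outcome"] == "stick"]
    paths["impact"] = outdir / "impact.csv"
    impact_df.to_csv(paths["impact"], index=False)
    paths["stick"] = outdir / "stick.csv"
    stick_df.to_csv(paths["stick"], index=False)

    det_cols = ["particle_id", "dp", "x", "y", "z", "region", "u_star",
                "uR_star", "uS_star", "FD", "drag_moment", "adhesion_moment"]

    def det_rows(outcome):
        return [{"particle_id": d.particle_id, "dp": d.dp,
                 "x": d.position[0], "y": d.position[1], "z": d.position[2],
                 "region": d.region, "u_star": d.assessment.u_star,
                 "uR_star": d.assessment.uR_star, "uS_star": d.assessment.uS_star,
                 "FD": d.assessment.FD, "drag_moment": d.assessment.drag_moment,
                 "adhesion_moment": d.assessment.adhesion_moment}
                for d in result.detachments if d.assessment.outcome is outcome]

    paths["detach_rolling"] = outdir / "detach_rolling.csv"
    pd.DataFrame(det_rows(DetachmentOutcome.DETACH_ROLLING),
                 columns=det_cols).to_csv(paths["detach_rolling"], index=False)
    paths["detach_sliding"] = outdir / "detach_sliding.csv"
    pd.DataFrame(det_rows(DetachmentOutcome.DETACH_SLIDING),
                 columns=det_cols).to_csv(paths["detach_sliding"], index=False)
    return paths
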