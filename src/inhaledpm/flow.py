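"""Steady flow fields for particle tracking.

The carrier flow is prescribed, not solved: at the 60 L/min operating
point the instantaneous flow rate stays near its peak for most of an
inhalation, so a steady field is a close approximation, and the particle
physics only needs velocities and near-wall shear. Three analytic
surrogate kinds are provided, all flux-calibrated to the configured
volumetric flow rate:

``pipe_poiseuille``
    Parabolic axial profile on the local duct radius R(z), with the
    radial component that keeps the parabolic family divergence-free as
    R(z) varies. Exact Poiseuille in any constant-radius section.
``chamber_swirl``
    The above plus a Rankine (solid-body core / free vortex) swirl in the
    capsule and central chambers, mimicking the tangential-inlet
    recirculation of capsule devices; the swirl decays axially before the
    grid.
``grid_jet_composite``
    The swirl field plus a screen model: approaching the grid plane the
    flow is steered laterally toward the nearest grid opening and
    accelerated through it by the inverse open-area fraction, emulating
    the high-velocity grid jets.

Gridded fields (trilinear interpolation) can be loaded from a CSV point
dialect (columns ``x,y,z,ux,uy,uz``, SI units, header required) or from a
legacy ASCII VTK STRUCTURED_POINTS file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .geometry import SurrogateGeometry
from .materials import FluidProperties

__all__ = [
    "FlowField",
    "CallableField",
    "AnalyticDuctField",
    "GriddedField",
    "WallShearSample",
    "make_analytic_field",
    "load_gridded_field",
    "write_gridded_field",
    "sample_field_on_grid",
    "wall_friction_velocity",
    "friction_velocity_from_field",
    "outlet_flux",
]

LPM_TO_M3S = 1.0 / 60000.0
DEFAULT_DS = 50.0e-6   # m, first-sample wall offset for shear evaluation


@dataclass(frozen=True)
class WallShearSample:
    """Near-wall shear state at one wall point.

    The triple satisfies the wall-function identity
    ``u* = mu * y_plus / (rho_M * ds)`` exactly.
    """

    u_star: float
    y_plus: float
    ds: float


class FlowField:
    """Contract: steady velocity at interior points + wall offset ds."""

    ds: float = DEFAULT_DS
    flow_rate_lpm: float | None = None
    pressure_drop: float | None = None

    def velocity(self, points: np.ndarray) -> np.ndarray:
        """Velocity vectors (m/s) at points (n, 3) -> (n, 3)."""
        raise NotImplementedError


class CallableField(FlowField):
    """Wrap an arbitrary ``f(points) -> (n, 3)`` callable as a field."""

    def __init__(self, func, ds: float = DEFAULT_DS):
        self._func = func
        self.ds = ds

    def velocity(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.asarray(self._func(points), dtype=float)
        return out.reshape(points.shape)


class AnalyticDuctField(FlowField):
    """Analytic surrogate field on a :class:`SurrogateGeometry`."""

    def __init__(self, geometry: SurrogateGeometry, flow_rate_lpm: float,
                 kind: str = "pipe_poiseuille",
                 swirl_peak: float = 0.0, swirl_core_fraction: float = 0.5,
                 grid_slab: float | None = None, grid_steer: float = 1.0,
                 ds: float = DEFAULT_DS, pressure_drop: float = 2800.0):
        if flow_rate_lpm <= 0:
            raise ValueError("flow rate must be positive")
        if kind not in ("pipe_poiseuille", "chamber_swirl", "grid_jet_composite"):
            raise ValueError(f"unsupported analytic field kind {kind!r}")
        self.geometry = geometry
        self.kind = kind
        self.flow_rate_lpm = flow_rate_lpm
        self.Q = flow_rate_lpm * LPM_TO_M3S
        self.swirl_peak = float(swirl_peak)
        self.swirl_core_fraction = float(swirl_core_fraction)
        self.grid_slab = grid_slab if grid_slab is not None else 1.5 * geometry.grid_pitch
        self.grid_steer = float(grid_steer)
        self.ds = ds
        self.pressure_drop = pressure_drop

    # swirl active through capsule + central chamber, cosine-decayed to zero
    # between the chamber exit and the grid plane
    def _swirl_envelope(self, z):
        z_dec0 = self.geometry.region_breaks[2]
        z_dec1 = self.geometry.z_grid
        env = np.ones_like(z)
        ramp = np.clip((z - z_dec0) / max(z_dec1 - z_dec0, 1e-12), 0.0, 1.0)
        env = 0.5 * (1.0 + np.cos(math.pi * ramp))
        return env

    def velocity(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        x, y, z = p[:, 0], p[:, 1], p[:, 2]
        g = self.geometry
        R = np.asarray(g.radius_at(z))
        m = np.asarray(g.slope_at(z))
        r = np.hypot(x, y)
        rr = np.clip(r / R, 0.0, 1.0)
        Ubar = self.Q / (math.pi * R**2)
        uz = 2.0 * Ubar * (1.0 - rr**2)
        # continuity-consistent radial component of the parabolic family
        ur = (2.0 * self.Q * m / (math.pi * R**3)) * r * (1.0 - rr**2)
        with np.errstate(invalid="ignore", divide="ignore"):
            cx = np.where(r > 0, x / r, 0.0)
            cy = np.where(r > 0, y / r, 0.0)
        ux = ur * cx
        uy = ur * cy

        if self.kind in ("chamber_swirl", "grid_jet_composite") and self.swirl_peak > 0:
            rc = self.swirl_core_fraction * R
            vth = np.where(r <= rc, self.swirl_peak * r / rc,
                           self.swirl_peak * rc / np.maximum(r, 1e-300))
            vth = vth * self._swirl_envelope(z)
            ux += -vth * cy
            uy += vth * cx

        if self.kind == "grid_jet_composite":
            dzg = np.abs(z - g.z_grid)
            slab = self.grid_slab
            gfac = np.clip(1.0 - dzg / slab, 0.0, 1.0)
            active = gfac > 0
            if np.any(active):
                xa, ya = x[active], y[active]
                xc, yc = g.opening_center(xa, ya)
                open_mask = g.grid_open(xa, ya)
                phi = g.grid_open_fraction
                # jet acceleration through openings, blockage over bars
                boost = 1.0 + gfac[active] * (np.where(open_mask, 1.0 / phi, 0.0) - 1.0)
                uz_a = uz[active]
                uz[active] = uz_a * boost
                # lateral steering toward the nearest opening centre
                steer = self.grid_steer * gfac[active] * np.abs(uz_a) / slab
                ux[active] += steer * (xc - xa)
                uy[active] += steer * (yc - ya)

        out = np.stack([ux, uy, uz], axis=1)
        return out


class GriddedField(FlowField):
    """Velocity field on a regular grid with trilinear interpolation."""

    def __init__(self, xs, ys, zs, U, ds: float = DEFAULT_DS,
                 flow_rate_lpm: float | None = None):
        U = np.asarray(U, dtype=float)
        if U.shape != (len(xs), len(ys), len(zs), 3):
            raise ValueError("velocity array shape must be (nx, ny, nz, 3)")
        if not np.all(np.isfinite(U)):
            raise ValueError("velocity field contains non-finite values")
        self.xs, self.ys, self.zs = (np.asarray(v, float) for v in (xs, ys, zs))
        self.U = U
        self._interp = RegularGridInterpolator((self.xs, self.ys, self.zs), U,
                                               method="linear", bounds_error=True)
        self.ds = ds
        self.flow_rate_lpm = flow_rate_lpm

    @property
    def bounds(self):
        return ((self.xs[0], self.xs[-1]), (self.ys[0], self.ys[-1]),
                (self.zs[0], self.zs[-1]))

    def velocity(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return self._interp(p)


def make_analytic_field(kind: str, geometry: SurrogateGeometry, flow_rate: float,
                        **params) -> AnalyticDuctField:
    """Build an analytic surrogate field (``flow_rate`` in L/min)."""
    return AnalyticDuctField(geometry, flow_rate, kind=kind, **params)


def outlet_flux(field, geometry: SurrogateGeometry, n_r: int = 200) -> float:
    """Volumetric flux (m^3/s) through the outlet plane, by quadrature."""
    Rout = geometry.outlet_radius
    z = geometry.z_top - 1e-9
    r = (np.arange(n_r) + 0.5) * Rout / n_r
    pts = np.stack([r, np.zeros_like(r), np.full_like(r, z)], axis=1)
    uz = field.velocity(pts)[:, 2]
    return float(np.sum(uz * 2 * math.pi * r) * (Rout / n_r))


# ---------------------------------------------------------------------------
# wall shear

def wall_friction_velocity(y_plus, ds, fluid: FluidProperties):
    """Wall friction velocity from the wall-function identity.

    ``u* = mu * y_plus / (rho_M * ds)`` with ds the first-grid-point
    distance from the wall.
    """
    ds = np.asarray(ds, dtype=float)
    y_plus = np.asarray(y_plus, dtype=float)
    if np.any(ds <= 0):
        raise ValueError("wall offset ds must be strictly positive")
    if np.any(y_plus < 0):
        raise ValueError("y_plus must be non-negative")
    out = fluid.mu * y_plus / (fluid.rho_M * ds)
    return out if out.ndim else float(out)


def friction_velocity_from_field(field: FlowField, wall_point, fluid: FluidProperties,
                                 normal=None, ds: float | None = None) -> WallShearSample:
    """Evaluate the local friction velocity at a wall point.

    Samples the tangential fluid speed ``|u_t|`` at offset ``ds`` along
    the inward normal and inverts the linear-sublayer profile:
    ``u* = sqrt(mu |u_t| / (rho ds))``. ``y_plus`` is back-computed so the
    stored triple satisfies the wall-function identity exactly.
    """
    wall_point = np.asarray(wall_point, dtype=float)
    if normal is None:
        normal = _infer_normal(field, wall_point)
    normal = np.asarray(normal, dtype=float)
    nrm = float(np.linalg.norm(normal))
    if not math.isclose(nrm, 1.0, rel_tol=1e-6):
        normal = normal / nrm
    if ds is None:
        ds = field.ds
    sample = wall_point + ds * normal
    u = field.velocity(sample[None, :])[0]
    u_t = u - (u @ normal) * normal
    ut_mag = float(np.linalg.norm(u_t))
    u_star = math.sqrt(fluid.mu * ut_mag / (fluid.rho * ds))
    y_plus = fluid.rho_M * u_star * ds / fluid.mu
    return WallShearSample(u_star=u_star, y_plus=y_plus, ds=ds)


def _infer_normal(field: FlowField, wall_point: np.ndarray) -> np.ndarray:
    geom = getattr(field, "geometry", None)
    if geom is None:
        raise ValueError("field has no geometry; pass the wall normal explicitly")
    z = float(wall_point[2])
    if z <= 1e-9:
        return np.array([0.0, 0.0, 1.0])
    if z >= geom.z_top - 1e-9:
        return np.array([0.0, 0.0, -1.0])
    r = math.hypot(wall_point[0], wall_point[1])
    R = geom.radius_at(z)
    if abs(r - R) > 1e-6 and abs(z - geom.z_grid) < 1e-6:
        return np.array([0.0, 0.0, 1.0])   # grid bar face (lower side)
    if r == 0:
        raise ValueError("point is on the axis, not adjacent to a wall")
    m = geom.slope_at(z)
    n = np.array([-wall_point[0] / r, -wall_point[1] / r, m])
    return n / np.linalg.norm(n)


# ---------------------------------------------------------------------------
# gridded-field I/O

class FieldParseError(ValueError):
    """Raised for malformed gridded-field files."""


def sample_field_on_grid(field: FlowField, bounds, shape) -> GriddedField:
    """Sample any field on a regular grid (for fixtures and export)."""
    (x0, x1), (y0, y1), (z0, z1) = bounds
    nx, ny, nz = shape
    xs = np.linspace(x0, x1, nx)
    ys = np.linspace(y0, y1, ny)
    zs = np.linspace(z0, z1, nz)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    U = field.velocity(pts).reshape(nx, ny, nz, 3)
    return GriddedField(xs, ys, zs, U, ds=field.ds,
                        flow_rate_lpm=field.flow_rate_lpm)


def write_gridded_field(grid: GriddedField, path, format: str = "csv_points") -> None:
    """Write a gridded field as CSV points or legacy-VTK structured points."""
    path = Path(path)
    if format == "csv_points":
        X, Y, Z = np.meshgrid(grid.xs, grid.ys, grid.zs, indexing="ij")
        df = pd.DataFrame({
            "x": X.ravel(), "y": Y.ravel(), "z": Z.ravel(),
            "ux": grid.U[..., 0].ravel(),
            "uy": grid.U[..., 1].ravel(),
            "uz": grid.U[..., 2].ravel(),
        })
        df.to_csv(path, index=False, float_format="%.17g")
    elif format == "vtk_structured":
        xs, ys, zs = grid.xs, grid.ys, grid.zs
        for name, c in (("x", xs), ("y", ys), ("z", zs)):
            d = np.diff(c)
            if len(d) and not np.allclose(d, d[0], rtol=1e-9, atol=0):
                raise ValueError(f"vtk_structured requires uniform {name} spacing")
        nx, ny, nz = len(xs), len(ys), len(zs)
        sp = [c[1] - c[0] if len(c) > 1 else 1.0 for c in (xs, ys, zs)]
        lines = [
            "# vtk DataFile Version 3.0",
            "steady velocity field",
            "ASCII",
            "DATASET STRUCTURED_POINTS",
            f"DIMENSIONS {nx} {ny} {nz}",
            f"ORIGIN {xs[0]:.9e} {ys[0]:.9e} {zs[0]:.9e}",
            f"SPACING {sp[0]:.9e} {sp[1]:.9e} {sp[2]:.9e}",
            f"POINT_DATA {nx * ny * nz}",
            "VECTORS velocity double",
        ]
        # VTK structured-points ordering: x varies fastest
        U = np.transpose(grid.U, (2, 1, 0, 3)).reshape(-1, 3)
        lines += [f"{u:.9e} {v:.9e} {w:.9e}" for u, v, w in U]
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def load_gridded_field(path, format: str = "csv_points", ds: float = DEFAULT_DS) -> GriddedField:
    """Load a gridded velocity field from CSV points or legacy VTK."""
    path = Path(path)
    if format == "csv_points":
        return _load_csv_points(path, ds)
    if format == "vtk_structured":
        return _load_vtk_structured(path, ds)
    raise ValueError(f"unknown format {format!r}")


def _load_csv_points(path: Path, ds: float) -> GriddedField:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FieldParseError(f"{path}: {exc}") from exc
    required = ["x", "y", "z", "ux", "uy", "uz"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FieldParseError(f"{path}: missing columns {missing} (header required)")
    if df[required].isna().any().any():
        raise ValueError(f"{path}: velocity field contains NaN values")
    xs = np.unique(df["x"].to_numpy())
    ys = np.unique(df["y"].to_numpy())
    zs = np.unique(df["z"].to_numpy())
    if len(xs) * len(ys) * len(zs) != len(df):
        raise FieldParseError(
            f"{path}: rows do not form a full tensor-product grid "
            f"({len(xs)}x{len(ys)}x{len(zs)} != {len(df)})")
    df = df.sort_values(["x", "y", "z"], kind="mergesort")
    U = df[["ux", "uy", "uz"]].to_numpy().reshape(len(xs), len(ys), len(zs), 3)
    return GriddedField(xs, ys, zs, U, ds=ds)


def _load_vtk_structured(path: Path, ds: float) -> GriddedField:
    lines = path.read_text().splitlines()
    dims = origin = spacing = None
    data_start = None
    n_expected = None
    for i, ln in enumerate(lines):
        t = ln.split()
        if not t:
            continue
        key = t[0].upper()
        try:
            if key == "DIMENSIONS":
                dims = tuple(int(v) for v in t[1:4])
            elif key == "ORIGIN":
                origin = tuple(float(v) for v in t[1:4])
            elif key == "SPACING":
                spacing = tuple(float(v) for v in t[1:4])
            elif key == "POINT_DATA":
                n_expected = int(t[1])
            elif key == "VECTORS":
                data_start = i + 1
                break
        except (ValueError, IndexError) as exc:
            raise FieldParseError(f"{path}:{i + 1}: malformed header line {ln!r}") from exc
    if None in (dims, origin, spacing, data_start, n_expected):
        raise FieldParseError(f"{path}: incomplete STRUCTURED_POINTS header")
    vals = []
    for i, ln in enumerate(lines[data_start:], start=data_start):
        if ln.strip():
            try:
                vals.extend(float(v) for v in ln.split())
            except ValueError as exc:
                raise FieldParseError(f"{path}:{i + 1}: bad vector data {ln!r}") from exc
    arr = np.asarray(vals, dtype=float)
    nx, ny, nz = dims
    if arr.size != 3 * nx * ny * nz or n_expected != nx * ny * nz:
        raise FieldParseError(f"{path}: expected {3 * nx * ny * nz} values, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{path}: velocity field contains non-finite values")
    U = arr.reshape(nz, ny, nx, 3).transpose(2, 1, 0, 3)
    xs = origin[0] + spacing[0] * np.arange(nx)
    ys = origin[1] + spacing[1] * np.arange(ny)
    zs = origin[2] + spacing[2] * np.arange(nz)
    return GriddedField(xs, ys, zs, U, ds=ds)
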