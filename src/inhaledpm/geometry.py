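"""Idealised inhaler-like computational domain.

The real capsule-based device geometry is proprietary CAD; this surrogate
preserves its four-region topology — capsule chamber at the bottom,
central (dispersion) chamber, perforated grid zone, mouthpiece on top —
as an axisymmetric body of revolution with a piecewise-linear radius
profile ``R(z)`` and a perforated screen (periodic square openings)
spanning the grid plane. The default mouthpiece bore is sized so that a
60 L/min flow gives a mean outlet speed near 12 m/s.

Coordinates: z axial (m), bottom of the capsule chamber at z = 0, outlet
plane at z = H. Collision detection is exact: segments are intersected
with the bottom disc, the conical/cylindrical lateral surface, the grid
screen and the outlet plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Section", "SurrogateGeometry", "WallHit", "build_default_geometry"]

REGIONS = ("capsule_chamber", "central_chamber", "grid_zone", "mouthpiece")

_S_EPS = 1e-12          # reject crossings at the very start of a segment
WALL_NUDGE = 1e-8       # m, re-entry offset along the inward normal


@dataclass(frozen=True)
class Section:
    """One axial section of the body of revolution (cylinder or cone)."""

    z0: float
    z1: float
    R0: float
    R1: float

    @property
    def slope(self) -> float:
        return (self.R1 - self.R0) / (self.z1 - self.z0)


@dataclass(frozen=True)
class WallHit:
    """First boundary crossing of a trajectory segment."""

    point: np.ndarray          # (3,) hit location, m
    normal: np.ndarray         # (3,) unit inward normal
    region: str
    kind: str                  # wall | grid_bar | outlet | inlet
    s: float                   # fractional position along the segment


@dataclass
class SurrogateGeometry:
    """Axisymmetric four-region inhaler surrogate.

    ``sections`` define the lateral profile R(z); ``region_breaks`` are the
    axial boundaries [0, z1, z2, z3, H] of capsule chamber, central
    chamber, grid zone and mouthpiece. The grid screen sits at ``z_grid``
    with periodic square openings of pitch ``grid_pitch`` and open-area
    fraction ``grid_open_fraction``.
    """

    sections: list[Section]
    region_breaks: tuple[float, float, float, float, float]
    z_grid: float
    grid_pitch: float
    grid_open_fraction: float
    release_height: float
    inlet_z: tuple[float, float] = (2.0e-3, 6.0e-3)
    inlet_half_angle: float = 0.3   # rad, two tangential ports at phi = 0, pi
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(s.z1 <= s.z0 or s.R0 <= 0 or s.R1 <= 0 for s in self.sections):
            raise ValueError("sections must have positive extent and radii")
        for a, b in zip(self.sections[:-1], self.sections[1:]):
            if not math.isclose(a.z1, b.z0) or not math.isclose(a.R1, b.R0):
                raise ValueError("sections must be contiguous in z and R")
        zb = self.region_breaks
        if list(zb) != sorted(zb) or not math.isclose(zb[0], 0.0):
            raise ValueError("region breaks must be increasing from 0")
        if not math.isclose(zb[-1], self.z_top):
            raise ValueError("last region break must equal the outlet height")
        if not (0 < self.grid_open_fraction < 1):
            raise ValueError("grid open-area fraction must lie in (0, 1)")
        if not (zb[0] < self.release_height < zb[1]):
            raise ValueError("release height must lie inside the capsule chamber")
        if not (zb[2] <= self.z_grid <= zb[3]):
            raise ValueError("grid plane must lie inside the grid zone")

    # -- profile ---------------------------------------------------------

    @property
    def z_top(self) -> float:
        return self.sections[-1].z1

    @property
    def outlet_radius(self) -> float:
        return self.sections[-1].R1

    def radius_at(self, z):
        """Wall radius R(z), vectorised; clamped to the domain ends."""
        scalar = np.ndim(z) == 0
        zc = np.clip(np.atleast_1d(np.asarray(z, dtype=float)), 0.0, self.z_top)
        out = np.empty_like(zc)
        for sec in self.sections:
            m = (zc >= sec.z0) & (zc <= sec.z1)
            out[m] = sec.R0 + sec.slope * (zc[m] - sec.z0)
        return float(out[0]) if scalar else out

    def slope_at(self, z):
        """dR/dz, vectorised (piecewise constant)."""
        scalar = np.ndim(z) == 0
        zc = np.clip(np.atleast_1d(np.asarray(z, dtype=float)), 0.0, self.z_top)
        out = np.zeros_like(zc)
        for sec in self.sections:
            m = (zc >= sec.z0) & (zc <= sec.z1)
            out[m] = sec.slope
        return float(out[0]) if scalar else out

    # -- point queries ---------------------------------------------------

    def inside(self, p, tol: float = 0.0):
        """True for points strictly inside the domain (vectorised over rows)."""
        scalar = np.ndim(p) == 1
        p = np.atleast_2d(np.asarray(p, dtype=float))
        r = np.hypot(p[:, 0], p[:, 1])
        z = p[:, 2]
        ok = (z > -tol) & (z < self.z_top + tol) & (r < self.radius_at(z) + tol)
        return bool(ok[0]) if scalar else ok

    def region_of(self, p) -> str:
        """Region label of an interior point."""
        p = np.asarray(p, dtype=float)
        if not self.inside(p, tol=1e-12):
            raise ValueError(f"point {p} lies outside the domain")
        return self.region_of_z(float(p[2]))

    def region_of_z(self, z):
        """Region label(s) from the axial coordinate alone (vectorised)."""
        z = np.asarray(z, dtype=float)
        idx = np.clip(np.searchsorted(self.region_breaks[1:-1], z, side="right"), 0, 3)
        if z.ndim == 0:
            return REGIONS[int(idx)]
        return np.asarray(REGIONS, dtype=object)[idx]

    # -- grid screen -----------------------------------------------------

    def _open_halfwidth(self) -> float:
        return math.sqrt(self.grid_open_fraction)

    def grid_open(self, x, y):
        """True where the screen is open (square openings, period = pitch)."""
        w = self._open_halfwidth()
        fx = np.mod(np.asarray(x, dtype=float) / self.grid_pitch, 1.0)
        fy = np.mod(np.asarray(y, dtype=float) / self.grid_pitch, 1.0)
        out = (fx < w) & (fy < w)
        return out if np.ndim(out) else bool(out)

    def opening_center(self, x, y):
        """Centre of the nearest grid opening (used by the jet surrogate)."""
        p, w = self.grid_pitch, self._open_halfwidth()

        def centre(c):
            c = np.asarray(c, dtype=float)
            i = np.floor(c / p)
            frac = c / p - i
            left = (i + 0.5 * w) * p
            right = (i + 1 + 0.5 * w) * p
            use_right = frac > 0.5 * (1 + w)
            return np.where(use_right, right, left)

        return centre(x), centre(y)

    # -- collision detection ---------------------------------------------

    def intersect_path(self, p0, p1) -> WallHit | None:
        """Earliest boundary crossing of the segment p0 -> p1, or None."""
        hits = self.intersect_paths(np.asarray(p0, float)[None, :],
                                    np.asarray(p1, float)[None, :])
        return hits[0]

    def intersect_paths(self, P0: np.ndarray, P1: np.ndarray) -> list[WallHit | None]:
        """Vectorised first-crossing test for n segments (rows of P0, P1)."""
        P0 = np.atleast_2d(P0).astype(float)
        P1 = np.atleast_2d(P1).astype(float)
        n = P0.shape[0]
        D = P1 - P0
        s_best = np.full(n, np.inf)
        kind_best = np.full(n, -1, dtype=int)      # 0 wall-lateral, 1 bottom, 2 outlet, 3 grid bar
        norm_best = np.zeros((n, 3))

        dz = D[:, 2]
        # bottom disc z = 0 (inward normal +z)
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.where(dz < 0, (0.0 - P0[:, 2]) / dz, np.inf)
        self._consider_plane(P0, D, s, np.array([0.0, 0.0, 1.0]), 1, None,
                             s_best, kind_best, norm_best)
        # outlet plane z = H (inward normal -z)
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.where(dz > 0, (self.z_top - P0[:, 2]) / dz, np.inf)
        self._consider_plane(P0, D, s, np.array([0.0, 0.0, -1.0]), 2, None,
                             s_best, kind_best, norm_best)
        # grid screen (bars only block; openings pass)
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.where(dz != 0, (self.z_grid - P0[:, 2]) / dz, np.inf)
        s_safe = np.where(np.isfinite(s), s, 0.0)
        xg = P0[:, 0] + s_safe * D[:, 0]
        yg = P0[:, 1] + s_safe * D[:, 1]
        on_bar = ~self.grid_open(xg, yg)
        s = np.where(on_bar, s, np.inf)
        normal_sign = np.where(dz > 0, -1.0, 1.0)
        valid = (s > _S_EPS) & (s <= 1.0) & (s < s_best)
        if np.any(valid):
            s_best[valid] = s[valid]
            kind_best[valid] = 3
            norm_best[valid] = 0.0
            norm_best[valid, 2] = normal_sign[valid]
        # lateral surface, per section
        a = D[:, 0] ** 2 + D[:, 1] ** 2
        b_half = P0[:, 0] * D[:, 0] + P0[:, 1] * D[:, 1]
        r0sq = P0[:, 0] ** 2 + P0[:, 1] ** 2
        for sec in self.sections:
            m = sec.slope
            c0 = sec.R0 + m * (P0[:, 2] - sec.z0)
            c1 = m * dz
            A = a - c1 ** 2
            B = 2.0 * (b_half - c0 * c1)
            C = r0sq - c0 ** 2
            s = _smallest_root(A, B, C)
            zhit = P0[:, 2] + np.where(np.isfinite(s), s, 0.0) * dz
            in_sec = (zhit >= sec.z0 - 1e-12) & (zhit <= sec.z1 + 1e-12)
            s = np.where(in_sec, s, np.inf)
            valid = (s > _S_EPS) & (s <= 1.0) & (s < s_best)
            if np.any(valid):
                xh = P0[valid, 0] + s[valid] * D[valid, 0]
                yh = P0[valid, 1] + s[valid] * D[valid, 1]
                r = np.hypot(xh, yh)
                r = np.where(r == 0, 1.0, r)
                nn = np.stack([-xh / r, -yh / r, np.full_like(xh, m)], axis=1)
                nn /= np.linalg.norm(nn, axis=1, keepdims=True)
                s_best[valid] = s[valid]
                kind_best[valid] = 0
                norm_best[valid] = nn

        hits: list[WallHit | None] = [None] * n
        kinds = {0: "wall", 1: "wall", 2: "outlet", 3: "grid_bar"}
        for i in np.flatnonzero(np.isfinite(s_best)):
            pt = P0[i] + s_best[i] * D[i]
            kind = kinds[kind_best[i]]
            if kind_best[i] == 0 and self._on_inlet(pt):
                kind = "inlet"
            hits[i] = WallHit(point=pt, normal=norm_best[i].copy(),
                              region=self.region_of_z(float(pt[2])),
                              kind=kind, s=float(s_best[i]))
        return hits

    @staticmethod
    def _consider_plane(P0, D, s, normal, code, _unused, s_best, kind_best, norm_best):
        valid = (s > _S_EPS) & (s <= 1.0) & (s < s_best)
        if np.any(valid):
            s_best[valid] = s[valid]
            kind_best[valid] = code
            norm_best[valid] = normal

    def _on_inlet(self, pt: np.ndarray) -> bool:
        z = pt[2]
        if not (self.inlet_z[0] <= z <= self.inlet_z[1]):
            return False
        phi = math.atan2(pt[1], pt[0])
        for phi0 in (0.0, math.pi):
            d = math.atan2(math.sin(phi - phi0), math.cos(phi - phi0))
            if abs(d) <= self.inlet_half_angle:
                return True
        return False

    # -- export ----------------------------------------------------------

    def export_surface_obj(self, path, n_theta: int = 48, n_z: int = 80) -> None:
        """Write the lateral surface of revolution as a Wavefront OBJ mesh."""
        z = np.linspace(0.0, self.z_top, n_z)
        R = self.radius_at(z)
        th = np.linspace(0.0, 2 * math.pi, n_theta, endpoint=False)
        verts = []
        for zi, Ri in zip(z, R):
            for t in th:
                verts.append((Ri * math.cos(t), Ri * math.sin(t), zi))
        lines = [f"v {x:.6e} {y:.6e} {zz:.6e}" for x, y, zz in verts]
        for i in range(n_z - 1):
            for j in range(n_theta):
                a = i * n_theta + j + 1
                b = i * n_theta + (j + 1) % n_theta + 1
                c = a + n_theta
                d = b + n_theta
                lines.append(f"f {a} {b} {d}")
                lines.append(f"f {a} {d} {c}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def _smallest_root(A, B, C):
    """Smallest positive root of A s^2 + B s + C = 0, elementwise; inf if none."""
    out = np.full_like(np.asarray(B, dtype=float), np.inf)
    lin = np.abs(A) < 1e-300
    with np.errstate(divide="ignore", invalid="ignore"):
        s_lin = np.where(lin & (np.abs(B) > 0), -C / np.where(B == 0, 1.0, B), np.inf)
    out = np.where(lin & (s_lin > 0), s_lin, out)
    disc = B ** 2 - 4 * A * C
    ok = (~lin) & (disc >= 0)
    sq = np.sqrt(np.where(ok, disc, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r1 = (-B - sq) / (2 * A)
        r2 = (-B + sq) / (2 * A)
    lo = np.minimum(r1, r2)
    hi = np.maximum(r1, r2)
    cand = np.where(lo > _S_EPS, lo, np.where(hi > _S_EPS, hi, np.inf))
    return np.where(ok, cand, out)


def build_default_geometry(
    capsule_radius: float = 10.0e-3,
    capsule_height: float = 20.0e-3,
    central_radius: float = 8.0e-3,
    central_height: float = 16.0e-3,
    grid_radius: float = 6.0e-3,
    grid_zone_height: float = 6.0e-3,
    mouthpiece_radius: float = 5.15e-3,
    mouthpiece_height: float = 30.0e-3,
    taper_length: float = 4.0e-3,
    grid_pitch: float = 1.2e-3,
    grid_open_fraction: float = 0.6,
    release_height: float = 12.5e-3,
) -> SurrogateGeometry:
    """Default four-region surrogate.

    The mouthpiece bore (5.15 mm radius) is sized so a 60 L/min flow gives
    a ~12 m/s mean outlet speed; the release plane sits 12.5 mm above the
    base, the resting position of the drug capsule.
    """
    for name, v in (("capsule_radius", capsule_radius), ("capsule_height", capsule_height),
                    ("central_radius", central_radius), ("central_height", central_height),
                    ("grid_radius", grid_radius), ("grid_zone_height", grid_zone_height),
                    ("mouthpiece_radius", mouthpiece_radius),
                    ("mouthpiece_height", mouthpiece_height),
                    ("taper_length", taper_length), ("grid_pitch", grid_pitch)):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    z0 = 0.0
    z1 = capsule_height
    z2 = z1 + taper_length
    z3 = z2 + central_height
    z4 = z3 + taper_length
    z5 = z4 + grid_zone_height
    z6 = z5 + taper_length
    z7 = z6 + mouthpiece_height
    sections = [
        Section(z0, z1, capsule_radius, capsule_radius),
        Section(z1, z2, capsule_radius, central_radius),
        Section(z2, z3, central_radius, central_radius),
        Section(z3, z4, central_radius, grid_radius),
        Section(z4, z5, grid_radius, grid_radius),
        Section(z5, z6, grid_radius, mouthpiece_radius),
        Section(z6, z7, mouthpiece_radius, mouthpiece_radius),
    ]
    breaks = (0.0, (z1 + z2) / 2, (z3 + z4) / 2, z6, z7)
    return SurrogateGeometry(
        sections=sections,
        region_breaks=breaks,
        z_grid=(z4 + z5) / 2,
        grid_pitch=grid_pitch,
        grid_open_fraction=grid_open_fraction,
        release_height=release_height,
    )
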