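"""Periodic unit-cell viscous flow around one DLD pillar.

A DLD array is periodic up to the row shift: the geometry one along-flow
pitch downstream is the same geometry shifted laterally by the row shift
``s``.  One pillar in a (pitch_x × pitch_y) box with shifted-periodic
boundaries therefore captures the whole array.

The solver is a depth-corrected 2D (midplane) model: the depth-averaged
in-plane velocity obeys the Stokes–Brinkman equation

    −∇p + µ ∇²u − (12 µ / h²) u = 0,     ∇·u = 0,

where the drag term is the exact depth correction for a locally parabolic
profile across a slab of depth ``h``.  In streamfunction form (u = ψ_y,
v = −ψ_x) the pressure drops out:

    µ ∇⁴ψ − ∇·(α ∇ψ) = 0,

with α = 12µ/h² in the fluid and a large penalization value inside the
pillar mask (volume penalization enforces no-slip to within a penetration
depth far below the grid spacing).  The equation is discretized with
compact finite differences on a uniform grid and solved directly; the
streamfunction jump across one lateral pitch *is* the imposed per-gap
flux, so the target flow rate is met exactly by construction (Stokes
linearity), and mass conservation across any cross-section is exact by
telescoping.

Midplane quantities are 1.5x the depth-averaged ones (parabolic depth
profile); wall shear on the floor/ceiling is 6µ|u|/h.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp
from scipy.interpolate import RegularGridInterpolator
from scipy.sparse.linalg import splu

from .geometry import CriticalDiameterResult, PillarShape

__all__ = [
    "UnitCell",
    "FlowField",
    "Streamline",
    "rasterize_pillar",
    "solve_unit_cell",
    "plug_flow_field",
    "critical_diameter_from_field",
    "wall_shear_map",
    "ShearReport",
    "asymmetry_metric",
    "trace_streamline",
]

UL_MIN_TO_M3_S = 1e-9 / 60.0


# ---------------------------------------------------------------------------
# unit cell and rasterization
# ---------------------------------------------------------------------------

def _hybrid_halfwidth(shape: PillarShape) -> Callable[[np.ndarray], np.ndarray]:
    """Lateral half-width profile w(x) of the hybrid pillar footprint.

    x measured from the upstream edge of the footprint.  Upstream part
    (fraction 1 − ellipse_fraction of the along-flow extent): rectangle of
    half-width W/2 with a symmetric groove (depth d·W, along-flow width
    f·L_rect, centered) notched into each lateral face.  Downstream part:
    semi-ellipse tapering to zero.
    """
    w2 = shape.lateral_extent_ / 2.0
    lf = shape.alongflow_extent
    l_ell = shape.ellipse_fraction * lf
    l_rect = lf - l_ell
    gw = shape.groove_width_fraction * l_rect
    gd = shape.groove_depth_fraction * shape.lateral_extent_
    g0 = (l_rect - gw) / 2.0

    def halfwidth(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        w = np.zeros_like(x)
        rect = (x >= 0) & (x <= l_rect)
        w[rect] = w2
        grooved = (x >= g0) & (x <= g0 + gw)
        w[grooved] = w2 - gd
        ell = (x > l_rect) & (x <= lf)
        t = (x[ell] - l_rect) / l_ell
        w[ell] = w2 * np.sqrt(np.clip(1.0 - t ** 2, 0.0, 1.0))
        return w

    return halfwidth


@dataclass
class UnitCell:
    """One pillar in a shifted-periodic box.

    ``mask[i, j]`` is True inside the pillar; index i runs along flow (x),
    j lateral (y); node (i, j) sits at ((i+0.5)·res, (j+0.5)·res).
    ``halfwidth(x)`` gives the analytic lateral half-extent of the pillar
    about its center for sub-grid wall placement (None for free-form
    masks).
    """

    mask: np.ndarray
    resolution: float          # µm per cell
    length_x: float            # along-flow pitch (µm)
    length_y: float            # lateral pitch (µm)
    depth: float               # ceiling height h (µm)
    row_shift: float           # lateral offset per along-flow period (µm)
    pillar_center: Tuple[float, float]
    shape: Optional[PillarShape] = None
    halfwidth: Optional[Callable[[np.ndarray], np.ndarray]] = None
    x_upstream_edge: float = 0.0   # x of pillar upstream edge (µm)

    def __post_init__(self) -> None:
        nx, ny = self.mask.shape
        if abs(nx * self.resolution - self.length_x) > 1e-6 or \
           abs(ny * self.resolution - self.length_y) > 1e-6:
            raise ValueError("mask shape inconsistent with domain extents")
        m = round(self.row_shift / self.resolution)
        if abs(m * self.resolution - self.row_shift) > 1e-9:
            raise ValueError("row_shift must be an integer number of grid cells")
        if self.mask[0, :].any() or self.mask[-1, :].any():
            raise ValueError("pillar mask must not touch the inflow/outflow faces")

    @property
    def shift_cells(self) -> int:
        return round(self.row_shift / self.resolution)

    @property
    def node_x(self) -> np.ndarray:
        return (np.arange(self.mask.shape[0]) + 0.5) * self.resolution

    @property
    def node_y(self) -> np.ndarray:
        return (np.arange(self.mask.shape[1]) + 0.5) * self.resolution

    def gap_throat(self) -> Tuple[int, float, float]:
        """(column index, wall_y_top_of_pillar, gap width) at the narrowest
        cross-section (maximum pillar lateral extent)."""
        extents = self.mask.sum(axis=1)
        i = int(np.argmax(extents))
        cx, cy = self.pillar_center
        if self.halfwidth is not None:
            hw = float(self.halfwidth(np.array([self.node_x[i] -
                                                self.x_upstream_edge]))[0])
        else:
            hw = extents[i] * self.resolution / 2.0
        wall = cy + hw
        return i, wall, self.length_y - 2.0 * hw


def rasterize_pillar(shape: PillarShape, resolution: float,
                     pitch_x: float, pitch_y: float, depth: float,
                     row_shift: float) -> UnitCell:
    """Discretize a pillar footprint into a unit cell.

    Raises if the resolution cannot resolve the smallest shape feature or
    if the raster area strays more than 2% from the analytic footprint.
    """
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    smallest = shape.diameter if shape.kind == "cylinder" else min(
        shape.groove_width_fraction * (1 - shape.ellipse_fraction)
        * shape.alongflow_extent,
        shape.groove_depth_fraction * shape.lateral_extent_)
    if resolution > smallest / 2.0:
        raise ValueError(
            f"resolution {resolution} µm too coarse for smallest pillar "
            f"feature {smallest:.1f} µm")
    nx = round(pitch_x / resolution)
    ny = round(pitch_y / resolution)
    x = (np.arange(nx) + 0.5) * resolution
    y = (np.arange(ny) + 0.5) * resolution
    X, Y = np.meshgrid(x, y, indexing="ij")
    cx, cy = pitch_x / 2.0, pitch_y / 2.0

    if shape.kind == "cylinder":
        r = shape.diameter / 2.0
        mask = (X - cx) ** 2 + (Y - cy) ** 2 <= r ** 2
        x_up = cx - r

        def hw_from_upstream(xs):
            xs = np.asarray(xs, float)
            return np.sqrt(np.clip(r ** 2 - (xs - r) ** 2, 0.0, None))

        cell = UnitCell(mask=mask, resolution=resolution, length_x=pitch_x,
                        length_y=pitch_y, depth=depth, row_shift=row_shift,
                        pillar_center=(cx, cy), shape=shape,
                        halfwidth=hw_from_upstream, x_upstream_edge=x_up)
    else:
        hw = _hybrid_halfwidth(shape)
        x_up = cx - shape.alongflow_extent / 2.0
        w = hw(X - x_up)
        mask = (np.abs(Y - cy) <= w) & (w > 0)
        cell = UnitCell(mask=mask, resolution=resolution, length_x=pitch_x,
                        length_y=pitch_y, depth=depth, row_shift=row_shift,
                        pillar_center=(cx, cy), shape=shape,
                        halfwidth=hw, x_upstream_edge=x_up)

    area = mask.sum() * resolution ** 2
    target = shape.footprint_area()
    if abs(area - target) > 0.02 * target:
        raise ValueError(
            f"raster footprint area {area:.1f} µm² deviates >2% from the "
            f"analytic {target:.1f} µm² — refine the resolution")
    return cell


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------

def _neighbor_maps(nx: int, ny: int, shift: int):
    """Flat-index neighbor maps on the shifted-periodic grid.

    Crossing the +x face lands on column 0 with the lateral index shifted
    by −shift (the next row of pillars sits ``row_shift`` further in +y, so
    the periodic image of the field is shifted back).
    """
    I, J = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")

    def flat(i, j):
        return (i * ny + j).ravel()

    jp = (J + 1) % ny
    jm = (J - 1) % ny
    ip = I + 1
    im = I - 1
    j_ip = np.where(ip == nx, (J - shift) % ny, J)
    i_ip = ip % nx
    j_im = np.where(im < 0, (J + shift) % ny, J)
    i_im = im % nx
    return (flat(i_ip, j_ip), flat(i_im, j_im), flat(I, jp), flat(I, jm))


def _shift_op(n: int, target: np.ndarray) -> sp.csr_matrix:
    return sp.csr_matrix((np.ones(n), (np.arange(n), target)), shape=(n, n))


@dataclass
class FlowField:
    """Depth-averaged 2D velocity field on a unit cell.

    ``u``/``v`` are depth-averaged (m/s); multiply by 1.5 for midplane
    values.  ``psi`` is the streamfunction (m²/s per unit depth in the
    scaled sense: u = ∂ψ/∂y with y in metres).
    """

    cell: UnitCell
    u: np.ndarray
    v: np.ndarray
    psi: np.ndarray
    mean_velocity: float        # superficial mean velocity U (m/s)
    per_gap_flux_ul_min: float
    viscosity_mpas: float
    model: str = "midplane_2d_brinkman"

    def __post_init__(self) -> None:
        self._interp_cache = {}
        self._u_raw = None
        self._v_raw = None

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.u, self.v)

    def wall_psi(self) -> float:
        """Streamfunction value on the pillar surface, read at the node
        just inside the gap-throat wall (robust to any branch cut a
        synthetic field may carry inside the pillar)."""
        cell = self.cell
        i, _, _ = cell.gap_throat()
        col = cell.mask[i, :]
        if not col.any():
            return float(self.psi[i, 0])
        j_wall = int(np.flatnonzero(col).max())
        return float(self.psi[i, j_wall])

    @property
    def achieved_per_gap_flux_ul_min(self) -> float:
        """Flux through the first cross-section, recomputed from the field."""
        h = self.cell.depth * 1e-6
        r = self.cell.resolution * 1e-6
        q = float(self.u[0, :].sum()) * r * h
        return q / UL_MIN_TO_M3_S

    def _padded(self, a: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Array padded one ring using the shifted-periodic wrap, plus the
        padded node coordinate vectors (µm)."""
        nx, ny = a.shape
        m = self.cell.shift_cells
        out = np.empty((nx + 2, ny + 2))
        out[1:-1, 1:-1] = a
        out[0, 1:-1] = np.roll(a[-1, :], -m)    # image at x < 0
        out[-1, 1:-1] = np.roll(a[0, :], m)     # image at x > Lx
        out[:, 0] = out[:, -2]
        out[:, -1] = out[:, 1]
        res = self.cell.resolution
        xs = np.concatenate(([-0.5 * res], self.cell.node_x,
                             [self.cell.length_x + 0.5 * res]))
        ys = np.concatenate(([-0.5 * res], self.cell.node_y,
                             [self.cell.length_y + 0.5 * res]))
        return out, xs, ys

    def interpolator(self, which: str) -> RegularGridInterpolator:
        if which not in self._interp_cache:
            if which == "u":
                a = self.u
            elif which == "v":
                a = self.v
            elif which == "speed":
                a = self.speed
            elif which == "vorticity":
                a = self.vorticity()
            elif which == "shear_rate":
                a = self.shear_rate()
            elif which == "e11":
                a = self.strain_components()[0]
            elif which == "e12":
                a = self.strain_components()[1]
            elif which == "advect":
                # stacked channels (u, v, vorticity, e11, e12, shear_rate)
                # so transport loops pay for one interpolation per step
                e11, e12 = self.strain_components()
                chans = [self.u, self.v, self.vorticity(), e11, e12,
                         self.shear_rate()]
                pads = []
                for ch in chans:
                    pad, xs, ys = self._padded(ch)
                    pads.append(pad)
                self._interp_cache[which] = RegularGridInterpolator(
                    (xs, ys), np.stack(pads, axis=-1), bounds_error=False,
                    fill_value=None)
                return self._interp_cache[which]
            else:
                raise KeyError(which)
            pad, xs, ys = self._padded(a)
            self._interp_cache[which] = RegularGridInterpolator(
                (xs, ys), pad, bounds_error=False, fill_value=None)
        return self._interp_cache[which]

    def velocity_at(self, pts: np.ndarray) -> np.ndarray:
        """Depth-averaged velocity (m/s) at points (µm) inside the cell."""
        pts = np.atleast_2d(pts)
        return np.stack([self.interpolator("u")(pts),
                         self.interpolator("v")(pts)], axis=-1)

    def vorticity(self) -> np.ndarray:
        """ζ = ∂v/∂x − ∂u/∂y (1/s), shifted-periodic central differences."""
        r = self.cell.resolution * 1e-6
        dvdx = (self._roll_x(self.v, -1) - self._roll_x(self.v, 1)) / (2 * r)
        dudy = (np.roll(self.u, -1, axis=1) - np.roll(self.u, 1, axis=1)) / (2 * r)
        z = dvdx - dudy
        z[self.cell.mask] = 0.0
        return z

    def strain_components(self) -> Tuple[np.ndarray, np.ndarray]:
        """(E11, E12) of the in-plane strain-rate tensor (1/s); E22 = −E11
        by incompressibility."""
        r = self.cell.resolution * 1e-6
        dudx = (self._roll_x(self.u, -1) - self._roll_x(self.u, 1)) / (2 * r)
        dudy = (np.roll(self.u, -1, axis=1) - np.roll(self.u, 1, axis=1)) / (2 * r)
        dvdx = (self._roll_x(self.v, -1) - self._roll_x(self.v, 1)) / (2 * r)
        e11 = dudx
        e12 = 0.5 * (dudy + dvdx)
        e11[self.cell.mask] = 0.0
        e12[self.cell.mask] = 0.0
        return e11, e12

    def shear_rate(self) -> np.ndarray:
        """In-plane shear-rate magnitude (1/s) of the depth-averaged field."""
        r = self.cell.resolution * 1e-6
        dudx = (self._roll_x(self.u, -1) - self._roll_x(self.u, 1)) / (2 * r)
        dudy = (np.roll(self.u, -1, axis=1) - np.roll(self.u, 1, axis=1)) / (2 * r)
        dvdx = (self._roll_x(self.v, -1) - self._roll_x(self.v, 1)) / (2 * r)
        dvdy = (np.roll(self.v, -1, axis=1) - np.roll(self.v, 1, axis=1)) / (2 * r)
        g = np.sqrt(2 * dudx ** 2 + 2 * dvdy ** 2 + (dudy + dvdx) ** 2)
        g[self.cell.mask] = 0.0
        return g

    def _roll_x(self, a: np.ndarray, step: int) -> np.ndarray:
        """Roll along x honouring the shifted-periodic wrap (|step| = 1)."""
        m = self.cell.shift_cells
        out = np.roll(a, step, axis=0)
        if step == 1:       # row 0 now holds the image from x < 0
            out[0, :] = np.roll(a[-1, :], -m)
        elif step == -1:
            out[-1, :] = np.roll(a[0, :], m)
        else:
            raise ValueError("step must be ±1")
        return out

    def max_divergence(self) -> float:
        """Max |∇·u| over the cell, relative to the gradient scale U/res.

        The streamfunction construction makes the raw discrete divergence
        vanish by commutation of the central-difference operators, so this
        should sit at machine precision for solved fields.
        """
        r = self.cell.resolution * 1e-6
        u = self._u_raw if self._u_raw is not None else self.u
        v = self._v_raw if self._v_raw is not None else self.v
        dudx = (self._roll_x(u, -1) - self._roll_x(u, 1)) / (2 * r)
        dvdy = (np.roll(v, -1, axis=1) - np.roll(v, 1, axis=1)) / (2 * r)
        div = dudx + dvdy
        scale = max(abs(self.mean_velocity), 1e-300) / r
        return float(np.abs(div).max() / scale)


def solve_unit_cell(cell: UnitCell, per_gap_flux_ul_min: float,
                    viscosity_mpas: float = 1.0,
                    model: str = "midplane_2d_brinkman",
                    penal_eta_um: float = 0.25) -> FlowField:
    """Steady Stokes–Brinkman solve at an imposed per-gap flow rate.

    The per-gap flux (one lateral pitch of the array) fixes the
    superficial mean velocity U = Q/(h·pitch_y); the shifted-periodic
    streamfunction perturbation is solved by a direct sparse solve.  The
    achieved flux equals the target to round-off by construction.
    """
    if model == "coarse_3d":
        raise NotImplementedError(
            "full 3D slab solves are not provided; the depth-corrected 2D "
            "model (midplane_2d_brinkman) is the supported solver")
    if model != "midplane_2d_brinkman":
        raise ValueError(f"unknown model {model!r}")
    if per_gap_flux_ul_min <= 0:
        raise ValueError("per_gap_flux must be > 0")

    mu = viscosity_mpas * 1e-3
    h = cell.depth * 1e-6
    res = cell.resolution * 1e-6
    nx, ny = cell.mask.shape
    n = nx * ny
    shift = cell.shift_cells

    q = per_gap_flux_ul_min * UL_MIN_TO_M3_S
    U = q / (h * cell.length_y * 1e-6)

    alpha_fluid = 12.0 * mu / h ** 2
    alpha_solid = 12.0 * mu / (penal_eta_um * 1e-6) ** 2
    alpha = np.where(cell.mask, alpha_solid, alpha_fluid).ravel()

    ip, im, jp, jm = _neighbor_maps(nx, ny, shift)
    E_ip, E_im = _shift_op(n, ip), _shift_op(n, im)
    E_jp, E_jm = _shift_op(n, jp), _shift_op(n, jm)
    I = sp.identity(n, format="csr")

    lap = (E_ip + E_im + E_jp + E_jm - 4.0 * I) / res ** 2

    a_ip = 0.5 * (alpha + alpha[ip])
    a_im = 0.5 * (alpha + alpha[im])
    a_jp = 0.5 * (alpha + alpha[jp])
    a_jm = 0.5 * (alpha + alpha[jm])

    def d(v):
        return sp.diags(v)

    div_alpha_grad = (d(a_ip) @ E_ip + d(a_im) @ E_im + d(a_jp) @ E_jp +
                      d(a_jm) @ E_jm - d(a_ip + a_im + a_jp + a_jm)) / res ** 2

    A = (mu * (lap @ lap) - div_alpha_grad).tolil()
    b = U * (a_jp - a_jm) / res

    # pin the streamfunction constant at one fluid node
    pin = int(np.flatnonzero(~cell.mask.ravel())[0])
    A.rows[pin] = [pin]
    A.data[pin] = [1.0]
    b[pin] = 0.0

    lu = splu(A.tocsc())
    phi = lu.solve(b)
    resid = np.abs(A.tocsr() @ phi - b).max() / max(np.abs(b).max(), 1e-300)
    if not np.isfinite(phi).all() or resid > 1e-6:
        raise RuntimeError(f"unit-cell solve did not converge "
                           f"(relative residual {resid:.2e})")

    phi = phi.reshape(nx, ny)
    y = cell.node_y[None, :] * 1e-6
    psi = U * y + phi

    # velocities from central differences on phi (+ the mean-flow part)
    def roll_x(a, step):
        m = shift
        out = np.roll(a, step, axis=0)
        if step == 1:
            out[0, :] = np.roll(a[-1, :], -m)
        else:
            out[-1, :] = np.roll(a[0, :], m)
        return out

    u_raw = U + (np.roll(phi, -1, axis=1) - np.roll(phi, 1, axis=1)) / (2 * res)
    v_raw = -(roll_x(phi, -1) - roll_x(phi, 1)) / (2 * res)
    u = u_raw.copy()
    v = v_raw.copy()
    u[cell.mask] = 0.0
    v[cell.mask] = 0.0

    fieldobj = FlowField(cell=cell, u=u, v=v, psi=psi, mean_velocity=U,
                         per_gap_flux_ul_min=per_gap_flux_ul_min,
                         viscosity_mpas=viscosity_mpas, model=model)
    fieldobj._u_raw = u_raw
    fieldobj._v_raw = v_raw
    return fieldobj


def plug_flow_field(cell: UnitCell, per_gap_flux_ul_min: float,
                    viscosity_mpas: float = 1.0) -> FlowField:
    """Synthetic field with a uniform (plug) profile across every gap.

    Built from a streamfunction that rises linearly across the fluid part
    of each cross-section and is flat across the pillar, so it is exactly
    divergence-free and carries the stated flux.  Used as the closed-form
    oracle for the zigzag/displacement dichotomy (first-stream width
    beta = g·epsilon under a plug profile).
    """
    h = cell.depth * 1e-6
    res = cell.resolution * 1e-6
    q = per_gap_flux_ul_min * UL_MIN_TO_M3_S
    Ly = cell.length_y * 1e-6
    U = q / (h * Ly)
    total = U * Ly                      # streamfunction jump per period
    nx, ny = cell.mask.shape
    xs = cell.node_x

    # work in rolled lateral coordinates with the pillar at the edges and
    # the gap contiguous, so the wall streamfunction is one global constant
    k0 = ny // 2
    yy = (np.arange(ny) + 0.5) * cell.resolution    # rolled lateral coord, µm
    psi_r = np.zeros((nx, ny))
    for i in range(nx):
        if cell.halfwidth is not None:
            hw = float(cell.halfwidth(np.array([xs[i] - cell.x_upstream_edge]))[0])
        else:
            hw = cell.mask[i].sum() * cell.resolution / 2.0
        if hw > 0:
            y_lo, y_hi = hw, cell.length_y - hw
            t = np.clip((yy - y_lo) / (y_hi - y_lo), 0.0, 1.0)
            psi_r[i] = total * t
        else:
            psi_r[i] = total * (0.5 + (yy - cell.length_y / 2.0)
                                / cell.length_y)
    u_r = np.gradient(psi_r, res, axis=1)
    m = cell.shift_cells
    s_m = cell.row_shift * 1e-6
    # shifted-periodic x-neighbors with the branch cut (psi jump of one
    # period's flux) corrected on wrapped entries
    row_after = np.roll(psi_r[0], m) + U * s_m
    if m > 0:
        row_after[:m] -= total
    row_before = np.roll(psi_r[-1], -m) - U * s_m
    if m > 0:
        row_before[ny - m:] += total
    psi_xp = np.vstack([psi_r[1:], row_after[None, :]])
    psi_xm = np.vstack([row_before[None, :], psi_r[:-1]])
    v_r = -(psi_xp - psi_xm) / (2 * res)

    roll = lambda a: np.roll(a, k0, axis=1)     # noqa: E731  back to cell coords
    psi, u, v = roll(psi_r), roll(u_r), roll(v_r)
    u[cell.mask] = 0.0
    v[cell.mask] = 0.0
    return FlowField(cell=cell, u=u, v=v, psi=psi, mean_velocity=U,
                     per_gap_flux_ul_min=per_gap_flux_ul_min,
                     viscosity_mpas=viscosity_mpas, model="plug_synthetic")


# ---------------------------------------------------------------------------
# streamline-based critical diameter
# ---------------------------------------------------------------------------

def critical_diameter_from_field(field: FlowField,
                                 shift_fraction: float) -> CriticalDiameterResult:
    """Critical diameter by doubling the first-stream width.

    The first stream is the flow lane hugging the pillar wall that carries
    flux fraction epsilon of the per-gap flow; its width beta is measured
    at the gap throat from the streamfunction profile (flux between the
    wall and a station y is ψ(y) − ψ_wall).  D_c = 2·beta.  With the
    shifted-periodic cell every row is equivalent, so one throat profile
    is the row average.
    """
    if not 0.0 < shift_fraction <= 1.0:
        raise ValueError("shift_fraction must lie in (0, 1]")
    cell = field.cell
    i, wall_y, gap = cell.gap_throat()
    psi_col = field.psi[i, :]
    total = field.mean_velocity * cell.length_y * 1e-6
    psi_wall = field.wall_psi()

    ys = cell.node_y
    # walk the gap upward from the pillar top wall, unwrapping the lateral
    # period (the gap wraps around the cell edge back to the pillar image);
    # the flux fraction from the wall is (psi − psi_wall) mod (period flux),
    # which is branch-cut agnostic
    order = []
    for j in range(cell.mask.shape[1]):
        if cell.mask[i, j]:
            continue
        yj = ys[j] if ys[j] > wall_y else ys[j] + cell.length_y
        if wall_y < yj < wall_y + gap:
            frac = ((psi_col[j] - psi_wall) % total) / total
            order.append((yj - wall_y, frac))
    order.sort()
    w = np.array([o[0] for o in order])
    f = np.array([o[1] for o in order])
    # numerical wrap noise right at the wall can alias to ~1
    f[(f > 0.98) & (w < 0.05 * gap)] = 0.0
    # anchor both walls: zero flux at the near wall, full gap flux at the far
    w = np.concatenate(([0.0], w, [gap]))
    f = np.concatenate(([0.0], f, [1.0]))
    f = np.maximum.accumulate(f)
    target = shift_fraction
    if target > f[-1]:
        raise ValueError("flux fraction unattainable at the throat")
    beta = float(np.interp(target, f, w))
    return CriticalDiameterResult(d_c=2.0 * beta, method="cfd",
                                  first_stream_width=beta,
                                  profile_root=beta / gap)


# ---------------------------------------------------------------------------
# wall shear
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShearReport:
    peak_pa: float
    peak_location_um: Tuple[float, float]
    peak_surface: str                       # "pillar_wall" | "floor_ceiling"
    pillar_wall_peak_pa: float
    pillar_wall_peak_location_um: Tuple[float, float]
    depth_wall_peak_pa: float
    depth_wall_peak_location_um: Tuple[float, float]
    pillar_wall_shear_pa: np.ndarray = field(repr=False)   # (n_columns, 2)
    depth_wall_shear_pa: np.ndarray = field(repr=False)    # field 6µ|u|/h


def wall_shear_map(field: FlowField, viscosity_mpas: Optional[float] = None
                   ) -> ShearReport:
    """Midplane wall shear on pillar walls plus floor/ceiling shear.

    Pillar wall: τ = 1.5·µ·∂|u|/∂n with the wall-normal gradient from a
    one-sided second-order fit anchored at the analytic wall position
    (u = 0 at the wall, sampled at the two nearest fluid stations along
    the lateral normal).  Floor/ceiling: τ = 6µ|u|/h from the parabolic
    depth profile.  Returns both maps and the global peak.
    """
    cell = field.cell
    mu = (viscosity_mpas if viscosity_mpas is not None
          else field.viscosity_mpas) * 1e-3
    res = cell.resolution
    speed = field.speed
    cx, cy = cell.pillar_center
    ny = cell.mask.shape[1]
    ys = cell.node_y
    xs = cell.node_x

    pillar_cols = np.flatnonzero(cell.mask.any(axis=1))
    tau_wall = np.zeros((len(pillar_cols), 2))
    locs = []
    interp = field.interpolator("speed")
    for k, i in enumerate(pillar_cols):
        if cell.halfwidth is not None:
            hw = float(cell.halfwidth(np.array([xs[i] - cell.x_upstream_edge]))[0])
        else:
            hw = cell.mask[i].sum() * res / 2.0
        if hw <= 0:
            locs.append(((xs[i], cy), (xs[i], cy)))
            continue
        for side, sgn in ((0, +1.0), (1, -1.0)):
            y_wall = cy + sgn * hw
            d1, d2 = res, 2.0 * res
            p1 = (xs[i], (y_wall + sgn * d1) % cell.length_y)
            p2 = (xs[i], (y_wall + sgn * d2) % cell.length_y)
            u1 = float(interp(p1))
            u2 = float(interp(p2))
            # quadratic through (0,0),(d1,u1),(d2,u2): du/dn at the wall
            grad = (u1 * d2 ** 2 - u2 * d1 ** 2) / (d1 * d2 * (d2 - d1))
            tau_wall[k, side] = 1.5 * mu * max(grad, 0.0) / 1e-6  # per µm → per m
        locs.append(((xs[i], (cy + hw) % cell.length_y),
                     (xs[i], (cy - hw) % cell.length_y)))

    tau_floor = 6.0 * mu * np.abs(speed) / (cell.depth * 1e-6)
    tau_floor[cell.mask] = 0.0

    if tau_wall.size:
        kmax, smax = np.unravel_index(np.argmax(tau_wall), tau_wall.shape)
        pw_peak = float(tau_wall[kmax, smax])
        pw_loc = locs[kmax][smax]
    else:
        pw_peak, pw_loc = 0.0, (cx, cy)
    fi, fj = np.unravel_index(np.argmax(tau_floor), tau_floor.shape)
    fl_peak = float(tau_floor[fi, fj])
    fl_loc = (xs[fi], ys[fj])

    if pw_peak >= fl_peak:
        peak, loc, surf = pw_peak, pw_loc, "pillar_wall"
    else:
        peak, loc, surf = fl_peak, fl_loc, "floor_ceiling"
    return ShearReport(peak_pa=peak, peak_location_um=loc, peak_surface=surf,
                       pillar_wall_peak_pa=pw_peak,
                       pillar_wall_peak_location_um=pw_loc,
                       depth_wall_peak_pa=fl_peak,
                       depth_wall_peak_location_um=fl_loc,
                       pillar_wall_shear_pa=tau_wall,
                       depth_wall_shear_pa=tau_floor)


# ---------------------------------------------------------------------------
# asymmetry metric and streamlines
# ---------------------------------------------------------------------------

def asymmetry_metric(field: FlowField) -> float:
    """Streamline-pattern asymmetry of the flow past the pillar.

    Relative L2 difference between the speed field and its mirror image
    about the cross-gap line through the pillar center (upstream ↔
    downstream reflection), over nodes that are fluid in both the field
    and its mirror.  Zero for a perfectly fore-aft symmetric pattern;
    Stokes reversibility makes a fore-aft symmetric pillar in an untilted
    array score ~0, while the grooved/elliptic hybrid post disturbs the
    pattern and scores high.  The array tilt (row offset) itself
    contributes ~0.1 for any shape; comparisons that isolate pillar shape
    should be run on cells rasterized with ``row_shift=0``.
    """
    s = field.speed
    mirrored = s[::-1, :]
    fluid = ~field.cell.mask
    sym_fluid = fluid & fluid[::-1, :]
    num = np.linalg.norm((s - mirrored)[sym_fluid])
    den = np.linalg.norm(s[sym_fluid])
    return float(num / den) if den > 0 else 0.0


@dataclass
class Streamline:
    points: np.ndarray          # (n, 2) µm, cell coordinates (x unwrapped)
    seed: Tuple[float, float]
    terminal: str               # "exit" | "stagnation" | "max_steps"


def trace_streamline(field: FlowField, seed: Tuple[float, float],
                     max_length_um: float = None,
                     rtol: float = 1e-6) -> Streamline:
    """Integrate a midplane streamline from a seed point.

    Integration runs in cell coordinates with the shifted-periodic wrap
    unrolled in x; terminates on leaving the cell downstream (one
    along-flow pitch) or on stagnation.
    """
    cell = field.cell
    if max_length_um is None:
        max_length_um = 4.0 * cell.length_x
    uref = max(abs(field.mean_velocity), 1e-30)

    def local_velocity(p):
        x = p[0] % cell.length_x
        k = math.floor(p[0] / cell.length_x)
        y = (p[1] - k * cell.row_shift) % cell.length_y
        return field.velocity_at(np.array([[x, y]]))[0]

    def rhs(t, p):
        # arclength parametrization: unit tangent, t in µm along the path
        vel = local_velocity(p)
        speed = math.hypot(vel[0], vel[1])
        if speed < 1e-8 * uref:
            return np.zeros(2)
        return vel / speed

    def stagnated(t, p):
        vel = local_velocity(p)
        return math.hypot(vel[0], vel[1]) / uref - 1e-5
    stagnated.terminal = True

    def exited(t, p):
        return p[0] - cell.length_x
    exited.terminal = True

    sol = solve_ivp(rhs, (0.0, max_length_um), np.array(seed, dtype=float),
                    rtol=rtol, atol=1e-3, max_step=cell.resolution / 2.0,
                    events=(stagnated, exited))
    pts = sol.y.T
    if sol.t_events[1].size:
        term = "exit"
    elif sol.t_events[0].size:
        term = "stagnation"
    else:
        term = "max_steps"
    return Streamline(points=pts, seed=tuple(seed), terminal=term)
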