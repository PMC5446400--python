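"""Kinematic transport of spheres and rigid clusters through DLD arrays.

The reduced model that reproduces DLD mode logic: a particle's centroid
advects along the local (depth-averaged) velocity field of the unit cell;
a hard-contact rule keeps the centroid at least one effective radius away
from pillar surfaces (the DLD "bump"); particles whose effective radius
exceeds the first-stream width are pushed across the stream separatrix at
every row and ride the array tilt ("displacement" mode, one lateral pitch
of drift per reset), while smaller particles follow the flow ("zigzag",
zero net drift).  No hydrodynamic resistance tensors, deformation or
particle–particle interactions are modeled.

Clusters are rigid sphere assemblies.  The stage ceiling sets which axis
the array sees: a tall Stage 1 ceiling lets clusters stand their long
axis up (the array sees roughly the transverse axis), the shallow Stage 2
ceiling forces them flat, where the grooved pillar faces impart a
rotation that swings the long axis across the flow and enlarges the
presented width — the asymmetry-capture mechanism.  In-plane rotation is
driven by half the local vorticity plus a groove-alignment impulse whose
magnitude is an explicit free parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import networkx as nx
import numpy as np
import scipy.ndimage as ndi
from scipy.interpolate import RegularGridInterpolator

from .flowfield import FlowField
from .geometry import DeviceSpec, DLDStageSpec

__all__ = [
    "CellParticle",
    "RigidCluster",
    "ClusterAxes",
    "TrajectoryRecord",
    "PartitionResult",
    "cluster_axes",
    "advect_through_stage",
    "classify_mode",
    "simulate_device",
    "size_class",
]

DEFAULT_GROOVE_GAIN = 5.0       # dimensionless groove-alignment impulse gain
DEFAULT_TILT_SIGMA_DEG = 10.0   # Stage 1 vertical-alignment angular noise

_debug_trace = None             # internal: set to a list to capture steps


@dataclass(frozen=True)
class CellParticle:
    """A single spherical cell."""

    radius: float               # µm
    label: str = "cell"         # RBC / WBC / CTC / ...

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")


@dataclass
class RigidCluster:
    """Rigid assembly of touching member spheres.

    ``centers`` are body-frame offsets (n, 3) in µm, ``radii`` (n,) µm.
    Members must form a single connected contact graph — clusters do not
    fragment during simulation.
    """

    centers: np.ndarray
    radii: np.ndarray
    label: str = "cluster"

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.radii = np.asarray(self.radii, dtype=float).ravel()
        if self.centers.shape[0] != self.radii.size:
            raise ValueError("centers and radii length mismatch")
        if self.centers.shape[0] < 2:
            raise ValueError("a cluster has at least 2 member cells")
        if (self.radii <= 0).any():
            raise ValueError("radii must be > 0")
        g = self.contact_graph()
        if not nx.is_connected(g):
            raise ValueError("cluster members do not form a connected "
                             "contact graph")

    @property
    def n_cells(self) -> int:
        return int(self.radii.size)

    def contact_graph(self, tol: float = 0.5) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_cells))
        for i in range(self.n_cells):
            for j in range(i + 1, self.n_cells):
                d = np.linalg.norm(self.centers[i] - self.centers[j])
                if d <= self.radii[i] + self.radii[j] + tol:
                    g.add_edge(i, j)
        return g

    def principal_axes(self) -> Tuple[np.ndarray, np.ndarray]:
        """(axes 3x3 rows, extents 3) sorted longest first.

        Extents include member radii: extent along axis e is
        max_i(c_i·e + r_i) − min_i(c_i·e − r_i).
        """
        c = self.centers - self.centers.mean(axis=0)
        cov = c.T @ c
        _, vecs = np.linalg.eigh(cov)
        axes = vecs.T[::-1]     # descending variance
        extents = np.array([self.extent_along(a) for a in axes])
        order = np.argsort(extents)[::-1]
        return axes[order], extents[order]

    def extent_along(self, axis: np.ndarray) -> float:
        proj = self.centers @ axis
        return float((proj + self.radii).max() - (proj - self.radii).min())


@dataclass(frozen=True)
class ClusterAxes:
    """Principal extents and the lateral size the array actually sees."""

    longitudinal: float         # L_ax, largest principal extent (µm)
    transverse: float           # T_ax, smallest principal extent (µm)
    effective_diameter: float   # d_eff, presented lateral extent (µm)
    in_plane_angle: Optional[float] = None   # Stage 2 initial angle (rad)
    jammed: bool = False

    def __post_init__(self) -> None:
        if not self.jammed:
            assert self.transverse <= self.longitudinal + 1e-9
            assert self.transverse - 1e-9 <= self.effective_diameter \
                <= self.longitudinal + 1e-9


def _vertical_extent_profile(cluster: RigidCluster) -> Tuple[np.ndarray, float, float]:
    """Axes frame in which extents are sorted: returns (axes, L, T)."""
    axes, extents = cluster.principal_axes()
    return axes, float(extents[0]), float(extents[-1])


def cluster_axes(cluster: Union[RigidCluster, CellParticle], ceiling: float,
                 stage: str, rng: Optional[np.random.Generator] = None,
                 tilt_sigma_deg: float = DEFAULT_TILT_SIGMA_DEG) -> ClusterAxes:
    """Orientation-aware effective diameter under a stage ceiling.

    stage1 (tall ceiling): the long axis aligns near-vertically (folded
    normal tilt noise, sigma ``tilt_sigma_deg``); the presented lateral
    extent interpolates between the transverse and longitudinal extents.
    stage2 (shallow ceiling): the cluster lies flat; the long axis takes a
    uniform random in-plane angle and d_eff is the lateral extent at that
    angle.  A cluster taller than the ceiling in its flattest pose is
    flagged jammed.
    """
    rng = rng or np.random.default_rng()
    if isinstance(cluster, CellParticle):
        d = 2.0 * cluster.radius
        if d > ceiling:
            return ClusterAxes(d, d, d, jammed=True)
        return ClusterAxes(d, d, d)

    axes, L, T = _vertical_extent_profile(cluster)
    if T > ceiling:
        return ClusterAxes(L, T, T, jammed=True)

    if stage == "stage1":
        if L <= ceiling:
            theta = math.radians(abs(rng.normal(0.0, tilt_sigma_deg)))
        else:
            # cannot stand fully upright; limited by the ceiling
            theta = math.acos(min(1.0, ceiling / L))
        d_eff = math.sqrt((L * math.sin(theta)) ** 2 +
                          (T * math.cos(theta)) ** 2)
        d_eff = min(max(d_eff, T), L)
        return ClusterAxes(L, T, d_eff)
    if stage == "stage2":
        phi = rng.uniform(0.0, math.pi)
        d_eff = _planar_lateral_extent(cluster, phi)
        return ClusterAxes(L, T, min(max(d_eff, T), L), in_plane_angle=phi)
    raise ValueError(f"unknown stage {stage!r}")


def _planar_projection(cluster: RigidCluster) -> Tuple[np.ndarray, np.ndarray]:
    """Member (s, t) coordinates in the plane spanned by the two longest
    principal axes (the lie-flat pose), plus radii."""
    axes, _ = cluster.principal_axes()
    e1, e2 = axes[0], axes[1]
    c = cluster.centers - cluster.centers.mean(axis=0)
    coords = np.stack([c @ e1, c @ e2], axis=1)
    return coords, cluster.radii


def _planar_lateral_extent(cluster: RigidCluster, phi: float) -> float:
    """Lateral (y) extent of the flat-lying cluster when its long axis
    makes angle phi with the flow (x) axis."""
    coords, radii = _planar_projection(cluster)
    y = coords[:, 0] * math.sin(phi) + coords[:, 1] * math.cos(phi)
    return float((y + radii).max() - (y - radii).min())


@dataclass
class TrajectoryRecord:
    points: np.ndarray              # (n, 2) absolute (x, y) µm, downsampled
    bump_count: int
    bump_locations: np.ndarray      # (k, 2) µm
    drift_per_reset: float          # mean net lateral displacement (µm)
    mode: str                       # zigzag | displaced | mixed
    peak_shear_pa: float
    residence_time_s: float
    n_resets: int
    pitch: float


@dataclass
class PartitionResult:
    """Per-class routing fractions and per-particle outcomes."""

    fractions: Dict[str, Dict[str, float]]      # class -> outlet -> fraction
    counts: Dict[str, Dict[str, int]]
    outcomes: List[Tuple[int, str, str]]        # (index, class, outlet)

    def __post_init__(self) -> None:
        for cls, row in self.fractions.items():
            if abs(sum(row.values()) - 1.0) > 1e-9:
                raise ValueError(f"fractions for {cls} do not sum to 1")


def size_class(p: Union[CellParticle, RigidCluster]) -> str:
    """single (1 cell), small_cluster (2–8), large_cluster (>= 9)."""
    n = 1 if isinstance(p, CellParticle) else p.n_cells
    if n == 1:
        return "single"
    return "small_cluster" if n <= 8 else "large_cluster"


class _CellGeometry:
    """Smooth distance-to-pillar lookups on the shifted-periodic tiling.

    The Euclidean distance transform of the 3x3 tiled mask (lateral shift
    applied across x-periods) is interpolated linearly; surface normals
    come from a lightly smoothed gradient of the distance map, which keeps
    the contact direction stable to well below a grid cell — raw
    nearest-node normals at the pillar nose are noisy enough to push a
    particle across the first-stream separatrix.
    """

    def __init__(self, field: FlowField):
        cell = field.cell
        self.cell = cell
        mask = cell.mask
        m = cell.shift_cells
        rows = []
        for k in (-1, 0, 1):
            shifted = np.roll(mask, -k * m, axis=1)
            rows.append(np.concatenate([shifted] * 3, axis=1))
        tiled = np.concatenate(rows, axis=0)
        res = cell.resolution
        dist = ndi.distance_transform_edt(~tiled) * res
        nx_, ny_ = mask.shape
        margin = 4
        crop = dist[nx_ - margin:2 * nx_ + margin,
                    ny_ - margin:2 * ny_ + margin]
        gx, gy = np.gradient(ndi.gaussian_filter(crop, 1.0), res)
        xs = (np.arange(-margin, nx_ + margin) + 0.5) * res
        ys = (np.arange(-margin, ny_ + margin) + 0.5) * res
        self._dist = RegularGridInterpolator((xs, ys), crop,
                                             bounds_error=False,
                                             fill_value=None)
        self._gx = RegularGridInterpolator((xs, ys), gx, bounds_error=False,
                                           fill_value=None)
        self._gy = RegularGridInterpolator((xs, ys), gy, bounds_error=False,
                                           fill_value=None)
        self.res = res

    def distance(self, x: float, y: float) -> float:
        return float(self._dist([[x, y]])[0])

    def normal(self, x: float, y: float) -> Tuple[float, float]:
        gx = float(self._gx([[x, y]])[0])
        gy = float(self._gy([[x, y]])[0])
        g = math.hypot(gx, gy)
        if g < 1e-12:
            return 1.0, 0.0
        return gx / g, gy / g


def advect_through_stage(particle: Union[CellParticle, RigidCluster],
                         field: FlowField, stage: DLDStageSpec,
                         seed: Optional[int] = None,
                         n_resets: int = 3,
                         rotation: bool = True,
                         groove_gain: float = DEFAULT_GROOVE_GAIN,
                         d_eff: Optional[float] = None,
                         initial_angle: Optional[float] = None,
                         stage_name: str = "stage1",
                         step_um: Optional[float] = None,
                         shape_factor: Optional[float] = None) -> TrajectoryRecord:
    """Advect one particle through ``n_resets`` resets of a stage.

    The particle is a disk of diameter ``d_eff`` for pillar contact.  For
    clusters in the shallow stage the disk radius follows the in-plane
    angle, which evolves with half the local vorticity plus (optionally)
    the groove-alignment impulse while traversing the grooved upstream
    pillar half.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    cell = field.cell
    rows_per_reset = stage.rows_per_full_shift
    total_rows = n_resets * rows_per_reset
    res = cell.resolution
    step = step_um if step_um is not None else res
    geom = _CellGeometry(field)
    uref = max(abs(field.mean_velocity), 1e-30)

    is_cluster = isinstance(particle, RigidCluster)
    rotate = rotation and is_cluster and stage_name == "stage2"
    # Shape factor for the Jeffery strain coupling.  The rod (aligning)
    # limit B = 1 is the default: an undisturbed elongated cluster settles
    # into flow alignment and presents its transverse axis, which is the
    # behavior the groove impulse has to beat.  B < 1 gives periodic
    # tumbling instead.
    bretherton = shape_factor if shape_factor is not None else 1.0
    if not is_cluster:
        bretherton = 0.0
    if d_eff is None:
        ax = cluster_axes(particle, stage.ceiling_height, stage_name, rng)
        if ax.jammed:
            raise ValueError("particle is geometrically jammed under the "
                             "stage ceiling")
        d_eff = ax.effective_diameter
        if initial_angle is None:
            initial_angle = ax.in_plane_angle
    phi = initial_angle if initial_angle is not None else 0.0

    def r_eff(angle: float) -> float:
        if rotate:
            return 0.5 * _planar_lateral_extent(particle, angle)
        return 0.5 * d_eff

    bundle = field.interpolator("advect")   # (u, v, vort, e11, e12, gamma)
    mu = field.viscosity_mpas * 1e-3
    psi_wall = field.wall_psi()

    def psi_at(x: float, y: float) -> float:
        p = np.array([[x % cell.length_x, y % cell.length_y]])
        i = min(int(p[0, 0] / res), cell.mask.shape[0] - 1)
        j = min(int(p[0, 1] / res), cell.mask.shape[1] - 1)
        return float(field.psi[i, j])

    # seed laterally at random in the inflow face, clear of the pillar
    r0 = r_eff(phi)
    for _ in range(200):
        y0 = rng.uniform(0.0, cell.length_y)
        if geom.distance(0.0, y0) >= r0:
            break
    else:
        raise RuntimeError("could not seed the particle clear of pillars")

    x_local, y_local = 0.0, y0
    y_abs = y0
    row = 0
    t_s = 0.0
    peak_shear = 0.0
    bumps: List[Tuple[float, float]] = []
    in_contact = False
    pts = [(0.0, y_abs)]
    reset_marks = [y_abs]
    cx = cell.pillar_center[0]
    x_groove_lo = cell.x_upstream_edge
    x_groove_hi = cx
    max_steps = int(total_rows * cell.length_x / step * 10)

    for istep in range(max_steps):
        p = np.array([[x_local % cell.length_x, y_local % cell.length_y]])
        u, v, vort, e11, e12, gamma = bundle(p)[0]
        radius = r_eff(phi)
        d_here = geom.distance(x_local % cell.length_x,
                               y_local % cell.length_y)
        constrained = False
        if d_here < radius + 0.5 * res:
            # resting on a pillar: only the tangential velocity advances
            nx_, ny_ = geom.normal(x_local % cell.length_x,
                                   y_local % cell.length_y)
            vn = u * nx_ + v * ny_
            if vn < 0.0:
                u -= vn * nx_
                v -= vn * ny_
                constrained = True
        speed = math.hypot(u, v)
        if speed < 1e-4 * uref:
            if d_here < radius + 0.5 * res:
                # stagnation-line contact (pillar nose): slide around the
                # pillar on the side of the particle's own streamline
                nx_, ny_ = geom.normal(x_local % cell.length_x,
                                       y_local % cell.length_y)
                tx, ty = -ny_, nx_
                dplus = abs(psi_at(x_local + step * tx, y_local + step * ty)
                            - psi_wall)
                dminus = abs(psi_at(x_local - step * tx, y_local - step * ty)
                             - psi_wall)
                sgn = 1.0 if dplus >= dminus else -1.0
                u, v = sgn * tx * uref, sgn * ty * uref
                speed = uref
                constrained = True
            else:
                raise RuntimeError(
                    f"particle stalled at x={x_local:.1f}, y={y_local:.1f} µm")
        dt = step * 1e-6 / speed
        t_s += dt
        tau_local = 1.5 * mu * gamma
        if tau_local > peak_shear:
            peak_shear = tau_local

        if rotate:
            # Jeffery-orbit rotation: half-vorticity spin plus the strain
            # coupling that parks elongated bodies near flow alignment
            omega = 0.5 * vort + bretherton * (-e11 * math.sin(2 * phi)
                                               + e12 * math.cos(2 * phi))
            if (not constrained and groove_gain != 0.0 and
                    x_groove_lo <= (x_local % cell.length_x) <= x_groove_hi):
                a = phi % math.pi
                drive = math.sin(2.0 * a) if a > 1e-3 else 1.0
                omega += groove_gain * gamma * drive
            phi_new = phi + omega * dt
            if constrained and r_eff(phi_new) > r_eff(phi):
                # the wall reaction torque blocks rotation into a more
                # interfering pose; alignment rotation stays free
                phi_new = phi
            phi = phi_new

        # midpoint (RK2) advection step; contact-constrained steps keep the
        # projected/slide velocity (the midpoint resample would drive the
        # particle back into the wall)
        if constrained:
            um, vm, sm = u, v, speed
        else:
            xm = x_local + 0.5 * step * u / speed
            ym = y_local + 0.5 * step * v / speed
            pm = np.array([[xm % cell.length_x, ym % cell.length_y]])
            um, vm = bundle(pm)[0][:2]
            sm = math.hypot(um, vm)
            if sm < 1e-6 * uref:
                um, vm, sm = u, v, speed
        x_local += step * um / sm
        y_step = step * vm / sm
        y_local += y_step
        y_abs += y_step

        # hard contact with the pillar surface
        radius = r_eff(phi)
        d = geom.distance(x_local % cell.length_x, y_local % cell.length_y)
        touched = constrained
        if d < radius:
            nx_, ny_ = geom.normal(x_local % cell.length_x,
                                   y_local % cell.length_y)
            push = radius - d
            x_local += push * nx_
            y_local += push * ny_
            y_abs += push * ny_
            touched = True
        if touched and not in_contact:
            bumps.append((x_local + row * cell.length_x, y_abs))
        in_contact = touched

        if x_local >= cell.length_x:
            x_local -= cell.length_x
            y_local -= cell.row_shift       # next row is shifted +s
            row += 1
            if row % rows_per_reset == 0:
                reset_marks.append(y_abs)
            if row >= total_rows:
                break
        if istep % 8 == 0:
            pts.append((x_local + row * cell.length_x, y_abs))
        if _debug_trace is not None:
            _debug_trace.append((row, x_local, y_local, phi))
    else:
        raise RuntimeError("advection exceeded the step budget")

    drifts = np.diff(reset_marks)
    # the first reset is an entry transient (the particle still migrating
    # to its steady orbit); exclude it when more remain
    if drifts.size > 1:
        drifts = drifts[1:]
    drift = float(drifts.mean()) if drifts.size else 0.0
    rec = TrajectoryRecord(points=np.array(pts), bump_count=len(bumps),
                           bump_locations=np.array(bumps).reshape(-1, 2),
                           drift_per_reset=drift, mode="",
                           peak_shear_pa=peak_shear, residence_time_s=t_s,
                           n_resets=n_resets, pitch=stage.pitch)
    rec.mode = classify_mode(rec, stage)
    return rec


def classify_mode(record: TrajectoryRecord, stage: DLDStageSpec) -> str:
    """zigzag (|drift| <= 0.1 pitch/reset), displaced (>= 0.9), else mixed."""
    if record.n_resets < 1:
        raise ValueError("trajectory must span at least one full reset")
    ratio = record.drift_per_reset / stage.pitch
    if abs(ratio) <= 0.1:
        return "zigzag"
    if ratio >= 0.9:
        return "displaced"
    return "mixed"


def simulate_device(population: Sequence[Union[CellParticle, RigidCluster]],
                    dev: DeviceSpec, fields: Dict[str, FlowField],
                    seed: Optional[int] = None, n_resets: int = 3,
                    rotation: bool = True,
                    groove_gain: float = DEFAULT_GROOVE_GAIN,
                    tilt_sigma_deg: float = DEFAULT_TILT_SIGMA_DEG
                    ) -> PartitionResult:
    """Run a population through both stages and partition it.

    Stage 1 displaced → Stage 1 product.  Undeflected particles are
    re-oriented under the Stage 2 ceiling and run there; displaced →
    Stage 2 product; the rest → Waste.  Geometrically jammed particles
    are reported in the ``jammed`` outlet and excluded from flow.
    """
    rng = np.random.default_rng(seed)
    outcomes: List[Tuple[int, str, str]] = []
    outlets = ("stage1_product", "stage2_product", "waste", "jammed")
    counts: Dict[str, Dict[str, int]] = {}
    for idx, p in enumerate(population):
        cls = size_class(p)
        counts.setdefault(cls, {o: 0 for o in outlets})
        sub = np.random.default_rng(rng.integers(0, 2 ** 31 - 1))
        ax1 = cluster_axes(p, dev.stage1.ceiling_height, "stage1", sub,
                           tilt_sigma_deg)
        if ax1.jammed:
            outlet = "jammed"
        else:
            rec1 = advect_through_stage(
                p, fields["stage1"], dev.stage1,
                seed=int(sub.integers(0, 2 ** 31 - 1)), n_resets=n_resets,
                rotation=False, d_eff=ax1.effective_diameter,
                stage_name="stage1")
            if rec1.mode == "displaced":
                outlet = "stage1_product"
            else:
                ax2 = cluster_axes(p, dev.stage2.ceiling_height, "stage2", sub)
                if ax2.jammed:
                    outlet = "jammed"
                else:
                    rec2 = advect_through_stage(
                        p, fields["stage2"], dev.stage2,
                        seed=int(sub.integers(0, 2 ** 31 - 1)),
                        n_resets=n_resets, rotation=rotation,
                        groove_gain=groove_gain if rotation else 0.0,
                        d_eff=ax2.effective_diameter,
                        initial_angle=ax2.in_plane_angle,
                        stage_name="stage2")
                    outlet = ("stage2_product" if rec2.mode == "displaced"
                              else "waste")
        counts[cls][outlet] += 1
        outcomes.append((idx, cls, outlet))

    fractions = {}
    for cls, row in counts.items():
        total = sum(row.values())
        fractions[cls] = {o: row[o] / total for o in outlets} if total else {}
    assert sum(sum(r.values()) for r in counts.values()) == len(population)
    return PartitionResult(fractions=fractions, counts=counts,
                           outcomes=outcomes)
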