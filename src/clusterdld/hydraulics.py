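"""Hydraulic resistances, flow networks and stage flow budgets.

The chip routes flow with passive resistance matching: outlet channel
lengths/widths are chosen so the ratio of outlet resistances fixes the
fraction of each stage's flow that leaves through the product port.  This
module provides the rectangular-duct resistance formula, a linear
conservation solver for resistance networks, the inverse design helpers,
per-stage flow budgets at the pump rates, and closed-form peak-shear
screens.

Working fluid is Newtonian with viscosity 1 mPa·s by default (the same
uniform-viscosity assumption the device design itself rests on).

Units at the API: lengths mm (channel length) / µm (cross-section), flows
µL/min, viscosity mPa·s, resistances Pa·s/m³ (SI), stresses Pa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Tuple

import networkx as nx
import numpy as np
from scipy.optimize import brentq

from .geometry import DeviceSpec, DLDStageSpec

__all__ = [
    "Channel",
    "FlowConfig",
    "StageFlowReport",
    "channel_resistance",
    "tube_resistance",
    "solve_network",
    "design_split",
    "solve_channel_width",
    "stage_flow_summary",
    "analytic_peak_shear",
]

UL_MIN_TO_M3_S = 1e-9 / 60.0


@dataclass(frozen=True)
class Channel:
    """Straight rectangular channel."""

    length_mm: float
    width_um: float
    height_um: float
    viscosity_mpas: float = 1.0

    def __post_init__(self) -> None:
        if min(self.length_mm, self.width_um, self.height_um,
               self.viscosity_mpas) <= 0:
            raise ValueError("channel dimensions and viscosity must be > 0")

    @property
    def resistance(self) -> float:
        return channel_resistance(self)


def channel_resistance(c: Channel) -> float:
    """Laminar resistance of a rectangular duct, Pa·s/m³.

    R = 12 µ L / (w a³ (1 − 0.63 a/w)) with a the shorter and w the longer
    cross-section dimension (first-term Fourier truncation, <13% error even
    for a square duct).
    """
    a = min(c.height_um, c.width_um) * 1e-6
    w = max(c.height_um, c.width_um) * 1e-6
    mu = c.viscosity_mpas * 1e-3
    L = c.length_mm * 1e-3
    R = 12.0 * mu * L / (w * a ** 3 * (1.0 - 0.63 * a / w))
    assert R > 0
    return R


def tube_resistance(length_mm: float, inner_diameter_mm: float,
                    viscosity_mpas: float = 1.0) -> float:
    """Poiseuille resistance of a cylindrical tube (for TYGON appendages)."""
    if length_mm <= 0 or inner_diameter_mm <= 0:
        raise ValueError("tube dimensions must be > 0")
    r = inner_diameter_mm * 1e-3 / 2.0
    return 8.0 * viscosity_mpas * 1e-3 * length_mm * 1e-3 / (math.pi * r ** 4)


def solve_network(inflows: Dict[str, float],
                  edges: Iterable[Tuple[str, str, float]],
                  ground: str | Iterable[str]) -> Dict[Tuple[str, str], float]:
    """Solve a resistance network for per-edge flows.

    Parameters
    ----------
    inflows : node -> imposed inflow (µL/min, positive into the network)
    edges : (node_a, node_b, resistance Pa·s/m³); flow reported a→b positive
    ground : node name(s) held at zero pressure (the open outlets)

    Returns per-edge flows in µL/min.  Mass is conserved at every interior
    node to machine precision; a disconnected network raises a ValueError
    naming the stranded component.
    """
    edges = list(edges)
    grounds = {ground} if isinstance(ground, str) else set(ground)
    g = nx.Graph()
    for a, b, R in edges:
        if R <= 0:
            raise ValueError(f"non-positive resistance on edge {(a, b)}")
        g.add_edge(a, b)
    g.add_nodes_from(inflows)
    g.add_nodes_from(grounds)
    comps = list(nx.connected_components(g))
    live = {c for c in map(frozenset, comps) if c & grounds}
    for c in map(frozenset, comps):
        if c not in live:
            raise ValueError(f"network component {sorted(c)} is not connected "
                             "to any reference-pressure node")

    nodes = sorted(g.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    G = np.zeros((n, n))
    rhs = np.zeros(n)
    for a, b, R in edges:
        cond = 1.0 / R
        ia, ib = idx[a], idx[b]
        G[ia, ia] += cond
        G[ib, ib] += cond
        G[ia, ib] -= cond
        G[ib, ia] -= cond
    for node, q in inflows.items():
        rhs[idx[node]] += q * UL_MIN_TO_M3_S
    for node in grounds:
        i = idx[node]
        G[i, :] = 0.0
        G[i, i] = 1.0
        rhs[i] = 0.0
    p = np.linalg.solve(G, rhs)
    flows = {}
    for a, b, R in edges:
        q = (p[idx[a]] - p[idx[b]]) / R / UL_MIN_TO_M3_S
        flows[(a, b)] = q
    return flows


def design_split(target_fraction: float, fixed_resistance: float) -> float:
    """Resistance of the branch that must carry ``target_fraction``.

    Two branches from one node to ground split inversely to resistance, so
    the branch carrying fraction t needs R = R_other · (1 − t) / t.
    """
    if not 0.0 < target_fraction < 1.0:
        raise ValueError("target_fraction must lie strictly in (0, 1)")
    if fixed_resistance <= 0:
        raise ValueError("fixed_resistance must be > 0")
    return fixed_resistance * (1.0 - target_fraction) / target_fraction


def solve_channel_width(target_resistance: float, length_mm: float,
                        height_um: float, viscosity_mpas: float = 1.0,
                        width_bounds_um: Tuple[float, float] = (10.0, 5e4),
                        ) -> Channel:
    """Solve the one free dimension of a compensation channel.

    Used where the layout fixes length and height (e.g. the 340 mm long,
    200 µm high channel on the Stage 1 product path) and the width must be
    chosen to realise a target resistance.
    """
    if target_resistance <= 0:
        raise ValueError("target_resistance must be > 0")

    def f(w: float) -> float:
        return channel_resistance(Channel(length_mm, w, height_um,
                                          viscosity_mpas)) - target_resistance

    lo, hi = width_bounds_um
    if f(lo) * f(hi) > 0:
        raise ValueError("target resistance not attainable within width bounds")
    w = brentq(f, lo, hi, rtol=1e-12)
    return Channel(length_mm, w, height_um, viscosity_mpas)


@dataclass(frozen=True)
class FlowConfig:
    """Pump rates and design split fractions.

    Defaults are the 0.5 mL/hr operating point: 8.3 µL/min sample,
    31.6 µL/min Stage 1 buffer, 40 µL/min Stage 2 buffer, 1/3 of each
    stage's flow deflected to product.
    """

    q_sample: float = 8.3
    q_buffer1: float = 31.6
    q_buffer2: float = 40.0
    stage1_deflected_fraction: float = 1.0 / 3.0
    stage2_deflected_fraction: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if min(self.q_sample, self.q_buffer1, self.q_buffer2) < 0:
            raise ValueError("flows must be >= 0")
        for f in (self.stage1_deflected_fraction,
                  self.stage2_deflected_fraction):
            if not 0.0 < f < 1.0:
                raise ValueError("deflected fractions must lie in (0, 1)")

    def scaled(self, factor: float) -> "FlowConfig":
        """Same relative ratios at ``factor`` times the pump rates."""
        return FlowConfig(self.q_sample * factor, self.q_buffer1 * factor,
                          self.q_buffer2 * factor,
                          self.stage1_deflected_fraction,
                          self.stage2_deflected_fraction)


@dataclass(frozen=True)
class StageFlowReport:
    stage: str
    total_ul_min: float
    per_gap_ul_min: float
    mean_gap_velocity_mm_s: float
    outputs: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        s = sum(self.outputs.values())
        if self.outputs and abs(s - self.total_ul_min) > 1e-9 * max(1.0, self.total_ul_min):
            raise ValueError("outlet flows do not sum to stage total")


def _mean_gap_velocity_mm_s(per_gap_ul_min: float, stage: DLDStageSpec) -> float:
    q = per_gap_ul_min * UL_MIN_TO_M3_S
    area = stage.gap * 1e-6 * stage.ceiling_height * 1e-6
    return q / area * 1e3


def stage_flow_summary(cfg: FlowConfig, dev: DeviceSpec) -> Dict[str, StageFlowReport]:
    """Flow budget of both stages.

    Stage 1 carries sample + Stage 1 buffer; Stage 2 carries the
    undeflected Stage 1 fraction plus the Stage 2 buffer; per-gap flow is
    the stage total divided by the number of lateral pitches (columns).
    """
    q1 = cfg.q_sample + cfg.q_buffer1
    s1_prod = cfg.stage1_deflected_fraction * q1
    q2 = (1.0 - cfg.stage1_deflected_fraction) * q1 + cfg.q_buffer2
    s2_prod = cfg.stage2_deflected_fraction * q2
    waste = q2 - s2_prod
    r1 = StageFlowReport(
        stage="stage1", total_ul_min=q1,
        per_gap_ul_min=q1 / dev.stage1.n_columns,
        mean_gap_velocity_mm_s=_mean_gap_velocity_mm_s(
            q1 / dev.stage1.n_columns, dev.stage1),
        outputs={"stage1_product": s1_prod, "to_stage2": q1 - s1_prod})
    r2 = StageFlowReport(
        stage="stage2", total_ul_min=q2,
        per_gap_ul_min=q2 / dev.stage2.n_columns,
        mean_gap_velocity_mm_s=_mean_gap_velocity_mm_s(
            q2 / dev.stage2.n_columns, dev.stage2),
        outputs={"stage2_product": s2_prod, "waste": waste})
    return {"stage1": r1, "stage2": r2}


def analytic_peak_shear(report: StageFlowReport, stage: DLDStageSpec,
                        viscosity_mpas: float = 1.0) -> float:
    """Closed-form order-of-magnitude peak wall shear (Pa).

    Mean gap velocity U = Q_gap/(g·h); the midplane runs ~1.5x faster than
    the depth average.  Depth-wall (floor/ceiling) estimate 6µU_mid/h and
    pillar-wall parallel-plate estimate 6µU_mid/g; the larger is returned.
    This is a screen for pump-rate selection, not a substitute for the
    unit-cell solve in :mod:`clusterdld.flowfield`.
    """
    mu = viscosity_mpas * 1e-3
    g = stage.gap * 1e-6
    h = stage.ceiling_height * 1e-6
    u_mean = report.mean_gap_velocity_mm_s * 1e-3
    u_mid = 1.5 * u_mean
    tau_depth = 6.0 * mu * u_mid / h
    tau_pillar = 6.0 * mu * u_mid / g
    return max(tau_depth, tau_pillar)
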