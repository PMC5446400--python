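"""DLD array specifications and design arithmetic.

A deterministic lateral displacement (DLD) array is a tilted lattice of
micropillars.  Particles whose effective diameter exceeds the critical
diameter ``D_c`` are bumped laterally ("displacement" mode) and collected;
smaller particles weave through unperturbed ("zigzag" mode).  The design
knobs are the lateral gap ``g`` between pillars, the lateral pitch
``lambda = pillar width + g``, and the row shift fraction ``epsilon = 1/N``
(successive rows offset by ``s = lambda * epsilon``).

This module holds the two stage geometries of the two-stage cluster chip
(Stage 1: tall cylinders sorting by size; Stage 2: shallow asymmetric
hybrid pillars sorting by cluster asymmetry) plus the closed-form critical
diameter estimators.

Units: all lengths in micrometres unless a name says otherwise.
Coordinates: x = mean flow direction, y = lateral (positive toward the
product wall), z = depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from scipy.optimize import brentq

__all__ = [
    "PillarShape",
    "DLDStageSpec",
    "CriticalDiameterResult",
    "DeviceSpec",
    "critical_diameter",
    "parabolic_first_stream_root",
    "row_shift",
    "reset_requirements",
    "build_reference_device",
]


@dataclass(frozen=True)
class PillarShape:
    """Plan-view pillar footprint.

    ``cylinder`` is a disk of the given diameter.  ``asymmetric_hybrid`` is
    the Stage 2 post: the upstream half of the footprint is an "I" profile
    (a rectangle with symmetric grooves notched into its lateral faces) and
    the downstream half is a semi-ellipse.  Groove dimensions are not
    uniquely determined by the documented footprint, so they are exposed as
    fractions of the footprint.
    """

    kind: str  # "cylinder" | "asymmetric_hybrid"
    diameter: float = 0.0
    lateral_extent_: float = 0.0
    alongflow_extent: float = 0.0
    groove_width_fraction: float = 1.0 / 3.0
    groove_depth_fraction: float = 0.25
    ellipse_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.kind == "cylinder":
            if self.diameter <= 0:
                raise ValueError("cylinder diameter must be > 0")
        elif self.kind == "asymmetric_hybrid":
            if self.lateral_extent_ <= 0 or self.alongflow_extent <= 0:
                raise ValueError("hybrid pillar extents must be > 0")
            for name in ("groove_width_fraction", "groove_depth_fraction",
                         "ellipse_fraction"):
                v = getattr(self, name)
                if not 0.0 < v < 1.0:
                    raise ValueError(f"{name} must lie in (0, 1), got {v}")
        else:
            raise ValueError(f"unknown pillar kind {self.kind!r}")

    @classmethod
    def cylinder(cls, diameter: float) -> "PillarShape":
        return cls(kind="cylinder", diameter=diameter)

    @classmethod
    def asymmetric_hybrid(cls, lateral_extent: float, alongflow_extent: float,
                          groove_width_fraction: float = 1.0 / 3.0,
                          groove_depth_fraction: float = 0.25,
                          ellipse_fraction: float = 0.5) -> "PillarShape":
        return cls(kind="asymmetric_hybrid",
                   lateral_extent_=lateral_extent,
                   alongflow_extent=alongflow_extent,
                   groove_width_fraction=groove_width_fraction,
                   groove_depth_fraction=groove_depth_fraction,
                   ellipse_fraction=ellipse_fraction)

    @property
    def lateral_extent(self) -> float:
        """Footprint extent in the lateral (y) direction."""
        return self.diameter if self.kind == "cylinder" else self.lateral_extent_

    @property
    def alongflow(self) -> float:
        """Footprint extent in the flow (x) direction."""
        return self.diameter if self.kind == "cylinder" else self.alongflow_extent

    def footprint_area(self) -> float:
        """Analytic plan-view area of the pillar footprint (µm²)."""
        if self.kind == "cylinder":
            return math.pi * (self.diameter / 2.0) ** 2
        w = self.lateral_extent_
        lf = self.alongflow_extent
        l_ell = self.ellipse_fraction * lf
        l_rect = lf - l_ell
        rect = l_rect * w
        grooves = 2.0 * (self.groove_width_fraction * l_rect) * \
            (self.groove_depth_fraction * w)
        ellipse = 0.5 * math.pi * l_ell * (w / 2.0)
        return rect - grooves + ellipse


@dataclass(frozen=True)
class DLDStageSpec:
    """One DLD stage: pillar shape plus array layout.

    ``rows_per_reset`` is stored layout metadata; all trajectory and
    reset arithmetic uses the shift fraction (a reset spans ``1/epsilon``
    rows, after which the cumulative row shift equals one pitch).
    """

    pillar: PillarShape
    gap: float                 # lateral clearance g between pillars (µm)
    pitch: float               # lateral center-to-center period lambda (µm)
    row_shift: float           # s, lateral offset per row (µm)
    shift_fraction: float      # epsilon = 1/N
    rows_per_reset: int
    n_resets: int
    n_columns: int
    ceiling_height: float      # h (µm)

    def __post_init__(self) -> None:
        if not 0.0 < self.shift_fraction < 1.0:
            raise ValueError("shift_fraction must lie in (0, 1)")
        if min(self.gap, self.pitch, self.row_shift, self.ceiling_height) <= 0:
            raise ValueError("gap, pitch, row_shift, ceiling_height must be > 0")
        if min(self.rows_per_reset, self.n_resets, self.n_columns) < 1:
            raise ValueError("counts must be >= 1")
        if abs(self.pitch - (self.pillar.lateral_extent + self.gap)) > 1e-6:
            raise ValueError(
                f"pitch {self.pitch} != pillar lateral extent "
                f"{self.pillar.lateral_extent} + gap {self.gap}")
        # the chip layout rounds the shift to integer µm
        if abs(self.row_shift - self.pitch * self.shift_fraction) > 1.0:
            raise ValueError("row_shift inconsistent with pitch * shift_fraction")

    @property
    def rows_per_full_shift(self) -> int:
        """Rows over which the cumulative shift equals one pitch (= 1/epsilon)."""
        return round(1.0 / self.shift_fraction)


@dataclass(frozen=True)
class CriticalDiameterResult:
    d_c: float                      # µm
    method: str                     # plug | parabolic | davis | cfd
    first_stream_width: Optional[float] = None  # beta (µm)
    profile_root: Optional[float] = None        # x = beta / g

    def __post_init__(self) -> None:
        if self.first_stream_width is not None:
            assert abs(self.d_c - 2.0 * self.first_stream_width) < 1e-9


@dataclass(frozen=True)
class DeviceSpec:
    """Full two-stage device: three terminal outputs.

    ``split_fractions`` are the design fractions of each stage's flow that
    leave through the deflected (product) outlet.
    """

    stage1: DLDStageSpec
    stage2: DLDStageSpec
    split_fractions: dict = field(
        default_factory=lambda: {"stage1_product": 1.0 / 3.0,
                                 "stage2_product": 1.0 / 3.0})

    def __post_init__(self) -> None:
        for k, v in self.split_fractions.items():
            if not 0.0 < v < 1.0:
                raise ValueError(f"split fraction {k} must lie in (0, 1)")

    @property
    def outlet_names(self) -> tuple:
        return ("stage1_product", "stage2_product", "waste")


def parabolic_first_stream_root(shift_fraction: float) -> float:
    """Root x in (0, 0.5) of 3x² − 2x³ = epsilon.

    For a parabolic velocity profile across the gap, the flux carried
    between the pillar wall and a station ``beta = x·g`` is the cubic on
    the left; the first flow lane carries flux fraction epsilon of the gap.
    """
    eps = shift_fraction
    if not 0.0 < eps < 1.0:
        raise ValueError("shift_fraction must lie in (0, 1)")

    def f(x: float) -> float:
        return 3.0 * x * x - 2.0 * x ** 3 - eps

    # f(0) = -eps < 0, f(0.5) = 0.5 - eps; for eps >= 0.5 the lane fills
    # half the gap or more and the root moves past 0.5.
    hi = 0.5 if eps < 0.5 else 1.0
    x = brentq(f, 0.0, hi, xtol=1e-14, rtol=8.9e-16)
    assert abs(f(x)) < 1e-10
    return x


def critical_diameter(gap: float, shift_fraction: float,
                      method: str = "parabolic") -> CriticalDiameterResult:
    """Closed-form critical diameter of a DLD array.

    plug:      D_c = 2·g·eps          (uniform cross-gap profile)
    parabolic: D_c = 2·g·x, 3x²−2x³ = eps  (flux-weighted lane width)
    davis:     D_c = 1.4·g·eps^0.48   (empirical correlation)
    """
    if gap <= 0:
        raise ValueError("gap must be > 0")
    if not 0.0 < shift_fraction < 1.0:
        raise ValueError("shift_fraction must lie in (0, 1)")
    eps = shift_fraction
    if method == "plug":
        beta = gap * eps
        return CriticalDiameterResult(2.0 * beta, "plug", beta, eps)
    if method == "parabolic":
        x = parabolic_first_stream_root(eps)
        beta = gap * x
        return CriticalDiameterResult(2.0 * beta, "parabolic", beta, x)
    if method == "davis":
        return CriticalDiameterResult(1.4 * gap * eps ** 0.48, "davis")
    raise ValueError(f"unknown method {method!r}")


def row_shift(pitch: float, shift_fraction: float,
              round_to_um: bool = False) -> float:
    """Row-to-row lateral shift s = pitch * epsilon, optionally integer-rounded."""
    if pitch <= 0:
        raise ValueError("pitch must be > 0")
    if not 0.0 <= shift_fraction < 1.0:
        raise ValueError("shift_fraction must lie in [0, 1)")
    s = pitch * shift_fraction
    return float(round(s)) if round_to_um else s


def reset_requirements(n_columns: int, safety_margin: int = 0) -> tuple:
    """(minimum resets, total resets) for full-width displacement.

    A continuously displaced particle drifts one lateral pitch per reset,
    so crossing an ``n_columns``-wide array needs at least ``n_columns``
    resets; the safety margin absorbs deflection failures.
    """
    if n_columns < 1:
        raise ValueError("n_columns must be >= 1")
    if safety_margin < 0:
        raise ValueError("safety_margin must be >= 0")
    return n_columns, n_columns + safety_margin


def build_reference_device() -> DeviceSpec:
    """The reference two-stage cluster chip geometry.

    Stage 1: 50 µm cylinders, 63 µm gaps, 113 µm pitch, 16 µm shifts,
    eps = 1/7, 8 columns, 12 resets, 90 µm ceiling.
    Stage 2: 77 µm (lateral) x 60 µm (along-flow) hybrid pillars, 63 µm
    gaps, 140 µm pitch, 20 µm shifts, eps = 1/7, 32 columns, 48 resets,
    30 µm ceiling.  Both stages deflect 1/3 of their flow to product.
    """
    stage1 = DLDStageSpec(
        pillar=PillarShape.cylinder(50.0),
        gap=63.0, pitch=113.0, row_shift=16.0, shift_fraction=1.0 / 7.0,
        rows_per_reset=10, n_resets=12, n_columns=8, ceiling_height=90.0)
    stage2 = DLDStageSpec(
        pillar=PillarShape.asymmetric_hybrid(77.0, 60.0),
        gap=63.0, pitch=140.0, row_shift=20.0, shift_fraction=1.0 / 7.0,
        rows_per_reset=10, n_resets=48, n_columns=32, ceiling_height=30.0)
    return DeviceSpec(stage1=stage1, stage2=stage2)
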