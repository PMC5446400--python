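"""Seeded synthetic-data generators.

Everything the toolkit needs to exercise itself without external data:
cluster populations for the transport simulator (rigid sphere assemblies
built by random sequential attachment), fluorescence-like frames with
per-event ground truth for the enumeration pipeline (GFP-tagged cells on
a dark background), and multinomial count tables for the statistics
module.  All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple, Union

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .transport import CellParticle, RigidCluster

__all__ = [
    "PopulationSpec",
    "FrameSpec",
    "make_population",
    "make_cluster",
    "render_frame",
    "make_count_table",
    "LARGE_CLUSTER_AREA_CUTOFF_UM2",
    "REFERENCE_CELL_AREA_UM2",
]

# Area cutoff separating small from large clusters, and the single-cell
# reference area it implies (cutoff / ~8.67 cells; the reference area is
# inferred from the canonical cutoff pair, not measured directly).
LARGE_CLUSTER_AREA_CUTOFF_UM2 = 3169.0
REFERENCE_CELL_AREA_UM2 = LARGE_CLUSTER_AREA_CUTOFF_UM2 / 8.67   # ~365.5


@dataclass(frozen=True)
class PopulationSpec:
    """Mixed population of single cells and clusters.

    Cluster sizes follow a log-series distribution truncated to
    ``max_cells`` — heavily weighted toward 2–4-cell aggregates, with a
    tail out past 100 cells, the regime the device targets.  Single CTCs
    span a wide diameter range; blood cells are fixed-size stand-ins.
    """

    n_particles: int = 100
    logseries_p: float = 0.8
    max_cells: int = 120
    ctc_diameter_range: Tuple[float, float] = (4.0, 30.0)
    cluster_cell_diameter_mean: float = 15.0
    cluster_cell_diameter_sd: float = 1.5
    rbc_diameter: float = 8.0
    wbc_diameter: float = 12.0
    composition: Tuple[float, float, float] = (1.0, 0.0, 0.0)
    # fractions of (CTC-lineage, RBC-like, WBC-like) among size-1 draws
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if not 0.0 < self.logseries_p < 1.0:
            raise ValueError("logseries_p must lie in (0, 1)")
        if abs(sum(self.composition) - 1.0) > 1e-9:
            raise ValueError("composition must sum to 1")


def _logseries_pmf(p: float, kmax: int) -> np.ndarray:
    k = np.arange(1, kmax + 1)
    w = p ** k / k
    return w / w.sum()


def make_cluster(n_cells: int, rng: np.random.Generator,
                 cell_diameter_mean: float = 15.0,
                 cell_diameter_sd: float = 1.5,
                 max_retries: int = 200) -> RigidCluster:
    """Build one rigid cluster by random sequential attachment.

    Each new sphere attaches at a uniformly random direction on a
    uniformly chosen existing member, touching its surface; placements
    overlapping any other member by more than a small tolerance are
    rejected.  The contact graph is connected by construction and the
    resulting shapes are generically asymmetric.
    """
    if n_cells < 2:
        raise ValueError("a cluster needs >= 2 cells")
    radii = np.clip(rng.normal(cell_diameter_mean, cell_diameter_sd,
                               n_cells), 4.0, None) / 2.0
    centers = np.zeros((n_cells, 3))
    for i in range(1, n_cells):
        for attempt in range(max_retries):
            host = int(rng.integers(0, i))
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            c = centers[host] + v * (radii[host] + radii[i])
            d = np.linalg.norm(centers[:i] - c, axis=1)
            if (d >= radii[:i] + radii[i] - 1.0).all():
                centers[i] = c
                break
        else:
            raise RuntimeError(
                f"could not place member {i} after {max_retries} retries")
    return RigidCluster(centers=centers, radii=radii)


def make_population(spec: PopulationSpec) -> List[Union[CellParticle,
                                                        RigidCluster]]:
    """Draw a mixed population of singles and clusters (seeded)."""
    rng = np.random.default_rng(spec.seed)
    pmf = _logseries_pmf(spec.logseries_p, spec.max_cells)
    sizes = rng.choice(np.arange(1, spec.max_cells + 1), size=spec.n_particles,
                       p=pmf)
    out: List[Union[CellParticle, RigidCluster]] = []
    for n in sizes:
        if n == 1:
            kind = rng.choice(3, p=np.asarray(spec.composition))
            if kind == 0:
                d = rng.uniform(*spec.ctc_diameter_range)
                out.append(CellParticle(radius=d / 2.0, label="CTC"))
            elif kind == 1:
                out.append(CellParticle(radius=spec.rbc_diameter / 2.0,
                                        label="RBC"))
            else:
                out.append(CellParticle(radius=spec.wbc_diameter / 2.0,
                                        label="WBC"))
        else:
            out.append(make_cluster(int(n), rng,
                                    spec.cluster_cell_diameter_mean,
                                    spec.cluster_cell_diameter_sd))
    return out


# ---------------------------------------------------------------------------
# synthetic fluorescence frames
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrameSpec:
    """Rendering model for one synthetic fluorescence frame.

    Cells are flat discs with per-cell brightness, blurred by the optics
    PSF, on a uniform background with Gaussian read noise — the features
    the enumeration pipeline actually keys on.  It deliberately omits the
    RBC clutter and uneven illumination of real blood-run frames.
    """

    shape: Tuple[int, int] = (1040, 1392)       # rows, cols (pixels)
    pixel_scale: float = 0.65                   # µm per pixel
    events_per_frame: float = 18.0              # Poisson mean
    class_probs: Tuple[float, float, float] = (0.5, 0.4, 0.1)
    # (single, small cluster 2–8, large cluster 9–15)
    small_sizes: Tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8)
    small_weights: Tuple[float, ...] = (0.35, 0.25, 0.15, 0.1, 0.06, 0.05, 0.04)
    large_sizes: Tuple[int, ...] = (9, 10, 11, 12, 13, 14, 15)
    cell_radius_mean_um: float = 10.8           # disc radius (area ~366 µm²)
    cell_radius_sd_um: float = 0.8
    single_radius_range_um: Tuple[float, float] = (7.0, 12.0)
    background: float = 40.0
    amplitude_range: Tuple[float, float] = (110.0, 200.0)
    noise_sd: float = 6.0
    blur_sigma_px: float = 1.2

    def __post_init__(self) -> None:
        if min(self.shape) <= 0 or self.pixel_scale <= 0:
            raise ValueError("frame dimensions and pixel scale must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if abs(sum(self.class_probs) - 1.0) > 1e-9:
            raise ValueError("class_probs must sum to 1")


def _layout_cluster_2d(n: int, radii: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """2D random sequential attachment (touching discs), µm offsets."""
    centers = np.zeros((n, 2))
    for i in range(1, n):
        for _ in range(200):
            host = int(rng.integers(0, i))
            a = rng.uniform(0, 2 * math.pi)
            # slight overlap guarantees pixel-level contact after rasterizing
            c = centers[host] + (radii[host] + radii[i] - 0.5) * \
                np.array([math.cos(a), math.sin(a)])
            d = np.linalg.norm(centers[:i] - c, axis=1)
            if (d >= radii[:i] + radii[i] - 1.5).all():
                centers[i] = c
                break
        else:
            raise RuntimeError("2D cluster layout failed")
    return centers


def render_frame(spec: FrameSpec, seed: Optional[int] = None,
                 area_cutoff_um2: float = LARGE_CLUSTER_AREA_CUTOFF_UM2
                 ) -> Tuple[np.ndarray, pd.DataFrame]:
    """Render one frame; returns (float32 image, ground-truth table).

    Ground truth carries, per event: class (single / small_cluster /
    large_cluster, from the member count and the union-of-discs area
    against the cutoff), area (µm²), member count, centroid (pixels) and
    a clipped flag for events touching the frame border.
    """
    rng = np.random.default_rng(seed)
    h, w = spec.shape
    img = np.zeros((h, w), dtype=np.float64)
    gt_label = np.zeros((h, w), dtype=np.int32)
    records = []
    n_events = rng.poisson(spec.events_per_frame)
    margin = 60.0 / spec.pixel_scale
    placed: List[Tuple[float, float, float]] = []    # (row, col, radius px)

    for ev in range(n_events):
        cls_draw = rng.choice(3, p=np.asarray(spec.class_probs))
        if cls_draw == 0:
            n = 1
            radii = np.array([rng.uniform(*spec.single_radius_range_um)])
        elif cls_draw == 1:
            n = int(rng.choice(spec.small_sizes,
                               p=np.asarray(spec.small_weights)
                               / sum(spec.small_weights)))
            radii = np.clip(rng.normal(spec.cell_radius_mean_um,
                                       spec.cell_radius_sd_um, n), 5.0, None)
        else:
            n = int(rng.choice(spec.large_sizes))
            radii = np.clip(rng.normal(spec.cell_radius_mean_um,
                                       spec.cell_radius_sd_um, n), 5.0, None)
        offsets = (np.zeros((1, 2)) if n == 1
                   else _layout_cluster_2d(n, radii, rng))
        ext_px = (np.abs(offsets).max() + radii.max()) / spec.pixel_scale

        for _ in range(60):
            r0 = rng.uniform(margin, h - margin)
            c0 = rng.uniform(margin, w - margin)
            if all((r0 - pr) ** 2 + (c0 - pc) ** 2 >
                   (ext_px + prad + 25.0) ** 2
                   for pr, pc, prad in placed):
                break
        else:
            continue    # frame too crowded; skip this event
        placed.append((r0, c0, ext_px))

        ev_id = len(records) + 1
        area_px = 0
        rsum = csum = 0.0
        clipped = False
        for k in range(n):
            rr = r0 + offsets[k, 1] / spec.pixel_scale
            cc = c0 + offsets[k, 0] / spec.pixel_scale
            rad = radii[k] / spec.pixel_scale
            rlo, rhi = int(max(rr - rad - 1, 0)), int(min(rr + rad + 2, h))
            clo, chi = int(max(cc - rad - 1, 0)), int(min(cc + rad + 2, w))
            if rlo >= rhi or clo >= chi:
                clipped = True
                continue
            yy, xx = np.mgrid[rlo:rhi, clo:chi]
            disc = (yy - rr) ** 2 + (xx - cc) ** 2 <= rad ** 2
            amp = rng.uniform(*spec.amplitude_range)
            sub = img[rlo:rhi, clo:chi]
            img[rlo:rhi, clo:chi] = np.where(disc, np.maximum(sub, amp), sub)
            new = disc & (gt_label[rlo:rhi, clo:chi] != ev_id)
            gt_label[rlo:rhi, clo:chi][new] = ev_id
            area_px += int(new.sum())
            rsum += float(yy[new].sum())
            csum += float(xx[new].sum())
            if rr - rad < 0 or rr + rad > h - 1 or cc - rad < 0 or \
                    cc + rad > w - 1:
                clipped = True
        area = float(area_px) * spec.pixel_scale ** 2
        if n == 1:
            cls = "single"
        elif area > area_cutoff_um2:
            cls = "large_cluster"
        else:
            cls = "small_cluster"
        records.append({"event_id": ev_id, "cls": cls, "area_um2": area,
                        "n_cells": n,
                        "centroid_row": rsum / max(area_px, 1),
                        "centroid_col": csum / max(area_px, 1),
                        "clipped": clipped})

    img = ndi.gaussian_filter(img, spec.blur_sigma_px)
    img += spec.background
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, img.shape)
    img = np.clip(img, 0.0, None).astype(np.float32)
    truth = pd.DataFrame.from_records(
        records, columns=["event_id", "cls", "area_um2", "n_cells",
                          "centroid_row", "centroid_col", "clipped"])
    truth.attrs["gt_label"] = gt_label
    truth.attrs["seed"] = seed
    return img, truth


def make_count_table(probabilities: dict, n_per_class: dict, n_replicates: int,
                     seed: Optional[int] = None) -> List[pd.DataFrame]:
    """Multinomial per-replicate count tables.

    ``probabilities``: class -> sequence of per-stream probabilities (must
    sum to 1); ``n_per_class``: class -> events per replicate.  Streams
    are (stage1_product, stage2_product, waste).
    """
    rng = np.random.default_rng(seed)
    streams = ["stage1_product", "stage2_product", "waste"]
    tables = []
    for rep in range(n_replicates):
        rows = {}
        for cls, p in probabilities.items():
            p = np.asarray(p, dtype=float)
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"probabilities for {cls} must sum to 1")
            rows[cls] = rng.multinomial(n_per_class[cls], p)
        df = pd.DataFrame(rows, index=streams).T
        df.attrs["replicate"] = rep
        tables.append(df)
    return tables
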