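"""Capture statistics: partition fractions, recovery, depletion, viability.

Operates on per-replicate count tables (class × output stream) such as
those produced by the enumeration pipeline or the synthetic generators.
Conventions: streams are Stage 1 product, Stage 2 product and Waste;
classes are single / small_cluster / large_cluster; fractions are
reported in percent; spread is the sample standard deviation across
replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "STREAMS",
    "DepletionResult",
    "ViabilityRecord",
    "ViabilityComparison",
    "CytometryEvent",
    "partition_fractions",
    "total_recovery",
    "log10_depletion",
    "counts_from_concentration",
    "wbc_from_channels",
    "viability_compare",
    "cytometry_classify",
]

STREAMS = ("stage1_product", "stage2_product", "waste")


def partition_fractions(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Mean ± SD percent of each class routed to each stream.

    ``tables``: one DataFrame per replicate, rows = classes, columns =
    streams, integer counts.  Returns a tidy frame indexed by class with
    ``<stream>_mean`` / ``<stream>_sd`` columns in percent; per replicate
    and class the three stream fractions sum to 100%.  A class with zero
    total in a replicate is flagged by NaN fractions there.
    """
    if len(tables) == 0:
        raise ValueError("at least one replicate table required")
    per_rep = []
    for t in tables:
        totals = t.sum(axis=1)
        frac = t.div(totals.replace(0, np.nan), axis=0) * 100.0
        per_rep.append(frac)
    stacked = pd.concat(per_rep, keys=range(len(per_rep)))
    mean = stacked.groupby(level=1, sort=False).mean()
    sd = stacked.groupby(level=1, sort=False).std(ddof=1)
    out = pd.DataFrame(index=mean.index)
    for s in mean.columns:
        out[f"{s}_mean"] = mean[s]
        out[f"{s}_sd"] = sd[s]
    return out


def total_recovery(stage1_pct: float, stage2_pct: float,
                   stage1_sd: Optional[float] = None,
                   stage2_sd: Optional[float] = None
                   ) -> Tuple[float, Optional[float]]:
    """Percent recovered in the two product streams combined.

    Recovery = Stage 1 + Stage 2 product fractions (equivalently
    100 − waste).  When per-stream SDs are supplied, they are combined in
    quadrature — which treats the stream fractions as independent; true
    replicate recoveries are anticorrelated through the shared total, so
    when the per-replicate tables are available, prefer computing
    recovery per replicate and taking its SD directly.
    """
    rec = stage1_pct + stage2_pct
    sd = None
    if stage1_sd is not None and stage2_sd is not None:
        sd = math.hypot(stage1_sd, stage2_sd)
    return rec, sd


def recovery_by_replicate(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Per-class recovery (% in product streams) mean ± SD across
    replicates, computed replicate-wise."""
    recs = []
    for t in tables:
        totals = t.sum(axis=1)
        prod = t[["stage1_product", "stage2_product"]].sum(axis=1)
        recs.append(prod / totals.replace(0, np.nan) * 100.0)
    stacked = pd.concat(recs, axis=1)
    return pd.DataFrame({"recovery_mean": stacked.mean(axis=1),
                         "recovery_sd": stacked.std(axis=1, ddof=1)})


@dataclass(frozen=True)
class DepletionResult:
    log10_depletion: float
    censored: bool = False          # True when output count was zero

    def __str__(self) -> str:
        return (f"> {self.log10_depletion:.2f}" if self.censored
                else f"{self.log10_depletion:.2f}")


def log10_depletion(input_count: float, output_count: float) -> DepletionResult:
    """D = log10(input / output) for a contaminating cell type.

    A zero output (below the counting-chamber detection floor) yields a
    censored lower bound ``> log10(input)`` instead of infinity.
    """
    if input_count <= 0:
        raise ValueError("input_count must be > 0")
    if output_count < 0:
        raise ValueError("output_count must be >= 0")
    if output_count == 0:
        return DepletionResult(math.log10(input_count), censored=True)
    return DepletionResult(math.log10(input_count / output_count))


def counts_from_concentration(concentration_per_ml: float,
                              volume_ml: float) -> float:
    """Total cell count = concentration × volume."""
    if concentration_per_ml < 0 or volume_ml < 0:
        raise ValueError("concentration and volume must be >= 0")
    return concentration_per_ml * volume_ml


def wbc_from_channels(nuclear_total: int, cancer_channel: int) -> int:
    """White-cell count from paired channels: total nuclei minus
    cancer-tagged nuclei (per frame or per condition)."""
    if cancer_channel > nuclear_total:
        raise ValueError("cancer channel count exceeds total nuclei")
    return nuclear_total - cancer_channel


@dataclass(frozen=True)
class ViabilityRecord:
    condition: str
    live: int
    total: int

    def __post_init__(self) -> None:
        if self.total < 200:
            raise ValueError(
                "at least 200 cells must be counted per condition")
        if not 0 <= self.live <= self.total:
            raise ValueError("live count must lie in [0, total]")

    @property
    def viability_pct(self) -> float:
        return 100.0 * self.live / self.total

    @classmethod
    def from_percent(cls, condition: str, viability_pct: float,
                     total: int = 200) -> "ViabilityRecord":
        return cls(condition, round(viability_pct / 100.0 * total), total)


@dataclass(frozen=True)
class ViabilityComparison:
    difference_pct: float           # treated − control mean viability
    ci_low: float
    ci_high: float
    p_value: float
    significant: bool


def viability_compare(treated: Sequence[ViabilityRecord],
                      control: Sequence[ViabilityRecord],
                      alpha: float = 0.05) -> ViabilityComparison:
    """Two-sided comparison of replicate viability percentages.

    Pooled-variance two-sample t test on the per-replicate percentages
    with a matching 95% (1 − alpha) confidence interval on the mean
    difference.  Flags significance iff p < alpha.
    """
    a = np.array([r.viability_pct for r in treated], dtype=float)
    b = np.array([r.viability_pct for r in control], dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 replicates per group")
    t_res = sps.ttest_ind(a, b, equal_var=True)
    df = len(a) + len(b) - 2
    sp2 = (((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
           / df)
    se = math.sqrt(sp2 * (1.0 / len(a) + 1.0 / len(b)))
    diff = float(a.mean() - b.mean())
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
    return ViabilityComparison(
        difference_pct=diff, ci_low=diff - tcrit * se,
        ci_high=diff + tcrit * se, p_value=float(t_res.pvalue),
        significant=bool(t_res.pvalue < alpha))


@dataclass(frozen=True)
class CytometryEvent:
    """Marker intensities for one imaged cell."""

    nuclear: float          # DRAQ5-like
    viability: float        # Calcein-like
    apoptosis: float        # Caspase-like
    epithelial: float       # EpCAM-like
    leukocyte: float        # CD45-like

    def __post_init__(self) -> None:
        for f in ("nuclear", "viability", "apoptosis", "epithelial",
                  "leukocyte"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} intensity must be >= 0")


DEFAULT_GATES = {"nuclear": 100.0, "viability": 100.0, "apoptosis": 100.0,
                 "epithelial": 100.0, "leukocyte": 100.0}


def cytometry_classify(event: CytometryEvent,
                       thresholds: Optional[Dict[str, float]] = None) -> str:
    """Gate one event: {excluded, viable_cancer, nonviable_cancer,
    leukocyte}.

    Nucleated (nuclear⁺) events only; cancer = epithelial⁺ and
    leukocyte⁻; viable iff viability⁺ AND apoptosis⁻, nonviable iff
    apoptosis⁺ OR viability⁻.  Every event lands in exactly one bin.
    """
    g = {**DEFAULT_GATES, **(thresholds or {})}
    if event.nuclear < g["nuclear"]:
        return "excluded"
    if event.leukocyte >= g["leukocyte"] or event.epithelial < g["epithelial"]:
        return "leukocyte"
    if event.viability >= g["viability"] and event.apoptosis < g["apoptosis"]:
        return "viable_cancer"
    return "nonviable_cancer"
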