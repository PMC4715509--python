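"""Peak-to-gene assignment and primary target calling.

A gene is a potential direct target of the profiled transcription factor if
a binding peak lies within a window of its TSS (default 50 kb either side)
or anywhere in the gene body.  A gene is called a PRIMARY target if,
additionally, it is significantly regulated in the same direction at both
post-stimulation timepoints (BH-adjusted p <= alpha at each).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core import GeneModel, Peak

__all__ = [
    "DERecord",
    "TargetCallSummary",
    "assign_peaks_to_genes",
    "bh_adjust",
    "call_primary_targets",
    "tss_distance_profile",
    "read_de_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DERecord:
    """Per-gene differential-expression evidence at one timepoint."""

    gene_id: str
    timepoint: str
    log_fc: float
    p_adj: float

    def __post_init__(self) -> None:
        if not (0 <= self.p_adj <= 1):
            raise ValueError(f"p_adj must be in [0, 1], got {self.p_adj}")
        if not np.isfinite(self.log_fc):
            raise ValueError(f"log_fc must be finite, got {self.log_fc}")


@dataclass
class TargetCallSummary:
    n_regulated_t1: int
    n_regulated_t2: int
    n_same_direction: int
    n_with_arbs: int
    n_primary: int
    regulated_t1: List[str]
    regulated_t2: List[str]
    same_direction: List[str]
    with_arbs: List[str]
    primary: List[str]

    def to_dict(self) -> Dict:
        return {
            "n_regulated_t1": self.n_regulated_t1,
            "n_regulated_t2": self.n_regulated_t2,
            "n_same_direction": self.n_same_direction,
            "n_with_arbs": self.n_with_arbs,
            "n_primary": self.n_primary,
            "primary": self.primary,
        }


def assign_peaks_to_genes(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    window_bp: int = 50_000,
    ignore_strand: bool = False,
) -> Dict[str, List[str]]:
    """Map each gene to the peaks near its TSS or inside its body.

    Gene g receives peak p iff p overlaps the half-open window
    [TSS − window_bp, TSS + window_bp) (strand-aware TSS unless
    ``ignore_strand``) or p overlaps the gene body [start, end).  Overlap
    means >= 1 shared bp; one peak may map to several genes.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    out: Dict[str, List[str]] = {}
    for g in genes:
        tss = g.start if ignore_strand else g.tss
        win_lo, win_hi = tss - window_bp, tss + window_bp
        assigned: List[str] = []
        for p in peaks:
            if p.chrom != g.chrom:
                continue
            near_tss = p.start < win_hi and p.end > win_lo
            in_body = p.start < g.end and p.end > g.start
            if near_tss or in_body:
                assigned.append(p.name if p.name is not None else f"{p.chrom}:{p.start}-{p.end}")
        if assigned:
            out[g.id] = assigned
    return out


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, clipped to 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_primary_targets(
    de_t1: Sequence[DERecord],
    de_t2: Sequence[DERecord],
    gene_peak_map: Mapping[str, Sequence[str]],
    alpha: float = 0.05,
) -> TargetCallSummary:
    """Intersect two-timepoint same-direction regulation with peak-bearing genes.

    Regulated at a timepoint ⇔ p_adj <= alpha; same-direction ⇔ regulated at
    both timepoints with equal sign of log fold change; primary ⇔
    same-direction AND >= 1 assigned peak.  A gene present at only one
    timepoint is treated as unregulated at the other (logged).
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")

    def index(records: Sequence[DERecord]) -> Dict[str, DERecord]:
        d: Dict[str, DERecord] = {}
        for r in records:
            if r.gene_id in d:
                raise ValueError(f"duplicate gene {r.gene_id} in DE table")
            d[r.gene_id] = r
        return d

    t1, t2 = index(de_t1), index(de_t2)
    only_one = set(t1) ^ set(t2)
    if only_one:
        logger.info(
            "%d genes present at one timepoint only; treated as unregulated "
            "at the missing timepoint", len(only_one)
        )

    reg1 = sorted(g for g, r in t1.items() if r.p_adj <= alpha)
    reg2 = sorted(g for g, r in t2.items() if r.p_adj <= alpha)
    same = sorted(
        g
        for g in set(reg1) & set(reg2)
        if np.sign(t1[g].log_fc) == np.sign(t2[g].log_fc) and t1[g].log_fc != 0
    )
    with_arbs = sorted(g for g in gene_peak_map if gene_peak_map[g])
    primary = sorted(set(same) & set(with_arbs))
    return TargetCallSummary(
        n_regulated_t1=len(reg1),
        n_regulated_t2=len(reg2),
        n_same_direction=len(same),
        n_with_arbs=len(with_arbs),
        n_primary=len(primary),
        regulated_t1=reg1,
        regulated_t2=reg2,
        same_direction=same,
        with_arbs=with_arbs,
        primary=primary,
    )


def tss_distance_profile(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    bins: Sequence[float],
) -> Tuple[np.ndarray, np.ndarray, List[float]]:
    """Histogram of signed peak-centre-to-nearest-TSS distances.

    Each peak contributes the distance to the TSS of its nearest same-
    chromosome gene (tie on |distance| broken by lexicographically smaller
    gene id); distances are negated for − strand genes so that positive
    always means downstream of the TSS in the direction of transcription.
    Returns (counts, bin edges, raw distances).
    """
    by_chrom: Dict[str, List[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    distances: List[float] = []
    for p in peaks:
        cands = by_chrom.get(p.chrom)
        if not cands:
            continue
        best = min(
            cands, key=lambda g: (abs(p.midpoint - g.tss), g.id)
        )
        d = p.midpoint - best.tss
        if best.strand == "-":
            d = -d
        distances.append(d)
    counts, edges = np.histogram(distances, bins=np.asarray(bins, dtype=float))
    return counts, edges, distances


def read_de_table(path, timepoint: str) -> List[DERecord]:
    """Read a DE TSV with columns gene_id, log_fc, p_adj."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    required = {"gene_id", "log_fc", "p_adj"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: DE table needs columns {sorted(required)}")
    return [
        DERecord(row.gene_id, timepoint, float(row.log_fc), float(row.p_adj))
        for row in df.itertuples(index=False)
    ]
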