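"""Motif co-occurrence within binding-site windows and its permutation null.

Motif instances live inside fixed windows centred on binding peaks (one
window per peak name); an instance's genomic start is window.start + offset.
The observed statistic is the fraction of A-instances with at least one
B-instance within a distance cutoff; the null re-places every instance
uniformly (window chosen uniformly among windows, offset uniform among valid
offsets) and recomputes the same fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import Peak

__all__ = ["MotifInstance", "cooccurrence_rate", "coincidence_null",
           "permutation_pvalue", "read_motif_instances"]


@dataclass(frozen=True)
class MotifInstance:
    """One motif match inside a binding-site window."""

    motif_id: str
    arbs_id: str
    offset: int
    strand: str = "+"
    length: int = 1

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise ValueError("offset must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.length < 1:
            raise ValueError("motif length must be >= 1")


def _genomic_anchor(
    inst: MotifInstance, windows: Dict[str, Peak], anchor: str
) -> Tuple[str, float]:
    try:
        w = windows[inst.arbs_id]
    except KeyError:
        raise KeyError(f"window {inst.arbs_id!r} not found for motif instance") from None
    if inst.offset + inst.length > w.length:
        raise ValueError(
            f"motif instance (offset {inst.offset}, length {inst.length}) "
            f"does not fit in window {inst.arbs_id} of length {w.length}"
        )
    start = w.start + inst.offset
    if anchor == "start":
        return w.chrom, float(start)
    if anchor == "center":
        return w.chrom, start + inst.length / 2.0
    raise ValueError(f"unknown anchor {anchor!r} (use 'start' or 'center')")


def cooccurrence_rate(
    a: Sequence[MotifInstance],
    b: Sequence[MotifInstance],
    windows: Sequence[Peak],
    max_dist_bp: int = 100,
    anchor: str = "start",
) -> Tuple[float, int]:
    """Fraction of A-instances with any B-instance within ``max_dist_bp``.

    Distance is absolute genomic distance between anchors (start-to-start by
    default).  Returns (fraction, number of co-occurring A-instances).
    """
    if not a:
        raise ValueError("empty A-instance list: co-occurrence fraction undefined")
    wmap = {w.name: w for w in windows if w.name is not None}
    b_pos: Dict[str, List[float]] = {}
    for inst in b:
        chrom, pos = _genomic_anchor(inst, wmap, anchor)
        b_pos.setdefault(chrom, []).append(pos)
    b_arr = {c: np.sort(np.array(v)) for c, v in b_pos.items()}

    n_co = 0
    for inst in a:
        chrom, pos = _genomic_anchor(inst, wmap, anchor)
        arr = b_arr.get(chrom)
        if arr is None:
            continue
        i = np.searchsorted(arr, pos)
        near = False
        if i < len(arr) and arr[i] - pos <= max_dist_bp:
            near = True
        if i > 0 and pos - arr[i - 1] <= max_dist_bp:
            near = True
        if near:
            n_co += 1
    return n_co / len(a), n_co


def coincidence_null(
    a: Sequence[MotifInstance],
    b: Sequence[MotifInstance],
    windows: Sequence[Peak],
    n_perm: int = 1000,
    max_dist_bp: int = 100,
    rng_seed: int = 0,
    anchor: str = "start",
) -> Tuple[float, np.ndarray]:
    """Random-coincidence rate of A/B co-occurrence under uniform re-placement.

    Each permutation re-draws every instance's (window, offset) uniformly:
    the window uniform among all windows, the offset uniform among positions
    where the motif fits.  Instance counts per motif type are preserved
    exactly.  Returns (mean permuted rate, all permuted rates).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    win_list = [w for w in windows if w.name is not None]
    if not win_list:
        raise ValueError("no named windows")
    for inst in list(a) + list(b):
        if all(inst.length > w.length for w in win_list):
            raise ValueError("motif longer than every window")

    rng = np.random.default_rng(rng_seed)
    rates = np.empty(n_perm)
    for k in range(n_perm):
        perm_a = _replace_uniform(a, win_list, rng)
        perm_b = _replace_uniform(b, win_list, rng)
        rates[k], _ = cooccurrence_rate(
            perm_a, perm_b, win_list, max_dist_bp=max_dist_bp, anchor=anchor
        )
    return float(rates.mean()), rates


def _replace_uniform(
    instances: Sequence[MotifInstance],
    windows: List[Peak],
    rng: np.random.Generator,
) -> List[MotifInstance]:
    out: List[MotifInstance] = []
    for inst in instances:
        while True:
            w = windows[rng.integers(0, len(windows))]
            max_off = w.length - inst.length
            if max_off >= 0:
                break
        off = int(rng.integers(0, max_off + 1))
        out.append(replace(inst, arbs_id=w.name, offset=off))
    return out


def permutation_pvalue(observed_rate: float, perm_rates: np.ndarray) -> float:
    """Fraction of permutations reaching the observed co-occurrence rate."""
    return float((perm_rates >= observed_rate).mean())


def read_motif_instances(path) -> List[MotifInstance]:
    """Read a motif-instance TSV: motif_id, arbs_id, offset, strand [, length]."""
    df = pd.read_csv(path, sep="\t", dtype={"motif_id": str, "arbs_id": str, "strand": str})
    required = {"motif_id", "arbs_id", "offset", "strand"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: motif table needs columns {sorted(required)}")
    has_len = "length" in df.columns
    return [
        MotifInstance(
            row.motif_id,
            row.arbs_id,
            int(row.offset),
            row.strand,
            int(row.length) if has_len else 1,
        )
        for row in df.itertuples(index=False)
    ]
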