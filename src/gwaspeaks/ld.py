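"""Pairwise LD (r²) from phased haplotypes and proxy expansion of index SNPs.

r² between two biallelic sites is computed by direct haplotype counting —
r² = D² / (pA(1−pA) pB(1−pB)) with D = pAB − pA·pB — which for phased 0/1
columns is identical to the squared Pearson correlation of the allele
indicators.  Monomorphic columns have undefined LD and are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .core import Variant

__all__ = ["HaplotypePanel", "LDPair", "compute_r2", "expand_index_snps",
           "read_panel_tsv", "write_panel_tsv", "write_ld_pairs"]


@dataclass(frozen=True)
class LDPair:
    index_id: str
    proxy_id: str
    chrom: str
    pos: int
    r2: float


class HaplotypePanel:
    """Phased biallelic haplotype panel: alleles coded 0/1, haplotypes × variants."""

    def __init__(self, variants: Sequence[Variant], matrix: np.ndarray):
        matrix = np.asarray(matrix, dtype=np.int8)
        if matrix.ndim != 2:
            raise ValueError("haplotype matrix must be 2-D (haplotypes × variants)")
        if matrix.shape[1] != len(variants):
            raise ValueError(
                f"matrix has {matrix.shape[1]} columns but {len(variants)} variants"
            )
        if not np.isin(matrix, (0, 1)).all():
            raise ValueError("haplotype matrix entries must be 0 or 1 (biallelic)")
        ids = [v.id for v in variants]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate variant ids in panel")
        self.variants: List[Variant] = list(variants)
        self.matrix = matrix
        self._col: Dict[str, int] = {v.id: j for j, v in enumerate(variants)}

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_variants(self) -> int:
        return self.matrix.shape[1]

    def column(self, variant_id: str) -> np.ndarray:
        try:
            return self.matrix[:, self._col[variant_id]]
        except KeyError:
            raise KeyError(f"variant {variant_id!r} not in panel") from None

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._col


def compute_r2(col_a: np.ndarray, col_b: np.ndarray) -> float:
    """LD r² between two phased 0/1 allele columns.

    Symmetric, allele-label-flip invariant, and equal to the squared Pearson
    correlation of the two indicator vectors.
    """
    a = np.asarray(col_a, dtype=float)
    b = np.asarray(col_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("allele columns must be 1-D and of equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 haplotypes")
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise ValueError("monomorphic column: r² undefined")
    pab = (a * b).mean()
    d = pab - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))


def expand_index_snps(
    index: Sequence[Variant],
    panel: HaplotypePanel,
    r2_min: float = 0.5,
    window_bp: int = 1_000_000,
) -> List[LDPair]:
    """Expand GWAS index variants to linked proxies with r² >= ``r2_min``.

    Candidate proxies are panel variants on the same chromosome within
    ``window_bp`` of the index position.  Every index variant is also its own
    proxy with r² = 1.  Pairs sorted by index id then proxy position.
    """
    if not (0 < r2_min <= 1):
        raise ValueError(f"r2_min must be in (0, 1], got {r2_min}")
    missing = [v.id for v in index if v.id not in panel]
    if missing:
        raise KeyError(f"index variants absent from panel: {missing}")

    pairs: List[LDPair] = []
    for iv in sorted(index, key=lambda v: v.id):
        a = panel.column(iv.id)
        block: List[LDPair] = [LDPair(iv.id, iv.id, iv.chrom, iv.pos, 1.0)]
        for pv in panel.variants:
            if pv.id == iv.id or pv.chrom != iv.chrom:
                continue
            if abs(pv.pos - iv.pos) > window_bp:
                continue
            r2 = compute_r2(a, panel.column(pv.id))
            if r2 >= r2_min:
                block.append(LDPair(iv.id, pv.id, pv.chrom, pv.pos, r2))
        block.sort(key=lambda p: (p.pos, p.proxy_id))
        pairs.extend(block)
    return pairs


# ---------------------------------------------------------------------------
# I/O: panel TSV = variant metadata columns + one 0/1 column per haplotype
# ---------------------------------------------------------------------------

def read_panel_tsv(path) -> HaplotypePanel:
    """Read a panel TSV: columns id, chrom, pos, then hap_1 … hap_n (0/1)."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "chrom": str})
    meta_cols = {"id", "chrom", "pos"}
    if not meta_cols.issubset(df.columns):
        raise ValueError(f"{path}: panel needs columns {sorted(meta_cols)}")
    hap_cols = [c for c in df.columns if c not in meta_cols]
    if not hap_cols:
        raise ValueError(f"{path}: panel has no haplotype columns")
    variants = [
        Variant(row.id, row.chrom, int(row.pos)) for row in df.itertuples(index=False)
    ]
    matrix = df[hap_cols].to_numpy(dtype=np.int8).T  # haplotypes × variants
    return HaplotypePanel(variants, matrix)


def write_panel_tsv(panel: HaplotypePanel, path) -> None:
    hap_cols = {f"hap_{i + 1}": panel.matrix[i] for i in range(panel.n_haplotypes)}
    df = pd.DataFrame(
        {
            "id": [v.id for v in panel.variants],
            "chrom": [v.chrom for v in panel.variants],
            "pos": [v.pos for v in panel.variants],
            **hap_cols,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_ld_pairs(pairs: Sequence[LDPair], path) -> None:
    with open(path, "w") as fh:
        fh.write("index_id\tproxy_id\tchrom\tpos\tr2\n")
        for p in pairs:
            fh.write(f"{p.index_id}\t{p.proxy_id}\t{p.chrom}\t{p.pos}\t{p.r2:.6g}\n")
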