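"""Genomic coordinate types, interval overlap, and tabular readers/writers.

Conventions
-----------
Peaks and gene models use BED-style 0-based half-open intervals
``[start, end)``.  Variants use the VCF convention (1-based positions) and
are converted to 0-based internally wherever they are compared against
intervals.  Chromosome names are matched by exact string equality unless
:func:`normalize_chrom` is applied explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Peak",
    "Variant",
    "GeneModel",
    "ChromSizes",
    "read_bed",
    "write_bed",
    "read_variants",
    "write_variants",
    "read_genes",
    "read_chrom_sizes",
    "filter_peaks_by_score",
    "variant_in_peak",
    "count_overlaps",
    "normalize_chrom",
]


class ParseError(ValueError):
    """A malformed line in a tabular genomic file."""


@dataclass(frozen=True)
class Peak:
    """A ChIP-seq peak: half-open interval with an optional caller score.

    ``score`` is the peak caller's −10·log10(P); peaks passing a score
    threshold constitute the binding-site universe (e.g. ARBSs for an
    androgen-receptor ChIP).
    """

    chrom: str
    start: int
    end: int
    score: Optional[float] = None
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid peak interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.score is not None and self.score < 0:
            raise ValueError(f"negative peak score {self.score}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class Variant:
    """A point variant with rsID-style id and 1-based position."""

    id: str
    chrom: str
    pos: int
    role: str = "plain"  # index | proxy | plain

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("variant id must be non-empty")
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")
        if self.role not in ("index", "proxy", "plain"):
            raise ValueError(f"unknown variant role {self.role!r}")

    @property
    def pos0(self) -> int:
        """0-based position for comparison against half-open intervals."""
        return self.pos - 1


@dataclass(frozen=True)
class GeneModel:
    """A gene as a stranded half-open interval; TSS is the 5' end."""

    id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid gene interval [{self.start}, {self.end}) for {self.id}"
            )

    @property
    def tss(self) -> int:
        """Transcription start site (0-based): start on +, end−1 on −."""
        return self.start if self.strand == "+" else self.end - 1


class ChromSizes(dict):
    """Mapping chromosome name → length in bp, with coordinate validation."""

    def __init__(self, sizes: Dict[str, int]):
        for chrom, length in sizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length {length}")
        super().__init__(sizes)

    def validate_peaks(self, peaks: Iterable[Peak]) -> None:
        for p in peaks:
            if p.chrom not in self:
                raise ValueError(f"peak chromosome {p.chrom!r} not in chrom sizes")
            if p.end > self[p.chrom]:
                raise ValueError(
                    f"peak [{p.start}, {p.end}) exceeds {p.chrom} length {self[p.chrom]}"
                )

    def validate_variants(self, variants: Iterable[Variant]) -> None:
        for v in variants:
            if v.chrom not in self:
                raise ValueError(f"variant chromosome {v.chrom!r} not in chrom sizes")
            if v.pos0 >= self[v.chrom]:
                raise ValueError(
                    f"variant {v.id} position {v.pos} exceeds {v.chrom} length"
                )


def normalize_chrom(name: str) -> str:
    """Strip a leading ``chr`` prefix so 'chr1' and '1' compare equal."""
    return name[3:] if name.startswith("chr") else name


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_bed(path) -> List[Peak]:
    """Read a BED3/BED5 file into peaks.

    Column 2 is the 0-based start, column 3 the exclusive end; column 4
    (when present) is the name and column 5 (when present and numeric) the
    score.  Lines starting with ``#``, ``track`` or ``browser`` are skipped.
    """
    peaks: List[Peak] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if start >= end or start < 0:
                raise ParseError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            name = fields[3] if len(fields) > 3 and fields[3] not in ("", ".") else None
            score = None
            if len(fields) > 4 and fields[4] not in ("", "."):
                try:
                    score = float(fields[4])
                except ValueError:
                    score = None
            peaks.append(Peak(chrom, start, end, score=score, name=name))
    return peaks


def write_bed(peaks: Sequence[Peak], path) -> None:
    """Write peaks as BED5 (name/score columns written as '.' when absent)."""
    with open(path, "w") as fh:
        for p in peaks:
            name = p.name if p.name is not None else "."
            score = repr(p.score) if p.score is not None else "."
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t{score}\n")


def read_variants(path) -> List[Variant]:
    """Read a variant TSV with header columns id, chrom, pos [, role]."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"id": str, "chrom": str})
    required = {"id", "chrom", "pos"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: variant table needs columns {sorted(required)}")
    has_role = "role" in df.columns
    return [
        Variant(
            id=row.id,
            chrom=row.chrom,
            pos=int(row.pos),
            role=(row.role if has_role else "plain"),
        )
        for row in df.itertuples(index=False)
    ]


def write_variants(variants: Sequence[Variant], path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tchrom\tpos\trole\n")
        for v in variants:
            fh.write(f"{v.id}\t{v.chrom}\t{v.pos}\t{v.role}\n")


def read_genes(path) -> List[GeneModel]:
    """Read a gene-model TSV with header columns id, chrom, strand, start, end."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"id": str, "chrom": str, "strand": str})
    required = {"id", "chrom", "strand", "start", "end"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: gene table needs columns {sorted(required)}")
    return [
        GeneModel(row.id, row.chrom, row.strand, int(row.start), int(row.end))
        for row in df.itertuples(index=False)
    ]


def write_genes(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tchrom\tstrand\tstart\tend\n")
        for g in genes:
            fh.write(f"{g.id}\t{g.chrom}\t{g.strand}\t{g.start}\t{g.end}\n")


def read_chrom_sizes(path) -> ChromSizes:
    """Read a two-column TSV of chromosome name and length."""
    sizes: Dict[str, int] = {}
    path = Path(path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            try:
                sizes[fields[0]] = int(fields[1])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer length") from None
    return ChromSizes(sizes)


def write_chrom_sizes(sizes: ChromSizes, path) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def filter_peaks_by_score(peaks: Sequence[Peak], min_score: float) -> List[Peak]:
    """Keep peaks whose score is STRICTLY greater than ``min_score``.

    The binding-site universe is defined by score > threshold (a −10·log10 P
    cutoff); peaks lacking a score cannot be filtered and raise.
    """
    if math.isinf(min_score) and min_score < 0:
        return list(peaks)
    for p in peaks:
        if p.score is None:
            raise ValueError(
                f"peak {p.name or f'{p.chrom}:{p.start}-{p.end}'} has no score; "
                "cannot apply a score filter"
            )
    return [p for p in peaks if p.score > min_score]


def variant_in_peak(v: Variant, p: Peak) -> bool:
    """True iff the variant's 0-based position lies inside the half-open peak."""
    return v.chrom == p.chrom and p.start <= v.pos0 < p.end


def count_overlaps(
    variants: Sequence[Variant], peaks: Sequence[Peak]
) -> Tuple[int, List[Tuple[str, Optional[str]]]]:
    """Count DISTINCT variants lying in at least one peak.

    A variant inside two peaks counts once; ``hits`` lists every
    (variant id, peak name) pair.  Duplicate variant ids are rejected.
    """
    ids = [v.id for v in variants]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate variant ids: {dupes}")

    hits: List[Tuple[str, Optional[str]]] = []
    covered = set()
    by_chrom: Dict[str, List[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)

    for v in variants:
        for p in by_chrom.get(v.chrom, ()):
            if p.start <= v.pos0 < p.end:
                hits.append((v.id, p.name))
                covered.add(v.id)
    return len(covered), hits


def positions_in_intervals(
    pos0: np.ndarray, starts: np.ndarray, ends: np.ndarray
) -> np.ndarray:
    """Vectorised membership of 0-based positions in half-open intervals.

    Returns a boolean vector: position i lies in >=1 interval.  Intervals may
    overlap; positions and intervals must already be on one chromosome.
    """
    if len(starts) == 0 or len(pos0) == 0:
        return np.zeros(len(pos0), dtype=bool)
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    # position p is covered iff some interval j has s_j <= p < e_j; with starts
    # sorted, that is cummax(e)[idx-1] > p where idx = #(s_j <= p)
    cummax_e = np.maximum.accumulate(e)
    idx = np.searchsorted(s, pos0, side="right")
    ok = idx >= 1
    out = np.zeros(len(pos0), dtype=bool)
    out[ok] = pos0[ok] < cummax_e[idx[ok] - 1]
    return out
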