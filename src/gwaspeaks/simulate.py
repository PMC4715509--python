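"""Synthetic-data generators with planted, recorded ground truth.

Every input the pipeline consumes can be generated here: a genome with gene
models, ChIP-seq-like peaks with a tunable fraction of variants planted
inside them, a block-structured haplotype panel with decaying LD, two-
timepoint differential-expression tables with planted same-direction target
genes, and a patient cohort with a genotype-dependent expression/IHC effect.
Defaults describe the study conditions the pipeline targets: a 10 Mb genome
(2 × 5 Mb), ~300 peaks with log-normal lengths (median ~300 bp, ~1% genome
coverage), 200 variants with planted fraction 0.3, 100 haplotypes in
5-column LD blocks, 200 genes with 120 planted primary targets, and a
100-patient cohort at minor-allele frequency 0.13 with a −1 SD carrier
effect.  All generators are deterministic given ``master_seed``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import ChromSizes, GeneModel, Peak, Variant
from .ld import HaplotypePanel, compute_r2
from .targets import DERecord
from .tissue import IhcCore, PatientRecord, QpcrMeasurement

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_genome",
    "generate_peaks_and_variants",
    "generate_haplotype_panel",
    "generate_de_tables",
    "generate_tissue_cohort",
]


@dataclass
class SimConfig:
    # genome
    n_chromosomes: int = 2
    chrom_length_bp: int = 5_000_000
    n_genes: int = 200
    # peaks
    n_peaks: int = 300
    peak_length_median: float = 300.0
    peak_length_sigma: float = 0.5  # log-space sd
    min_peak_length: int = 50
    # variants
    n_index_snps: int = 20
    n_background_snps: int = 180
    planted_in_peak_fraction: float = 0.3
    # LD panel
    ld_block_size: int = 5
    ld_mutation_rate: float = 0.05
    n_haplotypes: int = 100
    # differential expression
    n_planted_primary: int = 120
    n_opposite_decoys: int = 20
    n_single_timepoint_decoys: int = 20
    de_effect_size: float = 1.5  # |log2 FC| of regulated genes
    de_alpha: float = 0.05
    # tissue cohort
    n_patients: int = 100
    tissue_snp: str = "rs11891426"
    major_allele: str = "T"
    minor_allele: str = "G"
    maf: float = 0.13
    genotype_effect_beta: float = -1.0  # in units of noise SD
    noise_sd: float = 1.0
    e_target: float = 1.9
    e_ref: float = 1.85
    calibrator_ct_target: float = 25.0
    calibrator_ct_ref: float = 24.0
    ct_noise_sd: float = 0.05
    # seed
    master_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "chrom_length_bp", "n_genes", "n_peaks",
                     "n_haplotypes", "n_patients"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("planted_in_peak_fraction", "ld_mutation_rate", "maf"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def n_variants(self) -> int:
        return self.n_index_snps + self.n_background_snps


@dataclass
class GroundTruth:
    """What was planted, so pipeline output can be checked exactly."""

    planted_in_peak_ids: List[str] = field(default_factory=list)
    ld_pairs: List[Tuple[str, str, float]] = field(default_factory=list)
    planted_primary_genes: List[str] = field(default_factory=list)
    genotype_effects: Dict[str, float] = field(default_factory=dict)
    carrier_patients: List[str] = field(default_factory=list)
    true_expression: Dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


_STREAMS = {"genome": 1, "peaks": 2, "panel": 3, "de": 4, "tissue": 5}


def _rng(cfg: SimConfig, stream: str) -> np.random.Generator:
    # named per-stage streams so regenerating one stage never shifts another
    entropy = np.random.SeedSequence(
        entropy=cfg.master_seed, spawn_key=(_STREAMS[stream],)
    )
    return np.random.default_rng(entropy)


# ---------------------------------------------------------------------------
# Genome and genes
# ---------------------------------------------------------------------------

def generate_genome(cfg: SimConfig) -> Tuple[ChromSizes, List[GeneModel]]:
    """A genome of equal-length chromosomes with log-normal gene lengths."""
    rng = _rng(cfg, "genome")
    sizes = ChromSizes(
        {f"chr{i + 1}": cfg.chrom_length_bp for i in range(cfg.n_chromosomes)}
    )
    chrom_names = list(sizes)
    genes: List[GeneModel] = []
    strands = rng.random(cfg.n_genes) < 0.5
    if cfg.n_genes >= 2 and strands.all() or (~strands).all() and cfg.n_genes >= 2:
        strands[0] = not strands[0]  # guarantee both strands appear
    for i in range(cfg.n_genes):
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        length = int(np.clip(rng.lognormal(np.log(20_000), 0.6), 1_000,
                             sizes[chrom] // 10))
        if length >= sizes[chrom]:
            raise ValueError("gene longer than chromosome; reduce gene length")
        start = int(rng.integers(0, sizes[chrom] - length))
        genes.append(
            GeneModel(
                id=f"gene_{i + 1}",
                chrom=chrom,
                strand="+" if strands[i] else "-",
                start=start,
                end=start + length,
            )
        )
    return sizes, genes


# ---------------------------------------------------------------------------
# Peaks and variants
# ---------------------------------------------------------------------------

def generate_peaks_and_variants(
    cfg: SimConfig,
    sizes: ChromSizes,
    placement: str = "planted",
) -> Tuple[List[Peak], List[Variant], GroundTruth]:
    """Peaks plus variants with a planted in-peak fraction.

    ``placement='planted'``: exactly round(f · n_variants) variants are
    placed uniformly inside randomly chosen peaks, the rest uniformly in
    non-peak space.  ``placement='uniform'``: every variant is placed
    uniformly over the genome regardless of peaks (the no-planting null for
    calibration studies; f is ignored).
    """
    if placement not in ("planted", "uniform"):
        raise ValueError("placement must be 'planted' or 'uniform'")
    rng = _rng(cfg, "peaks")
    chrom_names = list(sizes)
    chrom_lens = np.array([sizes[c] for c in chrom_names], dtype=np.int64)
    genome_bp = int(chrom_lens.sum())

    # peaks: position uniform by bp across the genome, length log-normal
    lengths = np.maximum(
        cfg.min_peak_length,
        rng.lognormal(np.log(cfg.peak_length_median), cfg.peak_length_sigma,
                      cfg.n_peaks).astype(np.int64),
    )
    if int(lengths.sum()) >= genome_bp:
        raise ValueError("total peak bp must be smaller than the genome")
    probs = chrom_lens / genome_bp
    peaks: List[Peak] = []
    for j in range(cfg.n_peaks):
        ci = int(rng.choice(len(chrom_names), p=probs))
        chrom = chrom_names[ci]
        L = int(min(lengths[j], sizes[chrom]))
        start = int(rng.integers(0, sizes[chrom] - L + 1))
        score = float(50.0 + rng.exponential(100.0))
        peaks.append(Peak(chrom, start, start + L, score=score, name=f"peak_{j + 1}"))

    by_chrom: Dict[str, List[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)

    def in_any_peak(chrom: str, pos0: int) -> bool:
        return any(p.start <= pos0 < p.end for p in by_chrom.get(chrom, ()))

    n_var = cfg.n_variants
    n_planted = 0
    if placement == "planted":
        n_planted = int(round(cfg.planted_in_peak_fraction * n_var))
        if n_planted > 0 and not peaks:
            raise ValueError("cannot plant variants in peaks: no peaks")

    used: set = set()
    positions: List[Tuple[str, int]] = []  # (chrom, 1-based pos)

    def place_unique(chrom: str, pos0: int) -> bool:
        key = (chrom, pos0)
        if key in used:
            return False
        used.add(key)
        positions.append((chrom, pos0 + 1))
        return True

    planted_idx = set(rng.choice(n_var, size=n_planted, replace=False).tolist())
    for i in range(n_var):
        for _ in range(10_000):
            if i in planted_idx:
                p = peaks[int(rng.integers(0, len(peaks)))]
                pos0 = int(rng.integers(p.start, p.end))
                ok = True
            else:
                ci = int(rng.choice(len(chrom_names), p=probs))
                chrom_i = chrom_names[ci]
                pos0 = int(rng.integers(0, sizes[chrom_i]))
                ok = placement == "uniform" or not in_any_peak(chrom_i, pos0)
                p = None
            if ok and place_unique(p.chrom if p else chrom_i, pos0):
                break
        else:
            raise RuntimeError("could not place a unique variant position")

    variants: List[Variant] = []
    truth = GroundTruth()
    index_idx = set(rng.choice(n_var, size=cfg.n_index_snps, replace=False).tolist())
    for i, (chrom, pos) in enumerate(positions):
        role = "index" if i in index_idx else "plain"
        vid = f"rs{i + 1:06d}"
        variants.append(Variant(vid, chrom, pos, role=role))
        if i in planted_idx:
            truth.planted_in_peak_ids.append(vid)
    return peaks, variants, truth


# ---------------------------------------------------------------------------
# Haplotype panel
# ---------------------------------------------------------------------------

def generate_haplotype_panel(
    cfg: SimConfig, variants: Sequence[Variant]
) -> Tuple[HaplotypePanel, GroundTruth]:
    """Block-copy LD structure: within each block of consecutive variants,
    each column is the previous column with independent per-haplotype flips
    at ``ld_mutation_rate`` — r² decays with the number of copy steps; across
    blocks columns are independent.  Realized within-block r² values are
    recorded in the ground truth.
    """
    if cfg.n_haplotypes < 20:
        raise ValueError("need at least 20 haplotypes")
    rng = _rng(cfg, "panel")
    order = sorted(range(len(variants)), key=lambda i: (variants[i].chrom, variants[i].pos))
    n_hap = cfg.n_haplotypes
    matrix = np.zeros((n_hap, len(variants)), dtype=np.int8)

    def draw_polymorphic(col: Optional[np.ndarray]) -> np.ndarray:
        for _ in range(100):
            if col is None:
                maf = rng.uniform(0.1, 0.5)
                cand = (rng.random(n_hap) < maf).astype(np.int8)
            else:
                flips = rng.random(n_hap) < cfg.ld_mutation_rate
                cand = np.where(flips, 1 - col, col).astype(np.int8)
            if 0 < cand.sum() < n_hap:
                return cand
        raise RuntimeError("could not generate a polymorphic haplotype column")

    truth = GroundTruth()
    block: List[int] = []
    prev_col: Optional[np.ndarray] = None
    prev_chrom: Optional[str] = None
    blocks: List[List[int]] = []
    for k, i in enumerate(order):
        v = variants[i]
        new_block = (
            prev_chrom != v.chrom or len(block) >= cfg.ld_block_size
        )
        if new_block:
            if block:
                blocks.append(block)
            block = []
            prev_col = None
        col = draw_polymorphic(prev_col)
        matrix[:, i] = col
        prev_col = col
        prev_chrom = v.chrom
        block.append(i)
    if block:
        blocks.append(block)

    for blk in blocks:
        for a_i in range(len(blk)):
            for b_i in range(a_i + 1, len(blk)):
                ia, ib = blk[a_i], blk[b_i]
                r2 = compute_r2(matrix[:, ia], matrix[:, ib])
                truth.ld_pairs.append((variants[ia].id, variants[ib].id, r2))

    return HaplotypePanel(list(variants), matrix), truth


# ---------------------------------------------------------------------------
# Differential expression tables
# ---------------------------------------------------------------------------

def generate_de_tables(
    cfg: SimConfig,
    genes: Sequence[GeneModel],
    gene_peak_map: Dict[str, List[str]],
) -> Tuple[List[DERecord], List[DERecord], GroundTruth]:
    """Two-timepoint DE tables with planted primary targets and decoys.

    Planted primaries (same-direction significant at both timepoints, drawn
    from genes bearing a peak) must be recovered exactly by the target
    caller; decoys exercise its exclusion clauses: opposite-direction genes,
    single-timepoint genes, and same-direction genes without peaks are never
    primary.
    """
    rng = _rng(cfg, "de")
    gene_ids = [g.id for g in genes]
    with_peaks = [g for g in gene_ids if gene_peak_map.get(g)]
    without_peaks = [g for g in gene_ids if not gene_peak_map.get(g)]
    if cfg.n_planted_primary > len(with_peaks):
        raise ValueError(
            f"cannot plant {cfg.n_planted_primary} primaries: only "
            f"{len(with_peaks)} genes have peaks"
        )
    planted = sorted(
        rng.choice(with_peaks, size=cfg.n_planted_primary, replace=False).tolist()
    )
    remaining = [g for g in gene_ids if g not in set(planted)]
    rng.shuffle(remaining)
    n_opp = min(cfg.n_opposite_decoys, len(remaining))
    opposite = remaining[:n_opp]
    n_single = min(cfg.n_single_timepoint_decoys, len(remaining) - n_opp)
    single_tp = remaining[n_opp:n_opp + n_single]
    nulls = remaining[n_opp + n_single:]

    def sig_p() -> float:
        return float(rng.uniform(1e-6, cfg.de_alpha * 0.8))

    def null_p() -> float:
        return float(rng.uniform(cfg.de_alpha * 2, 1.0))

    def lfc(sign: int) -> float:
        return float(sign * abs(rng.normal(cfg.de_effect_size, 0.3)))

    de_t1: List[DERecord] = []
    de_t2: List[DERecord] = []
    for g in planted:
        s = 1 if rng.random() < 0.5 else -1
        de_t1.append(DERecord(g, "t1", lfc(s), sig_p()))
        de_t2.append(DERecord(g, "t2", lfc(s), sig_p()))
    for g in opposite:
        s = 1 if rng.random() < 0.5 else -1
        de_t1.append(DERecord(g, "t1", lfc(s), sig_p()))
        de_t2.append(DERecord(g, "t2", lfc(-s), sig_p()))
    for g in single_tp:
        s = 1 if rng.random() < 0.5 else -1
        de_t1.append(DERecord(g, "t1", lfc(s), sig_p()))
        de_t2.append(DERecord(g, "t2", lfc(s), null_p()))
    for g in nulls:
        s = 1 if rng.random() < 0.5 else -1
        de_t1.append(DERecord(g, "t1", float(rng.normal(0, 0.2)), null_p()))
        de_t2.append(DERecord(g, "t2", float(rng.normal(0, 0.2)), null_p()))

    truth = GroundTruth(planted_primary_genes=planted)
    return de_t1, de_t2, truth


# ---------------------------------------------------------------------------
# Tissue cohort
# ---------------------------------------------------------------------------

def generate_tissue_cohort(
    cfg: SimConfig,
) -> Tuple[List[QpcrMeasurement], List[IhcCore], List[PatientRecord], GroundTruth]:
    """A genotyped cohort with a planted carrier effect on expression and IHC.

    Genotypes are drawn from Hardy–Weinberg proportions at ``cfg.maf``; a
    patient's latent expression (log2 scale) is baseline + β·carrier +
    N(0, noise_sd).  qPCR Ct values are back-computed so that the Pfaffl
    ratio recovers 2^latent (up to Ct measurement noise); IHC core scores
    carry the same planted effect on the intensity component.
    """
    if cfg.n_patients < 4:
        raise ValueError("need at least 4 patients")
    rng = _rng(cfg, "tissue")
    q = cfg.maf
    p_hw = np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2])  # TT, TG, GG
    genos = [
        f"{cfg.major_allele}/{cfg.major_allele}",
        f"{cfg.major_allele}/{cfg.minor_allele}",
        f"{cfg.minor_allele}/{cfg.minor_allele}",
    ]

    measurements: List[QpcrMeasurement] = []
    cores: List[IhcCore] = []
    patients: List[PatientRecord] = []
    truth = GroundTruth(genotype_effects={cfg.tissue_snp: cfg.genotype_effect_beta})

    log_e_t, log_e_r = np.log(cfg.e_target), np.log(cfg.e_ref)
    for i in range(cfg.n_patients):
        pid = f"pt_{i + 1:03d}"
        gi = int(rng.choice(3, p=p_hw))
        genotype = genos[gi]
        carrier = gi > 0
        if carrier:
            truth.carrier_patients.append(pid)
        latent = (
            cfg.genotype_effect_beta * cfg.noise_sd * carrier
            + rng.normal(0, cfg.noise_sd)
        )
        truth.true_expression[pid] = float(latent)

        # qPCR: pick Ct values whose Pfaffl ratio equals 2^latent
        ratio = 2.0 ** latent
        dct_ref = float(rng.normal(0, 0.5))
        dct_t = (np.log(ratio) + dct_ref * log_e_r) / log_e_t
        ct_t = cfg.calibrator_ct_target - dct_t + rng.normal(0, cfg.ct_noise_sd)
        ct_r = cfg.calibrator_ct_ref - dct_ref + rng.normal(0, cfg.ct_noise_sd)
        measurements.append(QpcrMeasurement(pid, "target", float(ct_t), cfg.e_target))
        measurements.append(QpcrMeasurement(pid, "reference", float(ct_r), cfg.e_ref))

        # IHC: three cores per tissue; carrier effect planted on intensity
        for tissue, base_int in (("benign", 10.0), ("cancer", 12.0)):
            for core in range(1, 4):
                intensity = max(
                    0.0,
                    base_int
                    + 2.0 * cfg.genotype_effect_beta * carrier
                    + rng.normal(0, 2.0 * cfg.noise_sd),
                )
                pct = float(np.clip(rng.normal(50, 15), 0, 100))
                cores.append(IhcCore(pid, tissue, core, float(intensity), pct))

        patients.append(
            PatientRecord(
                patient_id=pid,
                genotypes={cfg.tissue_snp: genotype},
                covariates={"age": int(rng.integers(45, 80))},
            )
        )
    return measurements, cores, patients, truth
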