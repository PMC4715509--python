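"""Tissue-level quantification and genotype-stratified statistics.

Implements the efficiency-corrected relative qPCR expression ratio (Pfaffl),
the immunohistochemistry immunoreactivity score (mean staining intensity ×
percent positive cells, averaged over a patient's tissue cores), and the
group comparisons used on top of them: Welch-corrected unpaired t-test,
Pearson correlation, and the chi-square test on genotype contingency tables.
Genotype stratification defaults to the dominant (carrier) model: minor-
allele carriers (het + hom) versus major-allele homozygotes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QpcrMeasurement",
    "IhcCore",
    "PatientRecord",
    "pfaffl_ratio",
    "efficiency_from_slope",
    "ihc_patient_score",
    "welch_compare",
    "pearson_corr",
    "genotype_table_test",
    "stratified_expression_report",
    "relative_expression_table",
]


@dataclass(frozen=True)
class QpcrMeasurement:
    sample_id: str
    gene: str  # "target" | "reference"
    ct: float
    efficiency: float  # amplification factor per cycle

    def __post_init__(self) -> None:
        if self.gene not in ("target", "reference"):
            raise ValueError(f"gene must be 'target' or 'reference', got {self.gene!r}")
        if self.ct <= 0:
            raise ValueError("Ct must be > 0")
        if not (1 < self.efficiency <= 2.05):
            raise ValueError(
                f"amplification efficiency must be in (1, 2], got {self.efficiency}"
            )


@dataclass(frozen=True)
class IhcCore:
    patient_id: str
    tissue: str  # "benign" | "cancer"
    core_index: int
    mean_intensity: float
    pct_positive: float

    def __post_init__(self) -> None:
        if self.tissue not in ("benign", "cancer"):
            raise ValueError(f"tissue must be 'benign' or 'cancer', got {self.tissue!r}")
        if not (1 <= self.core_index <= 3):
            raise ValueError("core_index must be 1..3")
        if self.mean_intensity < 0:
            raise ValueError("mean_intensity must be >= 0")
        if not (0 <= self.pct_positive <= 100):
            raise ValueError("pct_positive must be in [0, 100]")

    @property
    def score(self) -> float:
        return self.mean_intensity * self.pct_positive


@dataclass
class PatientRecord:
    patient_id: str
    genotypes: Dict[str, str]  # rsID -> e.g. "T/T", "T/G"
    covariates: Dict[str, object] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Quantification formulas
# ---------------------------------------------------------------------------

def pfaffl_ratio(e_target: float, dct_target: float,
                 e_ref: float, dct_ref: float) -> float:
    """Efficiency-corrected relative expression R.

    R = E_target^ΔCt_target / E_ref^ΔCt_ref where ΔCt = Ct(calibrator) −
    Ct(sample) for each assay.  With both efficiencies equal to 2 this
    reduces to the classic 2^−ΔΔCt.
    """
    if e_target <= 1 or e_ref <= 1:
        raise ValueError("amplification efficiencies must be > 1")
    return float(e_target ** dct_target / e_ref ** dct_ref)


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency from a standard-curve slope: E = 10^(−1/slope).

    A perfect assay has slope −1/log10(2) ≈ −3.32, giving E = 2.
    """
    if slope >= 0:
        raise ValueError("standard-curve slope must be negative")
    return float(10 ** (-1.0 / slope))


def ihc_patient_score(cores: Sequence[IhcCore]) -> float:
    """Patient immunoreactivity score: mean over cores of intensity × % positive."""
    if not (1 <= len(cores) <= 3):
        raise ValueError("expect 1..3 tissue cores per patient and tissue")
    if len({c.patient_id for c in cores}) != 1:
        raise ValueError("cores from multiple patients in one call")
    if len({c.tissue for c in cores}) != 1:
        raise ValueError("mixed tissue types in one call")
    return float(np.mean([c.score for c in cores]))


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

def welch_compare(group_a: Sequence[float], group_b: Sequence[float]) -> Tuple[float, float, float]:
    """Welch-corrected unpaired t-test: (t, Welch–Satterthwaite df, two-sided p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.allclose(a.mean(), b.mean()):
            return 0.0, float(len(a) + len(b) - 2), 1.0
        warnings.warn("both groups have zero variance; df degenerate")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def pearson_corr(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Pearson correlation with two-sided p from the t-transform (n−2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("x and y must have equal length >= 3")
    if x.var() == 0 or y.var() == 0:
        raise ValueError("zero-variance input: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def genotype_table_test(counts) -> Tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) on a contingency table."""
    table = np.asarray(counts)
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        table = np.asarray(counts, dtype=float)
        if np.any(table < 0) or np.any(table != np.round(table)):
            raise ValueError("contingency table must hold non-negative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


# ---------------------------------------------------------------------------
# Genotype-stratified reporting
# ---------------------------------------------------------------------------

def _is_carrier(genotype: str, minor_allele: str) -> bool:
    alleles = genotype.replace("|", "/").split("/")
    if len(alleles) != 2:
        raise ValueError(f"cannot parse genotype {genotype!r}")
    return minor_allele in alleles


def stratified_expression_report(
    scores: pd.DataFrame,
    patients: Sequence[PatientRecord],
    snp: str,
    minor_allele: str,
    strata: Sequence[str] = ("all", "benign", "cancer"),
) -> List[Dict]:
    """Carrier-vs-noncarrier comparison of expression scores per tissue stratum.

    ``scores`` is a long table with columns patient_id, tissue, score.
    Grouping follows the dominant model: patients with >= 1 copy of the
    minor allele versus major-allele homozygotes.  A stratum where either
    group has < 2 patients is skipped with a warning entry.
    """
    required = {"patient_id", "tissue", "score"}
    if not required.issubset(scores.columns):
        raise ValueError(f"scores table needs columns {sorted(required)}")
    geno = {p.patient_id: p.genotypes.get(snp) for p in patients}

    rows: List[Dict] = []
    for stratum in strata:
        sub = scores if stratum == "all" else scores[scores["tissue"] == stratum]
        carrier, noncarrier = [], []
        genotype_groups: Dict[str, List[float]] = {}
        for row in sub.itertuples(index=False):
            g = geno.get(row.patient_id)
            if g is None:
                continue
            genotype_groups.setdefault(g, []).append(row.score)
            (carrier if _is_carrier(g, minor_allele) else noncarrier).append(row.score)
        entry: Dict = {
            "stratum": stratum,
            "snp": snp,
            "n_carrier": len(carrier),
            "n_noncarrier": len(noncarrier),
            "per_genotype_n": {g: len(v) for g, v in sorted(genotype_groups.items())},
            "per_genotype_mean": {
                g: float(np.mean(v)) for g, v in sorted(genotype_groups.items())
            },
        }
        if len(carrier) < 2 or len(noncarrier) < 2:
            warnings.warn(
                f"stratum {stratum!r}: a genotype group has < 2 patients; "
                "comparison skipped"
            )
            entry["skipped"] = True
        else:
            t, df, p = welch_compare(carrier, noncarrier)
            entry.update(
                {
                    "skipped": False,
                    "mean_carrier": float(np.mean(carrier)),
                    "mean_noncarrier": float(np.mean(noncarrier)),
                    "t": t,
                    "df": df,
                    "p": p,
                }
            )
        rows.append(entry)
    return rows


def relative_expression_table(
    measurements: Sequence[QpcrMeasurement],
    calibrator_ct_target: float,
    calibrator_ct_ref: float,
) -> pd.DataFrame:
    """Per-sample Pfaffl relative expression from target/reference Ct pairs."""
    by_sample: Dict[str, Dict[str, QpcrMeasurement]] = {}
    for m in measurements:
        slot = by_sample.setdefault(m.sample_id, {})
        if m.gene in slot:
            raise ValueError(f"duplicate {m.gene} measurement for {m.sample_id}")
        slot[m.gene] = m
    rows = []
    for sample_id, slot in by_sample.items():
        if set(slot) != {"target", "reference"}:
            raise ValueError(f"sample {sample_id} lacks a target/reference pair")
        t, r = slot["target"], slot["reference"]
        ratio = pfaffl_ratio(
            t.efficiency,
            calibrator_ct_target - t.ct,
            r.efficiency,
            calibrator_ct_ref - r.ct,
        )
        rows.append({"patient_id": sample_id, "ratio": ratio})
    return pd.DataFrame(rows)
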