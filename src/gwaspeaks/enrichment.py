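"""Variant-in-peak enrichment against a chromosome/size-matched random-peak null.

The null preserves each observed peak's chromosome and length exactly and
redraws only its start, uniformly over the valid placements on that
chromosome.  The empirical p-value is the fraction of null sets whose
distinct-variant overlap count reaches the observed count, and the binomial
uncertainty of that fraction is summarised by a Wilson score interval.

Reproducibility: one master seed; the i-th null set uses the RNG stream
``numpy.random.SeedSequence(entropy=seed, spawn_key=(i,))``, so sets can be
regenerated (or parallelised) independently of each other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import norm

from .core import ChromSizes, Peak, Variant, count_overlaps, positions_in_intervals

__all__ = ["EnrichmentResult", "wilson_interval", "simulate_matched_peaks",
           "enrichment_test"]


def wilson_interval(x: int, n: int, conf_level: float = 0.95) -> Tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion x/n.

    Well-behaved at x = 0 (lower bound exactly 0, upper bound z²/(n+z²)),
    which is the regime of a permutation test where no null set reaches the
    observed statistic.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= x <= n):
        raise ValueError(f"x must be in [0, n], got x={x}, n={n}")
    if not (0 < conf_level < 1):
        raise ValueError("conf_level must be in (0, 1)")
    z = norm.ppf(1 - (1 - conf_level) / 2)
    phat = x / n
    denom = 1 + z * z / n
    center = (phat + z * z / (2 * n)) / denom
    half = z * math.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n)) / denom
    low = 0.0 if x == 0 else max(0.0, center - half)
    high = 1.0 if x == n else min(1.0, center + half)
    return low, high


@dataclass
class EnrichmentResult:
    """Outcome of the matched-peak permutation enrichment test."""

    observed: int
    null_counts: np.ndarray
    exceedances: int
    p_empirical: float
    p_add_one: float  # (exceedances + 1) / (n_sets + 1), never exactly 0
    wilson_low: float
    wilson_high: float
    n_sets: int
    conf_level: float
    seed: int

    def to_dict(self, include_null_counts: bool = False) -> Dict:
        d = {
            "observed": self.observed,
            "exceedances": self.exceedances,
            "p_empirical": self.p_empirical,
            "p_add_one": self.p_add_one,
            "wilson_low": self.wilson_low,
            "wilson_high": self.wilson_high,
            "n_sets": self.n_sets,
            "conf_level": self.conf_level,
            "seed": self.seed,
        }
        if include_null_counts:
            d["null_counts"] = self.null_counts.tolist()
        return d


def _placement_arrays(
    peaks: Sequence[Peak], sizes: ChromSizes
) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    """Per-peak length and max-start arrays, in input order."""
    lengths = np.array([p.length for p in peaks], dtype=np.int64)
    chroms = [p.chrom for p in peaks]
    highs = np.empty(len(peaks), dtype=np.int64)
    for j, p in enumerate(peaks):
        if p.chrom not in sizes:
            raise ValueError(f"peak chromosome {p.chrom!r} not in chrom sizes")
        room = sizes[p.chrom] - p.length
        if room < 0:
            raise ValueError(
                f"peak of length {p.length} does not fit on {p.chrom} "
                f"(length {sizes[p.chrom]})"
            )
        highs[j] = room + 1  # exclusive upper bound for integers()
    return lengths, highs, chroms


def _draw_starts(
    rng: np.random.Generator,
    highs: np.ndarray,
    lengths: np.ndarray,
    exclude_by_chrom: Optional[Dict[str, Tuple[np.ndarray, np.ndarray]]],
    chroms: List[str],
    max_retries: int = 1000,
) -> np.ndarray:
    """One start per peak, uniform on {0, …, chrom_len − length}.

    When an exclusion set is given, placements overlapping it are redrawn
    (bounded retries), so the null avoids e.g. assembly gaps or blacklists.
    """
    starts = rng.integers(0, highs)
    if not exclude_by_chrom:
        return starts
    for _ in range(max_retries):
        bad = np.zeros(len(starts), dtype=bool)
        for j, chrom in enumerate(chroms):
            iv = exclude_by_chrom.get(chrom)
            if iv is None:
                continue
            ex_s, ex_e = iv
            # overlap of [start, start+len) with any excluded interval
            hit = (starts[j] < ex_e) & (starts[j] + lengths[j] > ex_s)
            bad[j] = bool(hit.any())
        if not bad.any():
            return starts
        starts = starts.copy()
        starts[bad] = rng.integers(0, highs[bad])
    raise RuntimeError("could not place simulated peaks outside exclusion set")


def _exclude_arrays(
    exclude: Optional[Sequence[Peak]],
) -> Optional[Dict[str, Tuple[np.ndarray, np.ndarray]]]:
    if not exclude:
        return None
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for p in exclude:
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    return {
        c: (
            np.array([s for s, _ in iv], dtype=np.int64),
            np.array([e for _, e in iv], dtype=np.int64),
        )
        for c, iv in by_chrom.items()
    }


def _set_rng(seed: int, set_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(set_index,)))


def simulate_matched_peaks(
    peaks: Sequence[Peak],
    sizes: ChromSizes,
    rng_seed: int,
    set_index: int = 0,
    exclude: Optional[Sequence[Peak]] = None,
) -> List[Peak]:
    """One random peak set matching the input's chromosomes and lengths.

    Each output peak keeps its source peak's chromosome and length; only the
    start is redrawn, uniformly over all placements that fit on the
    chromosome.  Deterministic given (rng_seed, set_index).
    """
    lengths, highs, chroms = _placement_arrays(peaks, sizes)
    rng = _set_rng(rng_seed, set_index)
    starts = _draw_starts(rng, highs, lengths, _exclude_arrays(exclude), chroms)
    return [
        Peak(chrom, int(s), int(s + L), name=f"sim_{j}")
        for j, (chrom, s, L) in enumerate(zip(chroms, starts, lengths))
    ]


def enrichment_test(
    variants: Sequence[Variant],
    peaks: Sequence[Peak],
    sizes: ChromSizes,
    n_sets: int = 10_000,
    conf_level: float = 0.95,
    rng_seed: int = 0,
    exceedance: str = "ge",
    exclude: Optional[Sequence[Peak]] = None,
) -> EnrichmentResult:
    """Permutation enrichment of a variant set in a peak set.

    ``observed`` is the number of distinct variants inside >=1 real peak;
    each null count is the same statistic on one chromosome/size-matched
    random peak set.  ``exceedance='ge'`` (default, conservative) counts null
    sets with count >= observed; ``'gt'`` uses strict >.  The Wilson interval
    is computed on (exceedances, n_sets) at ``conf_level``.
    """
    if not variants:
        raise ValueError("empty variant list")
    if not peaks:
        raise ValueError("empty peak list")
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    if exceedance not in ("ge", "gt"):
        raise ValueError("exceedance must be 'ge' or 'gt'")
    sizes.validate_variants(variants)

    observed, _ = count_overlaps(variants, peaks)

    lengths, highs, chroms = _placement_arrays(peaks, sizes)
    ex = _exclude_arrays(exclude)

    # variant 0-based positions grouped by chromosome, aligned with peak columns
    var_pos: Dict[str, np.ndarray] = {}
    for v in variants:
        var_pos.setdefault(v.chrom, [])
    for v in variants:
        var_pos[v.chrom].append(v.pos0)  # type: ignore[union-attr]
    var_pos = {c: np.array(p, dtype=np.int64) for c, p in var_pos.items()}
    chrom_arr = np.array(chroms)
    peak_cols = {c: np.flatnonzero(chrom_arr == c) for c in var_pos}

    null_counts = np.empty(n_sets, dtype=np.int64)
    for i in range(n_sets):
        rng = _set_rng(rng_seed, i)
        starts = _draw_starts(rng, highs, lengths, ex, chroms)
        total = 0
        for c, pos in var_pos.items():
            cols = peak_cols[c]
            if len(cols) == 0:
                continue
            s = starts[cols]
            total += int(
                positions_in_intervals(pos, s, s + lengths[cols]).sum()
            )
        null_counts[i] = total

    if exceedance == "ge":
        exceed = int((null_counts >= observed).sum())
    else:
        exceed = int((null_counts > observed).sum())
    p_emp = exceed / n_sets
    p_add_one = (exceed + 1) / (n_sets + 1)
    low, high = wilson_interval(exceed, n_sets, conf_level)
    return EnrichmentResult(
        observed=observed,
        null_counts=null_counts,
        exceedances=exceed,
        p_empirical=p_emp,
        p_add_one=p_add_one,
        wilson_low=low,
        wilson_high=high,
        n_sets=n_sets,
        conf_level=conf_level,
        seed=rng_seed,
    )
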