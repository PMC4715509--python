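"""Peak-to-gene assignment, BH adjustment, and primary target calling."""

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from gwaspeaks.core import GeneModel, Peak
from gwaspeaks.targets import (
    DERecord,
    assign_peaks_to_genes,
    bh_adjust,
    call_primary_targets,
    tss_distance_profile,
)


def brute_force_assign(peaks, genes, window_bp, ignore_strand=False):
    out = {}
    for gene in genes:
        tss = gene.start if ignore_strand else gene.tss
        for p in peaks:
            if p.chrom != gene.chrom:
                continue
            near = p.start < tss + window_bp and p.end > tss - window_bp
            body = p.start < gene.end and p.end > gene.start
            if near or body:
                out.setdefault(gene.id, []).append(p.name)
    return out


class TestAssignPeaksToGenes:
    def test_window_boundary_under_half_open_convention(self):
        gene = GeneModel("g", "chr1", "+", 50_100, 60_000)  # TSS 50,100
        assert assign_peaks_to_genes([Peak("chr1", 0, 100, name="p")], [gene]) == {}
        got = assign_peaks_to_genes([Peak("chr1", 0, 101, name="p")], [gene])
        assert got == {"g": ["p"]}

    def test_gene_body_clause_reaches_beyond_tss_window(self):
        gene = GeneModel("g", "chr1", "+", 0, 400_000)
        peak = Peak("chr1", 200_000, 200_500, name="p")  # 200 kb from TSS
        assert assign_peaks_to_genes([peak], [gene]) == {"g": ["p"]}

    def test_minus_strand_tss_is_right_end(self):
        gene = GeneModel("g", "chr1", "-", 100_000, 200_000)  # TSS 199,999
        peak = Peak("chr1", 230_000, 230_100, name="p")  # 30 kb right of TSS
        assert assign_peaks_to_genes([peak], [gene], window_bp=50_000) == {"g": ["p"]}
        assert assign_peaks_to_genes([peak], [gene], window_bp=10_000) == {}

    def test_window_zero_reduces_to_gene_body_overlap(self):
        gene = GeneModel("g", "chr1", "+", 1000, 2000)
        inside = Peak("chr1", 1500, 1600, name="in")
        outside = Peak("chr1", 2500, 2600, name="out")
        got = assign_peaks_to_genes([inside, outside], [gene], window_bp=0)
        assert got == {"g": ["in"]}

    def test_matches_brute_force_oracle_on_random_instances(self, rng):
        for _ in range(20):
            peaks = [
                Peak("chr1", int(s), int(s) + int(L), name=f"p{i}")
                for i, (s, L) in enumerate(
                    zip(rng.integers(0, 10**6, 500), rng.integers(50, 2000, 500))
                )
            ]
            genes = [
                GeneModel(f"g{i}", "chr1", "+" if rng.random() < 0.5 else "-",
                          int(s), int(s) + int(L))
                for i, (s, L) in enumerate(
                    zip(rng.integers(0, 10**6, 50), rng.integers(1000, 50_000, 50))
                )
            ]
            got = assign_peaks_to_genes(peaks, genes, window_bp=50_000)
            assert got == brute_force_assign(peaks, genes, 50_000)


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged_and_all_ones_stay_one(self):
        assert bh_adjust([0.37]) == pytest.approx([0.37])
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_matches_reference_on_random_vectors(self, rng):
        p = rng.random(200)
        assert bh_adjust(p) == pytest.approx(
            multipletests(p, method="fdr_bh")[1], abs=1e-12
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestCallPrimaryTargets:
    def _records(self, rows, tp):
        return [DERecord(g, tp, fc, p) for g, fc, p in rows]

    def test_opposite_direction_gene_is_not_primary(self):
        de1 = self._records([("g1", 1.0, 0.01)], "t1")
        de2 = self._records([("g1", -1.0, 0.01)], "t2")
        s = call_primary_targets(de1, de2, {"g1": ["p"]})
        assert s.n_primary == 0 and s.n_same_direction == 0

    def test_same_direction_without_peak_is_not_primary(self):
        de1 = self._records([("g1", 1.0, 0.04)], "t1")
        de2 = self._records([("g1", 2.0, 0.05)], "t2")  # boundary p == alpha included
        s = call_primary_targets(de1, de2, {})
        assert s.n_same_direction == 1 and s.n_primary == 0

    def test_gene_at_one_timepoint_treated_as_unregulated(self):
        de1 = self._records([("g1", 1.0, 0.01), ("g2", 1.0, 0.01)], "t1")
        de2 = self._records([("g1", 1.0, 0.01)], "t2")
        s = call_primary_targets(de1, de2, {"g1": ["p"], "g2": ["p"]})
        assert s.primary == ["g1"]

    def test_row_order_invariance(self, rng):
        rows = [(f"g{i}", float(rng.normal()), float(rng.random()))
                for i in range(50)]
        gmap = {f"g{i}": ["p"] for i in range(0, 50, 2)}
        de1 = self._records(rows, "t1")
        de2 = self._records(rows, "t2")
        base = call_primary_targets(de1, de2, gmap)
        perm = list(rng.permutation(50))
        shuffled = call_primary_targets([de1[i] for i in perm],
                                        [de2[i] for i in perm], gmap)
        assert shuffled.primary == base.primary

    def test_raising_alpha_never_removes_a_primary(self, rng):
        rows1 = [(f"g{i}", 1.0, float(rng.random() * 0.2)) for i in range(40)]
        rows2 = [(f"g{i}", 0.5, float(rng.random() * 0.2)) for i in range(40)]
        gmap = {f"g{i}": ["p"] for i in range(40)}
        de1, de2 = self._records(rows1, "t1"), self._records(rows2, "t2")
        tight = set(call_primary_targets(de1, de2, gmap, alpha=0.05).primary)
        loose = set(call_primary_targets(de1, de2, gmap, alpha=0.10).primary)
        assert tight <= loose

    def test_recovers_planted_primaries_exactly(self, sim_cfg, genome, peaks_variants):
        import gwaspeaks as g
        _, genes = genome
        peaks, _, _ = peaks_variants
        gmap = assign_peaks_to_genes(peaks, genes)
        de1, de2, truth = g.generate_de_tables(sim_cfg, genes, gmap)
        s = call_primary_targets(de1, de2, gmap)
        assert s.primary == sorted(truth.planted_primary_genes)


class TestTssDistanceProfile:
    def test_peak_centred_on_tss_has_distance_zero(self):
        gene = GeneModel("g", "chr1", "+", 1000, 5000)
        peak = Peak("chr1", 950, 1050)  # midpoint 1000 = TSS
        _, _, distances = tss_distance_profile([peak], [gene], bins=[-10, 0, 10])
        assert distances == [0.0]

    def test_minus_strand_distance_flipped_towards_gene_body(self):
        gene = GeneModel("g", "chr1", "-", 0, 10_000)  # TSS 9,999
        peak = Peak("chr1", 8_949, 9_049)  # midpoint 8,999: 1 kb into the body
        _, _, distances = tss_distance_profile([peak], [gene], bins=[0, 2000])
        assert distances == [1000.0]

    def test_matches_brute_force_nearest_tss_scan(self, rng):
        genes = [
            GeneModel(f"g{i}", "chr1", "+" if rng.random() < 0.5 else "-",
                      int(s), int(s) + 10_000)
            for i, s in enumerate(rng.integers(0, 10**6, 30))
        ]
        peaks = [Peak("chr1", int(s), int(s) + 200)
                 for s in rng.integers(0, 10**6, 100)]
        bins = np.linspace(-1e6, 1e6, 41)
        counts, _, distances = tss_distance_profile(peaks, genes, bins)
        brute = []
        for p in peaks:
            best = min(genes, key=lambda g: (abs(p.midpoint - g.tss), g.id))
            d = p.midpoint - best.tss
            brute.append(-d if best.strand == "-" else d)
        assert distances == brute
        assert counts.sum() == len(peaks)
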