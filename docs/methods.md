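# Methods

## Coordinate conventions

Peaks and gene models are BED-style 0-based half-open intervals `[start,
end)`; variants are VCF-style 1-based points, converted to 0-based wherever
they are compared against intervals. A variant overlaps a peak iff
`start ≤ pos−1 < end` — anywhere in the peak region, not just the summit.
Chromosome names are matched by exact string equality; `normalize_chrom`
strips a `chr` prefix for callers mixing conventions. Overlapping peaks are
*not* merged before counting: the enrichment statistic counts distinct
variants, so merging cannot change it.

The peak-score filter keeps peaks with score **strictly greater than** the
threshold (default 50 on the −10·log10 P scale of common peak callers);
"more than" is read literally. Peaks without a score cannot be filtered
silently and raise.

## LD r² and proxy expansion

r² is computed from phased haplotypes by direct counting — no EM estimation
of haplotype frequencies, since the intended panels (e.g. 1000 Genomes
phased genotypes) and the synthetic panels are phased by construction. The
counting form is algebraically the squared Pearson correlation of the two
0/1 allele columns; the test suite verifies the identity to 1e-12.
Monomorphic and multi-allelic sites are rejected (r² undefined / out of
scope). Proxy expansion searches a 1 Mb window either side of each index SNP
(the conventional LD horizon; configurable) and **includes** ties at
r² = threshold. Each index SNP is emitted as its own proxy with r² = 1, so
the proxy set at any threshold always contains the index set.

## Matched-peak permutation enrichment

The null preserves each observed peak's chromosome and length exactly and
redraws its start uniformly on `{0, …, chrom_length − length}`. Simulated
peaks are placed independently and may overlap each other — no exclusion
rule is imposed, which keeps the null tractable; an optional exclusion BED
(blacklist/assembly gaps) triggers bounded rejection resampling. No
GC/mappability covariate matching is attempted: the null matches chromosome
and size only.

Exceedance uses `null count ≥ observed` (conservative standard; a `gt` flag
gives the strict alternative — the two coincide in the zero-exceedance
regime). Two estimators are reported: the plain `exceedances/n_sets` and the
add-one `(exceedances+1)/(n_sets+1)`, which is never exactly zero. The
Wilson score interval on `(exceedances, n_sets)` is the primary uncertainty
summary because it behaves well at zero successes, where the upper bound is
`z²/(n+z²)` — for n = 10,000 at 95%, 0.00038 to two significant figures.
The lower bound is clamped to exactly 0 at x = 0 (the closed form is
analytically 0 there; clamping removes floating-point residue).

RNG scheme: the i-th null set uses
`numpy.random.SeedSequence(entropy=seed, spawn_key=(i,))`, so any single set
can be regenerated independently and the loop could be parallelised without
changing results. The in-loop overlap counting is a vectorised
sorted-start/cummax-end membership test; a test asserts it equals the
peak-object path (`simulate_matched_peaks` + `count_overlaps`) set by set.

## Peak-to-gene assignment and primary targets

A gene receives a peak if the peak overlaps (≥1 bp) the half-open window
`[TSS − 50 kb, TSS + 50 kb)` or the gene body `[start, end)`. The window
anchors on the TSS only — the gene body is a separate clause, not a ±50 kb
dilation of the whole gene. The TSS is strand-aware (start on `+`, end−1 on
`-`); an `ignore_strand` flag reproduces the naive plain-start alternative
since either reading is defensible for annotation pipelines that ignore
strand. "Regulated" at a timepoint means BH-adjusted p ≤ α (default 0.05)
with no fold-change floor; "primary" requires same-direction regulation at
both timepoints (equal sign of log FC, zero excluded) and ≥1 assigned peak.
Genes present in only one timepoint's table are treated as unregulated at
the missing timepoint and logged, not rejected. BH adjustment delegates to
`statsmodels.stats.multitest.multipletests(method="fdr_bh")`.

Nearest-TSS distance profiles use the peak midpoint, negated for `-` strand
genes so positive always means downstream in the direction of transcription;
equidistant ties break to the lexicographically smaller gene id
(deterministic).

## Motif co-occurrence

The observed statistic is the fraction of A-instances with any B-instance
within `max_dist_bp` (default 100 bp), distance measured start-to-start
(simplest deterministic anchor; a `center` anchor is available). The
coincidence null re-draws every instance's (window, offset) uniformly —
window uniform among all binding-site windows, offset uniform among
placements where the motif fits — preserving instance counts per motif type
exactly. This uniform re-placement null is a design choice: it answers
"how often would the observed clustering arise if motif positions carried no
information beyond residing in binding-site windows?". Closed-form check:
for one A and one B over n equal-width windows on distinct chromosomes, the
co-occurrence probability is 1/n.

## Tissue statistics

- Pfaffl ratio `R = E_t^ΔCt_t / E_r^ΔCt_r`, with ΔCt = Ct(calibrator) −
  Ct(sample) per assay. With both efficiencies 2 this is identically
  2^−ΔΔCt (tested over a grid to 1e-12). Efficiencies are per-assay inputs
  from standard curves; a convenience converts a standard-curve slope,
  `E = 10^(−1/slope)`. The calibrator choice rescales all R by a constant,
  so carrier-vs-noncarrier comparisons are calibrator-invariant.
- IHC immunoreactivity: per-core score = mean staining intensity × percent
  positive cells; the patient score is the arithmetic mean over the
  available cores (up to 3) of one tissue type; mixing tissue types in one
  call is an error.
- Group comparisons delegate to scipy: Welch-corrected unpaired t
  (`ttest_ind(equal_var=False)`, Satterthwaite df), Pearson correlation with
  the t-transform p, Pearson chi-square without continuity correction.
  Genotype stratification defaults to the dominant carrier model (het + hom
  minor pooled against major homozygotes) because minor-allele homozygotes
  are rare at the MAFs of interest (~13%); per-genotype group sizes and
  means are reported alongside. Strata with a group of < 2 patients are
  skipped with a warning. No multiple-testing correction is applied across
  clinical stratifications (per-comparison reporting); a global BH pass can
  be applied by the caller via `bh_adjust`.

## Synthetic data: what it emulates and what it does not

Defaults describe the study conditions the pipeline targets: a 10 Mb genome
(2 × 5 Mb chromosomes), 300 peaks with log-normal lengths (median 300 bp,
σ_log = 0.5 — resembling ChIP-seq peak calls; ~1% genome coverage), 200
variants of which 20 are index SNPs and a fraction f = 0.3 is planted
uniformly *inside* randomly chosen peaks (the rest uniformly in non-peak
space), 100 haplotypes with LD blocks of 5 consecutive variants (each column
derived from its neighbour by independent 5% per-haplotype flips, giving r²
decaying with distance; across blocks independent), 200 genes with 120
planted primary targets plus opposite-direction and single-timepoint decoys,
and a 100-patient cohort with Hardy–Weinberg genotypes at MAF 0.13 and a
carrier effect of −1 noise-SD on log2 expression and on IHC intensity. Ct
values are back-computed through the Pfaffl relation (efficiencies 1.9/1.85)
with Gaussian noise in cycle space, the natural measurement scale.

A `placement="uniform"` mode drops the planting constraint entirely and
scatters variants uniformly over the genome; this is the correct null for
calibration studies (forcing variants into non-peak space at f = 0 makes the
observed count identically zero and the test degenerate, which is a
different regime from "no enrichment").

Variant positions are unique by rejection sampling. Every generator is
deterministic given `master_seed`, with fixed per-stage sub-streams so
regenerating one stage never shifts another.

What passing tests on these data do **not** show: real ChIP-seq peaks have
GC/mappability biases and cluster near promoters; real LD comes from
recombination and demography, not block-copying; real expression has batch
and covariate structure. The generators exercise the *logic and calibration*
of the statistics, not the biases of real data — conclusions about a real
dataset still require the usual covariate-aware nulls where those biases
matter.

## Problem sizes and numerical choices

The statistical suites run at: 200 replicates × 500 null sets for null
calibration of the enrichment test (rejection rate at p ≤ 0.05 checked
against the exact binomial 99% band [0.013, 0.105] for 200 trials at 0.05);
50 replicates × 1,000 null sets for power on planted signal (p ≤ 0.01
required in ≥ 95%); 1,000 random column pairs for the r² oracle at 1e-12;
20 seeds for exact planted-target recovery; 100 + 200 simulated cohorts for
genotype-effect power and calibration. These sizes give stable verdicts for
the suites while keeping a full run interactive.

Known limitations: the enrichment null ignores mappability and peak
clustering (by design, see above); r² is defined for phased biallelic sites
only; the motif null is the package's own construction and other nulls
(e.g. dinucleotide-shuffled sequence scanning) would give different expected
coincidence rates; no survival modelling is attempted for cohort covariates.
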