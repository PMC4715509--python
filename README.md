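# gwaspeaks

Regulatory interpretation of GWAS risk loci against transcription-factor
ChIP-seq binding sites, packaged as a tested, reusable pipeline.

Genome-wide association studies report index SNPs, but the causal variant at
a locus is usually one of many linked variants, and its mechanism is often
regulatory: it sits inside a transcription-factor binding site and perturbs
binding. `gwaspeaks` implements the desk-side statistics of that workflow for
any TF ChIP-seq experiment (the motivating use case is androgen-receptor
binding sites, ARBSs, in prostate cancer):

- **LD proxy expansion** — pairwise r² computed by direct haplotype counting
  from any phased panel, r² = D²/(p_A(1−p_A) p_B(1−p_B)) with
  D = p_AB − p_A·p_B, and expansion of index SNPs to all proxies with
  r² ≥ threshold (default 0.5) within a window.
- **SNP-in-peak enrichment** — the observed count of distinct variants inside
  peaks is compared with a null of random peak sets that match the real peaks'
  chromosomes and lengths exactly, redrawing only their starts uniformly.
  The empirical p is the fraction of null sets whose count reaches the
  observed one, with a Wilson score interval on that fraction (well-behaved
  at 0 exceedances: upper bound z²/(n+z²)).
- **Peak-to-gene assignment and primary-target calling** — a gene is a
  potential target if a peak lies within 50 kb of its TSS or inside the gene
  body; a *primary* target is additionally regulated in the same direction at
  both post-stimulation timepoints (BH-adjusted p ≤ 0.05 at each).
- **Motif co-occurrence** — the fraction of motif-A instances within 100 bp
  of a motif-B instance, against a null that re-places instances uniformly
  over the binding-site windows.
- **Tissue statistics** — the Pfaffl efficiency-corrected qPCR ratio
  R = E_target^ΔCt_target / E_ref^ΔCt_ref (ΔCt = calibrator − sample), the
  IHC immunoreactivity score (mean intensity × % positive cells, averaged
  over a patient's cores), and genotype-stratified comparisons (dominant
  carrier model, Welch t-test, Pearson correlation, chi-square tables).
- **Synthetic data** — generators for every input format with planted,
  recorded ground truth (in-peak variants, LD blocks, primary target genes,
  genotype effects), so the whole pipeline is testable without downloads.

## Worked example

```python
import gwaspeaks as g

cfg = g.SimConfig(master_seed=7)          # 10 Mb genome, ~1% peak coverage,
sizes, genes = g.generate_genome(cfg)     # 200 variants, 30% planted in peaks
peaks, variants, truth = g.generate_peaks_and_variants(cfg, sizes)

res = g.enrichment_test(variants, peaks, sizes, n_sets=10_000, rng_seed=7)
print(res.observed, res.exceedances, res.p_empirical,
      res.wilson_low, round(res.wilson_high, 5))

gmap = g.assign_peaks_to_genes(peaks, genes)
de1, de2, tde = g.generate_de_tables(cfg, genes, gmap)
print(g.call_primary_targets(de1, de2, gmap).n_primary)
```

Output:

```
observed SNPs in peaks: 60 (planted: 60)
null mean: 2.02  max: 10
exceedances: 0 / 10000
p_empirical: 0.0   add-one: 1.00e-04
Wilson 95% CI: (0, 0.00038)
primary targets called: 120 (planted: 120, exact match: True)
```

All 60 variants planted inside peaks are found; no random
chromosome/size-matched peak set among 10,000 reaches the observed count, so
the empirical p is 0 with Wilson 95% interval (0, 0.00038) — strong evidence
the variant set is enriched in binding sites. The target caller recovers the
120 planted same-direction, peak-bearing genes exactly.

The same stages are available from the shell:

```bash
gwaspeaks simulate --seed 7 --out run/in
gwaspeaks all --run-dir run/in --seed 7 --out run/out
gwaspeaks enrich --peaks peaks.bed --variants snps.tsv \
    --chrom-sizes sizes.tsv --n-sets 10000 --seed 7 --out result.json
```

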