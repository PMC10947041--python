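# mbsvkit

Common variants that fall inside miRNA recognition elements (MREs) in
3′UTRs can strengthen or weaken miRNA binding and thereby perturb
post-transcriptional regulation. `mbsvkit` is a Python toolkit for
identifying such **miRNA binding site variants (MBSVs)** from per-allele,
multi-algorithm target-prediction tables and for testing whether, as a
class, they carry more GWAS association signal than matched background
variants. It is aimed at statistical geneticists working with GWAS summary
statistics and regulatory annotations.

## What it computes

**Calling.** A per-allele prediction record carries a primary context-style
score *s* ≤ 0 (more negative = stronger predicted repression) plus support
flags from secondary algorithms. Records survive only with primary support
plus at least one secondary algorithm agreeing on the same
(allele, miRNA, gene). For each variant–gene pair the difference score is

Δ = min over alt-allele sites of *s* − min over ref-allele sites of *s*,

with a missing allele contributing 0 (no predicted site, no repression);
across genes the Δ of largest magnitude is representative. Positive Δ =
predicted loss of binding affinity for the alternate allele, negative Δ =
gain. An MBSV is a biallelic autosomal SNV with |Δ| ≥ 0.2, affecting a
tissue-expressed gene and miRNA (≥ 1 RPKM, resp. a CPM floor equal to 10
reads in the smallest library, in ≥ 75 % of samples), outside the MHC
(chr6:28,477,797–33,448,354, hg19).

**Testing.** MBSVs and the non-MBSV 3′UTR background are LD-pruned
(window 50 / step 5 variants, r² ≤ 0.1, MAF ≥ 0.01, MBSVs prioritized), then
compared by two-sample K–S tests and quantile regression
(τ ∈ {0.5, 0.9, 0.99, 0.999}, 200 paired bootstrap replicates) on −log₁₀ *p*
and |log effect|, and by Fisher's exact test on hit counts at
*p* < 5×10⁻⁸ and *p* < 1×10⁻⁵ (conditional-MLE odds ratio, BH FDR across
tests). GWAS p-values are aggregated with the weighted Cauchy combination
test

T = Σᵢ wᵢ tan[(½ − pᵢ)π],  p ≈ ½ − arctan(T / Σᵢ wᵢ)/π,  wᵢ = |Δᵢ|,

overall and per miRNA family (Bonferroni across all tests), combined across
traits by Stouffer's weighted Z (Zᵢ = Φ⁻¹(1 − pᵢ), weights = GWAS sample
sizes), and — within families with significant aggregate association —
alternate-allele-oriented effect sizes are regressed on Δ and on sign(Δ).

All inputs can be emulated by the bundled synthetic-data generator
(`mbsvkit.synthetic`), which plants known MBSVs, signal carriers and
single-filter-violating decoys, so every stage is testable without any
external download.

## Worked example

The published schizophrenia comparison — 9 genome-wide-significant MBSVs
out of 3207 pruned MBSVs versus 1 of 3326 background 3′UTR variants —
re-tested from its counts:

```python
>>> from mbsvkit.enrichment import fisher_exact
>>> res = fisher_exact(9, 3207, 1, 3326)
>>> print(f"p = {res.p:.3g}, OR (CMLE) = {res.odds_ratio:.3f}")
p = 0.0104, OR (CMLE) = 9.332
```

i.e. MBSVs are ~9-fold enriched among genome-wide-significant variants
(*p* ≈ 0.010). A full synthetic round trip:

```python
>>> from mbsvkit import pipeline
>>> from mbsvkit.synthetic import SimulationConfig, simulate_all
>>> d = simulate_all(SimulationConfig(n_variants=800, seed=7,
...                                   frac_mbsv=0.05, frac_decoy=0.2))
>>> inp = pipeline.PipelineInputs(
...     gwas=d.gwas, sites=d.sites, gene_expression=d.gene_rpkm,
...     gene_units="RPKM", mirna_counts=d.mirna_counts,
...     library_sizes=d.library_sizes, mirna_tiers=d.tiers,
...     family_map=d.family_map, gtex_eqtls=d.gtex_eqtls,
...     psychencode_eqtls=d.psychencode_eqtls, panel=d.panel)
>>> res = pipeline.run(inp, seed=1)
>>> res.manifest["counts"]
{'n_gwas_variants': 810, 'n_expressed_genes': 300, 'n_expressed_mirnas': 106,
 'n_mbsvs': 40, 'n_pruned': 32, 'n_pruned_mbsvs': 20, 'n_families': 31}
>>> set(res.mbsvs.variant_id) == set(d.truth.mbsv_ids)
True
```

All 40 planted MBSVs are recovered and all 170 decoys rejected; 32 of the
classified variants survive LD pruning, 20 of them MBSVs. The same analysis
is available from the shell:

```sh
mbsvkit simulate --seed 7 --n-variants 800 --out-dir sim/
mbsvkit run-all --gwas sim/gwas.tsv --sites sim/site_scores.tsv ... --out-dir out/
```

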