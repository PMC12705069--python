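# qtlcoloc

Most disease-associated variants found by GWAS are noncoding, yet only a
minority of those loci show a colocalized expression QTL (eQTL) — the
"missing regulation" problem. Chromatin-accessibility QTLs (caQTLs) sit
upstream of expression and are detected with less dependence on the distance
between the regulatory element and the gene's transcription start site
(TSS), so they can explain disease loci that eQTLs miss, either because
eQTL studies lack power or because the eQTL effect is specific to another
cellular context.

`qtlcoloc` implements the full analysis chain for studying this question on
synthetic data with known ground truth:

* **simulate** — genotype panels with distance-decaying LD (Gaussian-copula
  Markov haplotypes), a regulatory architecture (peak causal variants,
  distance-attenuated peak→gene wiring, per-context wiring masks), disease
  liability mediated through accessibility/expression plus a direct
  polygenic component, GWAS summary statistics drawn per LD block from
  `z ~ MVN(√N·R·β, R)`, and molecular-QTL statistics from actual regression
  on simulated individuals. Every derived truth (per-feature h²_cis, h²_SNP,
  mediated h²) is recorded.
* **qtlmap** — TMM library normalization (validated against edgeR), the
  CPM/count expression filter, per-feature inverse-normal transformation,
  permutation-based (parallel-analysis) selection of phenotype PCs, and
  per-variant cis association within a window after covariate
  residualization (200 kb around peaks, 1 Mb around TSSs, MAF ≥ 5%).
* **coloc** — the three-condition candidate-locus filter (lead disease
  p < 10⁻⁶, lead QTL p < 10⁻⁴, and a variant carrying ≥ 0.8×lead χ² for
  both traits), and Bayesian colocalization under the five-configuration
  single-shared-variant model with Wakefield approximate Bayes factors
  averaged over a prior-variance grid; loci with shared-variant posterior
  PP > 0.98 are called colocalized.
* **meta** — inverse-variance-weighted fixed-effects meta-analysis with the
  missing-variant rule (variants absent from some studies are combined from
  the available ones).
* **herit** — LD scores and mediation ("expression") scores with the
  unbiased r² adjustment, stratified χ² regression with per-category
  enrichment, mediated-heritability regression
  `E[χ²_j] = 1 + N·τ'·ℓ_j + N·Σ_d ω_d·E_jd` with block-jackknife SEs,
  Haseman–Elston cis-heritability (with a direct-REML small-n oracle),
  the union/intersection decomposition
  `h²_med,ca∩e = h²_med,ca + h²_med,e − h²_med,ca∪e`, peak strength/histone
  annotation subsets, peak-to-TSS distances, and the distance-quintile
  analyses (one-sided rank-sum and paired tests, OLS of eQTL h²_cis on
  caQTL h²_cis and distance in 100 kb units).
* **pipeline / cli** — one-config orchestration of the whole chain plus a
  `qtlcoloc` command-line tool (`simulate`, `qtl`, `coloc`, `meta`,
  `herit`, `run`, `report`).

## Worked example

Plant twelve disease loci whose peaks all carry a causal variant, with the
target genes wired strongly (4 loci), weakly (4), or only in a second
cellular context (4); then count loci with eQTL colocalization after a
single eQTL study, after meta-analyzing four studies, and after surveying
the second context:

```python
from qtlcoloc import benchmarks

out = benchmarks.staged_conversion(seed=6)
print(out["caQTL_loci"], out["stage1"], out["stage2"], out["stage3"])
# 12 5 8 12
```

All 12 loci colocalize with a caQTL, but only 5 with an eQTL in the single
study; meta-analysis (more power) recovers the weakly wired loci (8), and
the extra context recovers the rest (12) — the two mechanisms behind
missing regulation, reproduced from known truth.

Decomposing mediated heritability:

```python
from qtlcoloc.herit import decompose_mediated_h2

d = decompose_mediated_h2(h_ca=0.21, h_e=0.12, h_union=0.24)
print(d.just_ca, d.just_e, d.intersection, d.shared_fraction)
# 0.12 0.03 0.09 0.75
```

0.12 of liability-scale heritability is mediated only by accessibility,
0.03 only by expression, 0.09 by both; 75% of eQTL-mediated heritability is
shared with caQTLs.

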