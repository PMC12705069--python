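# Methods

## Generative model

### Genotypes

Haplotypes follow a first-order Gaussian-copula Markov chain along the
chromosome: a latent AR(1) process is thresholded at Φ⁻¹(f_j), so marginal
alternate-allele frequencies are exact by construction. The latent
correlation for each adjacent pair is solved by tetrachoric inversion
(Owen's-T evaluation of the bivariate normal orthant, Brent root-finding)
so that the realized *allele* correlation equals exp(−d/λ_LD) at distance
d. Because a high allele correlation is only achievable when the two
frequencies are similar (the Fréchet bound), allele frequencies themselves
are drawn from a latent process autocorrelated on the same length scale —
as in real data, where tightly linked common variants have similar
frequencies. Dosage = sum of two independent haplotypes. LD blocks split
the variants into equal-count ranges; each block stores its empirical
correlation matrix R, and all downstream quadratic forms treat cross-block
correlation as zero.

Defaults: MAF ∈ (0.05, 0.5) uniform (post-thresholding), λ_LD = 15–20 kb,
which gives r² ≈ 0.5 at 5 kb and near-independence beyond ~100 kb — a
compressed but qualitatively faithful caricature of common-variant LD,
chosen so that a few thousand simulated variants carry realistic
lead/proxy structure.

### Regulatory architecture and molecular phenotypes

Each peak carries at most one causal variant (uniform among the variants it
contains, present with probability `p_causal_peak`), with raw effect
b ~ N(0, σ_ca²) on the accessibility latent; the standardized effect is
b/√(b²+σ_a²), so σ_ca/σ_a sets the caQTL cis-heritability distribution.
Genes are driven by the standardized peak latents through wiring weights
whose magnitude is attenuated by exp(−distance/λ_wire); each edge is
independently active per cellular context. `wiring_kind="fixed_magnitude"`
replaces the half-normal magnitude with a deterministic one (random sign),
used by the distance benchmark where weight dispersion would otherwise
swamp the distance signal. Gene latents are standardized with their exact
model variance (including LD covariance between upstream causal variants),
so recorded per-gene cis effects α and h²_cis = α'Rα are exact.

Counts are negative binomial with mean `lib_i · exp(base_f +
0.5·latent_fi)`, log-abundances N(log depth, 1), lognormal library factors
(sd 0.2), and configurable overdispersion (0.1 default; 0 = Poisson). This
is deliberately minimal: it exercises the TMM/CPM/filter/inverse-normal
path and preserves latent ranks at high depth, but does not model GC or
fragment-length biases, peak-width effects, or mapping artefacts — passing
tests say nothing about those.

### Disease liability and truths

Liability = Σ_p δ_p·a_p + Σ_g γ_g·x_g + x'·d + ε, with δ (peak-direct), γ
(gene-mediated), and a dense/sparse direct vector d on variants. All
genetic flow is collected into a per-variant effect vector; dividing by the
exact liability SD gives the standardized β with h²_SNP = β'Rβ. Mediated
truths: through accessibility, Var(Σ_p c_p b_p x_kp) with c_p = δ_p + Σ_g
γ_g w̃_pg; through expression, Var(Σ_g γ_g·(gene genetic component)).
Because every modeled gene is downstream of peaks, expression-mediated
heritability is nested inside accessibility-mediated heritability, so the
union truth equals the accessibility component; the estimator-side
decomposition is unconstrained.

Two numerical safeguards:

* the direct vector is orthogonalized against the mediated component in
  the R inner product, making their realized covariance exactly zero —
  h²_med ≤ h²_SNP holds for every draw, and scored variants carry no
  systematic excess or deficit from the direct channel;
* when targets (h²_SNP, prop_mediated) are requested, the mediated and
  direct channels are rescaled by a closed-form solution (the mediated
  channel's non-genetic share bounds the achievable proportion; infeasible
  targets raise rather than silently truncating).

GWAS summary statistics are drawn per block from z ~ MVN(√N·Rβ, R)
(eigenvalue-clipped PSD repair with a logged warning if needed); molecular
QTL statistics always come from regressing simulated individuals, so both
generation paths are exercised.

## Analysis components

* **TMM**: reference = library whose 75th-percentile count fraction is
  closest to the mean; doubly trimmed (30% M, 5% A), precision-weighted
  log-ratio mean; factors renormalized to geometric mean 1. Matches
  Bioconductor edgeR to ≤1e-6 on a shared fixture. `weighted=False` drops
  the delta-method weights, making factors depend on count fractions only
  (then scaling a whole library leaves CPM exactly invariant).
* **Expression filter**: a feature is dropped iff the fraction of samples
  with CPM < 0.8 **or** count < 10 strictly exceeds 0.2.
* **Inverse-normal transform**: Φ⁻¹((rank−0.5)/n), average ranks for ties,
  constant features mapped to zeros with a warning.
* **Phenotype-PC selection**: parallel analysis — each permutation shuffles
  every feature independently; K = leading observed eigenvalues above the
  95th permutation percentile of the same rank, stopping at the first
  failure. Eigenvalues come from the smaller Gram matrix (same spectrum).
* **cis mapping**: phenotypes and dosages residualized on an intercept plus
  covariates; per-variant simple regression with df = n − 2 − #covariates,
  which reproduces the joint multiple-regression fit exactly
  (Frisch–Waugh); two-sided t p-values; in-sample MAF ≥ 0.05; windows
  measured from the anchor point (TSS) or nearest interval edge (peak);
  lead ties broken by genomic position then id.
* **Colocalization**: log Wakefield ABF = ½log(V/(V+W)) + (z²/2)·W/(V+W),
  averaged over W ∈ {0.01, 0.1, 0.5}; configuration sums assembled in log
  space (log-sum-exp; the two-distinct term uses log-diff-exp with a clamp
  at zero). Priors p1 = p2 = 1e-4, p12 = 1e-5 (the standard defaults for
  this model family); the decision threshold PP_shared > 0.98. Candidate
  windows are emitted greedily by ascending disease p with masking of leads
  inside already-emitted windows; the χ²-overlap comparison uses ≥ at the
  0.8 boundary. Allele harmonization flips the second trait's beta for
  ref/alt swaps and drops strand-ambiguous common variants.
* **IVW meta-analysis**: fixed effects only; single-study variants pass
  through bit-exactly; Cochran's Q is emitted as a diagnostic and never
  filtered on; p is recomputed from the combined z.
* **Scores and χ² regressions**: r² within block and window, unbiased
  adjustment r² − (1−r²)/(n−2) (disable with `adjust=False` when feeding
  exact population R). The regression of χ² on [1, N·ℓ, N·E] uses iterated
  weights 1/(max(ℓ,1)·fitted²) with fitted expectations floored at 1 — the
  floor matters: unfloored first-pass fits occasionally produce tiny
  fitted values, concentrating nearly all weight on a handful of variants
  and destabilizing the τ/ω split. Weighting from the joint fitted values
  (not an ℓ-only model) keeps weights matched to the actual
  heteroskedasticity at scored variants. SEs are delete-one block
  jackknives over contiguous variant blocks (20 at desk scale; the
  hundreds used genome-wide would leave too few variants per block here).
  h²_med per set = ω_d × Σ_features α'Rα; ratios are taken against h²_SNP
  from the same fit; negative ω is reported as-is with a warning.
* **Cis-heritability**: Haseman–Elston regression of y_i·y_j on the cis
  relatedness over i<j pairs, computed via Gram-matrix identities (the
  n×n relatedness is never formed); the analytic SE treats pairs as
  independent (an approximation; pairs share individuals). The REML oracle
  maximizes the profile restricted likelihood on an eigendecomposition of
  A. The two agree closely only for small cis sets — the moment estimator
  loses efficiency relative to the MLE as the number of cis variants
  grows, so the oracle comparison uses 3 cis variants at n = 60.
* **Peak-to-TSS distance**: 0 when the TSS lies inside the peak; otherwise
  distance to the 1-based anchor edges (start+1 on the left, end−1 on the
  right). The slight asymmetry is a frozen convention, chosen to match the
  package's worked numeric examples ([100,200) with TSS 500 → 301, TSS
  50 → 51).
* **Multiplicity**: Benjamini–Hochberg by default where subset enrichments
  are tested; a Storey-π₀ variant is exposed (`fdr_method="storey"`). BH is
  mildly more conservative when many hypotheses are non-null.

## Benchmark designs and problem sizes

The reference scenarios (`qtlcoloc.benchmarks`) fix study dimensions once:

* *Colocalization discrimination*: 60-variant loci, λ_LD 15 kb, QTL n=400
  with h²_cis 0.3, GWAS n=50,000 with a single causal variant at expected
  |z| = 7 — a strong but ordinary genome-wide-significant locus.
* *Mediated recovery*: one shared 2,400-variant genome (24 blocks, 16 Mb),
  300 always-causal peaks, 120 genes, dense direct background, targets
  h²_SNP = 0.3 with mediated proportion ∈ {0, 0.3, 0.6}; 20 replicates
  redraw architecture and GWAS noise.
* *Distance pattern*: 400 one-to-one peak–gene pairs with TSS offsets up
  to 480 kb, fixed-magnitude wiring attenuated with λ_wire = 450 kb,
  strong caQTLs (σ_a = 0.3) so that the distance trend is not drowned by
  effect-size dispersion; HE windows 200 kb (peaks) and 500 kb (genes).
* *Staged conversion*: 12 loci in disjoint LD blocks, three planted gene
  groups (strong / weak / second-context wiring), eQTL studies of n=150
  (single), +150/150/200 (meta), and n=300 in the second context.

Sizes were chosen so each scenario resolves its expected effect cleanly at
desk scale; they are stated here because every quantitative claim in the
test suite is conditional on them.

## Known limitations

* LD is Markovian and block-diagonal: no long-range haplotype structure,
  no population stratification or admixture, autosomes only.
* The count model omits technical covariates; the phenotype-PC machinery
  is therefore exercised on weaker latent structure than real assays have.
* The liability model is Gaussian (no case-control ascertainment), and
  GWAS draws condition on the realized β rather than integrating over
  effect-size priors, so χ²-regression residuals carry architecture noise
  that only averages out across replicates.
* Expression-mediated truth is nested within accessibility-mediated truth
  by construction; architectures where genes have peak-independent cis
  effects are not generated.
* Mediation scores use true (or externally supplied) cis effects;
  shrinkage-estimated scores from finite molecular panels would attenuate
  mediated-heritability estimates, which is part of why small-panel
  estimates are biased toward zero in practice.
* The union/intersection decomposition follows the set-consistent
  convention just_ca = union − h_e and just_e = union − h_ca; one
  published variant of the formula algebraically swaps the two "just"
  quantities, so signs should be checked when comparing conventions.
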