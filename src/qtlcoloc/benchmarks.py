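"""Reference simulation scenarios with known ground truth.

Each function sets up a self-contained study design — locus-level
colocalization discrimination, all-null calibration, mediated-heritability
recovery, the peak-to-TSS-distance architecture, and the staged
(power/context) conversion design — runs the package's own analysis path on
it, and returns summary measurements. The scenarios dimension the designs so
that the expected behaviour is unambiguous at desk scale; docs/methods.md
records the choices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import coloc, herit, qtlmap, simulate
from ._rng import derive_rng, derive_seed
from .datatypes import ColocPriors, Gene, Peak, PhenotypeMatrix

__all__ = [
    "coloc_discrimination",
    "null_calibration",
    "mediated_recovery",
    "distance_pattern",
    "staged_conversion",
]


# ----------------------------------------------------------------------------
# colocalization discrimination
# ----------------------------------------------------------------------------

def _one_locus(seed: int, shared: bool, n_gwas: int, n_qtl: int, h2_cis: float,
               z_disease: float) -> float:
    """PP_shared for one simulated locus (shared or distinct causal)."""
    panel = simulate.simulate_genotype_panel(
        n_qtl, 60, 200_000, ld_decay=15_000, n_blocks=1, seed=seed
    )
    X = panel.standardized_dosages()
    c1 = 30
    if shared:
        c2 = c1
    else:
        low_ld = np.flatnonzero(panel.ld_blocks[0].R[c1] ** 2 < 0.05)
        c2 = int(low_ld[np.argmin(np.abs(low_ld - c1))]) if len(low_ld) else 5
    beta = np.zeros(60)
    beta[c1] = z_disease / np.sqrt(n_gwas)
    model = type("Model", (), {"beta": beta})()
    disease = simulate.simulate_gwas_summary(panel, model, n_gwas, seed=derive_seed(seed, "d"))
    rng = derive_rng(seed, "pheno")
    y = np.sqrt(h2_cis) * X[:, c2] + np.sqrt(1 - h2_cis) * rng.normal(size=n_qtl)
    pm = PhenotypeMatrix(["f"], list(panel.sample_ids), y[None, :], "normalized")
    res = qtlmap.map_cis_qtl(panel, pm, None, {"f": ("chr1", 1, 200_000)}, 250_000, 0.05)[0]
    return coloc.colocalize_region(disease.table, res.table).pp_shared


def coloc_discrimination(
    n_shared: int = 100,
    n_distinct: int = 100,
    n_gwas: int = 50_000,
    n_qtl: int = 400,
    h2_cis: float = 0.3,
    z_disease: float = 7.0,
    pp_threshold: float = 0.98,
    seed: int = 0,
) -> dict:
    """Fractions of shared/distinct-causal loci called colocalized.

    Each locus carries one GWAS causal variant (expected |z| = z_disease, a
    strong but realistic single-locus association) and one molecular-QTL
    causal variant with the given cis-heritability; the QTL scan runs on
    simulated individuals while GWAS statistics follow the multivariate
    normal law.
    """
    shared_pp = [
        _one_locus(derive_seed(seed, "s", i), True, n_gwas, n_qtl, h2_cis, z_disease)
        for i in range(n_shared)
    ]
    distinct_pp = [
        _one_locus(derive_seed(seed, "d", i), False, n_gwas, n_qtl, h2_cis, z_disease)
        for i in range(n_distinct)
    ]
    return {
        "shared_rate": float(np.mean(np.array(shared_pp) > pp_threshold)),
        "distinct_rate": float(np.mean(np.array(distinct_pp) > pp_threshold)),
        "n_shared": n_shared,
        "n_distinct": n_distinct,
    }


# ----------------------------------------------------------------------------
# null calibration
# ----------------------------------------------------------------------------

def null_calibration(seed: int = 0, n_reps: int = 20) -> dict:
    """All-null simulation: QTL p uniformity, candidate-locus false calls,
    and the mediated-heritability ratio under zero disease effects."""
    # (a) QTL p-value uniformity on a no-LD panel
    panel0 = simulate.simulate_genotype_panel(
        100, 1000, 20_000_000, ld_decay=1.0, n_blocks=4, seed=derive_seed(seed, "p0")
    )
    rng = derive_rng(seed, "y")
    y = rng.normal(size=100)
    pm = PhenotypeMatrix(["f"], list(panel0.sample_ids), y[None, :], "normalized")
    res = qtlmap.map_cis_qtl(
        panel0, pm, None, {"f": ("chr1", 1, 20_000_000)}, 25_000_000, 0.05
    )[0]
    ks_p = float(stats.kstest(res.table["p"], "uniform").pvalue)

    # (b) candidate loci from null GWAS, using a real (non-null) QTL scan so
    # that only the disease condition can gate the filter
    panel = simulate.simulate_genotype_panel(
        400, 1000, 8_000_000, ld_decay=15_000, n_blocks=10, seed=derive_seed(seed, "p1")
    )
    peaks, genes = simulate.layout_peaks_genes(panel, 40, 20, seed=derive_seed(seed, "lay"))
    model = simulate.simulate_regulatory_model(
        panel, peaks, genes, p_causal_peak=0.8, sigma_ca=2.0,
        gamma_scale=0.0, delta_scale=0.0, seed=derive_seed(seed, "m"),
    )
    acc, _ = simulate.simulate_latent_phenotypes(panel, model, model.disease_context,
                                                 seed=derive_seed(seed, "lat"))
    ca = qtlmap.map_cis_qtl(
        panel, qtlmap.inverse_normal_transform(acc), None,
        {p.id: (p.chrom, p.start, p.end) for p in peaks}, 200_000, 0.05, "caQTL",
    )
    empty = 0
    for rep in range(n_reps):
        gwas = simulate.simulate_gwas_summary(panel, model, 50_000, seed=derive_seed(seed, "g", rep))
        loci = coloc.select_candidate_loci(gwas, ca)
        empty += len(loci) == 0
    # (c) mediated ratio under the null
    gwas = simulate.simulate_gwas_summary(panel, model, 50_000, seed=derive_seed(seed, "g0"))
    ld = herit.compute_ld_scores(panel, {"all": np.ones(panel.n_variants, bool)})
    ms = herit.compute_mediation_scores(panel, model.alpha_ca, "caQTL")
    fit = herit.mediated_h2_regression(gwas, ld, [ms], n_blocks=20)
    return {
        "ks_p": ks_p,
        "frac_zero_loci": empty / n_reps,
        "ratio": fit.ratio["caQTL"],
        "ratio_se": fit.se["ratio::caQTL"],
        "mean_chisq": float(gwas.table["chisq"].mean()),
        "n_reps": n_reps,
    }


# ----------------------------------------------------------------------------
# mediated-heritability recovery
# ----------------------------------------------------------------------------

def _recovery_panel(seed: int):
    panel = simulate.simulate_genotype_panel(
        600, 2400, 16_000_000, ld_decay=15_000, n_blocks=24, seed=derive_seed(seed, "panel")
    )
    ld = herit.compute_ld_scores(panel, {"all": np.ones(panel.n_variants, bool)})
    return panel, ld


def mediated_recovery(
    prop_mediated: float,
    n_reps: int = 20,
    n_gwas: int = 50_000,
    target_h2_snp: float = 0.3,
    seed: int = 0,
    panel_and_ld=None,
) -> dict:
    """Estimated h2_med/h2_snp for chromatin scores vs a calibrated truth.

    One genome (panel) is shared across replicates; each replicate draws a
    fresh regulatory architecture calibrated to the target heritability and
    mediated proportion, simulates GWAS statistics, and refits the
    mediated-heritability regression with true cis effects as scores.
    """
    panel, ld = panel_and_ld if panel_and_ld is not None else _recovery_panel(seed)
    ratios = []
    for rep in range(n_reps):
        s = derive_seed(seed, "rep", prop_mediated, rep)
        peaks, genes = simulate.layout_peaks_genes(panel, 300, 120, seed=s)
        model = simulate.simulate_regulatory_model(
            panel, peaks, genes, p_causal_peak=1.0, sigma_ca=2.0,
            gamma_scale=0.7, delta_scale=1.0, disease_gene_frac=0.5,
            p_causal_direct=1.0, direct_scale=1.0, max_wiring_dist=250_000,
            target_h2_snp=target_h2_snp, target_prop_mediated=prop_mediated, seed=s,
        )
        gwas = simulate.simulate_gwas_summary(panel, model, n_gwas, seed=derive_seed(s, "g"))
        ms = herit.compute_mediation_scores(panel, model.alpha_ca, "caQTL")
        fit = herit.mediated_h2_regression(gwas, ld, [ms], n_blocks=20)
        ratios.append(fit.ratio["caQTL"])
    return {
        "mean_ratio": float(np.mean(ratios)),
        "sd_ratio": float(np.std(ratios)),
        "truth": prop_mediated,
        "n_reps": n_reps,
    }


# ----------------------------------------------------------------------------
# peak-to-TSS-distance architecture
# ----------------------------------------------------------------------------

@dataclass
class DistanceSimResult:
    strictly_decreasing_medians: bool
    paired_ca_above_e_all_quintiles: bool
    regression_signs_correct: bool
    ca_trend_p: float
    coef_ca: float
    coef_dist: float
    median_h2_e: np.ndarray


def _distance_panel(seed: int):
    return simulate.simulate_genotype_panel(
        400, 2400, 30_000_000, ld_decay=15_000, n_blocks=24, seed=derive_seed(seed, "panel")
    )


def distance_pattern_one(panel, seed: int, n_pairs: int = 400,
                         wiring_decay: float = 450_000.0) -> DistanceSimResult:
    """One replicate: paired peak/gene architecture with exponentially
    attenuating wiring, Haseman-Elston cis-h2 for both molecular traits,
    and the quintile/regression analysis."""
    rng = derive_rng(seed, "arch")
    pos = panel.variants["pos"].to_numpy()
    region = panel.params["region_length"]
    centers = np.sort(
        rng.choice(pos[(pos > 700_000) & (pos < region - 700_000)], n_pairs, replace=False)
    )
    peaks = [Peak("chr1", int(c) - 300, int(c) + 300, f"peak{i:04d}") for i, c in enumerate(centers)]
    offs = rng.uniform(2_000, 480_000, n_pairs) * rng.choice([-1, 1], n_pairs)
    genes = [
        Gene(f"gene{i:04d}", "chr1", max(1, int(c + o)))
        for i, (c, o) in enumerate(zip(centers, offs))
    ]
    edges = [(p.id, g.id) for p, g in zip(peaks, genes)]
    model = simulate.simulate_regulatory_model(
        panel, peaks, genes, p_causal_peak=1.0, sigma_ca=2.0, sigma_a=0.3,
        wiring_decay=wiring_decay, wiring_scale=1.0, sigma_e=1.0,
        edges=edges, wiring_kind="fixed_magnitude", seed=derive_seed(seed, "model"),
    )
    acc, expr = simulate.simulate_latent_phenotypes(
        panel, model, "lcl", seed=derive_seed(seed, "lat")
    )
    rows = []
    for i, (p, g) in enumerate(zip(peaks, genes)):
        if p.id not in model.peak_causals:
            continue
        h2ca, _, _ = herit.estimate_cis_h2(panel, acc.values[i], (p.chrom, p.start, p.end), 200_000)
        h2e, _, _ = herit.estimate_cis_h2(panel, expr.values[i], (g.chrom, g.tss), 500_000)
        rows.append(
            {"distance": herit.peak_tss_distance(p, g), "h2_ca": h2ca, "h2_e": h2e}
        )
    da = herit.distance_stratified_h2(pd.DataFrame(rows))
    med_e = da.table.groupby("quintile")["h2_e"].median().to_numpy()
    paired = all(
        (da.table[da.table["quintile"] == q]["h2_ca"] - da.table[da.table["quintile"] == q]["h2_e"]).median() > 0
        for q in range(1, 6)
    )
    return DistanceSimResult(
        strictly_decreasing_medians=bool(np.all(np.diff(med_e) < 0)),
        paired_ca_above_e_all_quintiles=bool(paired),
        regression_signs_correct=bool(da.coef_ca > 0 and da.coef_dist < 0),
        ca_trend_p=da.trend_p_ca,
        coef_ca=da.coef_ca,
        coef_dist=da.coef_dist,
        median_h2_e=med_e,
    )


def distance_pattern(n_sims: int = 50, seed: int = 0) -> dict:
    panel = _distance_panel(seed)
    sims = [distance_pattern_one(panel, derive_seed(seed, "sim", i)) for i in range(n_sims)]
    return {
        "frac_strictly_decreasing": float(np.mean([s.strictly_decreasing_medians for s in sims])),
        "frac_paired_dominance": float(np.mean([s.paired_ca_above_e_all_quintiles for s in sims])),
        "frac_signs_correct": float(np.mean([s.regression_signs_correct for s in sims])),
        "frac_ca_no_trend": float(np.mean([s.ca_trend_p > 0.05 for s in sims])),
        "mean_coef_ca": float(np.mean([s.coef_ca for s in sims])),
        "mean_coef_dist": float(np.mean([s.coef_dist for s in sims])),
        "n_sims": n_sims,
    }


# ----------------------------------------------------------------------------
# staged conversion
# ----------------------------------------------------------------------------

def staged_conversion(
    seed: int = 0,
    n_loci: int = 12,
    n_gwas: int = 5_000,
    n_eqtl_primary: int = 150,
    meta_sizes: tuple[int, ...] = (150, 150, 200),
    n_context: int = 300,
) -> dict:
    """Planted three-group locus design (strong / weak / context-specific
    eQTL wiring) and the three-stage eQTL-colocalization accounting."""
    from .pipeline import PipelineConfig, _coloc_candidates, _meta_cis_results

    spacing = 1_200_000
    region = n_loci * spacing + 1_000_000
    panel = simulate.simulate_genotype_panel(
        100, n_loci * 100, region, ld_decay=15_000, n_blocks=n_loci,
        seed=derive_seed(seed, "panel"),
    )
    pos = panel.variants["pos"].to_numpy()
    peaks, genes, wiring, delta, causals = [], [], {}, {}, {}
    groups = (["strong", "weak", "ctx"] * n_loci)[:n_loci]
    for i in range(n_loci):
        lo = 500_000 + i * spacing
        cand = np.flatnonzero((pos > lo) & (pos < lo + 200_000))
        k = int(cand[len(cand) // 2])
        c = int(pos[k])
        pk = Peak("chr1", c - 300, c + 300, f"peak{i:02d}")
        g = Gene(f"gene{i:02d}", "chr1", c + 30_000)
        peaks.append(pk)
        genes.append(g)
        causals[pk.id] = (k, 0.63)
        delta[pk.id] = 1.0
        if groups[i] == "strong":
            wiring[(pk.id, g.id, "lcl")] = 1.2
        elif groups[i] == "weak":
            wiring[(pk.id, g.id, "lcl")] = 0.42
        else:
            wiring[(pk.id, g.id, "stim")] = 1.0
    model = simulate.assemble_regulatory_model(
        panel, peaks, genes, ["lcl", "stim"], causals, wiring, delta=delta
    )
    gwas = simulate.simulate_gwas_summary(panel, model, n_gwas, seed=derive_seed(seed, "g"))
    cfg = PipelineConfig(seed=seed)
    priors = ColocPriors()

    acc, _ = simulate.simulate_latent_phenotypes(panel, model, "lcl", seed=derive_seed(seed, "ca"))
    ca_res = qtlmap.map_cis_qtl(
        panel, qtlmap.inverse_normal_transform(acc), None,
        {p.id: (p.chrom, p.start, p.end) for p in peaks}, 200_000, 0.05, "caQTL",
    )
    ca_cand = _coloc_candidates(gwas, ca_res, cfg, priors)

    def eqtl_study(n, ctx, tag):
        s = derive_seed(seed, tag)
        sub = simulate.resample_panel(panel, n, s)
        _, expr = simulate.simulate_latent_phenotypes(sub, model, ctx, s)
        results = qtlmap.map_cis_qtl(
            sub, qtlmap.inverse_normal_transform(expr), None,
            {g.id: (g.chrom, g.tss) for g in genes}, 1_000_000, 0.05, "eQTL",
        )
        return simulate.QtlStudy(tag, n, ctx, results)

    st1 = eqtl_study(n_eqtl_primary, "lcl", "primary")
    e_cand = _coloc_candidates(gwas, st1.results, cfg, priors)
    studies = [st1] + [eqtl_study(n, "lcl", f"meta{i}") for i, n in enumerate(meta_sizes)]
    meta_cand = _coloc_candidates(gwas, _meta_cis_results(studies), cfg, priors)
    ctx_cand = _coloc_candidates(
        gwas, eqtl_study(n_context, "stim", "ctx").results, cfg, priors
    )

    def hit_set(cand):
        return {k for k, v in cand.items() if any(r.colocalized for r in v)}

    s1 = hit_set(e_cand)
    s2 = s1 | hit_set(meta_cand)
    s3 = s2 | hit_set(ctx_cand)
    return {
        "caQTL_loci": len(hit_set(ca_cand)),
        "stage1": len(s1),
        "stage2": len(s2),
        "stage3": len(s3),
        "sets": (s1, s2, s3),
        "n_loci": n_loci,
    }
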