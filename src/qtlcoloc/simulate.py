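"""Synthetic genotype, regulatory-architecture and summary-statistic generator.

The generator produces data with the statistical structure the downstream
analyses assume, with all ground truth recorded:

* genotypes as haplotype pairs from a first-order Markov chain along the
  chromosome, so that allele correlation between adjacent variants at
  distance ``d`` is ``exp(-d / ld_decay)`` (clipped where binomial transition
  probabilities would leave [0, 1]);
* chromatin peaks carrying at most one causal variant each, genes driven by
  peak activity through wiring weights whose magnitude decays exponentially
  with peak-to-TSS distance, and per-context wiring masks;
* a disease liability mediated through accessibility/expression plus an
  optional direct (non-mediated) polygenic component;
* GWAS summary statistics drawn from the multivariate-normal law
  ``z ~ MVN(sqrt(N) R beta, R)`` per LD block, and molecular-QTL summary
  statistics produced by actual regression on simulated individuals.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from ._rng import derive_rng, derive_seed
from .datatypes import (
    Gene,
    GenotypePanel,
    LDBlock,
    Peak,
    PhenotypeMatrix,
    RegulatoryModel,
    SummaryStats,
)

logger = logging.getLogger("qtlcoloc")

__all__ = [
    "simulate_genotype_panel",
    "resample_panel",
    "layout_peaks_genes",
    "simulate_regulatory_model",
    "assemble_regulatory_model",
    "simulate_latent_phenotypes",
    "simulate_molecular_phenotypes",
    "simulate_gwas_summary",
    "simulate_eqtl_studies",
    "QtlStudy",
    "SimBundle",
    "export_fixture",
    "import_fixture",
]


# ----------------------------------------------------------------------------
# genotypes
# ----------------------------------------------------------------------------

def _bvn_cdf(t1: float, t2: float, rho: float) -> float:
    """P(Z1 < t1, Z2 < t2) for standard bivariate normal via Owen's T."""
    if rho == 0:
        return float(stats.norm.cdf(t1) * stats.norm.cdf(t2))
    rho = float(np.clip(rho, -0.999999, 0.999999))
    denom = np.sqrt(1 - rho**2)
    if t1 == 0 and t2 == 0:
        return 0.25 + np.arcsin(rho) / (2 * np.pi)
    term1 = 0.25 if t1 == 0 else 0.5 * stats.norm.cdf(t1) - special.owens_t(
        t1, (t2 - rho * t1) / (t1 * denom)
    )
    term2 = 0.25 if t2 == 0 else 0.5 * stats.norm.cdf(t2) - special.owens_t(
        t2, (t1 - rho * t2) / (t2 * denom)
    )
    delta = 0.0 if t1 * t2 > 0 or (t1 * t2 == 0 and t1 + t2 >= 0) else 0.5
    return float(term1 + term2 - delta)


def _solve_latent_rho(f1: float, f2: float, r_target: float) -> float:
    """Latent (tetrachoric) correlation giving allele correlation r_target.

    When the target exceeds the maximum achievable for the two allele
    frequencies (Frechet bound), the latent correlation saturates near 1.
    """
    if r_target <= 1e-12:
        return 0.0
    t1, t2 = stats.norm.ppf(f1), stats.norm.ppf(f2)
    sd = np.sqrt(f1 * (1 - f1) * f2 * (1 - f2))

    def gap(rho: float) -> float:
        return (_bvn_cdf(t1, t2, rho) - f1 * f2) / sd - r_target

    hi = 0.9999
    if gap(hi) < 0:
        return hi
    return float(optimize.brentq(gap, 0.0, hi, xtol=1e-6))


def _chain_latent_rho(freqs: np.ndarray, positions: np.ndarray, ld_decay: float) -> np.ndarray:
    target = np.exp(-np.diff(positions) / ld_decay)
    return np.array(
        [_solve_latent_rho(freqs[j], freqs[j + 1], target[j]) for j in range(len(target))]
    )


def _draw_haplotypes(
    rng: np.random.Generator,
    n_haps: int,
    freqs: np.ndarray,
    latent_rho: np.ndarray,
) -> np.ndarray:
    """Gaussian-copula Markov-chain haplotypes.

    A latent AR(1) chain is thresholded at Phi^-1(f_j), so marginal allele
    frequencies are exact and adjacent allele correlations hit the
    tetrachoric-solved targets.
    """
    m = len(freqs)
    thresh = stats.norm.ppf(freqs)
    z = np.empty((n_haps, m))
    z[:, 0] = rng.normal(size=n_haps)
    for j in range(1, m):
        r = latent_rho[j - 1]
        z[:, j] = r * z[:, j - 1] + np.sqrt(1 - r**2) * rng.normal(size=n_haps)
    return (z < thresh[None, :]).astype(np.int8)


def _block_corr(dosages: np.ndarray) -> np.ndarray:
    """Empirical correlation matrix, robust to zero-variance columns."""
    x = dosages.astype(float)
    sd = x.std(axis=0)
    ok = sd > 0
    R = np.eye(x.shape[1])
    if ok.sum() >= 2:
        sub = np.corrcoef(x[:, ok], rowvar=False)
        R[np.ix_(ok, ok)] = sub
    np.fill_diagonal(R, 1.0)
    return R


def simulate_genotype_panel(
    n_samples: int,
    n_variants: int,
    region_length: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_decay: float = 20_000.0,
    n_blocks: int = 5,
    seed: int = 0,
    chrom: str = "chr1",
) -> GenotypePanel:
    """Simulate a genotype panel with distance-decaying LD.

    Two haplotypes per sample are generated by a first-order Markov chain
    along the ordered variants; the dosage is the haplotype sum. LD blocks
    partition the variants into ``n_blocks`` equal-count ranges, each with an
    empirically estimated correlation matrix.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if ld_decay <= 0:
        raise ValueError("ld_decay must be positive")
    if n_variants < n_blocks:
        raise ValueError("n_variants must be >= n_blocks")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must be within (0, 0.5]")

    rng = derive_rng(seed, "panel")
    positions = np.sort(rng.choice(np.arange(1, region_length + 1), size=n_variants, replace=False))
    # allele frequencies (== maf) autocorrelated along the chromosome: tightly
    # linked variants have similar frequencies, as strong LD requires
    decay_rho = np.exp(-np.diff(positions) / ld_decay)
    u = np.empty(n_variants)
    u[0] = rng.normal()
    for j in range(1, n_variants):
        u[j] = decay_rho[j - 1] * u[j - 1] + np.sqrt(1 - decay_rho[j - 1] ** 2) * rng.normal()
    freqs = lo + (hi - lo) * stats.norm.cdf(u)
    latent_rho = _chain_latent_rho(freqs, positions, ld_decay)
    h1 = _draw_haplotypes(rng, n_samples, freqs, latent_rho)
    h2 = _draw_haplotypes(rng, n_samples, freqs, latent_rho)
    dosages = (h1 + h2).astype(np.int8)

    variants = pd.DataFrame(
        {
            "id": [f"var{j:05d}" for j in range(n_variants)],
            "chrom": chrom,
            "pos": positions.astype(int),
            "ref": "A",
            "alt": "G",
            "maf": freqs,
        }
    )
    edges = np.linspace(0, n_variants, n_blocks + 1).astype(int)
    blocks = [
        LDBlock(int(a), int(b), _block_corr(dosages[:, a:b]))
        for a, b in zip(edges[:-1], edges[1:])
        if b > a
    ]
    params = {
        "freqs": freqs,
        "positions": positions,
        "latent_rho": latent_rho,
        "ld_decay": float(ld_decay),
        "chrom": chrom,
        "n_blocks": n_blocks,
        "region_length": int(region_length),
    }
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    return GenotypePanel(variants, sample_ids, dosages, blocks, params)


def resample_panel(panel: GenotypePanel, n_samples: int, seed: int) -> GenotypePanel:
    """Draw an independent sample of individuals from the same population."""
    p = panel.params
    rng = derive_rng(seed, "resample")
    h1 = _draw_haplotypes(rng, n_samples, p["freqs"], p["latent_rho"])
    h2 = _draw_haplotypes(rng, n_samples, p["freqs"], p["latent_rho"])
    dosages = (h1 + h2).astype(np.int8)
    blocks = [
        LDBlock(b.start, b.stop, _block_corr(dosages[:, b.start : b.stop]))
        for b in panel.ld_blocks
    ]
    sample_ids = [f"R{i:04d}" for i in range(n_samples)]
    return GenotypePanel(panel.variants.copy(), sample_ids, dosages, blocks, dict(p))


# ----------------------------------------------------------------------------
# regulatory architecture
# ----------------------------------------------------------------------------

def layout_peaks_genes(
    panel: GenotypePanel,
    n_peaks: int,
    n_genes: int,
    peak_width: int = 600,
    seed: int = 0,
) -> tuple[list[Peak], list[Gene]]:
    """Place peaks centred on randomly chosen variants and genes at random TSSs."""
    rng = derive_rng(seed, "layout")
    chrom = panel.params["chrom"]
    pos = panel.variants["pos"].to_numpy()
    centers = np.sort(rng.choice(pos, size=min(n_peaks, len(pos)), replace=False))
    peaks = []
    for i, c in enumerate(centers):
        start = max(0, int(c) - peak_width // 2)
        peaks.append(Peak(chrom, start, start + peak_width, f"peak{i:04d}"))
    span = panel.params["region_length"]
    tss = np.sort(rng.choice(np.arange(1, span + 1), size=n_genes, replace=False))
    genes = [Gene(f"gene{i:04d}", chrom, int(t), "+") for i, t in enumerate(tss)]
    return peaks, genes


def _block_quadratic(panel: GenotypePanel, v: np.ndarray) -> float:
    """v' R v aggregated over LD blocks (cross-block correlation treated as 0)."""
    total = 0.0
    for b in panel.ld_blocks:
        seg = v[b.start : b.stop]
        if np.any(seg):
            total += float(seg @ b.R @ seg)
    return total


def _pair_r(panel: GenotypePanel, j: int, k: int) -> float:
    if j == k:
        return 1.0
    for b in panel.ld_blocks:
        if b.start <= j < b.stop and b.start <= k < b.stop:
            return float(b.R[j - b.start, k - b.start])
    return 0.0


def _peak_tss_dist(peak: Peak, gene: Gene) -> int:
    # local import avoided: duplicate of herit.peak_tss_distance edge convention
    left, right = peak.start + 1, peak.end - 1
    if left <= gene.tss <= peak.end:
        return 0
    if gene.tss > peak.end:
        return gene.tss - right
    return left - gene.tss


def simulate_regulatory_model(
    panel: GenotypePanel,
    peaks: list[Peak],
    genes: list[Gene],
    p_causal_peak: float = 0.5,
    sigma_ca: float = 1.0,
    wiring_decay: float = 50_000.0,
    contexts: tuple[str, ...] = ("lcl",),
    prop_active_per_context: float = 1.0,
    gamma_scale: float = 0.0,
    delta_scale: float = 0.0,
    seed: int = 0,
    sigma_a: float = 1.0,
    sigma_e: float = 1.0,
    sigma_y: float = 1.0,
    wiring_scale: float = 1.0,
    max_wiring_dist: float = 1e6,
    p_edge: float = 1.0,
    disease_gene_frac: float = 1.0,
    disease_peak_frac: float = 1.0,
    p_causal_direct: float = 0.0,
    direct_scale: float = 0.0,
    target_h2_snp: float | None = None,
    target_prop_mediated: float | None = None,
    edges: list[tuple[str, str]] | None = None,
    wiring_kind: str = "normal",
) -> RegulatoryModel:
    """Draw the ground-truth causal architecture and derive all truth fields.

    Each peak independently receives one causal variant (uniform among the
    variants inside its interval) with probability ``p_causal_peak``; wiring
    weights between peaks and genes have magnitudes attenuated by
    ``exp(-distance / wiring_decay)`` and are masked per context. Disease
    effects enter through genes (``gamma``), peaks (``delta``) and optionally
    directly through variants; when ``target_h2_snp``/``target_prop_mediated``
    are given, the mediated and direct components are rescaled in closed form
    so the stored truths hit the targets exactly.
    """
    if not peaks:
        raise ValueError("peak list must not be empty")
    if not contexts:
        raise ValueError("need at least one context")
    rng = derive_rng(seed, "model")
    pos = panel.variants["pos"].to_numpy()
    chrom = panel.params["chrom"]
    m = panel.n_variants

    # --- peak causal variants -------------------------------------------------
    peak_causals: dict[str, tuple[int, float, float]] = {}
    for pk in peaks:
        inside = np.flatnonzero((pos > pk.start) & (pos <= pk.end) & (panel.variants["chrom"] == pk.chrom))
        if len(inside) == 0:
            continue
        if rng.random() < p_causal_peak:
            k = int(rng.choice(inside))
            b_raw = float(rng.normal(0.0, sigma_ca))
            b_std = b_raw / np.sqrt(b_raw**2 + sigma_a**2)
            peak_causals[pk.id] = (k, b_raw, b_std)

    # --- wiring ---------------------------------------------------------------
    peak_by_id = {p.id: p for p in peaks}
    gene_by_id = {g.id: g for g in genes}
    if edges is not None:
        candidate_edges = [(peak_by_id[p], gene_by_id[g]) for p, g in edges]
    else:
        candidate_edges = [
            (pk, g) for pk in peaks for g in genes if g.chrom == pk.chrom
        ]
    base_w: dict[tuple[str, str], float] = {}
    for pk, g in candidate_edges:
        d = _peak_tss_dist(pk, g)
        if edges is None and d > max_wiring_dist:
            continue
        if edges is None and p_edge < 1.0 and rng.random() >= p_edge:
            continue
        if wiring_kind == "fixed_magnitude":
            mag = wiring_scale
        elif wiring_kind == "normal":
            mag = float(rng.normal(0.0, wiring_scale))
        else:
            raise ValueError(f"unknown wiring_kind {wiring_kind!r}")
        sign = 1.0 if rng.random() < 0.5 else -1.0
        w = sign * mag * np.exp(-d / wiring_decay)
        base_w[(pk.id, g.id)] = w
    wiring: dict[tuple[str, str, str], float] = {}
    for ctx in contexts:
        for (pid, gid), w in base_w.items():
            if rng.random() < prop_active_per_context:
                wiring[(pid, gid, ctx)] = w

    # --- disease effects ------------------------------------------------------
    gamma = {
        g.id: float(rng.normal(0.0, gamma_scale)) if rng.random() < disease_gene_frac else 0.0
        for g in genes
    }
    delta = {
        pk.id: float(rng.normal(0.0, delta_scale)) if rng.random() < disease_peak_frac else 0.0
        for pk in peaks
    }
    direct = np.zeros(m)
    if p_causal_direct > 0 and direct_scale > 0:
        hit = rng.random(m) < p_causal_direct
        direct[hit] = rng.normal(0.0, direct_scale, size=int(hit.sum()))

    model = _derive_truths(
        panel, peaks, genes, list(contexts), peak_causals, wiring, gamma, delta,
        direct, sigma_a, sigma_e, sigma_y, contexts[0],
    )

    if target_h2_snp is not None:
        rho = 0.0 if target_prop_mediated is None else float(target_prop_mediated)
        model = _calibrate(model, panel, target_h2_snp, rho, sigma_y)
    return model


def assemble_regulatory_model(
    panel: GenotypePanel,
    peaks: list[Peak],
    genes: list[Gene],
    contexts: list[str],
    peak_causals: dict[str, tuple[int, float]],
    wiring: dict[tuple[str, str, str], float],
    gamma: dict[str, float] | None = None,
    delta: dict[str, float] | None = None,
    direct: np.ndarray | None = None,
    sigma_a: float = 1.0,
    sigma_e: float = 1.0,
    sigma_y: float = 1.0,
    disease_context: str | None = None,
) -> RegulatoryModel:
    """Build a model from explicit components (nothing is drawn).

    ``peak_causals`` maps peak id -> (variant index, standardized effect
    b_std in (-1, 1)); ``wiring`` maps (peak id, gene id, context) -> weight
    on the standardized peak latent. Useful for planting exact architectures
    in tests and demonstrations.
    """
    causals3: dict[str, tuple[int, float, float]] = {}
    for pid, (k, b_std) in peak_causals.items():
        if not (-1 < b_std < 1):
            raise ValueError("b_std must lie in (-1, 1)")
        b_raw = b_std * sigma_a / np.sqrt(1 - b_std**2)
        causals3[pid] = (int(k), float(b_raw), float(b_std))
    return _derive_truths(
        panel, peaks, genes, list(contexts), causals3, dict(wiring),
        dict(gamma or {}), dict(delta or {}),
        np.zeros(panel.n_variants) if direct is None else np.asarray(direct, float),
        sigma_a, sigma_e, sigma_y,
        disease_context if disease_context is not None else contexts[0],
    )


def _derive_truths(
    panel, peaks, genes, contexts, peak_causals, wiring, gamma, delta,
    direct, sigma_a, sigma_e, sigma_y, disease_context,
) -> RegulatoryModel:
    m = panel.n_variants
    peak_by_id = {p.id: p for p in peaks}
    b_std = {pid: v[2] for pid, v in peak_causals.items()}
    k_of = {pid: v[0] for pid, v in peak_causals.items()}

    # per-context gene standardization and cis effects
    alpha_e: dict[str, dict] = {}
    h2_cis_gene: dict[str, dict] = {}
    gene_sd: dict[str, dict] = {}
    for ctx in contexts:
        alpha_e[ctx], h2_cis_gene[ctx], gene_sd[ctx] = {}, {}, {}
        for g in genes:
            edges = [(pid, w) for (pid, gid, c), w in wiring.items() if gid == g.id and c == ctx]
            # Var(sum w a) with Cov(a_p, a_q) = b_p b_q r_{kp,kq} (p != q), Var = 1
            var_sig = 0.0
            for i, (pi, wi) in enumerate(edges):
                for pj, wj in edges:
                    if pi == pj:
                        continue
                    if pi in k_of and pj in k_of:
                        var_sig += wi * wj * b_std[pi] * b_std[pj] * _pair_r(panel, k_of[pi], k_of[pj])
                var_sig += wi * wi
            var_raw = var_sig + sigma_e**2
            sd = np.sqrt(var_raw)
            gene_sd[ctx][g.id] = float(sd)
            a_vec = np.zeros(m)
            for pid, w in edges:
                if pid in k_of:
                    a_vec[k_of[pid]] += (w / sd) * b_std[pid]
            idx = np.flatnonzero(a_vec)
            alpha_e[ctx][g.id] = (idx, a_vec[idx])
            h2_cis_gene[ctx][g.id] = _block_quadratic(panel, a_vec)

    alpha_ca = {
        pid: (np.array([k_of[pid]]), np.array([b_std[pid]])) for pid in peak_causals
    }
    h2_cis_peak = {pid: float(b_std[pid] ** 2) for pid in peak_causals}

    # disease composition in the disease context
    ctx = disease_context
    c_p: dict[str, float] = {}
    for pk in peaks:
        c = delta.get(pk.id, 0.0)
        for (pid, gid, cc), w in wiring.items():
            if pid == pk.id and cc == ctx:
                c += gamma.get(gid, 0.0) * (w / gene_sd[ctx][gid])
        c_p[pk.id] = c

    u_ca = np.zeros(m)
    for pid in peak_causals:
        u_ca[k_of[pid]] += c_p[pid] * b_std[pid]
    u_e = np.zeros(m)
    for g in genes:
        idx, a = alpha_e[ctx][g.id]
        u_e[idx] += gamma.get(g.id, 0.0) * a

    # orthogonalize the direct effects against the mediated component in the
    # R inner product: the realized mediated/direct covariance is exactly 0,
    # so the truth-conservation invariant h2_med <= h2_snp always holds and
    # scored variants carry no systematic excess from the direct channel
    v_u0 = _block_quadratic(panel, u_ca)
    if v_u0 > 0 and np.any(direct):
        inner = 0.5 * (
            _block_quadratic(panel, u_ca + direct) - v_u0 - _block_quadratic(panel, direct)
        )
        direct = direct - (inner / v_u0) * u_ca

    t = u_ca + direct
    v_t = _block_quadratic(panel, t)
    v_ca = _block_quadratic(panel, u_ca)
    v_e = _block_quadratic(panel, u_e)
    nongen = (
        sum(c_p[pid] ** 2 * (1 - b_std.get(pid, 0.0) ** 2) for pid in c_p if pid in b_std)
        + sum(c_p[pid] ** 2 for pid in c_p if pid not in b_std)
        + sum(gamma.get(g.id, 0.0) ** 2 * (sigma_e**2 / gene_sd[ctx][g.id] ** 2) for g in genes)
        + sigma_y**2
    )
    var_y = v_t + nongen
    beta = t / np.sqrt(var_y)
    peak_med = {
        pid: (c_p[pid] * b_std[pid]) ** 2 / var_y for pid in peak_causals
    }

    return RegulatoryModel(
        peaks=peaks,
        genes=genes,
        contexts=contexts,
        peak_causals=peak_causals,
        wiring=wiring,
        gamma=gamma,
        delta=delta,
        direct=direct,
        sigma_a=sigma_a,
        sigma_e=sigma_e,
        disease_context=disease_context,
        alpha_ca=alpha_ca,
        alpha_e=alpha_e,
        h2_cis_peak=h2_cis_peak,
        h2_cis_gene=h2_cis_gene,
        beta=beta,
        h2_snp=v_t / var_y,
        h2_med_ca=v_ca / var_y,
        h2_med_e=v_e / var_y,
        h2_med_union=v_ca / var_y,
        var_y=var_y,
        gene_sd=gene_sd,
        peak_med_contribution=peak_med,
    )


def _calibrate(
    model: RegulatoryModel,
    panel: GenotypePanel,
    H: float,
    rho: float,
    sigma_y: float,
) -> RegulatoryModel:
    """Rescale mediated (gamma, delta) and direct effects so that
    h2_snp == H and h2_med_ca/h2_snp == rho exactly."""
    if not (0 < H < 1) or not (0 <= rho <= 1):
        raise ValueError("need 0 < target_h2_snp < 1 and 0 <= prop_mediated <= 1")
    m = panel.n_variants
    ctx = model.disease_context
    # current unscaled components
    u_ca = np.zeros(m)
    b_std = {pid: v[2] for pid, v in model.peak_causals.items()}
    k_of = {pid: v[0] for pid, v in model.peak_causals.items()}
    c_p = {}
    for pk in model.peaks:
        c = model.delta.get(pk.id, 0.0)
        for (pid, gid, cc), w in model.wiring.items():
            if pid == pk.id and cc == ctx:
                c += model.gamma.get(gid, 0.0) * (w / model.gene_sd[ctx][gid])
        c_p[pk.id] = c
    for pid in model.peak_causals:
        u_ca[k_of[pid]] += c_p[pid] * b_std[pid]
    v_u = _block_quadratic(panel, u_ca)
    v_d = _block_quadratic(panel, model.direct)
    cross = 0.5 * (
        _block_quadratic(panel, u_ca + model.direct) - v_u - v_d
    )
    ng_med = (
        sum(c_p[pid] ** 2 * (1 - b_std.get(pid, 0.0) ** 2) for pid in c_p if pid in b_std)
        + sum(c_p[pid] ** 2 for pid in c_p if pid not in b_std)
        + sum(
            model.gamma.get(g.id, 0.0) ** 2
            * (model.sigma_e**2 / model.gene_sd[ctx][g.id] ** 2)
            for g in model.genes
        )
    )
    if rho > 0 and v_u <= 0:
        raise ValueError("no mediated genetic variance to calibrate against")
    if rho < 1 and v_d <= 0 and H > 0:
        raise ValueError("no direct effects to carry non-mediated heritability")

    if rho == 0:
        s = 0.0
        var_y = sigma_y**2 / (1 - H)
        s_d = np.sqrt(H * var_y / v_d) if H > 0 else 0.0
    else:
        denom = v_u * (1 - H) - rho * H * ng_med
        if denom <= 0:
            raise ValueError("infeasible (h2_snp, prop_mediated) target for this architecture")
        s = np.sqrt(rho * H * sigma_y**2 / denom)
        var_y = (s**2 * ng_med + sigma_y**2) / (1 - H)
        B = (1 - rho) * H * var_y
        if B <= 0:
            s_d = 0.0
        else:
            sc = s * cross
            s_d = (-sc + np.sqrt(sc**2 + v_d * B)) / v_d

    gamma = {k: s * v for k, v in model.gamma.items()}
    delta = {k: s * v for k, v in model.delta.items()}
    direct = s_d * model.direct
    return _derive_truths(
        panel, model.peaks, model.genes, model.contexts, model.peak_causals,
        model.wiring, gamma, delta, direct, model.sigma_a, model.sigma_e,
        sigma_y, model.disease_context,
    )


# ----------------------------------------------------------------------------
# molecular phenotypes
# ----------------------------------------------------------------------------

def simulate_latent_phenotypes(
    panel: GenotypePanel,
    model: RegulatoryModel,
    context: str,
    seed: int = 0,
) -> tuple[PhenotypeMatrix, PhenotypeMatrix]:
    """Standardized latent accessibility and expression (no count noise)."""
    if context not in model.contexts:
        raise ValueError(f"unknown context {context!r}")
    rng = derive_rng(seed, "latent", context)
    x = panel.standardized_dosages()
    n = panel.n_samples
    acc = np.zeros((len(model.peaks), n))
    for i, pk in enumerate(model.peaks):
        entry = model.peak_causals.get(pk.id)
        noise = rng.normal(size=n)
        if entry is None:
            acc[i] = noise
        else:
            k, _, b = entry
            acc[i] = b * x[:, k] + np.sqrt(max(0.0, 1 - b**2)) * noise
    peak_row = {pk.id: i for i, pk in enumerate(model.peaks)}
    expr = np.zeros((len(model.genes), n))
    for i, g in enumerate(model.genes):
        sd = model.gene_sd[context][g.id]
        raw = model.sigma_e * rng.normal(size=n)
        for (pid, gid, ctx), w in model.wiring.items():
            if gid == g.id and ctx == context:
                raw = raw + w * acc[peak_row[pid]]
        expr[i] = raw / sd
    a = PhenotypeMatrix([p.id for p in model.peaks], list(panel.sample_ids), acc, "latent")
    e = PhenotypeMatrix([g.id for g in model.genes], list(panel.sample_ids), expr, "latent")
    return a, e


def simulate_molecular_phenotypes(
    panel: GenotypePanel,
    model: RegulatoryModel,
    context: str,
    mean_depth: float = 50.0,
    dispersion: float = 0.1,
    seed: int = 0,
    count_scale: float = 0.5,
    libsize_sd: float = 0.2,
    abundance_sd: float = 1.0,
) -> tuple[PhenotypeMatrix, PhenotypeMatrix]:
    """Negative-binomial read counts driven by the latent phenotypes.

    The count mean for feature f in sample i is
    ``lib_i * exp(base_f + count_scale * latent_fi)`` with per-sample library
    factors ``lib_i`` lognormal around 1 and per-feature log-abundances
    ``base_f ~ Normal(log(mean_depth), abundance_sd^2)``. ``dispersion`` is
    the negative-binomial overdispersion (0 -> Poisson). Latent truths are
    attached on the returned matrices as ``.latent``.
    """
    lat_a, lat_e = simulate_latent_phenotypes(panel, model, context, seed)
    rng = derive_rng(seed, "counts", context)
    out = []
    for lat in (lat_a, lat_e):
        nf, n = lat.values.shape
        lib = rng.lognormal(mean=0.0, sigma=libsize_sd, size=n)
        lib /= lib.mean()
        base = rng.normal(np.log(mean_depth), abundance_sd, size=nf)
        mu = np.exp(base[:, None] + count_scale * lat.values) * lib[None, :]
        if dispersion > 0:
            r = 1.0 / dispersion
            counts = rng.negative_binomial(r, r / (r + mu))
        else:
            counts = rng.poisson(mu)
        pm = PhenotypeMatrix(list(lat.feature_ids), list(lat.sample_ids), counts.astype(np.int64), "raw_counts")
        pm.latent = lat.values  # type: ignore[attr-defined]
        out.append(pm)
    return out[0], out[1]


# ----------------------------------------------------------------------------
# summary statistics
# ----------------------------------------------------------------------------

def _repair_psd(R: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh((R + R.T) / 2)
    if w.min() >= -1e-10:
        return R
    logger.warning("LD block not PSD (min eig %.3g); clipping", w.min())
    w = np.clip(w, 0.0, None)
    R2 = (V * w) @ V.T
    d = np.sqrt(np.clip(np.diag(R2), 1e-12, None))
    R2 = R2 / np.outer(d, d)
    np.fill_diagonal(R2, 1.0)
    return R2


def simulate_gwas_summary(
    panel: GenotypePanel,
    model: RegulatoryModel,
    n_gwas: int,
    seed: int = 0,
    trait_id: str = "disease",
) -> SummaryStats:
    """GWAS summary statistics from z ~ MVN(sqrt(N) R beta, R) per LD block."""
    beta = model.beta
    rng = derive_rng(seed, "gwas", trait_id)
    z = np.empty(panel.n_variants)
    sqn = np.sqrt(n_gwas)
    for b in panel.ld_blocks:
        R = _repair_psd(b.R)
        mean = sqn * (R @ beta[b.start : b.stop])
        L = np.linalg.cholesky(R + 1e-10 * np.eye(R.shape[0]))
        z[b.start : b.stop] = mean + L @ rng.normal(size=R.shape[0])
    table = panel.variants[["id", "chrom", "pos", "ref", "alt"]].rename(columns={"id": "variant_id"}).copy()
    table["beta"] = z / sqn
    table["se"] = 1.0 / sqn
    return SummaryStats.from_beta_se(trait_id, "disease", "gwas_sim", n_gwas, table)


@dataclass
class QtlStudy:
    """One simulated QTL study: per-feature cis scans at a given sample size."""

    study_id: str
    n: int
    context: str
    results: list  # list[CisResult]

    def by_feature(self) -> dict[str, object]:
        return {r.feature_id: r for r in self.results}


def simulate_eqtl_studies(
    panel: GenotypePanel,
    model: RegulatoryModel,
    sample_sizes: list[int],
    context: str,
    seed: int = 0,
    cis_window: int = 1_000_000,
    maf_min: float = 0.05,
) -> list[QtlStudy]:
    """Independent eQTL studies sharing the model's true effects.

    For each study an independent genotype sample is drawn from the panel's
    population, latent expression is simulated under the shared architecture,
    inverse-normal transformed, and cis-mapped with the qtlmap module.
    """
    from . import qtlmap  # deferred to avoid import cycle

    if any(n < 10 for n in sample_sizes):
        raise ValueError("study sample sizes must be >= 10")
    studies = []
    for i, n in enumerate(sample_sizes):
        sub_seed = derive_seed(seed, "study", i)
        sub = resample_panel(panel, n, sub_seed)
        _, expr = simulate_latent_phenotypes(sub, model, context, sub_seed)
        normed = qtlmap.inverse_normal_transform(expr)
        anchors = {g.id: (g.chrom, g.tss) for g in model.genes}
        results = qtlmap.map_cis_qtl(
            sub, normed, covariates=None, anchors=anchors,
            cis_window=cis_window, maf_min=maf_min, trait_type="eQTL",
        )
        studies.append(QtlStudy(f"study{i}", n, context, results))
    return studies


# ----------------------------------------------------------------------------
# fixture export / import
# ----------------------------------------------------------------------------

@dataclass
class SimBundle:
    panel: GenotypePanel
    peaks: list[Peak]
    genes: list[Gene]
    acc_counts: PhenotypeMatrix | None = None
    expr_counts: PhenotypeMatrix | None = None
    gwas: SummaryStats | None = None
    truth: dict = field(default_factory=dict)


def export_fixture(bundle: SimBundle, directory: str, overwrite: bool = False) -> list[str]:
    """Write the bundle as plain-text files (BED/TSV/JSON); round-trip exact."""
    if os.path.isdir(directory) and os.listdir(directory) and not overwrite:
        raise FileExistsError(f"{directory} exists and is not empty")
    os.makedirs(directory, exist_ok=True)
    written = []

    def _w(name: str) -> str:
        path = os.path.join(directory, name)
        written.append(path)
        return path

    bundle.panel.variants.to_csv(_w("variants.tsv"), sep="\t", index=False)
    pd.DataFrame(
        bundle.panel.dosages,
        index=bundle.panel.sample_ids,
        columns=bundle.panel.variants["id"],
    ).to_csv(_w("dosages.tsv"), sep="\t")
    with open(_w("peaks.bed"), "w") as fh:
        for p in bundle.peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.id}\n")
    pd.DataFrame(
        [(g.id, g.chrom, g.tss, g.strand) for g in bundle.genes],
        columns=["id", "chrom", "tss", "strand"],
    ).to_csv(_w("genes.tsv"), sep="\t", index=False)
    for name, pm in (("acc_counts", bundle.acc_counts), ("expr_counts", bundle.expr_counts)):
        if pm is not None:
            pm.to_frame().to_csv(_w(f"{name}.tsv"), sep="\t")
    if bundle.gwas is not None:
        bundle.gwas.table.to_csv(_w("gwas.tsv"), sep="\t", index=False)
    with open(_w("truth.json"), "w") as fh:
        json.dump(bundle.truth, fh, indent=2, sort_keys=True)
    return written


def import_fixture(directory: str) -> SimBundle:
    variants = pd.read_csv(os.path.join(directory, "variants.tsv"), sep="\t")
    dos = pd.read_csv(os.path.join(directory, "dosages.tsv"), sep="\t", index_col=0)
    panel = GenotypePanel(
        variants,
        list(dos.index),
        dos.to_numpy(dtype=np.int8),
        [],
        {},
    )
    peaks = []
    with open(os.path.join(directory, "peaks.bed")) as fh:
        for line in fh:
            c, s, e, pid = line.rstrip("\n").split("\t")[:4]
            peaks.append(Peak(c, int(s), int(e), pid))
    gt = pd.read_csv(os.path.join(directory, "genes.tsv"), sep="\t")
    genes = [Gene(r.id, r.chrom, int(r.tss), r.strand) for r in gt.itertuples()]
    bundle = SimBundle(panel, peaks, genes)
    for name in ("acc_counts", "expr_counts"):
        path = os.path.join(directory, f"{name}.tsv")
        if os.path.exists(path):
            df = pd.read_csv(path, sep="\t", index_col=0)
            setattr(
                bundle,
                name,
                PhenotypeMatrix(list(df.index), list(df.columns), df.to_numpy(), "raw_counts"),
            )
    gpath = os.path.join(directory, "gwas.tsv")
    if os.path.exists(gpath):
        table = pd.read_csv(gpath, sep="\t")
        bundle.gwas = SummaryStats(
            "disease", "disease", "gwas_sim", int(table["n"].iloc[0]), table
        )
    with open(os.path.join(directory, "truth.json")) as fh:
        bundle.truth = json.load(fh)
    return bundle
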