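"""Candidate-locus selection and Bayesian colocalization.

Loci are screened with a three-condition filter (lead disease association,
lead QTL association, and a chi-square overlap requirement), then scored
under the five-configuration single-shared-variant model using Wakefield
approximate Bayes factors averaged over a prior effect-variance grid:

    H0 no association | H1 trait-1 only | H2 trait-2 only |
    H3 two distinct causal variants | H4 one shared causal variant

The posterior of the shared-variant configuration (``pp_shared``, reported
as PP[4]) is thresholded at 0.98 to call a locus colocalized.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .datatypes import (
    CandidateLocus,
    CisResult,
    ColocPriors,
    ColocResult,
    ColocalizedPair,
    GenotypePanel,
    SummaryStats,
)

logger = logging.getLogger("qtlcoloc")

__all__ = [
    "wakefield_log_abf",
    "colocalize_region",
    "select_candidate_loci",
    "classify_locus_sets",
    "pair_caqtl_eqtl",
    "harmonize",
]


def wakefield_log_abf(
    beta: np.ndarray | float,
    se: np.ndarray | float,
    W_grid: tuple[float, ...] = (0.01, 0.1, 0.5),
) -> np.ndarray | float:
    """Log approximate Bayes factor for association at a single variant.

    For prior effect variance W and V = se^2, z = beta/se:
    ``log BF = 0.5 log(V / (V + W)) + (z^2 / 2) W / (V + W)``; the result is
    the log of the arithmetic mean of the BFs over the grid, evaluated with
    log-sum-exp for stability.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    V = se**2
    z2 = (beta / se) ** 2
    W = np.asarray(W_grid, dtype=float)
    r = W / (V[..., None] + W)
    log_bf = 0.5 * np.log1p(-r) + 0.5 * z2[..., None] * r
    out = logsumexp(log_bf, axis=-1) - np.log(len(W))
    return out if out.ndim else float(out)


def _log_diff_exp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)), clamped at -inf when b >= a (with warning)."""
    if b >= a:
        if b > a + 1e-9:
            logger.warning("negative distinct-configuration mass clamped to 0")
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def colocalize_region(
    stats1: pd.DataFrame,
    stats2: pd.DataFrame,
    priors: ColocPriors = ColocPriors(),
    pp_threshold: float = 0.98,
    locus: CandidateLocus | None = None,
) -> ColocResult:
    """Posterior over the five causal configurations for one locus.

    ``stats1``/``stats2`` are summary tables restricted to the locus window;
    they are intersected on shared variants (allele-harmonized) before
    scoring. All configuration sums are evaluated in log space.
    """
    merged = harmonize(stats1, stats2)
    if len(merged) < 2:
        raise ValueError("need at least 2 shared variants in the region")
    l1 = wakefield_log_abf(merged["beta_1"].to_numpy(), merged["se_1"].to_numpy(), priors.W_grid)
    l2 = wakefield_log_abf(merged["beta_2"].to_numpy(), merged["se_2"].to_numpy(), priors.W_grid)
    log_s0 = 0.0
    log_sum1 = logsumexp(l1)
    log_sum2 = logsumexp(l2)
    log_sum12 = logsumexp(l1 + l2)
    log_s1 = np.log(priors.p1) + log_sum1
    log_s2 = np.log(priors.p2) + log_sum2
    log_s4 = np.log(priors.p12) + log_sum12
    log_s3 = np.log(priors.p1) + np.log(priors.p2) + _log_diff_exp(log_sum1 + log_sum2, log_sum12)
    logs = np.array([log_s0, log_s1, log_s2, log_s3, log_s4])
    pp = np.exp(logs - logsumexp(logs))
    pp /= pp.sum()
    return ColocResult(locus, pp, bool(pp[4] > pp_threshold), len(merged))


def harmonize(stats1: pd.DataFrame, stats2: pd.DataFrame) -> pd.DataFrame:
    """Intersect two summary tables on shared variants, aligning alleles.

    Records with swapped ref/alt get their second-trait beta sign flipped;
    strand-ambiguous common variants (A/T or C/G with MAF > 0.4, when a
    frequency column is available) and irreconcilable allele pairs are
    dropped.
    """
    m = stats1.merge(stats2, on="variant_id", suffixes=("_1", "_2"))
    if m.empty:
        return m
    same = (m["ref_1"] == m["ref_2"]) & (m["alt_1"] == m["alt_2"])
    flipped = (m["ref_1"] == m["alt_2"]) & (m["alt_1"] == m["ref_2"]) & ~same
    m = m[same | flipped].copy()
    flip = flipped[same | flipped]
    m.loc[flip, "beta_2"] = -m.loc[flip, "beta_2"]
    pair = m["ref_1"] + m["alt_1"]
    ambiguous = pair.isin(["AT", "TA", "CG", "GC"])
    if "maf_1" in m.columns:
        ambiguous &= m["maf_1"] > 0.4
        m = m[~ambiguous]
    return m


def select_candidate_loci(
    disease: SummaryStats,
    qtl: list[CisResult],
    p_disease_max: float = 1e-6,
    p_qtl_max: float = 1e-4,
    overlap_frac: float = 0.8,
    half_window: int = 100_000,
) -> list[CandidateLocus]:
    """Three-condition candidate-locus filter with greedy lead masking.

    Disease lead variants are visited in ascending p until ``p_disease_max``;
    leads falling inside an already-emitted window are skipped. For each
    window, every QTL feature whose in-window lead p is below ``p_qtl_max``
    is kept if some shared variant simultaneously has QTL chi-square at least
    ``overlap_frac`` times the feature's in-window lead chi-square and
    disease chi-square at least ``overlap_frac`` times the in-window disease
    lead chi-square.
    """
    if disease.table.empty:
        return []
    loci: list[CandidateLocus] = []
    emitted: list[tuple[str, int, int]] = []
    dis = disease.table.sort_values(["p", "pos", "variant_id"])
    for row in dis.itertuples():
        if row.p >= p_disease_max:
            break
        if any(c == row.chrom and lo <= row.pos <= hi for c, lo, hi in emitted):
            continue
        lo, hi = row.pos - half_window, row.pos + half_window
        dwin = disease.slice_window(row.chrom, lo, hi)
        d_lead_chisq = float(dwin["chisq"].max())
        any_emitted = False
        for res in qtl:
            qwin = res.table[
                (res.table["chrom"] == row.chrom)
                & (res.table["pos"] >= lo)
                & (res.table["pos"] <= hi)
            ]
            if qwin.empty:
                continue
            q_lead = qwin.loc[qwin["p"].idxmin()]
            if q_lead["p"] >= p_qtl_max:
                continue
            shared = qwin.merge(
                dwin[["variant_id", "chisq"]], on="variant_id", suffixes=("", "_dis")
            )
            c3 = bool(
                (
                    (shared["chisq"] >= overlap_frac * float(q_lead["chisq"]))
                    & (shared["chisq_dis"] >= overlap_frac * d_lead_chisq)
                ).any()
            )
            if not c3:
                continue
            loci.append(
                CandidateLocus(
                    disease_id=disease.trait_id,
                    feature_id=res.feature_id,
                    chrom=str(row.chrom),
                    window=(int(lo), int(hi)),
                    lead_disease_variant=str(row.variant_id),
                    lead_qtl_variant=str(q_lead["variant_id"]),
                    c1=True,
                    c2=True,
                    c3=True,
                )
            )
            any_emitted = True
        if any_emitted:
            emitted.append((str(row.chrom), lo, hi))
    return loci


def classify_locus_sets(
    ca_results: dict[str, list[ColocResult]],
    e_results: dict[str, list[ColocResult]],
    extra_e_results: dict[str, list[ColocResult]] | None = None,
) -> pd.DataFrame:
    """Per-locus labels from caQTL/eQTL colocalization outcomes.

    Results are keyed by locus id; a locus is labelled by whether any caQTL /
    any eQTL result at it is colocalized. When a second eQTL result set is
    given (meta-analyzed or other-context), the output also records which
    caQTL_only loci convert to ``both``.
    """
    keys = sorted(set(ca_results) | set(e_results) | set(extra_e_results or {}))
    rows = []
    for k in keys:
        ca = any(r.colocalized for r in ca_results.get(k, []))
        e = any(r.colocalized for r in e_results.get(k, []))
        if ca and e:
            label = "both"
        elif ca:
            label = "caQTL_only"
        elif e:
            label = "eQTL_only"
        else:
            label = "none"
        converts = False
        if extra_e_results is not None and label == "caQTL_only":
            converts = any(r.colocalized for r in extra_e_results.get(k, []))
        rows.append({"locus": k, "label": label, "converts_to_both": converts})
    return pd.DataFrame(rows)


def pair_caqtl_eqtl(
    caqtl: list[CisResult],
    eqtl: list[CisResult],
    panel: GenotypePanel,
    peaks_by_id: dict,
    genes_by_id: dict,
    disease: SummaryStats | None = None,
    p_qtl_max: float = 1e-4,
    p_disease_max: float = 1e-6,
    r2_min: float = 0.8,
    half_window: int = 200_000,
    priors: ColocPriors = ColocPriors(),
    pp_threshold: float = 0.98,
) -> list[ColocalizedPair]:
    """Colocalized (peak, gene) pairs with lead-variant LD gating.

    Candidate pairs require both QTL lead p-values below ``p_qtl_max`` and
    lead-variant LD r^2 >= ``r2_min``; when a disease summary set is given, a
    disease association below ``p_disease_max`` inside the window is also
    required. Colocalization is evaluated on variants within ``half_window``
    of the peak, and emitted pairs carry the peak-to-TSS distance.
    """
    from .herit import peak_tss_distance  # deferred: avoids import cycle

    var_index = {v: i for i, v in enumerate(panel.variants["id"])}
    X = panel.standardized_dosages()
    out: list[ColocalizedPair] = []
    for ca in caqtl:
        if ca.lead_p >= p_qtl_max:
            continue
        peak = peaks_by_id.get(ca.feature_id)
        if peak is None:
            continue
        lo = max(0, peak.start - half_window)
        hi = peak.end + half_window
        for eq in eqtl:
            if eq.lead_p >= p_qtl_max:
                continue
            gene = genes_by_id.get(eq.feature_id)
            if gene is None or gene.chrom != peak.chrom:
                continue
            i = var_index.get(ca.lead_variant)
            j = var_index.get(eq.lead_variant)
            if i is None or j is None:
                logger.warning(
                    "lead variant missing from panel for pair (%s, %s); skipped",
                    ca.feature_id,
                    eq.feature_id,
                )
                continue
            r = float(np.corrcoef(X[:, i], X[:, j])[0, 1]) if i != j else 1.0
            if r**2 < r2_min:
                continue
            if disease is not None:
                dwin = disease.slice_window(peak.chrom, lo, hi)
                if dwin.empty or float(dwin["p"].min()) >= p_disease_max:
                    continue
            s1 = ca.table[(ca.table["pos"] >= lo) & (ca.table["pos"] <= hi)]
            s2 = eq.table[(eq.table["pos"] >= lo) & (eq.table["pos"] <= hi)]
            if len(s1) < 2 or len(s2) < 2:
                continue
            try:
                res = colocalize_region(s1, s2, priors, pp_threshold)
            except ValueError:
                continue
            if res.colocalized:
                out.append(
                    ColocalizedPair(
                        peak_id=ca.feature_id,
                        gene_id=eq.feature_id,
                        distance=peak_tss_distance(peak, gene),
                        lead_r2=r**2,
                        pp_shared=res.pp_shared,
                    )
                )
    return out
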