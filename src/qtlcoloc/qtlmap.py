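"""Count normalization, covariate selection and cis-QTL mapping.

The processing chain mirrors standard molecular-QTL practice: TMM library
normalization, a CPM/count expression filter, per-feature inverse-normal
transformation, permutation-based (parallel-analysis) selection of phenotype
principal components, and per-variant linear association within a cis window
after residualizing phenotypes and dosages on covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import derive_rng
from .datatypes import (
    SUMMARY_COLUMNS,
    CisResult,
    GenotypePanel,
    PhenotypeMatrix,
    fill_summary_invariants,
)

logger = logging.getLogger("qtlcoloc")

__all__ = [
    "NormalizationRecord",
    "CovariateMatrix",
    "tmm_normalize",
    "filter_features",
    "inverse_normal_transform",
    "select_num_pcs",
    "map_cis_qtl",
]


@dataclass
class NormalizationRecord:
    sample_ids: list[str]
    factors: np.ndarray  # TMM scaling factor per sample, geometric mean 1
    lib_sizes: np.ndarray


@dataclass
class CovariateMatrix:
    sample_ids: list[str]
    values: np.ndarray  # samples x covariates
    labels: list[str]
    k_pheno: int = 0

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != len(self.labels):
            raise ValueError("covariate matrix shape does not match labels")
        if self.values.shape[1] and np.linalg.matrix_rank(self.values) < self.values.shape[1]:
            raise ValueError("covariate matrix is rank deficient")


# ----------------------------------------------------------------------------
# TMM
# ----------------------------------------------------------------------------

def _tmm_factor(
    obs: np.ndarray, ref: np.ndarray, trim_m: float, trim_a: float, weighted: bool = True
) -> float:
    n_o, n_r = obs.sum(), ref.sum()
    ok = (obs > 0) & (ref > 0)
    if ok.sum() == 0:
        return 1.0
    p_o, p_r = obs[ok] / n_o, ref[ok] / n_r
    M = np.log2(p_o / p_r)
    A = 0.5 * np.log2(p_o * p_r)
    # asymptotic (delta-method) variance of M, used as precision weights
    v = (n_o - obs[ok]) / (n_o * obs[ok]) + (n_r - ref[ok]) / (n_r * ref[ok])
    if np.allclose(M, 0.0, atol=1e-10):
        return 1.0
    n = len(M)
    rank_m = stats.rankdata(M, method="ordinal")
    rank_a = stats.rankdata(A, method="ordinal")
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if keep.sum() == 0:
        return 1.0
    if weighted:
        f = np.sum(M[keep] / v[keep]) / np.sum(1.0 / v[keep])
    else:
        f = np.mean(M[keep])
    return float(2.0**f)


def tmm_normalize(
    counts: PhenotypeMatrix,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
    weighted: bool = True,
) -> tuple[NormalizationRecord, PhenotypeMatrix]:
    """Trimmed-mean-of-M-values normalization and CPM against effective library sizes.

    The reference sample is the library whose 75th-percentile count fraction
    is closest to the mean across samples; per-sample factors are
    precision-weighted means of doubly trimmed log-ratios, renormalized to
    geometric mean 1. ``weighted=False`` drops the precision weights (plain
    trimmed mean), which makes the factors depend on count fractions only.
    """
    x = counts.values.astype(float)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    lib = x.sum(axis=0)
    zero = np.flatnonzero(lib == 0)
    if len(zero):
        raise ValueError(f"all-zero count samples: {[counts.sample_ids[i] for i in zero]}")
    q75 = np.array([np.quantile(x[:, i] / lib[i], 0.75) for i in range(x.shape[1])])
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    factors = np.array(
        [_tmm_factor(x[:, i], x[:, ref_idx], trim_m, trim_a, weighted) for i in range(x.shape[1])]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    cpm = x / (lib * factors)[None, :] * 1e6
    record = NormalizationRecord(list(counts.sample_ids), factors, lib)
    out = PhenotypeMatrix(list(counts.feature_ids), list(counts.sample_ids), cpm, "cpm")
    return record, out


def filter_features(
    counts: PhenotypeMatrix,
    cpm: PhenotypeMatrix,
    cpm_min: float = 0.8,
    count_min: int = 10,
    max_fail_frac: float = 0.2,
) -> list[str]:
    """Drop features failing (CPM < cpm_min or count < count_min) in more than
    ``max_fail_frac`` of samples (strict inequality); keep original order."""
    if counts.feature_ids != cpm.feature_ids or counts.sample_ids != cpm.sample_ids:
        raise ValueError("counts and cpm matrices are not aligned")
    fail = (cpm.values < cpm_min) | (counts.values < count_min)
    frac = fail.mean(axis=1)
    return [f for f, fr in zip(counts.feature_ids, frac) if fr <= max_fail_frac]


def inverse_normal_transform(matrix: PhenotypeMatrix) -> PhenotypeMatrix:
    """Per-feature rank-based transform to a standard normal: Phi^-1((r-0.5)/n)."""
    vals = np.asarray(matrix.values, dtype=float)
    if np.isnan(vals).any():
        raise ValueError("missing values not supported")
    n = vals.shape[1]
    out = np.empty_like(vals)
    for i, row in enumerate(vals):
        if np.all(row == row[0]):
            logger.warning("constant feature %s -> zeros", matrix.feature_ids[i])
            out[i] = 0.0
            continue
        ranks = stats.rankdata(row, method="average")
        out[i] = stats.norm.ppf((ranks - 0.5) / n)
    return PhenotypeMatrix(list(matrix.feature_ids), list(matrix.sample_ids), out, "normalized")


# ----------------------------------------------------------------------------
# parallel analysis (permutation PC selection)
# ----------------------------------------------------------------------------

def _eigenvalues(x: np.ndarray) -> np.ndarray:
    """Nonzero eigenvalues of the sample covariance (samples as observations)."""
    xc = x - x.mean(axis=1, keepdims=True)
    # dual trick: spectrum of the smaller Gram matrix equals the covariance spectrum
    s = np.linalg.svd(xc, compute_uv=False)
    return s**2 / (x.shape[1] - 1)


def select_num_pcs(
    matrix: PhenotypeMatrix,
    n_perm: int = 99,
    alpha: float = 0.05,
    seed: int = 0,
) -> int:
    """Permutation parallel analysis for the number of phenotype PCs.

    Each permutation independently shuffles every feature's values across
    samples; the retained K is the number of leading observed eigenvalues
    exceeding the (1 - alpha) permutation quantile of the same-rank
    eigenvalue, stopping at the first failure.
    """
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19")
    rng = derive_rng(seed, "parallel-analysis")
    x = np.asarray(matrix.values, dtype=float)
    obs = _eigenvalues(x)
    kmax = len(obs)
    perm_eigs = np.empty((n_perm, kmax))
    for p in range(n_perm):
        xp = np.array([rng.permutation(row) for row in x])
        e = _eigenvalues(xp)
        perm_eigs[p, : len(e)] = e[:kmax]
    thresh = np.quantile(perm_eigs, 1 - alpha, axis=0)
    k = 0
    for lam, th in zip(obs, thresh):
        if lam > th:
            k += 1
        else:
            break
    return k


# ----------------------------------------------------------------------------
# cis mapping
# ----------------------------------------------------------------------------

def _residualize(y: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Project out span(Q) from the columns of y (y: n x k)."""
    coef, *_ = np.linalg.lstsq(Q, y, rcond=None)
    return y - Q @ coef


def _cis_mask(
    variants: pd.DataFrame, anchor: tuple, window: int
) -> np.ndarray:
    chrom = anchor[0]
    pos = variants["pos"].to_numpy()
    on_chrom = (variants["chrom"] == chrom).to_numpy()
    if len(anchor) == 2:  # point anchor (TSS)
        return on_chrom & (np.abs(pos - anchor[1]) <= window)
    start, end = anchor[1], anchor[2]  # 0-based half-open interval
    inside = (pos > start) & (pos <= end)
    dist = np.where(pos <= start, start + 1 - pos, pos - end)
    return on_chrom & (inside | (dist <= window))


def map_cis_qtl(
    panel: GenotypePanel,
    phenos: PhenotypeMatrix,
    covariates: CovariateMatrix | np.ndarray | None,
    anchors: dict[str, tuple],
    cis_window: int = 200_000,
    maf_min: float = 0.05,
    trait_type: str = "caQTL",
) -> list[CisResult]:
    """Per-variant linear cis association after covariate residualization.

    Anchors map feature ids to ``(chrom, tss)`` points or
    ``(chrom, start, end)`` intervals; the window is measured from the anchor
    point or the nearest interval edge. Variants with in-sample MAF below
    ``maf_min`` are excluded. Betas/SEs come from simple regression of the
    residualized phenotype on the residualized dosage with
    ``df = n - 2 - n_covariates``, which matches the full multiple-regression
    fit by Frisch-Waugh.
    """
    if phenos.sample_ids != list(panel.sample_ids):
        raise ValueError("phenotype and panel samples are not aligned")
    n = panel.n_samples
    if isinstance(covariates, CovariateMatrix):
        C = covariates.values
    elif covariates is None:
        C = np.empty((n, 0))
    else:
        C = np.asarray(covariates, dtype=float)
    Q = np.column_stack([np.ones(n), C])
    df = n - 2 - C.shape[1]
    if df < 1:
        raise ValueError("not enough samples for the covariate model")

    maf = panel.empirical_maf()
    keep_maf = maf >= maf_min
    G = _residualize(panel.dosages.astype(float), Q)
    Y = _residualize(phenos.values.T, Q).T  # features x samples
    gss = np.einsum("ij,ij->j", G, G)

    results: list[CisResult] = []
    var_tab = panel.variants
    for fi, fid in enumerate(phenos.feature_ids):
        if fid not in anchors:
            continue
        mask = _cis_mask(var_tab, anchors[fid], cis_window) & keep_maf
        nz = gss > 1e-12
        skipped = mask & ~nz
        if skipped.any():
            logger.debug("feature %s: %d zero-variance dosages skipped", fid, skipped.sum())
        mask &= nz
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            continue
        y = Y[fi]
        gy = y @ G[:, idx]
        beta = gy / gss[idx]
        rss = (y @ y) - beta * gy
        sigma2 = np.clip(rss, 0.0, None) / df
        se = np.sqrt(sigma2 / gss[idx])
        tstat = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
        p = 2.0 * stats.t.sf(np.abs(tstat), df)
        table = var_tab.iloc[idx][["id", "chrom", "pos", "ref", "alt"]].rename(
            columns={"id": "variant_id"}
        )
        table = table.assign(beta=beta, se=se, n=n)
        table = fill_summary_invariants(table)
        # t-based p-value (chi2 fill is asymptotic); keep the exact t p-value
        table["p"] = p
        table = table[SUMMARY_COLUMNS].reset_index(drop=True)
        order = np.lexsort((table["variant_id"], table["pos"], table["p"]))
        lead = table.iloc[order[0]]
        results.append(
            CisResult(fid, trait_type, table, str(lead["variant_id"]), float(lead["p"]))
        )
    return results
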