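"""Stratified and QTL-mediated heritability, cis-heritability, and
peak-to-TSS-distance analyses.

Core regressions relate per-variant GWAS chi-square statistics to LD scores
(per-category enrichment) and to mediation scores built from squared cis
effects of molecular features (mediated heritability):

    E[chisq_j] = 1 + N * sum_c tau_c l_jc + N * sum_d omega_d E_jd

with ``h2_med,d = omega_d * sum_g h2_cis,g`` over the features in set d.
Standard errors come from a delete-one block jackknife over contiguous
variant blocks. Cis-heritability of individual molecular phenotypes is
estimated by Haseman-Elston regression on the cis relatedness matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    Gene,
    GenotypePanel,
    HeritabilityEstimate,
    MediatedDecomposition,
    Peak,
    PhenotypeMatrix,
    SummaryStats,
)

logger = logging.getLogger("qtlcoloc")

__all__ = [
    "LDScores",
    "MediationScores",
    "DistanceAnalysis",
    "compute_ld_scores",
    "stratified_h2_regression",
    "estimate_cis_h2",
    "compute_mediation_scores",
    "mediated_h2_regression",
    "decompose_mediated_h2",
    "mediated_h2_enrichment",
    "annotate_peak_subsets",
    "peak_tss_distance",
    "distance_stratified_h2",
    "tss_window_mediated_h2",
]


# ----------------------------------------------------------------------------
# scores
# ----------------------------------------------------------------------------

@dataclass
class LDScores:
    variant_ids: list[str]
    categories: list[str]
    scores: np.ndarray  # variants x categories
    membership: np.ndarray  # variants x categories, boolean


@dataclass
class MediationScores:
    label: str
    variant_ids: list[str]
    scores: np.ndarray  # E_j per variant
    total_h2_cis: float  # sum over features of alpha' R alpha


def _adjusted_r2_blocks(
    panel: GenotypePanel, window: float, adjust: bool = True
) -> list[tuple[int, np.ndarray]]:
    """Per LD block: (start index, matrix of adjusted r^2 masked to the window).

    r^2 is computed from panel dosages; the unbiased adjustment
    ``r2_adj = r2 - (1 - r2)/(n - 2)`` counters sampling inflation of
    estimated r^2 (disable with ``adjust=False`` for exact population R).
    Pairs farther apart than ``window`` (or in different blocks) contribute
    nothing.
    """
    n = panel.n_samples
    pos = panel.variants["pos"].to_numpy()
    out = []
    for b in panel.ld_blocks:
        r2 = b.R**2
        r2a = r2 - (1.0 - r2) / (n - 2) if adjust else r2
        p = pos[b.start : b.stop]
        near = np.abs(p[:, None] - p[None, :]) <= window
        out.append((b.start, r2a * near))
    return out


def compute_ld_scores(
    panel: GenotypePanel,
    annotations: dict[str, np.ndarray],
    window: float = 1e6,
    adjust: bool = True,
) -> LDScores:
    """Per-variant, per-category LD scores ``l_jc = sum_{k in c} r2_adj_jk``.

    ``annotations`` maps category label -> boolean mask or integer indices
    over panel variants. Categories with no variants get a zero column with
    a warning.
    """
    m = panel.n_variants
    cats = list(annotations)
    member = np.zeros((m, len(cats)), dtype=bool)
    for c, lab in enumerate(cats):
        sel = np.asarray(annotations[lab])
        if sel.dtype == bool:
            member[:, c] = sel
        else:
            member[sel, c] = True
        if member[:, c].sum() == 0:
            logger.warning("LD-score category %r has no variants", lab)
    scores = np.zeros((m, len(cats)))
    for start, r2a in _adjusted_r2_blocks(panel, window, adjust):
        stop = start + r2a.shape[0]
        scores[start:stop] += r2a @ member[start:stop].astype(float)
    return LDScores(list(panel.variants["id"]), cats, scores, member)


def compute_mediation_scores(
    panel: GenotypePanel,
    alpha: dict[str, tuple[np.ndarray, np.ndarray]],
    label: str = "set",
    window: float = 1e6,
    adjust: bool = True,
) -> MediationScores:
    """Mediation ("expression") scores ``E_j = sum_g sum_k r2_adj_jk alpha_kg^2``.

    ``alpha`` maps feature id -> (variant indices, standardized cis effects).
    The recorded total is ``sum_g alpha' R alpha`` over the feature set.
    """
    m = panel.n_variants
    a2 = np.zeros(m)
    total = 0.0
    for idx, vals in alpha.values():
        a2[idx] += np.asarray(vals) ** 2
        v = np.zeros(m)
        v[idx] = vals
        for b in panel.ld_blocks:
            seg = v[b.start : b.stop]
            if np.any(seg):
                total += float(seg @ b.R @ seg)
    scores = np.zeros(m)
    for start, r2a in _adjusted_r2_blocks(panel, window, adjust):
        stop = start + r2a.shape[0]
        scores[start:stop] = r2a @ a2[start:stop]
    return MediationScores(label, list(panel.variants["id"]), scores, total)


# ----------------------------------------------------------------------------
# chi-square regressions with block jackknife
# ----------------------------------------------------------------------------

def _jackknife(values: np.ndarray) -> float:
    """Delete-one jackknife SE from leave-one-block-out estimates."""
    b = len(values)
    if b < 2:
        return float("nan")
    mean = values.mean()
    return float(np.sqrt((b - 1) / b * np.sum((values - mean) ** 2)))


def _drop_collinear(X: np.ndarray, labels: list[str]) -> tuple[np.ndarray, list[str], list[int]]:
    keep: list[int] = []
    for j in range(X.shape[1]):
        trial = keep + [j]
        if np.linalg.matrix_rank(X[:, trial]) == len(trial):
            keep.append(j)
        else:
            logger.warning("dropping collinear column %r", labels[j])
    return X[:, keep], [labels[j] for j in keep], keep


def _chisq_regression(
    chisq: np.ndarray,
    design: np.ndarray,
    labels: list[str],
    n_blocks: int,
    summarize,
    ld_all: np.ndarray | None = None,
) -> tuple[dict, dict, list[np.ndarray]]:
    """Weighted regression of chi-square on the design with block jackknife.

    A first unweighted pass estimates per-variant expected chi-square; the
    second pass uses the standard LD-score-regression weights
    ``1 / (max(l_j, 1) * E[chisq_j]^2)``, which counter both the
    heteroskedasticity of chi-square statistics and the over-counting of
    variants in strong LD. ``summarize(coef)`` maps a coefficient vector
    (intercept first) to a dict of scalar quantities; returns
    (point estimates, jackknife SEs, [coef]).
    """
    m = len(chisq)
    X = np.column_stack([np.ones(m), design])
    X, _, keep = _drop_collinear(X, ["intercept"] + labels)
    # iterated weights: fitted expectations floored at 1 (a chi-square mean
    # below 1 is impossible under the model), LD denominator counters
    # over-counting of variants in strong LD
    denom = np.clip(ld_all, 1.0, None) if ld_all is not None else np.ones(m)
    coef, *_ = np.linalg.lstsq(X, chisq, rcond=None)
    for _ in range(2):
        fitted = np.clip(X @ coef, 1.0, None)
        sw = np.sqrt(1.0 / (denom * fitted**2))
        coef, *_ = np.linalg.lstsq(X * sw[:, None], chisq * sw, rcond=None)
    fitted = np.clip(X @ coef, 1.0, None)
    sw = np.sqrt(1.0 / (denom * fitted**2))
    Xw, yw = X * sw[:, None], chisq * sw

    def _fit(mask: np.ndarray) -> np.ndarray:
        c, *_ = np.linalg.lstsq(Xw[mask], yw[mask], rcond=None)
        return _expand_coef(c, keep, 1 + design.shape[1])

    full = np.ones(m, dtype=bool)
    full_coef = _fit(full)
    point = summarize(full_coef)
    edges = np.linspace(0, m, n_blocks + 1).astype(int)
    reps: dict[str, list[float]] = {k: [] for k in point}
    for a, b in zip(edges[:-1], edges[1:]):
        mask = np.ones(m, dtype=bool)
        mask[a:b] = False
        rep = summarize(_fit(mask))
        for k, v in rep.items():
            reps[k].append(v)
    ses = {k: _jackknife(np.asarray(v)) for k, v in reps.items()}
    return point, ses, [full_coef]


def _expand_coef(coef: np.ndarray, keep: list[int], total: int) -> np.ndarray:
    full = np.zeros(total)
    for c, j in zip(coef, keep):
        full[j] = c
    return full


def _all_category_scores(scores: LDScores) -> np.ndarray | None:
    """LD scores of a category covering every variant, if one exists."""
    for c in range(len(scores.categories)):
        if scores.membership[:, c].all():
            return scores.scores[:, c]
    return None


def _align(disease: SummaryStats, variant_ids: list[str]) -> np.ndarray:
    t = disease.table.set_index("variant_id")
    missing = [v for v in variant_ids if v not in t.index]
    if missing:
        raise ValueError(f"{len(missing)} score variants missing from summary stats")
    return t.loc[variant_ids, "chisq"].to_numpy(dtype=float)


def stratified_h2_regression(
    disease: SummaryStats,
    scores: LDScores,
    m_c: dict[str, int] | None = None,
    n_blocks: int = 20,
) -> HeritabilityEstimate:
    """Stratified LD-score regression with per-category enrichment.

    Regresses chi-square on ``N * l_jc`` with an intercept; per-variant
    expected heritability is ``sum_c tau_c 1{j in c}``, aggregated into
    per-category h2 and enrichment ``(h2_c/h2_tot)/(m_c/m_tot)`` with
    block-jackknife SEs and a one-sided normal p-value for enrichment > 1.
    """
    chisq = _align(disease, scores.variant_ids)
    N = disease.n
    member = scores.membership.astype(float)
    m_tot = member.shape[0]
    counts = {
        lab: (m_c[lab] if m_c else int(member[:, c].sum()))
        for c, lab in enumerate(scores.categories)
    }

    def summarize(full_coef: np.ndarray) -> dict:
        tau = full_coef[1:]
        per_snp = member @ tau
        h2_tot = float(per_snp.sum())
        out = {"h2_snp": h2_tot}
        for c, lab in enumerate(scores.categories):
            h2c = float(per_snp[scores.membership[:, c]].sum())
            out[f"h2::{lab}"] = h2c
            prop_snp = counts[lab] / m_tot
            if h2_tot != 0 and prop_snp > 0:
                out[f"enr::{lab}"] = (h2c / h2_tot) / prop_snp
            else:
                out[f"enr::{lab}"] = float("nan")
        return out

    point, ses, coefs = _chisq_regression(
        chisq, N * scores.scores, scores.categories, n_blocks, summarize,
        ld_all=_all_category_scores(scores),
    )
    tau = coefs[0][1:]
    enr = {lab: point[f"enr::{lab}"] for lab in scores.categories}
    enr_se = {lab: ses[f"enr::{lab}"] for lab in scores.categories}
    enr_p = {}
    for lab in scores.categories:
        se = enr_se[lab]
        enr_p[lab] = (
            float(stats.norm.sf((enr[lab] - 1.0) / se)) if se and np.isfinite(se) and se > 0 else float("nan")
        )
    return HeritabilityEstimate(
        label="sldsc",
        tau=tau,
        tau_labels=list(scores.categories),
        omega=np.array([]),
        omega_labels=[],
        h2_snp=point["h2_snp"],
        h2_med={},
        ratio={},
        se={"h2_snp": ses["h2_snp"], **{f"h2::{k}": ses[f"h2::{k}"] for k in scores.categories}},
        n_blocks=n_blocks,
        intercept=coefs[0][0],
        category_h2={lab: point[f"h2::{lab}"] for lab in scores.categories},
        enrichment=enr,
        enrichment_se=enr_se,
        enrichment_p=enr_p,
    )


def mediated_h2_regression(
    disease: SummaryStats,
    ld: LDScores,
    score_sets: list[MediationScores],
    n_blocks: int = 20,
) -> HeritabilityEstimate:
    """Mediated-heritability regression over one or more mediation-score sets.

    Joint fit of ``E[chisq] = 1 + N tau' l + N sum_d omega_d E_d`` with
    intercept estimated; ``h2_med,d = omega_d * total_d``; the joint (union)
    mediated heritability is the sum over sets from the same fit; ratios are
    taken against ``h2_snp`` from that fit. Negative omegas are reported
    as-is with a warning.
    """
    if not score_sets:
        raise ValueError("need at least one mediation-score set")
    chisq = _align(disease, ld.variant_ids)
    N = disease.n
    member = ld.membership.astype(float)
    E = np.column_stack([s.scores for s in score_sets])
    design = np.column_stack([N * ld.scores, N * E])
    labels = list(ld.categories) + [s.label for s in score_sets]
    n_tau = len(ld.categories)
    totals = np.array([s.total_h2_cis for s in score_sets])

    def summarize(full_coef: np.ndarray) -> dict:
        tau = full_coef[1 : 1 + n_tau]
        omega = full_coef[1 + n_tau :]
        h2_med = omega * totals
        h2_nonmed = float((member @ tau).sum())
        h2_snp = h2_nonmed + float(h2_med.sum())
        out = {"h2_snp": h2_snp, "h2_med_union": float(h2_med.sum())}
        out["ratio_union"] = float(h2_med.sum()) / h2_snp if h2_snp != 0 else float("nan")
        for s, h in zip(score_sets, h2_med):
            out[f"h2_med::{s.label}"] = float(h)
            out[f"ratio::{s.label}"] = float(h) / h2_snp if h2_snp != 0 else float("nan")
        return out

    point, ses, coefs = _chisq_regression(
        chisq, design, labels, n_blocks, summarize, ld_all=_all_category_scores(ld)
    )
    omega = coefs[0][1 + n_tau :]
    if np.any(omega < 0):
        logger.warning("negative omega estimate(s): %s", omega)
    h2_med = {s.label: point[f"h2_med::{s.label}"] for s in score_sets}
    h2_med["union"] = point["h2_med_union"]
    ratio = {s.label: point[f"ratio::{s.label}"] for s in score_sets}
    ratio["union"] = point["ratio_union"]
    se = {
        "h2_snp": ses["h2_snp"],
        "h2_med_union": ses["h2_med_union"],
        "ratio_union": ses["ratio_union"],
        **{f"h2_med::{s.label}": ses[f"h2_med::{s.label}"] for s in score_sets},
        **{f"ratio::{s.label}": ses[f"ratio::{s.label}"] for s in score_sets},
    }
    return HeritabilityEstimate(
        label="mediated",
        tau=coefs[0][1 : 1 + n_tau],
        tau_labels=list(ld.categories),
        omega=omega,
        omega_labels=[s.label for s in score_sets],
        h2_snp=point["h2_snp"],
        h2_med=h2_med,
        ratio=ratio,
        se=se,
        n_blocks=n_blocks,
        intercept=coefs[0][0],
    )


# ----------------------------------------------------------------------------
# cis heritability
# ----------------------------------------------------------------------------

def estimate_cis_h2(
    panel: GenotypePanel,
    phenotype: np.ndarray,
    anchor: tuple,
    window: float = 200_000.0,
) -> tuple[float, float, int]:
    """Haseman-Elston estimate of cis-heritability with an analytic SE.

    The phenotype is standardized; cis dosages are standardized into the
    relatedness ``A = X X'/m_cis``; the slope of ``y_i y_j`` on ``A_ij`` over
    i < j pairs estimates h2_cis. The reported value is clipped to [0, 1];
    the raw slope is recoverable from the returned tuple's sign convention
    (value, se, m_cis) where value is the raw slope.
    """
    if panel.n_samples < 30:
        raise ValueError("need at least 30 samples")
    pos = panel.variants["pos"].to_numpy()
    chrom = (panel.variants["chrom"] == anchor[0]).to_numpy()
    if len(anchor) == 2:
        mask = chrom & (np.abs(pos - anchor[1]) <= window)
    else:
        start, end = anchor[1], anchor[2]
        inside = (pos > start) & (pos <= end)
        dist = np.where(pos <= start, start + 1 - pos, pos - end)
        mask = chrom & (inside | (dist <= window))
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        raise ValueError("no cis variants in window")
    X = panel.standardized_dosages()[:, idx]
    m_cis = len(idx)
    n = panel.n_samples
    y = np.asarray(phenotype, dtype=float)
    y = (y - y.mean()) / y.std()
    # pairwise sums over i<j via Gram-matrix identities (A = X X'/m never formed)
    col_sums = X.sum(axis=0)
    diag_a = np.einsum("ij,ij->i", X, X) / m_cis
    xty = X.T @ y
    gram = X.T @ X
    sum_a = float(col_sums @ col_sums) / m_cis
    tr_a = float(diag_a.sum())
    frob_a = float(np.sum(gram**2)) / m_cis**2
    s_a = (sum_a - tr_a) / 2.0
    s_a2 = (frob_a - np.sum(diag_a**2)) / 2.0
    s_p = ((y.sum()) ** 2 - np.sum(y**2)) / 2.0
    s_ap = (float(xty @ xty) / m_cis - np.sum(diag_a * y**2)) / 2.0
    s_p2 = ((np.sum(y**2)) ** 2 - np.sum(y**4)) / 2.0
    n_pairs = n * (n - 1) // 2
    var_a = s_a2 / n_pairs - (s_a / n_pairs) ** 2
    cov_ap = s_ap / n_pairs - (s_a / n_pairs) * (s_p / n_pairs)
    if var_a <= 0:
        raise ValueError("degenerate cis relatedness")
    slope = cov_ap / var_a
    # OLS residual variance over pairs (approximate: pairs share individuals)
    var_p = s_p2 / n_pairs - (s_p / n_pairs) ** 2
    resid_var = max(var_p - slope**2 * var_a, 0.0)
    se = float(np.sqrt(resid_var / (var_a * n_pairs)))
    return float(slope), se, m_cis


def reml_cis_h2(A: np.ndarray, y: np.ndarray) -> float:
    """Direct REML maximization of h2 for y ~ N(0, h2 A + (1-h2) I).

    Small-n oracle used to validate the Haseman-Elston estimator; grid plus
    golden-section refinement over h2 in [0, 1].
    """
    n = len(y)
    y = (y - y.mean()) / y.std()
    w, V = np.linalg.eigh(A)
    u = V.T @ y
    ones = V.T @ np.ones(n)

    def neg_loglik(h2: float) -> float:
        d = h2 * w + (1 - h2)
        d = np.clip(d, 1e-8, None)
        # REML: profile out the mean and the overall scale
        xvx = np.sum(ones**2 / d)
        beta = np.sum(ones * u / d) / xvx
        r = u - beta * ones
        quad = np.sum(r**2 / d)
        sigma2 = quad / (n - 1)
        return 0.5 * (np.sum(np.log(d)) + (n - 1) * np.log(sigma2) + np.log(xvx))

    grid = np.linspace(0.0, 0.999, 60)
    vals = [neg_loglik(h) for h in grid]
    best = grid[int(np.argmin(vals))]
    lo, hi = max(0.0, best - 0.03), min(0.999, best + 0.03)
    fine = np.linspace(lo, hi, 40)
    vals = [neg_loglik(h) for h in fine]
    return float(fine[int(np.argmin(vals))])


# ----------------------------------------------------------------------------
# decomposition and enrichment
# ----------------------------------------------------------------------------

def decompose_mediated_h2(h_ca: float, h_e: float, h_union: float) -> MediatedDecomposition:
    """Union/intersection decomposition of two mediated-heritability estimates.

    ``intersection = h_ca + h_e - h_union``; ``just_ca = h_union - h_e``;
    ``just_e = h_union - h_ca``; the identities hold exactly for any inputs
    (negative components from noisy inputs are passed through).
    """
    for v in (h_ca, h_e, h_union):
        if not np.isfinite(v):
            raise ValueError("inputs must be finite")
    intersection = h_ca + h_e - h_union
    just_ca = h_union - h_e
    just_e = h_union - h_ca
    shared_fraction = intersection / h_e if h_e != 0 else float("nan")
    return MediatedDecomposition(h_ca, h_e, h_union, just_ca, just_e, intersection, shared_fraction)


def mediated_h2_enrichment(
    subset_h2med: dict[str, float],
    total_h2med: float,
    prop_features: dict[str, float],
    subset_jack: dict[str, np.ndarray] | None = None,
    total_jack: np.ndarray | None = None,
    fdr_method: str = "fdr_bh",
) -> pd.DataFrame:
    """Mediated-heritability enrichment per feature subset with FDR control.

    ``enrichment = (subset h2_med / total h2_med) / prop_features``; one-sided
    p-values (enrichment > 1) from jackknife replicates when given;
    multiplicity adjusted across the tested family (Benjamini-Hochberg by
    default, ``fdr_method='storey'`` for the Storey variant).
    """
    rows = []
    for lab, h in subset_h2med.items():
        prop = prop_features.get(lab, float("nan"))
        undefined = total_h2med <= 0 or not prop or not np.isfinite(prop)
        enr = float("nan") if undefined else (h / total_h2med) / prop
        se = float("nan")
        if subset_jack is not None and total_jack is not None and not undefined:
            reps = (subset_jack[lab] / total_jack) / prop
            se = _jackknife(np.asarray(reps))
        p = (
            float(stats.norm.sf((enr - 1.0) / se))
            if np.isfinite(se) and se > 0
            else float("nan")
        )
        rows.append(
            {"subset": lab, "enrichment": enr, "se": se, "p": p, "undefined": bool(undefined)}
        )
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    out["q"] = np.nan
    if ok.any():
        pvals = out.loc[ok, "p"].to_numpy()
        if fdr_method == "storey":
            out.loc[ok, "q"] = _storey_q(pvals)
        else:
            out.loc[ok, "q"] = multipletests(pvals, method="fdr_bh")[1]
    out["significant"] = out["q"] < 0.05
    return out


def _storey_q(pvals: np.ndarray, lam: float = 0.5) -> np.ndarray:
    pi0 = min(1.0, np.mean(pvals > lam) / (1 - lam)) if len(pvals) else 1.0
    order = np.argsort(pvals)
    m = len(pvals)
    q = np.empty(m)
    prev = 1.0
    for rank, i in list(enumerate(order, start=1))[::-1]:
        prev = min(prev, pi0 * pvals[i] * m / rank)
        q[i] = prev
    return q


# ----------------------------------------------------------------------------
# peak annotation and distance analyses
# ----------------------------------------------------------------------------

def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    """At least 1 bp of overlap between 0-based half-open intervals."""
    return max(a_start, b_start) < min(a_end, b_end)


def annotate_peak_subsets(
    peaks: list[Peak],
    cpm: PhenotypeMatrix,
    mark_intervals: dict[str, list[tuple[str, int, int]]] | None = None,
) -> pd.DataFrame:
    """Per-peak strength quintiles, histone-mark overlap flags, derived labels.

    Strength quintile 1 holds the strongest peaks by descending
    95th-percentile CPM. Mark flags require >= 1 bp of interval overlap.
    Labels: ``promoter-like`` = H3K27ac and H3K4me3; ``enhancer-like`` =
    H3K27ac without H3K4me3; ``ATAC-only`` = none of the three marks.
    """
    row = {f: i for i, f in enumerate(cpm.feature_ids)}
    strength = np.array([np.quantile(cpm.values[row[p.id]], 0.95) if p.id in row else np.nan for p in peaks])
    order = np.argsort(np.argsort(-strength, kind="stable"), kind="stable")
    n = len(peaks)
    quintile = (order * 5 // n) + 1
    out = pd.DataFrame({"peak_id": [p.id for p in peaks], "strength_cpm95": strength, "strength_quintile": quintile})
    marks = mark_intervals or {}
    for mark, intervals in marks.items():
        flags = []
        for p in peaks:
            flags.append(
                any(c == p.chrom and _overlaps(p.start, p.end, s, e) for c, s, e in intervals)
            )
        out[mark] = flags
    k27 = out["H3K27ac"] if "H3K27ac" in out else pd.Series(False, index=out.index)
    k4me3 = out["H3K4me3"] if "H3K4me3" in out else pd.Series(False, index=out.index)
    k4me1 = out["H3K4me1"] if "H3K4me1" in out else pd.Series(False, index=out.index)
    out["promoter_like"] = k27 & k4me3
    out["enhancer_like"] = k27 & ~k4me3
    out["atac_only"] = ~(k27 | k4me3 | k4me1)
    return out


def peak_tss_distance(peak: Peak, gene: Gene) -> int:
    """Shortest distance from a peak edge to the gene's TSS (0 if inside).

    The peak's 0-based half-open interval is anchored at 1-based edge bases
    ``start + 1`` and ``end - 1``; a TSS within the peak gives distance 0.
    """
    if peak.chrom != gene.chrom:
        raise ValueError("peak and gene on different chromosomes")
    left, right = peak.start + 1, peak.end - 1
    if left <= gene.tss <= peak.end:
        return 0
    if gene.tss > peak.end:
        return gene.tss - right
    return left - gene.tss


@dataclass
class DistanceAnalysis:
    table: pd.DataFrame  # distance, h2_ca, h2_e, quintile
    rank_p_e: dict[int, float]  # later quintile < first, eQTL h2_cis
    rank_p_ca: dict[int, float]
    trend_p_e: float  # pooled later quintiles < first
    trend_p_ca: float
    paired_p: dict[int, float]  # caQTL > eQTL within quintile
    coef_ca: float
    se_ca: float
    p_ca: float
    coef_dist: float
    se_dist: float
    p_dist: float
    skipped_quintiles: list[int] = field(default_factory=list)


def distance_stratified_h2(pairs: pd.DataFrame) -> DistanceAnalysis:
    """Quintile-stratified comparison of caQTL and eQTL cis-heritability.

    ``pairs`` needs columns distance, h2_ca, h2_e. Pairs are split into
    distance quintiles (ties to the lower quintile); one-sided rank-sum
    tests compare each later quintile against the first (alternative: later
    < first) for eQTL and caQTL h2_cis; a one-sided paired test per quintile
    checks caQTL > eQTL; and OLS regresses eQTL h2_cis on caQTL h2_cis and
    distance in 100 kb units.
    """
    if len(pairs) < 10:
        raise ValueError("need at least 10 pairs")
    df = pairs.copy().reset_index(drop=True)
    if (df["distance"] < 0).any():
        raise ValueError("distances must be non-negative")
    order = np.argsort(np.argsort(df["distance"].to_numpy(), kind="stable"), kind="stable")
    df["quintile"] = (order * 5 // len(df)) + 1

    rank_p_e: dict[int, float] = {}
    rank_p_ca: dict[int, float] = {}
    paired_p: dict[int, float] = {}
    skipped = []
    first = df[df["quintile"] == 1]
    for q in range(2, 6):
        sub = df[df["quintile"] == q]
        if len(sub) < 2 or len(first) < 2:
            skipped.append(q)
            continue
        rank_p_e[q] = float(
            stats.mannwhitneyu(sub["h2_e"], first["h2_e"], alternative="less").pvalue
        )
        rank_p_ca[q] = float(
            stats.mannwhitneyu(sub["h2_ca"], first["h2_ca"], alternative="less").pvalue
        )
    for q in range(1, 6):
        sub = df[df["quintile"] == q]
        if len(sub) < 2:
            if q not in skipped:
                skipped.append(q)
            continue
        diff = sub["h2_ca"].to_numpy() - sub["h2_e"].to_numpy()
        if np.allclose(diff, 0):
            paired_p[q] = 0.5
        else:
            paired_p[q] = float(stats.wilcoxon(diff, alternative="greater").pvalue)

    rest = df[df["quintile"] > 1]
    trend_p_e = trend_p_ca = float("nan")
    if len(rest) >= 2 and len(first) >= 2:
        trend_p_e = float(
            stats.mannwhitneyu(rest["h2_e"], first["h2_e"], alternative="less").pvalue
        )
        trend_p_ca = float(
            stats.mannwhitneyu(rest["h2_ca"], first["h2_ca"], alternative="less").pvalue
        )

    X = sm.add_constant(
        np.column_stack([df["h2_ca"].to_numpy(), df["distance"].to_numpy() / 1e5])
    )
    fit = sm.OLS(df["h2_e"].to_numpy(), X).fit()
    return DistanceAnalysis(
        table=df,
        rank_p_e=rank_p_e,
        rank_p_ca=rank_p_ca,
        trend_p_e=trend_p_e,
        trend_p_ca=trend_p_ca,
        paired_p=paired_p,
        coef_ca=float(fit.params[1]),
        se_ca=float(fit.bse[1]),
        p_ca=float(fit.pvalues[1]),
        coef_dist=float(fit.params[2]),
        se_dist=float(fit.bse[2]),
        p_dist=float(fit.pvalues[2]),
        skipped_quintiles=skipped,
    )


def tss_window_mediated_h2(
    peak_contrib: dict[str, float],
    peak_tss_dist: dict[str, float],
    windows: list[float],
) -> pd.DataFrame:
    """Proportion of mediated heritability from peaks within each TSS window.

    ``peak_contrib`` maps peak id -> its mediated-heritability contribution;
    ``peak_tss_dist`` maps peak id -> distance to the nearest gene TSS.
    Windows must be ascending.
    """
    if list(windows) != sorted(windows):
        raise ValueError("windows must be ascending")
    total = sum(peak_contrib.values())
    n_peaks = len(peak_contrib)
    rows = []
    for w in windows:
        inside = [p for p in peak_contrib if peak_tss_dist.get(p, np.inf) <= w]
        sub = sum(peak_contrib[p] for p in inside)
        rows.append(
            {
                "window": w,
                "prop_h2_med": sub / total if total > 0 else float("nan"),
                "prop_peaks": len(inside) / n_peaks if n_peaks else float("nan"),
            }
        )
    return pd.DataFrame(rows)
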