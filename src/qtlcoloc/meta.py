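"""Inverse-variance-weighted fixed-effects meta-analysis of summary statistics.

Per variant, over the studies in which it appears:
``w_i = 1/se_i^2``, combined ``beta = sum(w_i beta_i)/sum(w_i)``,
``se = sum(w_i)^-0.5``; z, chi-square and p are recomputed from the combined
beta/se. Variants missing from a subset of studies are combined from the
available statistics only. Cochran's Q is emitted as a diagnostic column but
never used for filtering (fixed effects only).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import SUMMARY_COLUMNS, SummaryStats, fill_summary_invariants

logger = logging.getLogger("qtlcoloc")

__all__ = ["ivw_meta"]


def ivw_meta(
    studies: list[SummaryStats],
    trait_id: str | None = None,
    study_id: str = "ivw_meta",
) -> SummaryStats:
    """Fixed-effects IVW combination of per-variant records across studies."""
    if not studies:
        raise ValueError("need at least one study")
    frames = []
    for s in studies:
        t = s.table.copy()
        bad = t["se"] <= 0
        if bad.any():
            logger.warning(
                "study %s: dropping %d records with non-positive se", s.study_id, bad.sum()
            )
            t = t[~bad]
        t["study_n"] = s.n
        frames.append(t)
    allrec = pd.concat(frames, ignore_index=True)
    w = 1.0 / allrec["se"] ** 2
    allrec = allrec.assign(w=w, wb=w * allrec["beta"], wb2=w * allrec["beta"] ** 2)
    grp = allrec.groupby("variant_id", sort=False)
    agg = grp.agg(
        chrom=("chrom", "first"),
        pos=("pos", "first"),
        ref=("ref", "first"),
        alt=("alt", "first"),
        sw=("w", "sum"),
        swb=("wb", "sum"),
        swb2=("wb2", "sum"),
        k_studies=("w", "size"),
        n_total=("study_n", "sum"),
        beta_first=("beta", "first"),
        se_first=("se", "first"),
    ).reset_index()
    beta = agg["swb"] / agg["sw"]
    se = 1.0 / np.sqrt(agg["sw"])
    # a variant seen in exactly one study passes through unchanged
    single = agg["k_studies"] == 1
    beta[single] = agg.loc[single, "beta_first"]
    se[single] = agg.loc[single, "se_first"]
    # Cochran's Q = sum w_i beta_i^2 - (sum w_i beta_i)^2 / sum w_i
    q = agg["swb2"] - agg["swb"] ** 2 / agg["sw"]
    table = agg[["variant_id", "chrom", "pos", "ref", "alt"]].copy()
    table["beta"] = beta
    table["se"] = se
    table["n"] = agg["n_total"].astype(int)
    table = fill_summary_invariants(table)
    table["k_studies"] = agg["k_studies"].astype(int)
    table["n_total"] = agg["n_total"].astype(int)
    table["cochran_q"] = q
    table = table.sort_values("pos", kind="stable").reset_index(drop=True)
    first = studies[0]
    return SummaryStats(
        trait_id if trait_id is not None else first.trait_id,
        first.trait_type,
        study_id,
        int(sum(s.n for s in studies)),
        table[SUMMARY_COLUMNS + ["k_studies", "n_total", "cochran_q"]],
    )
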