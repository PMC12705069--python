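"""Shared in-memory containers for the simulation and analysis modules.

Conventions
-----------
* Variant positions are 1-based; peak intervals are 0-based half-open (BED).
* Dosages are an ``n_samples x n_variants`` array with values in {0, 1, 2}.
* Summary statistics live in a pandas DataFrame with one row per variant and
  the invariants ``z = beta/se``, ``chisq = z**2`` and
  ``p = P(chi2_1 > chisq)`` maintained at construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

SUMMARY_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "beta",
    "se",
    "z",
    "chisq",
    "p",
    "n",
]


@dataclass(frozen=True)
class Variant:
    id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    maf: float

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"maf must be in (0, 0.5], got {self.maf}")


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    id: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid peak interval [{self.start}, {self.end})")


@dataclass(frozen=True)
class Gene:
    id: str
    chrom: str
    tss: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tss < 1:
            raise ValueError("tss must be >= 1 (1-based)")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")


@dataclass
class LDBlock:
    """Half-open variant index range [start, stop) with its correlation matrix."""

    start: int
    stop: int
    R: np.ndarray


@dataclass
class GenotypePanel:
    """Dosage matrix plus variant metadata and per-block LD.

    ``variants`` is a DataFrame with columns id/chrom/pos/ref/alt/maf ordered
    by position. ``params`` stores the generative settings (allele
    frequencies, positions, LD decay) so that independent samples of new
    individuals can be drawn from the same population.
    """

    variants: pd.DataFrame
    sample_ids: list[str]
    dosages: np.ndarray
    ld_blocks: list[LDBlock]
    params: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def block_of(self, j: int) -> int:
        for i, b in enumerate(self.ld_blocks):
            if b.start <= j < b.stop:
                return i
        raise IndexError(j)

    def standardized_dosages(self) -> np.ndarray:
        """Column-standardized dosage matrix (zero-variance columns -> 0), cached."""
        cached = getattr(self, "_std_cache", None)
        if cached is not None:
            return cached
        x = self.dosages.astype(float)
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        out = (x - mu) / sd
        object.__setattr__(self, "_std_cache", out)
        return out

    def empirical_maf(self) -> np.ndarray:
        f = self.dosages.mean(axis=0) / 2.0
        return np.minimum(f, 1.0 - f)


@dataclass
class PhenotypeMatrix:
    """Features x samples value matrix with a processing-stage tag."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    stage: str = "raw_counts"

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match feature/sample ids")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def subset(self, feature_ids: list[str]) -> "PhenotypeMatrix":
        idx = [self.feature_ids.index(f) for f in feature_ids]
        return PhenotypeMatrix(
            list(feature_ids), list(self.sample_ids), self.values[idx], self.stage
        )


def fill_summary_invariants(table: pd.DataFrame) -> pd.DataFrame:
    """Fill z, chisq and p from beta and se in place and return the table."""
    table = table.copy()
    se = np.asarray(table["se"], dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    z = np.asarray(table["beta"], dtype=float) / se
    table["z"] = z
    table["chisq"] = z**2
    table["p"] = stats.chi2.sf(z**2, df=1)
    return table


@dataclass
class SummaryStats:
    """Per-variant association records for one trait in one study/context."""

    trait_id: str
    trait_type: str  # disease | caQTL | eQTL
    study_id: str
    n: int
    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.trait_type not in ("disease", "caQTL", "eQTL"):
            raise ValueError(f"bad trait_type {self.trait_type}")
        missing = [c for c in SUMMARY_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"summary table missing columns: {missing}")

    @classmethod
    def from_beta_se(
        cls,
        trait_id: str,
        trait_type: str,
        study_id: str,
        n: int,
        table: pd.DataFrame,
    ) -> "SummaryStats":
        table = table.copy()
        table["n"] = n
        table = fill_summary_invariants(table)
        return cls(trait_id, trait_type, study_id, n, table[SUMMARY_COLUMNS])

    def slice_window(self, chrom: str, lo: int, hi: int) -> pd.DataFrame:
        t = self.table
        return t[(t["chrom"] == chrom) & (t["pos"] >= lo) & (t["pos"] <= hi)]


@dataclass
class CisResult:
    """Per-feature cis association scan."""

    feature_id: str
    trait_type: str  # caQTL | eQTL
    table: pd.DataFrame  # SUMMARY_COLUMNS rows restricted to the cis window
    lead_variant: str
    lead_p: float

    def to_summary(self, study_id: str = "cis", n: int | None = None) -> SummaryStats:
        n_eff = int(n if n is not None else self.table["n"].iloc[0])
        return SummaryStats(self.feature_id, self.trait_type, study_id, n_eff, self.table)


@dataclass
class RegulatoryModel:
    """Ground-truth causal architecture tying variants to peaks, genes, disease.

    All effect fields are on standardized scales: dosages standardized per
    variant, latent accessibility and expression standardized to unit
    variance, disease liability standardized to unit variance.
    """

    peaks: list[Peak]
    genes: list[Gene]
    contexts: list[str]
    # peak_id -> (variant index, b_raw, b_std); b_std is the effect of the
    # standardized dosage on the standardized accessibility latent.
    peak_causals: dict[str, tuple[int, float, float]]
    # (peak_id, gene_id, context) -> raw wiring weight on the standardized peak latent
    wiring: dict[tuple[str, str, str], float]
    gamma: dict[str, float]  # gene -> disease effect
    delta: dict[str, float]  # peak -> disease effect
    direct: np.ndarray  # per-variant direct (non-mediated) liability effects
    sigma_a: float
    sigma_e: float
    disease_context: str
    # derived truths
    alpha_ca: dict[str, tuple[np.ndarray, np.ndarray]]  # peak -> (variant idx, alpha)
    alpha_e: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]]  # context -> gene -> ...
    h2_cis_peak: dict[str, float]
    h2_cis_gene: dict[str, dict[str, float]]  # context -> gene -> h2
    beta: np.ndarray  # standardized per-variant joint disease effect vector
    h2_snp: float
    h2_med_ca: float
    h2_med_e: float
    h2_med_union: float
    var_y: float
    gene_sd: dict[str, dict[str, float]] = field(default_factory=dict)
    peak_med_contribution: dict[str, float] = field(default_factory=dict)

    def causal_variant_of(self, peak_id: str) -> int | None:
        entry = self.peak_causals.get(peak_id)
        return None if entry is None else entry[0]


@dataclass
class HeritabilityEstimate:
    label: str
    tau: np.ndarray
    tau_labels: list[str]
    omega: np.ndarray
    omega_labels: list[str]
    h2_snp: float
    h2_med: dict[str, float]
    ratio: dict[str, float]
    se: dict[str, float]
    n_blocks: int
    intercept: float = 1.0
    category_h2: dict[str, float] = field(default_factory=dict)
    enrichment: dict[str, float] = field(default_factory=dict)
    enrichment_se: dict[str, float] = field(default_factory=dict)
    enrichment_p: dict[str, float] = field(default_factory=dict)


@dataclass
class MediatedDecomposition:
    h_ca: float
    h_e: float
    h_union: float
    just_ca: float
    just_e: float
    intersection: float
    shared_fraction: float


@dataclass
class ColocPriors:
    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    W_grid: tuple[float, ...] = (0.01, 0.1, 0.5)

    def __post_init__(self) -> None:
        if not (0 < self.p12 <= min(self.p1, self.p2) < 1):
            raise ValueError("require 0 < p12 <= min(p1, p2) < 1")
        if any(w <= 0 for w in self.W_grid):
            raise ValueError("W_grid values must be positive")


@dataclass
class CandidateLocus:
    disease_id: str
    feature_id: str
    chrom: str
    window: tuple[int, int]
    lead_disease_variant: str
    lead_qtl_variant: str
    c1: bool
    c2: bool
    c3: bool


@dataclass
class ColocResult:
    locus: CandidateLocus | None
    pp: np.ndarray  # (null, trait1_only, trait2_only, two_distinct, shared)
    colocalized: bool
    n_variants: int

    @property
    def pp_shared(self) -> float:
        return float(self.pp[4])


@dataclass
class ColocalizedPair:
    peak_id: str
    gene_id: str
    distance: int
    lead_r2: float
    pp_shared: float
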