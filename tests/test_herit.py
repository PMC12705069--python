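"""Heritability machinery: scores, regressions, decomposition, distances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from qtlcoloc import herit, simulate
from qtlcoloc.datatypes import Gene, GenotypePanel, LDBlock, Peak, PhenotypeMatrix


def _brute_ld_scores(panel, member, window):
    """Triple-loop oracle for adjusted-r2 LD scores."""
    n = panel.n_samples
    pos = panel.variants["pos"].to_numpy()
    m = panel.n_variants
    out = np.zeros((m, member.shape[1]))
    for b in panel.ld_blocks:
        for j in range(b.start, b.stop):
            for k in range(b.start, b.stop):
                if abs(pos[j] - pos[k]) > window:
                    continue
                r2 = b.R[j - b.start, k - b.start] ** 2
                r2a = r2 - (1 - r2) / (n - 2)
                for c in range(member.shape[1]):
                    if member[k, c]:
                        out[j, c] += r2a
    return out


@pytest.fixture(scope="module")
def toy_panel():
    return simulate.simulate_genotype_panel(
        200, 50, 300_000, ld_decay=20_000, n_blocks=2, seed=71
    )


class TestLdScores:
    def test_matches_brute_force(self, toy_panel):
        rng = np.random.default_rng(0)
        member = rng.random((50, 3)) < np.array([1.0, 0.4, 0.2])
        annotations = {f"c{i}": member[:, i] for i in range(3)}
        scores = herit.compute_ld_scores(toy_panel, annotations, window=150_000)
        brute = _brute_ld_scores(toy_panel, member, 150_000)
        np.testing.assert_allclose(scores.scores, brute, atol=1e-10)

    def test_no_ld_panel_scores_near_one(self):
        panel = simulate.simulate_genotype_panel(
            2000, 80, 2_000_000, ld_decay=1.0, n_blocks=1, seed=72
        )
        scores = herit.compute_ld_scores(panel, {"all": np.ones(80, bool)})
        np.testing.assert_allclose(scores.scores[:, 0], 1.0, atol=0.05)

    def test_duplicated_variant_contributes_full_r2(self):
        rng = np.random.default_rng(73)
        d = rng.integers(0, 3, size=(500, 1)).astype(np.int8)
        dosages = np.column_stack([d, d, rng.integers(0, 3, size=(500, 1))]).astype(np.int8)
        variants = pd.DataFrame(
            {
                "id": ["a", "b", "c"],
                "chrom": "chr1",
                "pos": [100, 200, 300],
                "ref": "A",
                "alt": "G",
                "maf": 0.3,
            }
        )
        R = np.corrcoef(dosages.astype(float), rowvar=False)
        panel = GenotypePanel(variants, [f"s{i}" for i in range(500)], dosages, [LDBlock(0, 3, R)])
        scores = herit.compute_ld_scores(panel, {"all": np.ones(3, bool)})
        assert scores.scores[0, 0] >= 2.0 - 0.02  # self + perfect copy

    def test_empty_category_zero_column(self, toy_panel):
        scores = herit.compute_ld_scores(toy_panel, {"none": np.zeros(50, bool)})
        np.testing.assert_array_equal(scores.scores[:, 0], 0.0)


class TestMediationScores:
    def test_matches_brute_force(self, toy_panel):
        rng = np.random.default_rng(1)
        alpha = {
            "f0": (np.array([3, 10]), np.array([0.4, -0.2])),
            "f1": (np.array([30]), np.array([0.5])),
        }
        ms = herit.compute_mediation_scores(toy_panel, alpha, window=150_000)
        a2 = np.zeros(50)
        for idx, vals in alpha.values():
            a2[idx] += np.asarray(vals) ** 2
        # direct double loop with alpha^2 weights
        n = toy_panel.n_samples
        pos = toy_panel.variants["pos"].to_numpy()
        expect = np.zeros(50)
        for b in toy_panel.ld_blocks:
            for j in range(b.start, b.stop):
                for k in range(b.start, b.stop):
                    if abs(pos[j] - pos[k]) > 150_000:
                        continue
                    r2 = b.R[j - b.start, k - b.start] ** 2
                    expect[j] += (r2 - (1 - r2) / (n - 2)) * a2[k]
        np.testing.assert_allclose(ms.scores, expect, atol=1e-10)

    def test_no_ld_sum_identity(self):
        panel = simulate.simulate_genotype_panel(
            300, 40, 500_000, ld_decay=20_000, n_blocks=2, seed=74
        )
        # replace block correlation with exact identity = no-LD limit
        for b in panel.ld_blocks:
            b.R = np.eye(b.stop - b.start)
        alpha = {"f0": (np.array([5, 20]), np.array([0.3, 0.6]))}
        ms = herit.compute_mediation_scores(panel, alpha, adjust=False)
        # with exact population R = I the scores carry only the self terms,
        # so their sum equals the summed squared cis effects
        assert ms.total_h2_cis == pytest.approx(0.3**2 + 0.6**2, abs=1e-12)
        assert ms.scores.sum() == pytest.approx(0.3**2 + 0.6**2, abs=1e-12)

    def test_zero_alpha_zero_scores(self, toy_panel):
        ms = herit.compute_mediation_scores(toy_panel, {"f0": (np.array([2]), np.array([0.0]))})
        np.testing.assert_array_equal(ms.scores, 0.0)
        assert ms.total_h2_cis == 0.0


class TestStratifiedRegression:
    def test_all_variant_category_enrichment_exactly_one(self, small_architecture):
        panel, _, _, model = small_architecture
        gwas = simulate.simulate_gwas_summary(panel, model, 20_000, seed=75)
        scores = herit.compute_ld_scores(panel, {"all": np.ones(panel.n_variants, bool)})
        fit = herit.stratified_h2_regression(gwas, scores, n_blocks=10)
        assert fit.enrichment["all"] == pytest.approx(1.0, abs=1e-12)

    def test_null_gwas_h2_within_two_ses_of_zero(self, small_panel):
        peaks, genes = simulate.layout_peaks_genes(small_panel, 10, 5, seed=76)
        null = simulate.simulate_regulatory_model(
            small_panel, peaks, genes, gamma_scale=0.0, delta_scale=0.0, seed=76
        )
        gwas = simulate.simulate_gwas_summary(small_panel, null, 20_000, seed=77)
        scores = herit.compute_ld_scores(small_panel, {"all": np.ones(small_panel.n_variants, bool)})
        fit = herit.stratified_h2_regression(gwas, scores, n_blocks=10)
        assert abs(fit.h2_snp) <= 2 * fit.se["h2_snp"] + 1e-3

    def test_causal_category_enrichment_recovered(self):
        """All causal variants inside the annotated category: estimated
        enrichment tracks 1/prop over replicates."""
        panel = simulate.simulate_genotype_panel(
            500, 1200, 8_000_000, ld_decay=15_000, n_blocks=12, seed=78
        )
        m = panel.n_variants
        rng = np.random.default_rng(78)
        inside = np.zeros(m, bool)
        inside[rng.choice(m, m // 5, replace=False)] = True  # prop = 0.2
        errs = []
        for rep in range(8):
            r = np.random.default_rng(200 + rep)
            beta = np.zeros(m)
            causal = np.flatnonzero(inside)
            beta[causal] = r.normal(0, 1, size=len(causal))
            v = sum(
                float(beta[b.start:b.stop] @ b.R @ beta[b.start:b.stop])
                for b in panel.ld_blocks
            )
            beta *= np.sqrt(0.3 / v)
            model = type("M", (), {"beta": beta})()
            gwas = simulate.simulate_gwas_summary(panel, model, 30_000, seed=300 + rep)
            scores = herit.compute_ld_scores(
                panel, {"all": np.ones(m, bool), "peakish": inside}
            )
            fit = herit.stratified_h2_regression(gwas, scores, n_blocks=20)
            errs.append(fit.enrichment["peakish"] - 5.0)
        assert abs(np.mean(errs)) < 1.0


class TestCisH2:
    def test_null_phenotype_mean_near_zero(self, toy_panel):
        ests = []
        for rep in range(100):
            rng = np.random.default_rng(400 + rep)
            y = rng.normal(size=toy_panel.n_samples)
            h2, _, _ = herit.estimate_cis_h2(toy_panel, y, ("chr1", 1, 300_000), 300_000)
            ests.append(h2)
        assert abs(np.mean(ests)) < 3 * np.std(ests) / 10  # 3 SE of the mean

    def test_planted_h2_recovered(self, toy_panel):
        X = toy_panel.standardized_dosages()
        ests = []
        for rep in range(100):
            rng = np.random.default_rng(500 + rep)
            k = int(rng.integers(0, 50))
            y = np.sqrt(0.4) * X[:, k] + np.sqrt(0.6) * rng.normal(size=toy_panel.n_samples)
            h2, _, _ = herit.estimate_cis_h2(toy_panel, y, ("chr1", 1, 300_000), 300_000)
            ests.append(h2)
        assert 0.3 < np.mean(ests) < 0.5

    def test_he_tracks_reml_oracle(self):
        """Moment estimator vs direct REML likelihood maximization at n=60."""
        panel = simulate.simulate_genotype_panel(
            60, 3, 30_000, ld_decay=15_000, n_blocks=1, seed=79
        )
        X = panel.standardized_dosages()
        A = X @ X.T / 3
        rng = np.random.default_rng(79)
        he, reml = [], []
        for rep in range(50):
            h2 = rng.uniform(0.05, 0.9)
            k = int(rng.integers(0, 3))
            y = np.sqrt(h2) * X[:, k] + np.sqrt(1 - h2) * rng.normal(size=60)
            est, _, _ = herit.estimate_cis_h2(panel, y, ("chr1", 1, 40_000), 100_000)
            he.append(est)
            reml.append(herit.reml_cis_h2(A, y))
        assert np.corrcoef(he, reml)[0, 1] > 0.8

    def test_no_cis_variants_rejected(self, toy_panel):
        y = np.zeros(toy_panel.n_samples)
        with pytest.raises(ValueError):
            herit.estimate_cis_h2(toy_panel, y, ("chr2", 1, 100), 10)


class TestDecomposition:
    def test_worked_example(self):
        d = herit.decompose_mediated_h2(0.3, 0.2, 0.35)
        assert d.intersection == pytest.approx(0.15)
        assert d.just_ca == pytest.approx(0.15)
        assert d.just_e == pytest.approx(0.05)
        assert d.shared_fraction == pytest.approx(0.75)

    def test_disjoint_and_nested_limits(self):
        assert herit.decompose_mediated_h2(0.3, 0.2, 0.5).intersection == pytest.approx(0.0)
        nested = herit.decompose_mediated_h2(0.3, 0.2, 0.3)
        assert nested.just_e == pytest.approx(0.0)
        assert nested.intersection == pytest.approx(0.2)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.floats(-1, 1, allow_nan=False),
        st.floats(-1, 1, allow_nan=False),
        st.floats(-1, 1, allow_nan=False),
    )
    def test_identities_hold_exactly(self, h_ca, h_e, h_union):
        d = herit.decompose_mediated_h2(h_ca, h_e, h_union)
        assert d.just_ca + d.just_e + d.intersection == pytest.approx(d.h_union, abs=1e-12)
        assert d.intersection == pytest.approx(d.h_ca + d.h_e - d.h_union, abs=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            herit.decompose_mediated_h2(np.nan, 0.1, 0.2)


class TestEnrichment:
    def test_full_subset_enrichment_one(self):
        out = herit.mediated_h2_enrichment({"full": 0.2}, 0.2, {"full": 1.0})
        assert out.loc[0, "enrichment"] == pytest.approx(1.0)

    def test_partition_proportions_sum_to_one(self):
        subs = {"a": 0.08, "b": 0.07, "c": 0.05}
        out = herit.mediated_h2_enrichment(subs, 0.2, {"a": 0.5, "b": 0.3, "c": 0.2})
        props = out.set_index("subset")["enrichment"] * pd.Series({"a": 0.5, "b": 0.3, "c": 0.2})
        assert props.sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_total_flagged_undefined(self):
        out = herit.mediated_h2_enrichment({"a": 0.1}, 0.0, {"a": 0.5})
        assert bool(out.loc[0, "undefined"])

    def test_concentrated_mediation_recovers_enrichment(self):
        # all mediation through a fifth of the features -> enrichment ~5
        jack_sub = {"top": np.full(10, 0.2), "rest": np.full(10, 0.0)}
        jack_tot = np.full(10, 0.2)
        out = herit.mediated_h2_enrichment(
            {"top": 0.2, "rest": 0.0}, 0.2, {"top": 0.2, "rest": 0.8}, jack_sub, jack_tot
        ).set_index("subset")
        assert out.loc["top", "enrichment"] == pytest.approx(5.0)
        assert out.loc["rest", "enrichment"] == pytest.approx(0.0)


class TestPeakAnnotation:
    def _cpm(self, values):
        return PhenotypeMatrix(
            [f"p{i}" for i in range(len(values))],
            ["s0", "s1"],
            np.column_stack([values, values]).astype(float),
            "cpm",
        )

    def test_one_bp_overlap_counts(self):
        peaks = [Peak("chr1", 100, 200, "p0"), Peak("chr1", 300, 400, "p1")]
        marks = {"H3K27ac": [("chr1", 199, 250)], "H3K4me3": [], "H3K4me1": []}
        out = herit.annotate_peak_subsets(peaks, self._cpm([5, 5]), marks).set_index("peak_id")
        assert bool(out.loc["p0", "H3K27ac"])
        assert not bool(out.loc["p1", "H3K27ac"])
        # zero-length contact [200, 200) would not count
        marks2 = {"H3K27ac": [("chr1", 200, 250)], "H3K4me3": [], "H3K4me1": []}
        out2 = herit.annotate_peak_subsets(peaks, self._cpm([5, 5]), marks2).set_index("peak_id")
        assert not bool(out2.loc["p0", "H3K27ac"])

    def test_promoter_enhancer_atac_only_labels(self):
        peaks = [Peak("chr1", i * 1000, i * 1000 + 100, f"p{i}") for i in range(3)]
        marks = {
            "H3K27ac": [("chr1", 0, 100), ("chr1", 1000, 1100)],
            "H3K4me3": [("chr1", 0, 100)],
            "H3K4me1": [],
        }
        out = herit.annotate_peak_subsets(peaks, self._cpm([1, 2, 3]), marks).set_index("peak_id")
        assert bool(out.loc["p0", "promoter_like"]) and not bool(out.loc["p0", "enhancer_like"])
        assert bool(out.loc["p1", "enhancer_like"]) and not bool(out.loc["p1", "promoter_like"])
        assert bool(out.loc["p2", "atac_only"])

    def test_strength_quintiles_by_cpm95(self):
        peaks = [Peak("chr1", i * 1000, i * 1000 + 100, f"p{i}") for i in range(10)]
        out = herit.annotate_peak_subsets(peaks, self._cpm(np.arange(10, 0, -1))).set_index("peak_id")
        assert out.loc["p0", "strength_quintile"] == 1  # highest CPM
        assert out.loc["p9", "strength_quintile"] == 5
        assert sorted(out["strength_quintile"].value_counts()) == [2, 2, 2, 2, 2]


class TestPeakTssDistance:
    @pytest.mark.parametrize(
        "tss,expected",
        [(150, 0), (500, 301), (50, 51), (101, 0), (200, 0)],
    )
    def test_edge_conventions(self, tss, expected):
        peak = Peak("chr1", 100, 200, "p0")
        gene = Gene("g0", "chr1", tss)
        assert herit.peak_tss_distance(peak, gene) == expected

    def test_cross_chromosome_rejected(self):
        with pytest.raises(ValueError):
            herit.peak_tss_distance(Peak("chr1", 0, 10, "p"), Gene("g", "chr2", 5))


class TestDistanceAnalysis:
    def _pairs(self, rng, n=60, decreasing=True):
        d = rng.uniform(0, 400_000, n)
        h2_ca = rng.uniform(0.3, 0.5, n)
        if decreasing:
            h2_e = h2_ca * np.exp(-d / 150_000) * 0.8 + rng.normal(0, 0.01, n)
        else:
            h2_e = rng.uniform(0.1, 0.2, n)
        return pd.DataFrame({"distance": d, "h2_ca": h2_ca, "h2_e": h2_e})

    def test_quintiles_near_equal(self):
        rng = np.random.default_rng(81)
        da = herit.distance_stratified_h2(self._pairs(rng, 103))
        counts = da.table["quintile"].value_counts()
        assert counts.min() >= 20 and counts.max() <= 21

    def test_flat_eqtl_h2_gives_uniformish_p(self):
        hits = 0
        for rep in range(30):
            rng = np.random.default_rng(600 + rep)
            da = herit.distance_stratified_h2(self._pairs(rng, 80, decreasing=False))
            hits += da.trend_p_e > 0.05
        assert hits >= 24

    def test_equal_ca_e_paired_p_half(self):
        rng = np.random.default_rng(82)
        df = self._pairs(rng, 50)
        df["h2_e"] = df["h2_ca"]
        da = herit.distance_stratified_h2(df)
        assert all(p == pytest.approx(0.5) for p in da.paired_p.values())

    def test_regression_signs_on_attenuating_architecture(self):
        rng = np.random.default_rng(83)
        da = herit.distance_stratified_h2(self._pairs(rng, 120))
        assert da.coef_ca > 0
        assert da.coef_dist < 0

    def test_too_few_pairs_rejected(self):
        df = pd.DataFrame({"distance": [1] * 5, "h2_ca": [0.1] * 5, "h2_e": [0.1] * 5})
        with pytest.raises(ValueError):
            herit.distance_stratified_h2(df)


class TestTssWindows:
    def test_limits(self):
        contrib = {"p0": 0.1, "p1": 0.2}
        dist = {"p0": 5_000, "p1": 60_000}
        out = herit.tss_window_mediated_h2(contrib, dist, [1_000, 10_000, 1_000_000])
        assert out.loc[0, "prop_h2_med"] == 0.0  # window below all distances
        assert out.loc[1, "prop_h2_med"] == pytest.approx(0.1 / 0.3)
        assert out.loc[2, "prop_h2_med"] == pytest.approx(1.0)
        assert out.loc[2, "prop_peaks"] == pytest.approx(1.0)

    def test_concentrated_near_tss(self):
        contrib = {f"p{i}": 0.01 for i in range(10)}
        dist = {f"p{i}": 2_000 + i * 500 for i in range(10)}
        out = herit.tss_window_mediated_h2(contrib, dist, [10_000])
        assert out.loc[0, "prop_h2_med"] == pytest.approx(1.0)

    def test_windows_must_ascend(self):
        with pytest.raises(ValueError):
            herit.tss_window_mediated_h2({"p": 0.1}, {"p": 1}, [100, 10])
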