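"""Generator fidelity: LD structure, declared frequencies, truth bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from qtlcoloc import simulate
from qtlcoloc.datatypes import Gene, Peak


class TestGenotypePanel:
    def test_determinism_same_seed(self):
        a = simulate.simulate_genotype_panel(50, 40, 500_000, seed=7)
        b = simulate.simulate_genotype_panel(50, 40, 500_000, seed=7)
        np.testing.assert_array_equal(a.dosages, b.dosages)
        pd.testing.assert_frame_equal(a.variants, b.variants)

    def test_no_ld_limit_near_independence(self):
        # ld_decay of 1 bp with variants >= kb apart: mean off-diagonal |r| small
        panel = simulate.simulate_genotype_panel(
            2000, 100, 2_000_000, ld_decay=1.0, n_blocks=2, seed=11
        )
        R = panel.ld_blocks[0].R
        off = np.abs(R[np.triu_indices_from(R, 1)])
        assert off.mean() < 0.05

    def test_adjacent_correlation_matches_exponential_decay(self):
        # Monte-Carlo oracle: average empirical adjacent correlations over
        # seeds and compare with exp(-d/ld_decay)
        ld_decay = 20_000.0
        n_seeds = 12
        acc = None
        for s in range(n_seeds):
            panel = simulate.simulate_genotype_panel(
                2000, 60, 600_000, ld_decay=ld_decay, n_blocks=1, seed=500 + s
            )
            X = panel.standardized_dosages()
            rs = np.array(
                [np.corrcoef(X[:, j - 1], X[:, j])[0, 1] for j in range(1, 60)]
            )
            pos = panel.variants["pos"].to_numpy()
            target = np.exp(-np.diff(pos) / ld_decay)
            dev = np.abs(rs - target)
            acc = dev if acc is None else np.concatenate([acc, dev])
        assert acc.mean() < 0.1

    def test_empirical_maf_near_declared(self, small_panel):
        dev = np.abs(small_panel.empirical_maf() - small_panel.variants["maf"])
        assert dev.max() < 0.05

    def test_ld_decay_monotone_in_binned_distance(self, small_panel):
        b = small_panel.ld_blocks[0]
        pos = small_panel.variants["pos"].to_numpy()[b.start : b.stop]
        iu = np.triu_indices(b.R.shape[0], 1)
        d = np.abs(pos[:, None] - pos[None, :])[iu]
        r2 = b.R[iu] ** 2
        qs = np.quantile(d, np.linspace(0, 1, 7)[1:-1])
        bins = np.digitize(d, qs)
        means = [r2[bins == k].mean() for k in range(6)]
        rho = stats.spearmanr(np.arange(6), means).statistic
        assert rho <= 0

    def test_rejects_bad_arguments(self):
        with pytest.raises(ValueError):
            simulate.simulate_genotype_panel(50, 10, 1000, ld_decay=0.0)
        with pytest.raises(ValueError):
            simulate.simulate_genotype_panel(50, 3, 1000, n_blocks=5)
        with pytest.raises(ValueError):
            simulate.simulate_genotype_panel(1, 10, 1000)

    def test_block_matrices_unit_diagonal_psd(self, small_panel):
        for b in small_panel.ld_blocks:
            np.testing.assert_allclose(np.diag(b.R), 1.0, atol=1e-12)
            w = np.linalg.eigvalsh((b.R + b.R.T) / 2)
            assert w.min() > -1e-8

    def test_resample_draws_new_individuals_same_population(self, small_panel):
        sub = simulate.resample_panel(small_panel, 800, seed=9)
        assert sub.n_samples == 800
        dev = np.abs(sub.empirical_maf() - small_panel.variants["maf"])
        assert dev.max() < 0.06


class TestRegulatoryModel:
    def test_no_decay_limit_weights_independent_of_distance(self, small_panel):
        peaks, genes = simulate.layout_peaks_genes(small_panel, 20, 15, seed=3)
        cors = []
        for s in range(50):
            model = simulate.simulate_regulatory_model(
                small_panel, peaks, genes, wiring_decay=1e15, seed=600 + s
            )
            ws, ds = [], []
            pk_by = {p.id: p for p in peaks}
            g_by = {g.id: g for g in genes}
            for (pid, gid, ctx), w in model.wiring.items():
                ws.append(abs(w))
                ds.append(simulate._peak_tss_dist(pk_by[pid], g_by[gid]))
            cors.append(np.corrcoef(ws, ds)[0, 1])
        assert abs(np.mean(cors)) < 0.05

    def test_null_disease_effects_zero_truths(self, small_panel):
        peaks, genes = simulate.layout_peaks_genes(small_panel, 20, 15, seed=3)
        model = simulate.simulate_regulatory_model(
            small_panel, peaks, genes, gamma_scale=0.0, delta_scale=0.0, seed=4
        )
        assert model.h2_snp == 0.0
        assert model.h2_med_ca == 0.0
        assert model.h2_med_e == 0.0

    def test_truth_conservation_over_seeds(self, small_panel):
        peaks, genes = simulate.layout_peaks_genes(small_panel, 25, 15, seed=3)
        for s in range(10):
            model = simulate.simulate_regulatory_model(
                small_panel, peaks, genes,
                sigma_ca=2.0, gamma_scale=0.7, delta_scale=1.0,
                p_causal_direct=0.3, direct_scale=0.8, seed=700 + s,
            )
            assert 0.0 <= model.h2_med_e <= model.h2_med_ca + 1e-12
            assert model.h2_med_ca <= model.h2_snp + 1e-12
            assert model.h2_snp <= 1.0

    def test_gene_h2_cis_matches_variance_oracle(self, small_panel):
        """True h2_cis equals the variance of the genetic component computed
        independently from the generative equations on a large sample."""
        peaks, genes = simulate.layout_peaks_genes(small_panel, 25, 15, seed=3)
        model = simulate.simulate_regulatory_model(
            small_panel, peaks, genes, p_causal_peak=0.9, sigma_ca=1.5, seed=8
        )
        big = simulate.resample_panel(small_panel, 20_000, seed=88)
        X = big.standardized_dosages()
        ctx = model.disease_context
        checked = 0
        for g in genes:
            idx, a = model.alpha_e[ctx][g.id]
            if len(idx) == 0:
                continue
            mc = (X[:, idx] @ a).var()
            assert model.h2_cis_gene[ctx][g.id] == pytest.approx(mc, abs=0.05)
            checked += 1
        assert checked >= 3

    def test_calibration_hits_targets_exactly(self, small_architecture):
        _, _, _, model = small_architecture
        assert model.h2_snp == pytest.approx(0.3, abs=1e-9)
        assert model.h2_med_ca / model.h2_snp == pytest.approx(0.5, abs=1e-9)

    def test_empty_peak_list_rejected(self, small_panel):
        with pytest.raises(ValueError):
            simulate.simulate_regulatory_model(small_panel, [], [], seed=1)


class TestMolecularPhenotypes:
    def test_noiseless_limit_counts_track_latents(self, small_panel):
        peaks, genes = simulate.layout_peaks_genes(small_panel, 15, 10, seed=3)
        model = simulate.simulate_regulatory_model(
            small_panel, peaks, genes, p_causal_peak=1.0, seed=5
        )
        acc, _ = simulate.simulate_molecular_phenotypes(
            small_panel, model, model.disease_context,
            mean_depth=5e4, dispersion=0.0, libsize_sd=0.0, seed=5,
        )
        logc = np.log(acc.values + 0.5)
        cors = [np.corrcoef(logc[i], acc.latent[i])[0, 1] for i in range(len(peaks))]
        assert min(cors) > 0.99

    def test_masked_wiring_gene_has_zero_genetic_variance(self, small_panel):
        peaks, genes = simulate.layout_peaks_genes(small_panel, 10, 5, seed=3)
        model = simulate.simulate_regulatory_model(
            small_panel, peaks, genes,
            contexts=("a", "b"), prop_active_per_context=0.5, seed=6,
        )
        for ctx in ("a", "b"):
            for g in genes:
                wired = any(
                    gid == g.id and c == ctx for (pid, gid, c) in model.wiring
                )
                if not wired:
                    assert model.h2_cis_gene[ctx][g.id] == 0.0

    def test_unknown_context_rejected(self, small_architecture):
        panel, _, _, model = small_architecture
        with pytest.raises(ValueError):
            simulate.simulate_molecular_phenotypes(panel, model, "nope", seed=1)


class TestGwasSummary:
    def test_null_gwas_mean_chisq_near_one(self):
        panel = simulate.simulate_genotype_panel(
            200, 6000, 40_000_000, ld_decay=15_000, n_blocks=40, seed=21
        )
        peaks = [Peak("chr1", 1000, 2000, "p0")]
        genes = [Gene("g0", "chr1", 5000)]
        model = simulate.simulate_regulatory_model(
            panel, peaks, genes, gamma_scale=0.0, delta_scale=0.0, seed=21
        )
        gs = simulate.simulate_gwas_summary(panel, model, 10_000, seed=22)
        assert 0.9 < gs.table["chisq"].mean() < 1.1

    def test_single_causal_no_ld_mean_z_matches_closed_form(self):
        panel = simulate.simulate_genotype_panel(
            500, 50, 2_000_000, ld_decay=1.0, n_blocks=1, seed=23
        )
        peaks = [Peak("chr1", 0, 2_000_000, "p0")]
        genes = []
        model = simulate.simulate_regulatory_model(
            panel, peaks, genes, p_causal_peak=1.0, delta_scale=0.0, seed=23
        )
        k = model.peak_causals["p0"][0]
        beta = np.zeros(50)
        beta[k] = 0.02
        model.beta = beta
        n_gwas = 10_000
        zs = []
        for rep in range(200):
            gs = simulate.simulate_gwas_summary(panel, model, n_gwas, seed=100 + rep)
            zs.append(gs.table["z"].iloc[k])
        # E[z] = sqrt(N) * (R beta)_k ~ sqrt(N) beta_k in the no-LD limit
        expected = np.sqrt(n_gwas) * float(panel.ld_blocks[0].R[k] @ beta)
        se = 1.0 / np.sqrt(200)
        assert abs(np.mean(zs) - expected) < 3 * se

    def test_determinism(self, small_architecture):
        panel, _, _, model = small_architecture
        a = simulate.simulate_gwas_summary(panel, model, 5000, seed=3)
        b = simulate.simulate_gwas_summary(panel, model, 5000, seed=3)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_summary_invariants(self, small_architecture):
        panel, _, _, model = small_architecture
        t = simulate.simulate_gwas_summary(panel, model, 5000, seed=3).table
        np.testing.assert_allclose(t["z"], t["beta"] / t["se"], atol=1e-9)
        np.testing.assert_allclose(t["chisq"], t["z"] ** 2, atol=1e-9)
        np.testing.assert_allclose(t["p"], stats.chi2.sf(t["chisq"], 1), atol=1e-9)


class TestEqtlStudies:
    def test_single_study_list_length(self, small_architecture):
        panel, _, _, model = small_architecture
        studies = simulate.simulate_eqtl_studies(panel, model, [60], model.disease_context, seed=5)
        assert len(studies) == 1
        assert studies[0].n == 60

    def test_betas_correlated_across_studies_for_heritable_genes(self, small_architecture):
        panel, _, genes, model = small_architecture
        ctx = model.disease_context
        heritable = [g.id for g in genes if model.h2_cis_gene[ctx][g.id] > 0.1]
        if len(heritable) < 3:
            pytest.skip("architecture drew too few heritable genes")
        studies = simulate.simulate_eqtl_studies(panel, model, [500, 500], ctx, seed=6)
        rs = []
        for gid in heritable:
            t1 = studies[0].by_feature()[gid].table.set_index("variant_id")["beta"]
            t2 = studies[1].by_feature()[gid].table.set_index("variant_id")["beta"]
            common = t1.index.intersection(t2.index)
            rs.append(np.corrcoef(t1[common], t2[common])[0, 1])
        assert np.mean(rs) > 0.5

    def test_null_gene_p_uniform_across_replicate_studies(self, small_panel):
        # a gene with no genetic variance: its p-value at a fixed variant over
        # independent studies is uniform
        peaks = [Peak("chr1", 1000, 2000, "p0")]
        genes = [Gene("g0", "chr1", 500_000)]
        model = simulate.assemble_regulatory_model(
            small_panel, peaks, genes, ["lcl"],
            peak_causals={}, wiring={},
        )
        ps = []
        for rep in range(120):
            st = simulate.simulate_eqtl_studies(small_panel, model, [80], "lcl", seed=900 + rep)
            tab = st[0].results[0].table
            ps.append(float(tab["p"].iloc[len(tab) // 2]))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_small_sample_rejected(self, small_architecture):
        panel, _, _, model = small_architecture
        with pytest.raises(ValueError):
            simulate.simulate_eqtl_studies(panel, model, [5], model.disease_context, seed=1)


class TestFixtureRoundTrip:
    def test_export_import_bit_exact(self, tmp_path, small_architecture):
        panel, peaks, genes, model = small_architecture
        acc, expr = simulate.simulate_molecular_phenotypes(
            panel, model, model.disease_context, seed=9
        )
        gwas = simulate.simulate_gwas_summary(panel, model, 5000, seed=9)
        bundle = simulate.SimBundle(
            panel, peaks, genes, acc, expr, gwas,
            truth={"h2_snp": model.h2_snp, "h2_med_ca": model.h2_med_ca},
        )
        out = tmp_path / "fx"
        simulate.export_fixture(bundle, str(out))
        back = simulate.import_fixture(str(out))
        np.testing.assert_array_equal(back.panel.dosages, panel.dosages)
        np.testing.assert_array_equal(back.acc_counts.values, acc.values)
        pd.testing.assert_frame_equal(
            back.gwas.table.reset_index(drop=True), gwas.table.reset_index(drop=True)
        )
        assert back.truth["h2_snp"] == model.h2_snp
        assert [p.id for p in back.peaks] == [p.id for p in peaks]

    def test_bed_rows_valid(self, tmp_path, small_architecture):
        panel, peaks, genes, _ = small_architecture
        bundle = simulate.SimBundle(panel, peaks, genes)
        simulate.export_fixture(bundle, str(tmp_path / "fx"))
        with open(tmp_path / "fx" / "peaks.bed") as fh:
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                assert len(fields) >= 4
                assert int(fields[1]) < int(fields[2])

    def test_refuses_nonempty_directory(self, tmp_path, small_architecture):
        panel, peaks, genes, _ = small_architecture
        bundle = simulate.SimBundle(panel, peaks, genes)
        out = tmp_path / "fx"
        simulate.export_fixture(bundle, str(out))
        with pytest.raises(FileExistsError):
            simulate.export_fixture(bundle, str(out))
        simulate.export_fixture(bundle, str(out), overwrite=True)
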