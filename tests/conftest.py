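import logging

import numpy as np
import pytest

from qtlcoloc import simulate

logging.getLogger("qtlcoloc").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_panel():
    """Shared 300-sample, 300-variant panel with moderate LD."""
    return simulate.simulate_genotype_panel(
        300, 300, 2_000_000, (0.05, 0.5), ld_decay=15_000, n_blocks=6, seed=101
    )


@pytest.fixture(scope="session")
def small_architecture(small_panel):
    """Panel plus a mediating architecture with calibrated disease truths."""
    peaks, genes = simulate.layout_peaks_genes(small_panel, 30, 20, seed=101)
    model = simulate.simulate_regulatory_model(
        small_panel,
        peaks,
        genes,
        p_causal_peak=0.8,
        sigma_ca=2.0,
        gamma_scale=0.7,
        delta_scale=1.0,
        disease_gene_frac=0.5,
        p_causal_direct=0.5,
        direct_scale=0.6,
        max_wiring_dist=250_000,
        target_h2_snp=0.3,
        target_prop_mediated=0.5,
        seed=101,
    )
    return small_panel, peaks, genes, model


def rng_for(test_tag: str) -> np.random.Generator:
    return np.random.default_rng(abs(hash(test_tag)) % (2**31))
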