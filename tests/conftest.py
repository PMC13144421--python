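import numpy as np
import pytest

from diploscan.pseudogenes import translate_cds
from diploscan.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def rich_sim():
    """One moderately sized diploidized-tetraploid genome exercising every
    process: fractionation with residuals, pseudogenization, retrocopies,
    tandem duplications, intronic TEs."""
    cfg = SimulationConfig(
        seed=3,
        n_chromosome_pairs=2,
        genes_per_chromosome=80,
        wgd_divergence=0.03,
        fractionation_prob=0.2,
        pseudogenization_prob=0.15,
        retrocopy_prob=0.08,
        tandem_dup_prob=0.03,
        residual_prob=0.6,
        te_insertions_per_intron=0.4,
    )
    bundles, truth = simulate(cfg)
    return cfg, bundles, truth


@pytest.fixture(scope="session")
def null_sim():
    """No divergence, no fractionation, no pseudogenes, no TEs: two identical
    homoeologous sets."""
    cfg = SimulationConfig(
        seed=5, n_chromosome_pairs=2, genes_per_chromosome=40, wgd_divergence=0.0
    )
    bundles, truth = simulate(cfg)
    return cfg, bundles, truth


def curated_from_outgroup(bundles):
    """Curated reference proteins: the outgroup's first-haplotype proteome,
    keyed by family (= ancestral gene) id."""
    og = bundles["outgroup"]
    return {
        g.family_id: translate_cds(g.spliced_cds(og.sequences))
        for g in og.genes
        if g.gene_id.endswith("_O1")
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
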