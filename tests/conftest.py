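import numpy as np
import pytest

from gbmethyl import synthetic_data as sd


@pytest.fixture(scope="session")
def small_config():
    """A compact study: one 120-kb scaffold, 30 genes."""
    return sd.paper_like(seed=11, n_scaffolds=1, scaffold_length=120_000, n_genes=30)


@pytest.fixture(scope="session")
def small_study(small_config):
    rng = np.random.default_rng(small_config.seed)
    genome, annotation, truth = sd.generate_genome(small_config, rng)
    return genome, annotation, truth


@pytest.fixture(scope="session")
def small_sites(small_config, small_study):
    """Retained CpG sites for the small study at the default depth."""
    _, _, truth = small_study
    rng = np.random.default_rng(101)
    counts = sd.generate_site_counts(truth.cpg_sites, small_config, rng)
    return sd.retained_sites(counts)
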