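import numpy as np
import pytest
from hypothesis import settings

from homoeoscan import arrayio, pipeline, synthdata

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def deletion_cfg():
    """Mid-sized cohort with planted deletions, shared across module tests."""
    return synthdata.GeneratorConfig(
        n_genes=300, seed=11, n_chromosomes=2,
        fraction_At_deleted=0.1, fraction_Aa_deleted=0.1)


@pytest.fixture(scope="session")
def deletion_bundle(deletion_cfg):
    return synthdata.simulate(deletion_cfg)


@pytest.fixture(scope="session")
def deletion_truth(deletion_bundle):
    return deletion_bundle.truth.set_index("gene_id")


@pytest.fixture(scope="session")
def deletion_gene_bundles(deletion_bundle):
    table = arrayio.ProbeIntensityTable(deletion_bundle.probes)
    pre = arrayio.preprocess(table, background="none",
                             groups=arrayio.PER_GENOTYPE_GROUPS)
    return pipeline.assemble_genes(pre)


@pytest.fixture(scope="session")
def retention_run(deletion_gene_bundles):
    result, extras = pipeline.run_retention(deletion_gene_bundles)
    return result, extras


@pytest.fixture(scope="session")
def expression_run(deletion_gene_bundles, retention_run):
    _, extras = retention_run
    return pipeline.run_expression(deletion_gene_bundles, extras["per_gene"])


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
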