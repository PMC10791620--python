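import numpy as np
import pytest

from stratamap.formats_io import GeneModel, Sample, VariantSite, load_table1_fixture
from stratamap.synthetic_data import SimConfig, build_truth


@pytest.fixture(scope="session")
def fixture_rows():
    return load_table1_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_gene():
    # 10 codons, no stops
    return GeneModel(gene_id="g1", pos_kb=100.0, cds="ATGGCTGGAACCCTTGAAGGTCACTTCAAA")


def make_site(gene_id="g1", cds_pos=1, ref="A", alt="G", quality=1000.0, genotypes=None):
    return VariantSite(
        gene_id=gene_id,
        cds_pos=cds_pos,
        ref=ref,
        alt=alt,
        quality=quality,
        genotypes=genotypes or {},
    )


@pytest.fixture(scope="session")
def small_truth():
    """Error-free cross + wild truth shared by several test modules."""
    cfg = SimConfig(
        seed=11,
        n_genes=12,
        cds_len=300,
        theta_per_site=0.02,
        boundaries_kb=(27000.0, 27000.0, 41500.0),
        par_recomb_prob=0.0,
        depth=30.0,
        err=0.0,
    )
    return build_truth(cfg)
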