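import pytest

from tissue_ase import (Assay, AlleleCountRecord, HetSite, SimConfig,
                        VariantClass, simulate_dataset, smoke_config)


@pytest.fixture
def ct_site():
    return HetSite(site_id="s1", chrom="chr1", pos=100, ref_base="C",
                   alt_base="T", gene_id="G1")


@pytest.fixture
def site_map():
    return {
        "s1": HetSite(site_id="s1", chrom="chr1", pos=100, ref_base="C",
                      alt_base="T", gene_id="G1"),
        "s2": HetSite(site_id="s2", chrom="chr1", pos=200, ref_base="A",
                      alt_base="G", gene_id="G2",
                      variant_class=VariantClass.NONSENSE, maf=0.12),
        "s3": HetSite(site_id="s3", chrom="chr1", pos=300, ref_base="G",
                      alt_base="A", is_intragenic=False),
    }


def make_record(site_id="s1", tissue="liver", rep="rep1", assay=Assay.MMPCR,
                ref=50, alt=50, other=0):
    return AlleleCountRecord(site_id=site_id, tissue_id=tissue, replicate_id=rep,
                             assay=assay, ref_count=ref, alt_count=alt,
                             other_count=other)


@pytest.fixture(scope="session")
def smoke_dataset():
    """Small simulated dataset shared across tests (fixed seed)."""
    return simulate_dataset(smoke_config(seed=7))


@pytest.fixture(scope="session")
def default_dataset():
    """Default-sized simulated dataset (500 sites, 8 tissues)."""
    return simulate_dataset(SimConfig(seed=101))
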