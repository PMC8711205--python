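import pytest

from chromintegrate.intervals import GeneModel, GenomicInterval
from chromintegrate.synthetic import SimulationConfig


@pytest.fixture
def plus_gene() -> GeneModel:
    return GeneModel("geneP", GenomicInterval("chr1", 10000, 15000, "+"))


@pytest.fixture
def minus_gene() -> GeneModel:
    return GeneModel("geneM", GenomicInterval("chr1", 5000, 10001, "-"))


@pytest.fixture
def small_sim() -> SimulationConfig:
    """A scaled-down simulation for fast end-to-end tests."""
    return SimulationConfig(
        seed=7,
        n_chroms=2,
        chrom_length=400_000,
        n_genes=20,
        n_tes=60,
        n_planted_enriched=6,
        n_regions=200,
        n_planted_diff=10,
        planted_categories={"I": 2, "II": 3, "III": 1},
    )
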