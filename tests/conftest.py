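import numpy as np
import pytest

from popqtl.simulate import (
    GenomeConfig,
    QTLSpec,
    SimConfig,
    SpatialConfig,
    TraitModel,
    make_map,
    simulate_backcross,
)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(
        n_chrom=3,
        markers_per_chrom=6,
        chrom_length_cM=100.0,
        n_genotypes=200,
        ramets_per_genotype=2,
        missing_rate=0.0,
        qtl_spec=(QTLSpec(2, 40.0, 1.0, "trait"),),
        trait_models={"trait": TraitModel(family="normal", h2=0.4)},
        spatial=SpatialConfig(amplitude=0.0),
        genome=GenomeConfig(genes_per_chrom=200, mean_intergenic_bp=8_000),
        seed=101,
    )


@pytest.fixture(scope="session")
def small_map(small_cfg):
    return make_map(small_cfg)


@pytest.fixture(scope="session")
def small_geno(small_map, small_cfg):
    return simulate_backcross(small_map, small_cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
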