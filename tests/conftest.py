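import pytest

from nlrcnv.io_formats import GeneModel
from nlrcnv.simulate import RegimeParams, SimConfig, simulate_dataset


def gene(gid, chrom, start, end, genotype="GT", exons=None, **kw):
    """Terse GeneModel builder for tests."""
    return GeneModel(
        gene_id=gid,
        genotype=genotype,
        chrom=chrom,
        start=start,
        end=end,
        exons=exons or [(start, end)],
        **kw,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Two high- and two low-regime genotypes at desk scale."""
    cfg = SimConfig(
        seed=11,
        n_genotypes=4,
        regimes=("high", "high", "low", "low"),
        n_background_genes=120,
        n_nlr_founders=12,
    )
    return cfg, simulate_dataset(cfg)


@pytest.fixture(scope="session")
def tandem_only_cohort():
    """Segmental and dispersed planting disabled: every duplicate is local."""
    cfg = SimConfig(
        seed=7,
        n_genotypes=2,
        regimes=("high", "high"),
        n_background_genes=80,
        n_nlr_founders=10,
        high=RegimeParams(3, 1.0, 0.0, 0.0, 0.0),
        p_pseudogenize=0.0,
    )
    return cfg, simulate_dataset(cfg)
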