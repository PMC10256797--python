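import pytest

from ylandscape import GenomeDef, MappingSummary
from ylandscape import simulate as sim


@pytest.fixture
def two_chrom_genome() -> GenomeDef:
    """chrA diploid without gaps, chrY haploid with a 100 bp gap."""
    return GenomeDef(
        [("chrA", 1000), ("chrY", 500)],
        gaps={"chrY": [(100, 200)]},
        ploidy={"chrY": 1},
    )


@pytest.fixture
def proportional_summary(two_chrom_genome) -> MappingSummary:
    g = two_chrom_genome
    return MappingSummary(
        "baseline",
        {c: 3 * g.non_n_size(c) * g.chrom_ploidy(c) for c in g.names},
    )


@pytest.fixture(scope="session")
def synthetic_genome():
    return sim.make_genome(seed=11)


@pytest.fixture(scope="session")
def haplogroup_tree():
    return sim.default_tree()
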