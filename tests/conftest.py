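import pytest

from nbith.genome import Arm, Chromosome, EventCallingConfig, GenomeModel


@pytest.fixture(scope="session")
def genome():
    from nbith.genome import load_genome

    return load_genome("default")


@pytest.fixture(scope="session")
def cfg():
    return EventCallingConfig()


def make_mini_genome(n_chroms: int = 2, chrom_len: int = 200_000) -> GenomeModel:
    """Tiny genome for brute-force comparisons: p arm 45%, q arm 45%,
    a 10% centromere gap, one catalogue gene on chromosome 1's p arm."""
    chroms = {}
    arms = {}
    for i in range(1, n_chroms + 1):
        name = str(i)
        cen = (int(chrom_len * 0.45), int(chrom_len * 0.55))
        chroms[name] = Chromosome(name, chrom_len, cen)
        arms[f"{name}p"] = Arm(name, "p", 0, cen[0])
        arms[f"{name}q"] = Arm(name, "q", cen[1], chrom_len)
    genes = {"G1": ("1", int(chrom_len * 0.10), int(chrom_len * 0.12))}
    return GenomeModel(
        "mini", chroms, arms, genes,
        typical_sca_catalog=frozenset({"+1q", "1p-"}),
        atypical_sca_catalog=frozenset({"+2q"} if n_chroms > 1 else set()),
    )


def mini_config(chrom_len: int = 200_000) -> EventCallingConfig:
    """Config with sizes scaled to the mini genome (3 Mb -> 3% of 200 kb)."""
    return EventCallingConfig(
        focal_max_size=int(chrom_len * 0.03),
        min_sca_size=int(chrom_len * 0.03),
        whole_chrom_fraction=0.95,
        cnloh_min_size=int(chrom_len * 0.10),
        shift_tolerance=int(chrom_len * 0.05),
    )


@pytest.fixture(scope="session")
def mini_genome():
    return make_mini_genome()


@pytest.fixture(scope="session")
def mini_cfg():
    return mini_config()
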