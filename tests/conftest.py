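import pytest

from castling import assembly, simulate, targets


@pytest.fixture(scope="session")
def cassette():
    return assembly.synthetic_cassette()


@pytest.fixture(scope="session")
def small_genome():
    """One-chromosome fixture genome with a handful of ORFs on both strands."""
    return simulate.random_genome(n_chroms=1, chrom_len=9000, n_orfs=5, seed=11)


@pytest.fixture(scope="session")
def rules():
    return targets.DesignRules()


@pytest.fixture(scope="session")
def designed_pool(small_genome, cassette, rules):
    """Ranked selection + oligo designs on the small fixture genome."""
    selected, undesignable = targets.select_candidates(small_genome, rules)
    designs, failures = assembly.design_pool(small_genome, selected, cassette, rules)
    return {
        "selected": selected,
        "undesignable": undesignable,
        "designs": designs,
        "failures": failures,
    }
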