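import pytest

from nucshift import fixtures, pipeline


@pytest.fixture(scope="session")
def seven_mer():
    """Single-stranded d(GCGAAGC) toy structure, one model."""
    return fixtures.make_toy_nucleic("GCGAAGC", form="single")


@pytest.fixture(scope="session")
def seven_mer_pipeline(seven_mer):
    """(graph, partition, parents) for the 7-mer at the 5 Å cutoff."""
    return pipeline.build_all_parents(seven_mer, cutoff=5.0)


@pytest.fixture(scope="session")
def duplex24():
    """24-nucleotide toy duplex (12 bp per strand)."""
    return fixtures.make_toy_nucleic("GCGCATGCTACG", form="duplex")


@pytest.fixture(scope="session")
def duplex24_pipeline(duplex24):
    return pipeline.build_all_parents(duplex24, cutoff=5.0)


@pytest.fixture(scope="session")
def aga_peptide():
    return fixtures.make_toy_peptide("AGA")


@pytest.fixture(scope="session")
def gc_synthetic():
    """Small noise-free synthetic system with known truth."""
    st = fixtures.make_toy_nucleic("GCGC", form="single")
    truth = fixtures.SyntheticTruth(sigma_standard=31.0, noise=0.0, seed=3)
    table, sigma, star = fixtures.make_synthetic_shifts(st, truth)
    return st, truth, table, sigma, star
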