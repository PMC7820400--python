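import numpy as np
import pytest

from strpopgen.str_data import AlleleLabel, FrequencyTable, GenotypeTable


@pytest.fixture(scope="session")
def kuwait_freqs():
    from strpopgen import load_kuwait_frequencies

    return load_kuwait_frequencies()


@pytest.fixture(scope="session")
def kuwait_stats():
    from strpopgen import load_kuwait_reported_stats

    return load_kuwait_reported_stats()


def make_genotypes(genotype_counts, locus="L"):
    """Build a one-locus GenotypeTable from {(a, b): count} with int labels."""
    samples, calls = [], {}
    i = 0
    for (a, b), count in genotype_counts.items():
        pair = (AlleleLabel.parse(str(a)), AlleleLabel.parse(str(b)))
        for _ in range(count):
            sid = f"s{i}"
            i += 1
            samples.append(sid)
            calls[sid] = {locus: pair}
    return GenotypeTable(samples, [locus], calls)


def uniform_base(n_loci=10, n_alleles=4, n2=400):
    """Equifrequent multi-allele frequency table for simulations."""
    freqs = {
        f"L{i}": {AlleleLabel(8 + j): 1.0 / n_alleles for j in range(n_alleles)}
        for i in range(n_loci)
    }
    return FrequencyTable(freqs, {f"L{i}": n2 for i in range(n_loci)})


@pytest.fixture
def two_locus_table():
    """Ten individuals typed at two independent-looking loci."""
    rng = np.random.default_rng(0)
    samples, calls = [], {}
    for i in range(10):
        sid = f"s{i}"
        samples.append(sid)
        a = sorted(AlleleLabel(int(x)) for x in rng.integers(10, 13, 2))
        b = sorted(AlleleLabel(int(x)) for x in rng.integers(7, 10, 2))
        calls[sid] = {"A": tuple(a), "B": tuple(b)}
    return GenotypeTable(samples, ["A", "B"], calls)
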