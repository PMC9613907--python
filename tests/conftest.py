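import numpy as np
import pandas as pd
import pytest

from islescan.genotype_io import GenotypeMatrix, SampleSheet


def make_gm(dosage, samples=None, scaffold="s1", positions=None,
            contig_len=None):
    """Build a GenotypeMatrix from a (sites x samples) dosage array."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_sites, n_samples = dosage.shape
    if samples is None:
        samples = [f"ind{i+1}" for i in range(n_samples)]
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 10
    sites = pd.DataFrame({
        "scaffold": [scaffold] * n_sites,
        "pos": positions,
        "ref": ["A"] * n_sites,
        "alt": ["T"] * n_sites,
    })
    lengths = {scaffold: contig_len or int(max(positions, default=1)) + 10}
    return GenotypeMatrix(sites, list(samples), dosage, lengths)


def matching_oracle(a: int, b: int) -> float:
    """Brute-force matching proportion: enumerate the four allele pairings
    of two diploid genotypes given as alt dosages."""
    alleles = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    ai, bi = alleles[a], alleles[b]
    return float(np.mean([x == y for x in ai for y in bi]))


@pytest.fixture
def two_pop_sheet():
    return SampleSheet(
        {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        {"A": "island", "B": "mainland"})
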