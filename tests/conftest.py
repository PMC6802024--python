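import numpy as np
import pytest

from ormiapop.genotype_data import MISSING, GenotypeDataset, LocusInfo


def make_dataset(pop_genotypes, motif=4):
    """Build a GenotypeDataset from {pop: [[(a1,b1),(a2,b2),...], ...]} where
    each individual is a list of per-locus allele pairs; None = missing."""
    n_loci = len(next(iter(pop_genotypes.values()))[0])
    individuals, populations, rows = [], {}, []
    for pop, inds in pop_genotypes.items():
        for k, geno in enumerate(inds):
            ind = f"{pop}_{k + 1}"
            individuals.append(ind)
            populations[ind] = pop
            row = [
                (MISSING, MISSING) if pair is None else pair for pair in geno
            ]
            rows.append(row)
    loci = [LocusInfo(f"L{j + 1}", motif) for j in range(n_loci)]
    return GenotypeDataset(individuals, populations, loci, np.array(rows))


@pytest.fixture
def toy_two_pop():
    # pop A: AA, AB at locus 1 -> counts {100:3, 104:1}
    return make_dataset(
        {
            "A": [[(100, 100), (120, 124)], [(100, 104), (120, 120)]],
            "B": [[(100, 100), (124, 124)], [(100, 100), (120, 124)]],
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
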