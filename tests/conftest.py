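"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from endemica.datamodel import GenotypeTable


def make_table(pops_by_locus):
    """Build a GenotypeTable from {pop: [[(a,b) per locus] per individual]}.

    ``pops_by_locus`` maps a subpopulation name to a list of individuals,
    each a list of (allele1, allele2) tuples, one per locus (0 = missing).
    """
    individuals = []
    rows = []
    n_loci = None
    for pop, inds in pops_by_locus.items():
        for k, genotype in enumerate(inds):
            if n_loci is None:
                n_loci = len(genotype)
            assert len(genotype) == n_loci
            individuals.append((f"{pop}-{k}", pop))
            rows.append(genotype)
    loci = [f"L{j + 1}" for j in range(n_loci)]
    calls = np.array(rows, dtype=np.int64)
    return GenotypeTable(individuals, loci, calls)


def random_table(rng, n_pops=3, n_per_pop=6, n_loci=3, n_alleles=4, p_missing=0.1):
    """A random genotype table for oracle-equivalence checks."""
    alleles = 100 + 2 * np.arange(1, n_alleles + 1)
    pops = {}
    for p in range(n_pops):
        inds = []
        for _ in range(n_per_pop):
            genotype = []
            for _ in range(n_loci):
                if rng.random() < p_missing:
                    genotype.append((0, 0))
                else:
                    a, b = rng.choice(alleles, size=2)
                    genotype.append((int(a), int(b)))
            inds.append(genotype)
        pops[f"P{p + 1}"] = inds
    return make_table(pops)


def pop_locus_genotypes(g, pop, locus):
    """Extract [(a, b), ...] for one (subpopulation, locus) from a table."""
    j = g.loci.index(locus)
    return [tuple(int(x) for x in g.calls[i, j]) for i in g.pop_indices(pop)]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
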