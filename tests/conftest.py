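"""Shared fixtures: tiny hand-built pedigrees and a reduced synthetic population."""

import numpy as np
import pytest

from pedbias import (Individual, Pedigree, SyntheticConfig, generate_pedigree,
                     simulate_trait)

# reduced study population used by the slower statistical tests: same shape
# as the default (six cohorts, 12.5% EPY, clustered nests), smaller counts
SMALL_CONFIG = SyntheticConfig(n_founders=240, n_offspring=150)


def trio(ids=("S1", "D1", "O1")):
    """Two unrelated founders and one offspring."""
    s, d, o = ids
    return [
        Individual(s, "M", 2000),
        Individual(d, "F", 2000),
        Individual(o, "M", 2001, dam_id=d, social_sire_id=s,
                   genetic_sire_id=s, brood_id="B1"),
    ]


@pytest.fixture(scope="session")
def trio_pedigree():
    return Pedigree(trio())


@pytest.fixture(scope="session")
def small_population():
    return generate_pedigree(SMALL_CONFIG, seed=11)


@pytest.fixture(scope="session")
def default_population():
    """The full-size study population (960 founders, 593 offspring)."""
    return generate_pedigree(seed=11)


@pytest.fixture(scope="session")
def small_trait(small_population):
    return simulate_trait(small_population.social, "social", 0.5, seed=5)


def random_pedigree(rng, n=15, n_founders=6, cohorts=3):
    """A random multi-generation pedigree for oracle comparisons."""
    inds = []
    males, females = [], []
    for k in range(n_founders):
        sex = "M" if k % 2 == 0 else "F"
        ident = f"P{k}"
        inds.append(Individual(ident, sex, 2000))
        (males if sex == "M" else females).append(ident)
    for k in range(n - n_founders):
        year = 2001 + int(rng.integers(cohorts))
        pool_m = [i for i in inds if i.sex == "M" and i.cohort < year]
        pool_f = [i for i in inds if i.sex == "F" and i.cohort < year]
        sire = pool_m[rng.integers(len(pool_m))].id if pool_m else None
        dam = pool_f[rng.integers(len(pool_f))].id if pool_f else None
        sex = "M" if rng.random() < 0.5 else "F"
        ident = f"I{k}"
        inds.append(Individual(ident, sex, year, dam_id=dam,
                               social_sire_id=sire, genetic_sire_id=sire))
    order = rng.permutation(len(inds))
    return Pedigree([inds[i] for i in order])
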