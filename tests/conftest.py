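"""Shared fixtures: small simulated populations reused across test modules."""

import numpy as np
import pytest

import trmgs as t


@pytest.fixture(scope="session")
def founders_2chr():
    chroms = [t.ChromSpec("c1", 50_000_000, 80.0), t.ChromSpec("c2", 50_000_000, 80.0)]
    return t.simulate_founders(1000, chroms, seed=11)


@pytest.fixture(scope="session")
def f2_pop(founders_2chr):
    return t.make_f2_population(founders_2chr, 150, seed=12)


@pytest.fixture(scope="session")
def ril_pop(founders_2chr):
    return t.make_ril_population(founders_2chr, 120, 6, seed=13)


@pytest.fixture(scope="session")
def f2_binmap(f2_pop):
    return t.make_binmap(f2_pop)


@pytest.fixture(scope="session")
def natural_panel():
    chroms = [t.ChromSpec("c1", 50_000_000, 80.0)]
    founders = t.simulate_founders(
        2000, chroms, maf_law=lambda rng, size: rng.uniform(0.1, 0.5, size), seed=21
    )
    geno, labels = t.make_natural_population(founders, 2, 100, 0.2, seed=22)
    return geno, labels


@pytest.fixture(scope="session")
def f2_trait(f2_pop):
    """Additive F2 trait with multi-environment records and its truth."""
    arch = t.random_architecture(f2_pop.n_markers, n_additive=20, fa=0.5, seed=31)
    records, truth = t.simulate_phenotypes(f2_pop, arch, n_envs=2, n_reps=2, seed=32)
    return arch, records, truth
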