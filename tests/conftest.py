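"""Shared fixtures: energy tables, small oracle fixtures (fully enumerable),
and the session-wide optimizer pool used by the search tests."""

from __future__ import annotations

import random

import pytest

from branchfold.bnb import PairCache, build_region_lists
from branchfold.energy import EnergyTables
from branchfold.fixtures import FixtureSpec, generate, generate_family
from branchfold.polytope import build_polytope
from branchfold.structures import clean_reference


@pytest.fixture(scope="session")
def tables() -> EnergyTables:
    return EnergyTables.load()


#: Small fixtures whose structure spaces are fully enumerable in well under
#: a second each; the brute-force oracles run on these.
ORACLE_SPECS = [
    FixtureSpec(shape="hairpin", helix_lengths=(4,), loop_sizes=(4,), seed=1),
    FixtureSpec(shape="Y3", helix_lengths=(2, 2, 2), loop_sizes=(3, 3, 0, 0, 0),
                seed=7, tail=(0, 0)),
    FixtureSpec(shape="Y3", helix_lengths=(2, 2, 2), loop_sizes=(3, 4, 1, 0, 1),
                seed=3, mutation_rate=0.1, tail=(1, 0)),
    FixtureSpec(shape="cloverleaf4", helix_lengths=(2, 2, 2, 2),
                loop_sizes=(3, 3, 3, 0, 0, 0, 0), seed=5, tail=(0, 0)),
]


@pytest.fixture(scope="session")
def oracle_fixtures():
    return [generate(spec) for spec in ORACLE_SPECS]


def make_pool(tables):
    """The mixed Y3/cloverleaf family behind the optimizer tests: four
    fixtures of each shape, mutated, small enough that the exhaustive
    oracle stays tractable at N = 8."""
    fam = (
        generate_family(
            FixtureSpec(shape="Y3", helix_lengths=(2, 2, 2),
                        loop_sizes=(3, 3, 0, 0, 0), mutation_rate=0.12,
                        tail=(0, 0)), 4, seed=31)
        + generate_family(
            FixtureSpec(shape="cloverleaf4", helix_lengths=(2, 2, 2, 2),
                        loop_sizes=(3, 3, 3, 0, 0, 0, 0), mutation_rate=0.12,
                        tail=(0, 0)), 4, seed=32)
    )
    polys = [build_polytope(s, tables) for s, _ in fam]
    refs = [clean_reference(r, s) for s, r in fam]
    lists = build_region_lists(polys, refs, tables)
    return fam, polys, refs, lists


@pytest.fixture(scope="session")
def bnb_pool(tables):
    fam, polys, refs, lists = make_pool(tables)
    cache = PairCache(lists)
    return {"family": fam, "polytopes": polys, "references": refs,
            "lists": lists, "cache": cache}


def instance_schedule(seed: int = 1):
    """The 20 seeded optimizer instances: subsets of the pool with
    N = 2..8 sequences, mixing both shapes."""
    rng = random.Random(seed)
    sizes = [2] * 5 + [3] * 5 + [4] * 4 + [5, 5, 6, 6, 7, 8]
    return [sorted(rng.sample(range(8), n)) for n in sizes]
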