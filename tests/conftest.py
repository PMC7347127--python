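import logging

import pytest

from ontosim import FixtureSpec, compute_ic, make_fixture, toy5

# obonet logs a warning for headerless synthetic files; keep test output clean
logging.getLogger().setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def toy():
    """The 5-term worked-example ontology with its 3-entity corpus and IC."""
    graph, corpus = toy5()
    return graph, corpus, compute_ic(graph, corpus)


import functools


@functools.lru_cache(maxsize=512)
def _cached_fixture(seed, items):
    spec = FixtureSpec(
        n_terms=15, n_entities=8, max_parents=2, part_of_fraction=0.25,
        annotations_per_entity=(1, 3), seed=seed, **dict(items),
    )
    graph, corpus = make_fixture(spec)
    return graph, corpus, compute_ic(graph, corpus)


def random_fixture(seed: int, **overrides):
    """A seeded random DAG + corpus + IC table for property tests (cached)."""
    return _cached_fixture(seed, tuple(sorted(overrides.items())))
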