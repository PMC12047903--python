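"""Shared fixtures: one toy chemical space and a seeded route corpus."""

import random

import pytest

from synspace import (
    PerfectOracle,
    make_toy_space,
    route_to_record,
    sample_corpus,
)


@pytest.fixture(scope="session")
def space():
    """Default toy space: 7 families x 20 blocks + 5 coupling templates."""
    return make_toy_space(n_per_family=20, seed=0)


@pytest.fixture(scope="session")
def corpus_routes(space):
    """50 seeded routes with unique targets."""
    return sample_corpus(space, 50, rng=random.Random(42))


@pytest.fixture(scope="session")
def records(space, corpus_routes):
    return [route_to_record(r, space.registry) for r in corpus_routes]


@pytest.fixture(scope="session")
def oracle(records):
    return PerfectOracle(records)
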