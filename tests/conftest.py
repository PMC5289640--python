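"""Shared fixtures: small hand-built populations and datasets."""

import numpy as np
import pytest
from hypothesis import settings

from tcrpair.simdata import (
    Clone,
    ClonePopulation,
    SamplingPlan,
    Well,
    WellDataset,
    generate_population,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_population(specs, drop=0.0, err=0.0):
    """Build a ClonePopulation from (alpha_ids, beta_ids, frequency) triples
    with uniform drop and error rates."""
    clones = [
        Clone(alpha_ids=tuple(a), beta_ids=tuple(b), frequency=f, drop_rate=drop)
        for a, b, f in specs
    ]
    alpha_err = {cid: err for c in clones for cid in c.alpha_ids}
    beta_err = {cid: err for c in clones for cid in c.beta_ids}
    return ClonePopulation(clones, alpha_err, beta_err)


@pytest.fixture
def clean_population():
    """Sharing-free, dual-free, error-free: 6 clones with distinct chains."""
    n = 6
    specs = [((f"a{i}",), (f"b{i}",), 1.0 / n) for i in range(n)]
    return make_population(specs)


@pytest.fixture
def toy_wells():
    """The two-well worked example used for the score arithmetic."""
    return WellDataset(
        [
            Well(size=5, alpha_set=frozenset({"a1", "a2"}), beta_set=frozenset({"b1"})),
            Well(size=5, alpha_set=frozenset({"a1"}), beta_set=frozenset({"b1", "b3"})),
        ]
    )


@pytest.fixture(scope="session")
def default_population():
    """One default-parameter population (2100 clones, 25 in the top 50%)."""
    return generate_population(seed=20)
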