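"""Shared fixtures: synthetic structures and their detection pipelines."""

import numpy as np
import pytest

from ankpred import (
    AnkFixtureSpec,
    build_ank_fixture,
    build_contact_network,
    principal_eigenvector,
)
from ankpred.ss_assign import assign_internal


@pytest.fixture(scope="session")
def ank4():
    """4-copy ANK-like fixture with its network, profile and segments."""
    chain = build_ank_fixture(AnkFixtureSpec(n_copies=4, seed=1))
    net = build_contact_network(chain)
    profile = principal_eigenvector(net)
    segments = assign_internal(chain)
    return chain, net, profile, segments


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
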