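"""Shared fixtures: networks are built once per session (structure is
immutable; tests that mutate bounds work on copies)."""

import numpy as np
import pytest

from gutflux.network import (CrowdingSampler, MetabolicNetwork, Metabolite,
                             Reaction, build_toy_network, split_reversible)


@pytest.fixture(scope="session")
def toy_net():
    return build_toy_network()


@pytest.fixture(scope="session")
def split_toy(toy_net):
    return split_reversible(toy_net)


@pytest.fixture()
def sampler():
    return CrowdingSampler(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def chain_net():
    """The hand-solvable one-variable problem: glucose import (a=0.01,
    ub=10) feeding a 2-ATP catabolic lump (a=0.05), ATP sink objective.
    At V_prot=0.2 the crowding row binds: f = 0.2/0.06 = 10/3."""
    mets = [Metabolite("glc", carbon_count=6), Metabolite("atp")]
    rxns = [
        Reaction("UP", {"glc": 1}, 0, 10, 0.01),
        Reaction("CAT", {"glc": -1, "atp": 2}, 0, 999999, 0.05),
        Reaction("ATPM", {"atp": -1}, 0, 999999, 0.0),
    ]
    return MetabolicNetwork(mets, rxns, "ATPM")
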