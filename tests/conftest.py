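import pytest

import mcskit as mk


@pytest.fixture
def chain():
    return mk.make_toy("chain")


@pytest.fixture
def diamond():
    return mk.make_toy("diamond")


@pytest.fixture
def branch():
    return mk.make_toy("branch")


@pytest.fixture
def cycle_rev():
    return mk.make_toy("cycle_rev")


def target_ge(net, rid, value=1.0, label="target"):
    """Target polyhedron {r : r_rid >= value}."""
    return mk.LinearFluxConstraintSet.flux_bound(net, rid, ">=", value,
                                                 label=label)


def oracle_mcs(net, target_rxn, max_size, universe=None):
    """Ground-truth MCS family: Berge transversal of the oracle's target EMs."""
    tems = mk.target_em_supports(net, [target_rxn])
    if universe is None:
        universe = net.reaction_ids
    return set(mk.minimal_hitting_sets(tems, universe, max_size))


def milp_mcs(net, target_rxn, max_size, algorithm="fixed_size", mode="bigm",
             value=1.0, **kwargs):
    """MILP-path MCS family for a single-reaction target r >= value."""
    target = target_ge(net, target_rxn, value)
    problem = mk.InterventionProblem(net, target, max_size=max_size)
    config = mk.EnumerationConfig(algorithm=algorithm, size_ub=max_size,
                                  mode=mode, **kwargs)
    return mk.smallest_mcs(problem, config)


def random_net(seed, n_reactions=8, n_metabolites=4, reversible_fraction=0.25):
    return mk.make_random(mk.ToyNetworkSpec(
        seed=seed, n_metabolites=n_metabolites, n_reactions=n_reactions,
        reversible_fraction=reversible_fraction))
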