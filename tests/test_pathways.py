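"""Pathway enumeration semantics on hand-built networks, net reactions,
limit monotonicity, and the Reaxys batch plumbing."""

import pytest

from routenet.fixtures import planted_network
from routenet.model import Molecule
from routenet.pathways import (
    PathwayError, SearchLimits, StoichiometryError, find_pathways, net_reaction,
    write_reaxys_batch,
)

from conftest import build_network

LIMITS = SearchLimits(max_steps=8, max_generations=8)


def test_linear_chain_single_pathway(linear_net):
    found = find_pathways(linear_net, "C", ["A"], [], LIMITS)
    assert len(found) == 1
    assert found[0].reactions == ["r1|A>>B", "r2|B>>C"]
    assert found[0].feedstocks == ["A"]
    assert found[0].depth == 2


def test_diamond_two_pathways(diamond_net):
    found = find_pathways(diamond_net, "C", ["A"], [], LIMITS)
    assert len(found) == 2
    sets = {frozenset(p.reactions) for p in found}
    assert sets == {
        frozenset({"r1|A>>B", "r3|B>>C"}),
        frozenset({"r2|A>>B2", "r4|B2>>C"}),
    }


def test_convergent_fork_includes_both_branches(convergent_net):
    """Multi-reactant step: the routes to each reactant are integral to the
    pathway, so all three reactions appear in the single result."""
    found = find_pathways(convergent_net, "C", ["A", "D"], [], LIMITS)
    assert len(found) == 1
    assert set(found[0].reactions) == {"r1|A>>B", "r2|D>>E", "r3|B.E>>C"}
    assert found[0].feedstocks == ["A", "D"]


def test_atom_economy_limit_drops_wasteful_branch():
    """Diamond where one branch dumps a heavy by-product: a threshold above
    that branch's net AE leaves exactly one pathway."""
    net = build_network(
        [
            ("r1", ["A"], ["B"]),
            ("r2", ["A"], ["B2", "W"]),  # heavy waste W
            ("r3", ["B"], ["C"]),
            ("r4", ["B2"], ["C"]),
        ],
        masses={"A": 100.0, "B": 100.0, "B2": 50.0, "W": 50.0, "C": 100.0},
    )
    loose = find_pathways(net, "C", ["A"], [], SearchLimits(max_steps=4, max_generations=4))
    assert len(loose) == 2
    # branch via r2: net products C + W -> AE = 100/150 = 2/3
    tight = find_pathways(
        net, "C", ["A"], [],
        SearchLimits(max_steps=4, max_generations=4, min_atom_economy=0.8),
    )
    assert len(tight) == 1
    assert set(tight[0].reactions) == {"r1|A>>B", "r3|B>>C"}


def test_helpers_are_always_terminal(convergent_net):
    """Declaring E's source a helper removes the need for its producer."""
    found = find_pathways(convergent_net, "C", ["A"], ["E"], LIMITS)
    keys = {frozenset(p.reactions) for p in found}
    assert frozenset({"r1|A>>B", "r3|B.E>>C"}) in keys


def test_cycle_never_returned():
    net = build_network([
        ("r1", ["A"], ["B"]),
        ("r2", ["B"], ["X"]),
        ("r3", ["X"], ["B"]),  # 2-cycle B <-> X
        ("r4", ["B"], ["C"]),
    ])
    found = find_pathways(net, "C", ["A"], [], LIMITS)
    assert {frozenset(p.reactions) for p in found} == {frozenset({"r1|A>>B", "r4|B>>C"})}


def test_target_absent_raises(linear_net):
    with pytest.raises(PathwayError):
        find_pathways(linear_net, "ZZZ", ["A"], [], LIMITS)


def test_max_pathways_cap_flags_incomplete(diamond_net):
    capped = find_pathways(
        diamond_net, "C", ["A"], [],
        SearchLimits(max_steps=4, max_generations=4, max_pathways=1),
    )
    assert len(capped) == 1 and capped.incomplete
    full = find_pathways(diamond_net, "C", ["A"], [], LIMITS)
    assert not full.incomplete


@pytest.mark.parametrize("tighten", ["steps", "ae"])
def test_monotone_limits_never_add_pathways(tighten):
    """Shrinking max_steps or raising min_atom_economy only shrinks results."""
    for seed in range(12):
        pn = planted_network(seed, n_reactions=10)
        loose = find_pathways(
            pn.network, pn.target, pn.starters, pn.helpers,
            SearchLimits(max_steps=6, max_generations=8),
        )
        if tighten == "steps":
            lim = SearchLimits(max_steps=3, max_generations=8)
        else:
            lim = SearchLimits(max_steps=6, max_generations=8, min_atom_economy=0.5)
        tight = find_pathways(pn.network, pn.target, pn.starters, pn.helpers, lim)
        assert {frozenset(p.reactions) for p in tight} <= {
            frozenset(p.reactions) for p in loose
        }


# -- net reactions ---------------------------------------------------------

def test_net_single_reaction_is_itself(linear_net):
    nr = net_reaction(["r1|A>>B"], "B", linear_net)
    assert nr.net_reactants == {"A": 1} and nr.net_products == {"B": 1}


def test_net_cancels_intermediate(linear_net):
    nr = net_reaction(["r1|A>>B", "r2|B>>C"], "C", linear_net)
    assert nr.net_reactants == {"A": 1}
    assert nr.net_products == {"C": 1}
    assert set(nr.multipliers.values()) == {1}


def test_net_two_step_with_coreagent():
    net = build_network([
        ("r1", ["A"], ["B"]),
        ("r2", ["B", "H"], ["C"]),
    ])
    nr = net_reaction(sorted(net.reactions), "C", net)
    assert nr.net_reactants == {"A": 1, "H": 1}
    assert nr.net_products == {"C": 1}


def test_net_integer_multipliers_for_stoichiometric_fork():
    """B is made one-at-a-time but consumed two-at-a-time: the producer step
    must run twice."""
    net = build_network([
        ("r1", ["A"], ["B"]),
        ("r2", ["B", "B"], ["C"]),
    ])
    nr = net_reaction(sorted(net.reactions), "C", net)
    assert nr.multipliers == {"r1|A>>B": 2, "r2|B.B>>C": 1}
    assert nr.net_reactants == {"A": 2}


def test_net_excludes_cofactors():
    net = build_network([("r1", ["A", "COF_IN"], ["C", "COF_OUT"])])
    net.molecules["COF_IN"].roles.add("cofactor")
    net.molecules["COF_OUT"].roles.add("cofactor")
    nr = net_reaction(["r1|A.COF_IN>>C.COF_OUT"], "C", net)
    assert nr.net_reactants == {"A": 1}
    assert nr.net_products == {"C": 1}


def test_net_inconsistent_raises():
    """The target is consumed to make itself one-for-one: no positive
    multipliers can leave a net production."""
    net = build_network([("r1", ["C", "A"], ["C"])])
    with pytest.raises(StoichiometryError):
        net_reaction(["r1|A.C>>C"], "C", net)


# -- Reaxys batch ----------------------------------------------------------

def test_reaxys_batch_dedupes_shared_reactions(diamond_net, tmp_path):
    found = find_pathways(diamond_net, "C", ["A"], [], LIMITS)
    # share r1|A>>B across both pathway files by duplicating the list
    batch, template = write_reaxys_batch(found + found, diamond_net, tmp_path / "batch.txt")
    lines = batch.read_text().strip().splitlines()
    assert len(lines) == 4  # union of reactions, not sum over pathways
    rows = template.read_text().strip().splitlines()
    assert rows[0] == "reaction_index,hits"
    assert len(rows) - 1 == len(lines)
    assert all(row.endswith(",0") for row in rows[1:])


def test_reaxys_batch_empty_list_raises(diamond_net, tmp_path):
    with pytest.raises(PathwayError):
        write_reaxys_batch([], diamond_net, tmp_path / "batch.txt")
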