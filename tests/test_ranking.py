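"""Criterion values, min-max normalization, totals, ranks, and weight sweeps."""

import pytest

from routenet.expand import ExpansionConfig, expand
from routenet.model import Molecule, Network, Reaction
from routenet.pathways import NetReaction, SearchLimits, find_pathways
from routenet.ranking import (
    DEFAULT_WEIGHTS, RankingContext, RankingError, atom_economy,
    byproduct_numbers, criterion_values, normalize_and_rank, validate_weights,
    weight_sweep,
)

from conftest import build_network


# -- atom economy ----------------------------------------------------------

def _net(target, reactants, products, masses):
    network = build_network([("r", list(reactants), list(products))], masses=masses)
    return NetReaction(
        target=target,
        net_reactants={m: 1 for m in reactants},
        net_products={m: list(products).count(m) for m in set(products)},
        multipliers={},
    ), network


def test_atom_economy_isomerization_is_one():
    nr, net = _net("B", ["A"], ["B"], {"A": 58.1, "B": 58.1})
    assert atom_economy(nr, net) == 1.0


def test_atom_economy_styrene_dehydrogenation():
    nr, net = _net(
        "STY", ["EB"], ["STY", "H2"],
        {"EB": 106.17, "STY": 104.15, "H2": 2.016},
    )
    assert atom_economy(nr, net) == pytest.approx(0.981, abs=0.001)


def test_atom_economy_counts_one_desired_copy():
    """Ether hydrolysis yields two ethanol, only one of which is desired."""
    nr, net = _net("EtOH", ["Ether", "W"], ["EtOH", "EtOH"],
                   {"Ether": 74.12, "W": 18.02, "EtOH": 46.07})
    assert atom_economy(nr, net) == pytest.approx(0.5, abs=1e-9)


# -- by-product numbers ----------------------------------------------------

@pytest.fixture(scope="module")
def ethene_pathway(rules):
    """Real-chemistry pathway ethene -> ethanol -> acetaldehyde."""
    cfg = ExpansionConfig(
        strategy="forward", generations=2, rules=rules,
        starters=["C=C"], helpers=["O"],
    )
    net = expand(cfg)
    found = find_pathways(net, "CC=O", ["C=C"], ["O"], SearchLimits(max_steps=3, max_generations=3))
    assert found
    return net, found[0]


def test_byproduct_numbers_on_real_pathway(rules, rules_by_id, ethene_pathway):
    net, pw = ethene_pathway
    soup_bp, inter_bp = byproduct_numbers(pw, rules, net)
    assert soup_bp > 0  # the soup is reactive under the full demo rule set
    assert inter_bp >= 0
    # a rule that cannot touch the soup changes nothing
    soup_bp2, inter_bp2 = byproduct_numbers(pw, rules + [rules_by_id["c25"]], net)
    assert (soup_bp2, inter_bp2) == (soup_bp, inter_bp)


def test_byproduct_numbers_inert_soup(rules):
    """A pathway over species no demo rule matches produces (0, 0)."""
    net = build_network([("r1", ["ClCl"], ["Cl", "Cl"])])
    found = find_pathways(net, "Cl", ["ClCl"], [], SearchLimits(max_steps=2, max_generations=2))
    pw = found[0]
    assert byproduct_numbers(pw, rules, net) == (0, 0)


# -- criterion values ------------------------------------------------------

def test_criterion_values_salt_and_steps(rules, benson):
    net = Network()
    for m in ("CCCl", "N", "CCN", "Cl"):
        net.add_molecule(Molecule(key=m))
    net.add_reaction(Reaction(rule_id="c12", reactants=["CCCl", "N"], products=["CCN", "Cl"]))
    found = find_pathways(net, "CCN", ["CCCl"], ["N"], SearchLimits(max_steps=2, max_generations=2))
    pw = found[0]
    vals = criterion_values(pw, RankingContext(network=net, rules=rules, thermo=benson))
    assert vals["n_steps"] == 1
    assert vals["salt_score"] == 1  # c12 is a salt-forming nitrogen rule
    assert vals["max_dh"] is not None


def test_max_dh_is_worst_step(benson):
    net = build_network([("r1", ["A"], ["B"]), ("r2", ["B"], ["C"])])
    net.reactions["r1|A>>B"].dh_rxn = -10.0
    net.reactions["r2|B>>C"].dh_rxn = 12.0
    found = find_pathways(net, "C", ["A"], [], SearchLimits(max_steps=3, max_generations=3))
    vals = criterion_values(found[0], RankingContext(network=net))
    assert vals["max_dh"] == 12.0


def test_reaxys_hits_percentage(linear_net):
    found = find_pathways(linear_net, "C", ["A"], [], SearchLimits(max_steps=3, max_generations=3))
    pw = found[0]
    all_hit = {k: True for k in pw.reactions}
    vals = criterion_values(pw, RankingContext(network=linear_net, reported=all_hit))
    assert vals["reaxys_hits"] == 100.0
    half = {pw.reactions[0]: True, pw.reactions[1]: False}
    vals = criterion_values(pw, RankingContext(network=linear_net, reported=half))
    assert vals["reaxys_hits"] == 50.0


def test_profitability_index_and_missing_price(linear_net):
    found = find_pathways(linear_net, "C", ["A"], [], SearchLimits(max_steps=3, max_generations=3))
    pw = found[0]
    ctx = RankingContext(network=linear_net, prices={"A": 1.0, "C": 3.0})
    vals = criterion_values(pw, ctx)
    assert vals["profitability_index"] == pytest.approx(3.0)  # same mass, 3x price
    vals = criterion_values(pw, RankingContext(network=linear_net, prices={"A": 1.0}))
    assert vals["profitability_index"] is None


def test_coolness_sums_rule_type_weights(rules, rules_by_id):
    net = build_network([("c01", ["A"], ["B"]), ("c05", ["B"], ["C"])])
    found = find_pathways(net, "C", ["A"], [], SearchLimits(max_steps=3, max_generations=3))
    ctx = RankingContext(network=net, rules=[rules_by_id["c01"], rules_by_id["c05"]],
                         coolness={"reduction": 2.0, "addition": -1.0})
    vals = criterion_values(found[0], ctx)
    assert vals["coolness"] == 1.0


# -- normalization and ranking ---------------------------------------------

def _vals(**per_pathway):
    """Build a values dict with all criteria None except those given."""
    out = {}
    for key, d in per_pathway.items():
        row = {c: None for c in DEFAULT_WEIGHTS}
        row.update(d)
        out[key] = row
    return out


def test_two_point_normalization():
    values = _vals(p1={"n_steps": 2.0}, p2={"n_steps": 5.0})
    table = normalize_and_rank(values, {"n_steps": 1.0})
    assert table.rank_of("p1") == 1 and table.rank_of("p2") == 2
    by_key = {r.pathway_key: r for r in table.rows}
    assert by_key["p1"].scores["n_steps"] == 1.0  # fewer steps is best
    assert by_key["p2"].scores["n_steps"] == 0.0


def test_scores_bounded_and_extremes_exact():
    values = _vals(
        a={"atom_economy": 0.2, "n_steps": 4.0},
        b={"atom_economy": 0.9, "n_steps": 2.0},
        c={"atom_economy": 0.5, "n_steps": 7.0},
    )
    table = normalize_and_rank(values, {"atom_economy": 0.5, "n_steps": 0.5})
    for row in table.rows:
        for s in row.scores.values():
            if s is not None:
                assert 0.0 <= s <= 1.0
    by_key = {r.pathway_key: r for r in table.rows}
    assert by_key["b"].scores["atom_economy"] == 1.0  # per-criterion best is exactly 1
    assert by_key["a"].scores["atom_economy"] == 0.0
    assert by_key["b"].scores["n_steps"] == 1.0
    assert by_key["c"].scores["n_steps"] == 0.0


def test_degenerate_criterion_scores_one():
    values = _vals(a={"n_steps": 3.0}, b={"n_steps": 3.0})
    table = normalize_and_rank(values, {"n_steps": 1.0})
    assert all(r.scores["n_steps"] == 1.0 for r in table.rows)


def test_totals_reproduce_weighted_sum():
    """Stacked decomposition: total equals sum of score x weight, per row."""
    values = _vals(
        a={"n_steps": 2.0, "max_dh": 30.0, "atom_economy": 0.6},
        b={"n_steps": 4.0, "max_dh": 10.0, "atom_economy": 0.9},
        c={"n_steps": 3.0, "max_dh": 20.0, "atom_economy": 0.3},
    )
    weights = {"n_steps": 0.4, "max_dh": 0.2, "atom_economy": 0.1}
    table = normalize_and_rank(values, weights)
    for row in table.rows:
        expected = sum(
            row.scores[c] * w for c, w in weights.items() if row.scores[c] is not None
        )
        assert row.total == pytest.approx(expected, abs=1e-12)
    # hand-checked row: pathway a scores (1.0, 0.0, 0.5) -> 0.4 + 0 + 0.05
    assert table.rank_of("a") == 1
    by_key = {r.pathway_key: r for r in table.rows}
    assert by_key["a"].total == pytest.approx(0.45, abs=1e-12)


def test_positive_weight_scaling_preserves_ranks():
    values = _vals(
        a={"n_steps": 2.0, "atom_economy": 0.3},
        b={"n_steps": 5.0, "atom_economy": 0.9},
        c={"n_steps": 3.0, "atom_economy": 0.6},
    )
    w1 = {"n_steps": 0.4, "atom_economy": 0.1}
    w10 = {c: 10 * w for c, w in w1.items()}
    r1 = normalize_and_rank(values, w1)
    r10 = normalize_and_rank(values, w10)
    assert [r.pathway_key for r in r1.rows] == [r.pathway_key for r in r10.rows]


def test_single_criterion_matches_raw_sort():
    values = _vals(
        a={"max_dh": 25.0}, b={"max_dh": 5.0}, c={"max_dh": 15.0},
    )
    table = normalize_and_rank(values, {"max_dh": 1.0})
    assert [r.pathway_key for r in table.rows] == ["b", "c", "a"]  # lower dH first
    values = _vals(a={"reaxys_hits": 10.0}, b={"reaxys_hits": 90.0})
    table = normalize_and_rank(values, {"reaxys_hits": 1.0})
    assert table.rank_of("b") == 1  # higher hit rate first


def test_adding_pathway_keeps_pairwise_order_single_criterion():
    base = _vals(a={"n_steps": 2.0}, b={"n_steps": 5.0})
    extended = _vals(a={"n_steps": 2.0}, b={"n_steps": 5.0}, c={"n_steps": 9.0})
    t1 = normalize_and_rank(base, {"n_steps": 1.0})
    t2 = normalize_and_rank(extended, {"n_steps": 1.0})
    assert (t1.rank_of("a") < t1.rank_of("b")) == (t2.rank_of("a") < t2.rank_of("b"))


def test_all_zero_weights_rejected():
    with pytest.raises(RankingError):
        validate_weights({"n_steps": 0.0, "atom_economy": 0.0})
    with pytest.raises(RankingError):
        normalize_and_rank(_vals(a={"n_steps": 1.0}), {"n_steps": 0.0})


def test_unknown_criterion_rejected():
    with pytest.raises(RankingError):
        validate_weights({"speediness": 1.0})


# -- weight sweep ----------------------------------------------------------

def test_sweep_three_criteria_step_point_one_is_66_points():
    values = _vals(
        a={"n_steps": 2.0, "max_dh": 30.0, "atom_economy": 0.6},
        b={"n_steps": 4.0, "max_dh": 10.0, "atom_economy": 0.9},
    )
    grid = weight_sweep(values, ["n_steps", "max_dh", "atom_economy"], step=0.1)
    assert len(grid) == 66  # compositions of 10 into 3 nonnegative parts
    for point in grid:
        assert sum(point["weights"].values()) == pytest.approx(1.0)


def test_sweep_dominant_pathway_ranks_first_everywhere():
    values = _vals(
        best={"n_steps": 1.0, "max_dh": 5.0, "atom_economy": 0.95},
        worse={"n_steps": 4.0, "max_dh": 25.0, "atom_economy": 0.5},
        worst={"n_steps": 6.0, "max_dh": 40.0, "atom_economy": 0.2},
    )
    grid = weight_sweep(values, ["n_steps", "max_dh", "atom_economy"], step=0.1)
    assert all(point["ranks"]["best"] == 1 for point in grid)


def test_sweep_corner_reproduces_single_criterion_sort():
    values = _vals(
        a={"n_steps": 2.0, "atom_economy": 0.1},
        b={"n_steps": 5.0, "atom_economy": 0.9},
    )
    grid = weight_sweep(values, ["n_steps", "atom_economy"], step=0.5)
    corner = next(p for p in grid if p["weights"]["n_steps"] == 1.0)
    single = normalize_and_rank(values, {"n_steps": 1.0})
    assert corner["ranks"] == {k: single.rank_of(k) for k in values}


def test_sweep_bad_step_rejected():
    values = _vals(a={"n_steps": 1.0}, b={"n_steps": 2.0})
    with pytest.raises(RankingError):
        weight_sweep(values, ["n_steps", "atom_economy"], step=0.3)
    with pytest.raises(RankingError):
        weight_sweep(values, ["n_steps"], step=0.1)  # needs 2-5 criteria
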