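"""Multi-criterion pathway ranking.

Eight criteria are computed per pathway: maximum step enthalpy, number of
steps, pathway by-product number, atom economy, salt score, database-hit
percentage, a user-weighted reaction-type preference ("coolness"), and a
profitability index. Each criterion is min-max normalized across the pathway
set — oriented so that 1 is always best — multiplied by a user weight, and
summed into a total score that determines the ranking. Weights need not sum
to anything in particular: only their relative sizes matter, and rescaling
all weights by a positive constant cannot change the ranking.

The intermediate by-product number is computed and reported as a reactivity
indicator but carries zero weight by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

from routenet.expand import one_generation
from routenet.model import Molecule, Network
from routenet.pathways import NetReaction, Pathway
from routenet.rules import ReactionRule
from routenet.thermo import ThermoModel, reaction_enthalpy

log = logging.getLogger(__name__)

BENEFIT_CRITERIA = {"atom_economy", "reaxys_hits", "coolness", "profitability_index"}
COST_CRITERIA = {"max_dh", "n_steps", "pathway_byproducts", "salt_score",
                 "intermediate_byproducts"}
ALL_CRITERIA = sorted(BENEFIT_CRITERIA | COST_CRITERIA)

#: Default weights: step count dominates, thermodynamics and by-products
#: next, atom economy least; the remaining criteria are opt-in.
DEFAULT_WEIGHTS: dict[str, float] = {
    "n_steps": 0.4,
    "max_dh": 0.2,
    "pathway_byproducts": 0.2,
    "atom_economy": 0.1,
    "salt_score": 0.0,
    "reaxys_hits": 0.0,
    "coolness": 0.0,
    "profitability_index": 0.0,
    "intermediate_byproducts": 0.0,
}


class RankingError(ValueError):
    pass


def validate_weights(weights: dict[str, float]) -> dict[str, float]:
    unknown = set(weights) - set(ALL_CRITERIA)
    if unknown:
        raise RankingError(f"unknown criteria {sorted(unknown)}; known: {ALL_CRITERIA}")
    if any(w < 0 for w in weights.values()):
        raise RankingError("weights must be >= 0")
    if not any(w > 0 for w in weights.values()):
        raise RankingError("at least one weight must be positive")
    return dict(weights)


RankingWeights = dict  # criterion -> weight >= 0, at least one positive


# -- raw criterion values --------------------------------------------------

def atom_economy(net: NetReaction, network: Network) -> float:
    """Desired-product mass over total net product mass.

    One desired copy of the target in the numerator; the denominator sums
    stoichiometry-weighted masses of every net product. Cofactors were
    already excluded when the net reaction was formed.
    """
    mw = lambda k: network.molecules[k].weight
    denom = sum(v * mw(m) for m, v in net.net_products.items())
    if denom <= 0:
        raise RankingError("net reaction has no products")
    return mw(net.target) / denom


def _soup(pathway: Pathway, network: Network) -> list[str]:
    keys = set(pathway.feedstocks)
    for rk in pathway.reactions:
        r = network.reactions[rk]
        keys.update(r.reactants)
        keys.update(r.products)
    return sorted(keys)


def _intermediates(pathway: Pathway, network: Network) -> list[str]:
    produced, consumed = set(), set()
    for rk in pathway.reactions:
        r = network.reactions[rk]
        produced.update(r.products)
        consumed.update(r.reactants)
    cof = {k for k in produced | consumed if "cofactor" in network.molecules[k].roles}
    return sorted((produced & consumed) - {pathway.target} - cof)


def byproduct_numbers(
    pathway: Pathway, rules: list[ReactionRule], network: Network
) -> tuple[int, int]:
    """(pathway by-product number, intermediate by-product number).

    All feedstocks, intermediates and products of the pathway are merged into
    a soup and expanded for one generation with every rule of interest; the
    pathway by-product number is the count of distinct new molecules outside
    the soup. The intermediate by-product number repeats the expansion once
    per intermediate with only that intermediate reactive (reactions among
    the other soup members are prohibited) and sums the distinct new-molecule
    counts.
    """
    soup = _soup(pathway, network)

    def expand_once(reactive: set[str]) -> set[str]:
        scratch = Network()
        for k in soup:
            scratch.add_molecule(Molecule(key=k, roles={"intermediate"}))
        _, new_mols = one_generation(scratch, rules, None, reactive)
        return new_mols

    pathway_byproducts = len(expand_once(set(soup)))
    inter_total = 0
    for m in _intermediates(pathway, network):
        inter_total += len(expand_once({m}))
    return pathway_byproducts, inter_total


@dataclass
class RankingContext:
    """Optional inputs for criterion computation; absent pieces mark the
    affected criteria unavailable rather than failing."""

    network: Network
    rules: list[ReactionRule] = field(default_factory=list)
    thermo: ThermoModel | None = None
    prices: dict[str, float] | None = None  # molecule key -> currency per kg
    reported: dict[str, bool] | None = None  # reaction key -> Reaxys-reported
    coolness: dict[str, float] | None = None  # reaction-type label -> weight

    def rule_of(self, rule_id: str) -> ReactionRule | None:
        for r in self.rules:
            if r.rule_id == rule_id:
                return r
        return None


def criterion_values(pathway: Pathway, context: RankingContext) -> dict[str, float | None]:
    """Raw criterion values for one pathway; ``None`` marks unavailable."""
    net = context.network
    rxns = [net.reactions[k] for k in pathway.reactions]

    # thermodynamics: worst (largest) step enthalpy
    max_dh: float | None = None
    if context.thermo is not None:
        dhs = []
        for r in rxns:
            rule = context.rule_of(r.rule_id)
            dh = r.dh_rxn if r.dh_rxn is not None else reaction_enthalpy(r, context.thermo, rule)
            if dh is None:
                dhs = None
                break
            dhs.append(dh)
        max_dh = max(dhs) if dhs else None
    else:
        dhs = [r.dh_rxn for r in rxns]
        max_dh = max(dhs) if all(d is not None for d in dhs) and dhs else None

    pathway_bp: float | None = None
    intermediate_bp: float | None = None
    if context.rules:
        pathway_bp, intermediate_bp = byproduct_numbers(pathway, context.rules, net)

    ae = pathway.atom_economy
    if ae is None and pathway.net is not None:
        ae = atom_economy(pathway.net, net)

    salt = 0
    for r in rxns:
        rule = context.rule_of(r.rule_id)
        if rule is not None and rule.salt_forming:
            salt += 1

    reaxys: float | None = None
    if context.reported is not None:
        hits = sum(1 for r in rxns if context.reported.get(r.key, r.reported_flag))
        reaxys = 100.0 * hits / len(rxns)
    elif any(r.reported_flag for r in rxns):
        reaxys = 100.0 * sum(r.reported_flag for r in rxns) / len(rxns)

    coolness: float | None = None
    if context.coolness is not None:
        coolness = 0.0
        for r in rxns:
            rule = context.rule_of(r.rule_id)
            for label in ((rule.coolness_class, rule.name) if rule else ()) + (r.rule_id,):
                if label in context.coolness:
                    coolness += context.coolness[label]
                    break

    pi: float | None = None
    if context.prices is not None and pathway.net is not None:
        try:
            revenue = sum(
                v * net.molecules[m].weight * context.prices[m]
                for m, v in pathway.net.net_products.items()
            )
            cost = sum(
                v * net.molecules[m].weight * context.prices[m]
                for m, v in pathway.net.net_reactants.items()
            )
            pi = revenue / cost if cost > 0 else None
        except KeyError as exc:
            log.info("pathway %s: missing price for %s; PI unavailable", pathway.key, exc)
            pi = None

    return {
        "max_dh": max_dh,
        "n_steps": float(pathway.n_steps),
        "pathway_byproducts": pathway_bp,
        "intermediate_byproducts": intermediate_bp,
        "atom_economy": ae,
        "salt_score": float(salt),
        "reaxys_hits": reaxys,
        "coolness": coolness,
        "profitability_index": pi,
    }


# -- normalization, totals, ranking ---------------------------------------

@dataclass
class RankingRow:
    pathway_key: str
    raw: dict[str, float | None]
    scores: dict[str, float | None]
    total: float
    rank: int = 0

    def to_dict(self) -> dict:
        return {
            "pathway": self.pathway_key,
            "raw": self.raw,
            "scores": self.scores,
            "total": self.total,
            "rank": self.rank,
        }


@dataclass
class RankingTable:
    rows: list[RankingRow]
    weights: dict[str, float]

    def rank_of(self, pathway_key: str) -> int:
        for row in self.rows:
            if row.pathway_key == pathway_key:
                return row.rank
        raise KeyError(pathway_key)

    def to_dict(self) -> dict:
        return {"weights": self.weights, "rows": [r.to_dict() for r in self.rows]}


def _tie_break(row: RankingRow) -> tuple:
    steps = row.raw.get("n_steps") or 0.0
    ae = row.raw.get("atom_economy") or 0.0
    return (-row.total, steps, -ae, row.pathway_key)


def normalize_and_rank(
    values: dict[str, dict[str, float | None]], weights: dict[str, float]
) -> RankingTable:
    """Min-max normalize raw values, apply weights, total, and rank.

    Benefit criteria score (v - min)/(max - min); cost criteria score
    (max - v)/(max - min), so 1 is always best and 0 worst. A degenerate
    criterion (max == min) scores 1.0 for everyone, which is rank-neutral.
    Pathways with an unavailable value are excluded from that criterion's
    normalization and receive no contribution from it.
    """
    if not values:
        raise RankingError("no pathways to rank")
    weights = validate_weights(weights)

    criteria = [c for c, w in weights.items() if w > 0]
    spans: dict[str, tuple[float, float]] = {}
    for c in criteria:
        avail = [v[c] for v in values.values() if v.get(c) is not None]
        if avail:
            spans[c] = (min(avail), max(avail))

    rows = []
    for pkey in sorted(values):
        raw = values[pkey]
        scores: dict[str, float | None] = {}
        total = 0.0
        for c, w in weights.items():
            v = raw.get(c)
            if w <= 0 or v is None or c not in spans:
                scores[c] = None if v is None else None
                continue
            lo, hi = spans[c]
            if hi == lo:
                s = 1.0
            elif c in BENEFIT_CRITERIA:
                s = (v - lo) / (hi - lo)
            else:
                s = (hi - v) / (hi - lo)
            scores[c] = s
            total += s * w
        rows.append(RankingRow(pathway_key=pkey, raw=dict(raw), scores=scores, total=total))

    rows.sort(key=_tie_break)
    for i, row in enumerate(rows, start=1):
        row.rank = i
    return RankingTable(rows=rows, weights=weights)


# -- weight sensitivity sweep ---------------------------------------------

def weight_sweep(
    values: dict[str, dict[str, float | None]],
    criteria: list[str],
    step: float = 0.1,
    pathways_of_interest: list[str] | None = None,
) -> list[dict]:
    """Recompute ranks on a simplex grid of weights over 2-5 criteria.

    Weights over the selected criteria vary in increments of ``step`` with
    total fixed to 1 (all other criteria weighted 0); every composition is
    evaluated — for 3 criteria at step 0.1 that is C(12,2) = 66 grid points.
    Returns one record per grid point: {"weights": {...}, "ranks": {...}},
    suitable for ternary-plot rendering.
    """
    if not (2 <= len(criteria) <= 5):
        raise RankingError("weight_sweep takes 2-5 criteria")
    n = round(1.0 / step)
    if abs(n * step - 1.0) > 1e-9:
        raise RankingError(f"step {step} does not divide 1")
    keys = pathways_of_interest or sorted(values)

    out = []
    k = len(criteria)
    for cuts in combinations(range(n + k - 1), k - 1):
        parts = []
        prev = -1
        for c in cuts:
            parts.append(c - prev - 1)
            prev = c
        parts.append(n + k - 2 - prev)
        weights = {c: p * step for c, p in zip(criteria, parts)}
        if not any(w > 0 for w in weights.values()):
            continue
        table = normalize_and_rank(values, weights)
        out.append({
            "weights": {c: round(w, 10) for c, w in weights.items()},
            "ranks": {pk: table.rank_of(pk) for pk in keys},
        })
    return out
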