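"""Composable molecule/reaction filters for network expansion.

Filters are predicate trees over molecules or reactions, combined with
AND/OR/NOT (short-circuit). Each leaf names a registered predicate; molecule
predicates gate admission of new molecules, reaction predicates gate
reactions. When an expression is evaluated in one scope, leaves of the other
scope are vacuously true, so a single mixed expression can be attached to
both hooks.

A textual spec like ``and(enthalpy_below(15), max_heavy_atoms(20))`` parses
into the same tree as the programmatic constructors.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Callable

from routenet import chem
from routenet.model import Reaction
from routenet.thermo import ThermoModel, reaction_enthalpy

log = logging.getLogger(__name__)


class FilterError(ValueError):
    pass


@dataclass
class _Predicate:
    name: str
    scope: str  # "molecule" | "reaction"
    make: Callable  # (*args, context) -> callable


class EvalContext:
    """Shared state needed by predicates: thermo model, rule lookup,
    per-molecule generation, and ring baseline for reaction-level checks."""

    def __init__(self, thermo: ThermoModel | None = None, rules_by_id: dict | None = None):
        self.thermo = thermo
        self.rules_by_id = rules_by_id or {}
        self.generations: dict[str, int] = {}


# -- predicate registry ----------------------------------------------------

REGISTRY: dict[str, _Predicate] = {}


def register(name: str, scope: str):
    def deco(fn):
        REGISTRY[name] = _Predicate(name, scope, fn)
        return fn
    return deco


@register("max_heavy_atoms", "molecule")
def _max_heavy_atoms(n, context):
    n = int(n)
    return lambda key: chem.heavy_atom_count(key) <= n


@register("max_mw", "molecule")
def _max_mw(x, context):
    x = float(x)
    return lambda key: chem.molecular_weight(key) <= x


@register("allowed_elements", "molecule")
def _allowed_elements(*symbols, context):
    allowed = {str(s) for s in symbols} | {"H"}
    return lambda key: chem.elements_of(key) <= allowed


@register("generation_cap", "molecule")
def _generation_cap(n, context):
    n = int(n)

    def pred(key):
        gen = context.generations.get(key, 0)
        return abs(gen) <= n

    return pred


@register("enthalpy_below", "reaction")
def _enthalpy_below(threshold, context):
    threshold = float(threshold)

    def pred(rxn: Reaction):
        if context.thermo is None:
            return True
        rule = context.rules_by_id.get(rxn.rule_id)
        dh = reaction_enthalpy(rxn, context.thermo, rule)
        if dh is None:
            # Unestimable endpoints never abort expansion: pass with a note.
            log.debug("enthalpy unavailable for %s; filter passes", rxn.key)
            return True
        rxn.dh_rxn = dh
        return dh < threshold

    return pred


@register("no_new_rings", "reaction")
def _no_new_rings(context):
    def pred(rxn: Reaction):
        before = sum(chem.ring_count(k) for k in rxn.reactants)
        after = sum(chem.ring_count(k) for k in rxn.products)
        return after <= before

    return pred


# -- expression tree -------------------------------------------------------

class FilterExpr:
    def admits_molecule(self, key: str) -> bool:
        raise NotImplementedError

    def admits_reaction(self, rxn: Reaction) -> bool:
        raise NotImplementedError


class Leaf(FilterExpr):
    def __init__(self, name: str, args: tuple, context: EvalContext):
        if name not in REGISTRY:
            raise FilterError(
                f"unknown predicate {name!r}; registry: {sorted(REGISTRY)}"
            )
        spec = REGISTRY[name]
        self.name = name
        self.scope = spec.scope
        self.fn = spec.make(*args, context=context)

    def admits_molecule(self, key: str) -> bool:
        return self.fn(key) if self.scope == "molecule" else True

    def admits_reaction(self, rxn: Reaction) -> bool:
        return self.fn(rxn) if self.scope == "reaction" else True


class And(FilterExpr):
    def __init__(self, *children: FilterExpr):
        self.children = children

    def admits_molecule(self, key):
        return all(c.admits_molecule(key) for c in self.children)

    def admits_reaction(self, rxn):
        return all(c.admits_reaction(rxn) for c in self.children)


class Or(FilterExpr):
    def __init__(self, *children: FilterExpr):
        self.children = children

    def admits_molecule(self, key):
        return any(c.admits_molecule(key) for c in self.children)

    def admits_reaction(self, rxn):
        return any(c.admits_reaction(rxn) for c in self.children)


class Not(FilterExpr):
    def __init__(self, child: FilterExpr):
        self.child = child

    def admits_molecule(self, key):
        return not self.child.admits_molecule(key)

    def admits_reaction(self, rxn):
        return not self.child.admits_reaction(rxn)


class AcceptAll(FilterExpr):
    def admits_molecule(self, key):
        return True

    def admits_reaction(self, rxn):
        return True


# -- textual spec parser ---------------------------------------------------

_TOKEN = re.compile(r"\s*([A-Za-z_][A-Za-z_0-9]*|[(),]|[-+]?[0-9]*\.?[0-9]+)")


def _tokenize(spec: str) -> list[str]:
    tokens, pos = [], 0
    while pos < len(spec):
        m = _TOKEN.match(spec, pos)
        if m is None:
            if spec[pos:].strip():
                raise FilterError(f"cannot tokenize filter spec at: {spec[pos:]!r}")
            break
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


def build_filter(spec: str | FilterExpr | None, context: EvalContext | None = None) -> FilterExpr:
    """Build an evaluable predicate tree from a textual spec.

    Grammar: ``expr := and(expr,...) | or(expr,...) | not(expr) |
    name(arg,...) | name``. Numeric args parse as numbers, bare words as
    strings (element symbols).
    """
    if spec is None:
        return AcceptAll()
    if isinstance(spec, FilterExpr):
        return spec
    context = context or EvalContext()
    tokens = _tokenize(spec)
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def eat(expected=None):
        nonlocal pos
        tok = peek()
        if tok is None or (expected is not None and tok != expected):
            raise FilterError(f"filter spec parse error near token {pos} in {spec!r}")
        pos += 1
        return tok

    def parse_expr() -> FilterExpr:
        name = eat()
        if not re.fullmatch(r"[A-Za-z_][A-Za-z_0-9]*", name):
            raise FilterError(f"expected predicate name, got {name!r}")
        lname = name.lower()
        if lname in ("and", "or", "not"):
            eat("(")
            children = [parse_expr()]
            while peek() == ",":
                eat(",")
                children.append(parse_expr())
            eat(")")
            if lname == "not":
                if len(children) != 1:
                    raise FilterError("not() takes exactly one argument")
                return Not(children[0])
            return (And if lname == "and" else Or)(*children)
        args: list = []
        if peek() == "(":
            eat("(")
            while peek() != ")":
                tok = eat()
                if tok == ",":
                    continue
                try:
                    args.append(float(tok) if "." in tok else int(tok))
                except ValueError:
                    args.append(tok)
            eat(")")
        return Leaf(name, tuple(args), context)

    expr = parse_expr()
    if pos != len(tokens):
        raise FilterError(f"trailing tokens in filter spec {spec!r}")
    return expr
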