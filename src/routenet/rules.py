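"""SMARTS reaction rules: loading, validation, reversal, and application.

A rule is a directional reaction SMARTS template plus metadata. Chemical/
chemocatalytic rules are written mass-balanced (helper species such as water
or H2 appear explicitly in the template) so that atom economy and elemental
balance are well defined. Enzymatic rules carry cofactor slots: the template
transforms the primary substrate only, and the currency couple (e.g. a methyl
donor and its spent form) is attached by :func:`resolve_cofactors` at
application time, which keeps the overall reaction balanced without requiring
cofactors among the starting molecules.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

from rdkit import Chem
from rdkit.Chem import AllChem

from routenet import chem
from routenet.model import Reaction

log = logging.getLogger(__name__)

# Deterministic guard against pathologically symmetric substrates: template
# matches beyond this count are truncated in canonical product order.
MAX_MATCHES = 256


class RuleError(ValueError):
    """A rule file or rule definition failed validation."""


@dataclass
class ReactionRule:
    """A directional reaction template with metadata."""

    rule_id: str
    name: str
    template: str  # reaction SMARTS "reactants>>products" with atom maps
    kind: str = "chemo"  # {"chemo", "enzymatic"}
    direction: str = "forward"  # {"forward", "retro"}
    stoichiometry: dict[str, int] = field(default_factory=dict)
    dh_correction: float = 0.0  # additive per-rule offset, kcal/mol
    salt_forming: bool = False
    coolness_class: str = ""
    cofactors_in: list[str] = field(default_factory=list)
    cofactors_out: list[str] = field(default_factory=list)
    provenance: str = ""
    mass_balanced: bool = True

    _rxn: object = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.kind not in ("chemo", "enzymatic"):
            raise RuleError(f"rule {self.rule_id}: unknown kind {self.kind!r}")
        if self.direction not in ("forward", "retro"):
            raise RuleError(f"rule {self.rule_id}: unknown direction {self.direction!r}")
        if ">>" not in self.template:
            raise RuleError(f"rule {self.rule_id}: template lacks '>>'")
        try:
            rxn = AllChem.ReactionFromSmarts(self.template)
        except Exception as exc:
            raise RuleError(
                f"rule {self.rule_id}: unparsable template {self.template!r}: {exc}"
            ) from exc
        if rxn is None:
            raise RuleError(f"rule {self.rule_id}: unparsable template {self.template!r}")
        rxn.Initialize()
        self._rxn = rxn
        if self.kind == "enzymatic":
            for c in self.cofactors_in + self.cofactors_out:
                try:
                    chem.canonicalize(c)
                except chem.ParseError as exc:
                    raise RuleError(f"rule {self.rule_id}: bad cofactor {c!r}") from exc
        self.cofactors_in = [chem.canonicalize(c) for c in self.cofactors_in]
        self.cofactors_out = [chem.canonicalize(c) for c in self.cofactors_out]

    @property
    def rxn(self) -> AllChem.ChemicalReaction:
        return self._rxn

    @property
    def arity(self) -> int:
        """Number of template reactant slots (cofactors excluded)."""
        return self._rxn.GetNumReactantTemplates()

    def to_dict(self) -> dict:
        return {
            "rule_id": self.rule_id,
            "name": self.name,
            "kind": self.kind,
            "template": self.template,
            "direction": self.direction,
            "stoichiometry": dict(self.stoichiometry),
            "dh_correction": self.dh_correction,
            "salt_forming": self.salt_forming,
            "coolness_class": self.coolness_class,
            "cofactors_in": list(self.cofactors_in),
            "cofactors_out": list(self.cofactors_out),
            "provenance": self.provenance,
            "mass_balanced": self.mass_balanced,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReactionRule":
        known = {
            "rule_id", "name", "kind", "template", "direction", "stoichiometry",
            "dh_correction", "salt_forming", "coolness_class", "cofactors_in",
            "cofactors_out", "provenance", "mass_balanced",
        }
        unknown = set(d) - known
        if unknown:
            raise RuleError(f"rule {d.get('rule_id', '?')}: unknown fields {sorted(unknown)}")
        return cls(**d)


# -- rule files ------------------------------------------------------------

def load_rules(path: str | Path) -> list[ReactionRule]:
    """Load and validate a JSON or TSV rule file, preserving file order.

    JSON: a list of objects with :class:`ReactionRule` fields. TSV: the same
    field names as columns; list/dict-valued columns are JSON-encoded cells.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".tsv":
        records = _read_tsv(path)
    else:
        records = json.loads(path.read_text())
        if not isinstance(records, list):
            raise RuleError(f"{path}: expected a JSON list of rules")
    rules = []
    seen: set[str] = set()
    for rec in records:
        rule = ReactionRule.from_dict(rec)
        if rule.rule_id in seen:
            raise RuleError(f"duplicate rule_id {rule.rule_id!r}")
        seen.add(rule.rule_id)
        rules.append(rule)
    return rules


def save_rules(rules: list[ReactionRule], path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".tsv":
        _write_tsv(rules, path)
    else:
        path.write_text(json.dumps([r.to_dict() for r in rules], indent=1))


_LISTY = {"stoichiometry", "cofactors_in", "cofactors_out"}


def _read_tsv(path: Path) -> list[dict]:
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            rec: dict = {}
            for k, v in row.items():
                if v is None or v == "":
                    continue
                if k in _LISTY:
                    rec[k] = json.loads(v)
                elif k == "dh_correction":
                    rec[k] = float(v)
                elif k in ("salt_forming", "mass_balanced"):
                    rec[k] = v.lower() in ("1", "true", "yes")
                else:
                    rec[k] = v
            records.append(rec)
    return records


def _write_tsv(rules: list[ReactionRule], path: Path) -> None:
    fields = list(rules[0].to_dict().keys())
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields, delimiter="\t")
        writer.writeheader()
        for r in rules:
            row = r.to_dict()
            for k in _LISTY:
                row[k] = json.dumps(row[k])
            writer.writerow(row)


# -- reversal --------------------------------------------------------------

def reverse_rule(rule: ReactionRule) -> ReactionRule:
    """Swap template sides, toggle direction, negate the thermo correction,
    and swap cofactor slots. An involution: ``reverse_rule(reverse_rule(r))``
    has the original template."""
    left, right = rule.template.split(">>")
    return replace(
        rule,
        template=f"{right}>>{left}",
        direction="retro" if rule.direction == "forward" else "forward",
        dh_correction=-rule.dh_correction,
        cofactors_in=list(rule.cofactors_out),
        cofactors_out=list(rule.cofactors_in),
        _rxn=None,
    )


# -- cofactors -------------------------------------------------------------

def resolve_cofactors(rule: ReactionRule, primary_reactants: tuple[str, ...]) -> tuple[list[str], list[str]]:
    """Full reactant multiset and the spent-cofactor product multiset.

    For enzymatic rules the currency couple rides along with every template
    application: ``cofactors_in`` joins the reactants and ``cofactors_out``
    joins every generated product set. Chemo rules pass through unchanged.
    """
    if rule.kind != "enzymatic":
        return list(primary_reactants), []
    return list(primary_reactants) + list(rule.cofactors_in), list(rule.cofactors_out)


# -- application -----------------------------------------------------------

def apply_rule(rule: ReactionRule, reactants: tuple[str, ...], generation: int = 0) -> set[Reaction]:
    """Apply a rule to an ordered tuple of molecule keys.

    Returns one :class:`Reaction` per distinct product multiset over all
    template matches — symmetry-equivalent matches collapse. Products are
    canonicalized; matches whose products fail sanitization are dropped and
    logged. Unmatched reactants give an empty set. Cofactors of enzymatic
    rules are folded into the reactant/product multisets.
    """
    if len(reactants) != rule.arity:
        raise ValueError(
            f"rule {rule.rule_id} takes {rule.arity} reactants, got {len(reactants)}"
        )
    mols = []
    for key in reactants:
        mols.append(chem.mol_from_smiles(key))
    try:
        product_sets = rule.rxn.RunReactants(tuple(mols), maxProducts=4 * MAX_MATCHES)
    except Exception as exc:  # RDKit kernel errors on odd inputs
        log.warning("rule %s failed on %s: %s", rule.rule_id, reactants, exc)
        return set()

    full_reactants, cof_products = resolve_cofactors(rule, reactants)
    full_reactants = [chem.canonicalize(k) for k in full_reactants]

    outcomes: set[tuple[str, ...]] = set()
    for pset in product_sets:
        keys = []
        ok = True
        for p in pset:
            try:
                Chem.SanitizeMol(p)
                keys.append(chem.canonicalize(Chem.MolToSmiles(p)))
            except Exception:
                log.debug("rule %s: dropped unsanitizable product on %s", rule.rule_id, reactants)
                ok = False
                break
        if ok:
            outcomes.add(tuple(sorted(keys + cof_products)))

    if len(outcomes) > MAX_MATCHES:
        log.warning(
            "rule %s on %s: %d outcomes, truncating to %d",
            rule.rule_id, reactants, len(outcomes), MAX_MATCHES,
        )
        outcomes = set(sorted(outcomes)[:MAX_MATCHES])

    return {
        Reaction(
            rule_id=rule.rule_id,
            reactants=list(full_reactants),
            products=list(products),
            generation=generation,
        )
        for products in outcomes
    }


def check_mass_balance(rule: ReactionRule, rxn: Reaction) -> bool:
    """Elemental balance of a generated reaction (cofactors included)."""
    return chem.formula_counter(rxn.reactants) == chem.formula_counter(rxn.products)
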