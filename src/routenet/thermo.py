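"""Gas-phase enthalpy of formation by Benson group additivity.

The Benson scheme writes the standard enthalpy of formation at 298 K as a sum
of next-nearest-neighbor group contributions: one group per polyvalent heavy
atom, described by the center's hybridization class and its sorted heavy-atom
neighbor classes, with hydrogens folded into the signature. Ring strain for
3-, 4- and 5-membered rings is added as a per-ring correction. Molecules too
small to have a polyvalent-center decomposition (H2, water, HCl, CO2, ...)
are looked up in a fixed molecular table; elements in their reference state
are zero by definition.

Center classes: ``C`` sp3 carbon, ``Cd`` doubly-bonded carbon (the sp2
partner is implicit in the class and not listed as a neighbor), ``Ct``
triply-bonded carbon, ``CB`` aromatic carbon (ring neighbors implicit),
``CO`` carbonyl carbon (the oxygen is implicit). Example: ethanol decomposes
to ``C-(C)(H)3 + C-(C)(O)(H)2 + O-(C)(H)``.

Estimates deliberately return "unavailable" (``None``) rather than a silent
zero whenever a group is missing from the table; network expansion treats
such molecules as passing the thermodynamic filter, so thermochemistry stays
optional and pluggable.

Known approximations of the shipped table: no gauche/ortho corrections, no
entropy or heat capacity, gas phase only.
"""

from __future__ import annotations

import csv
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Protocol

from rdkit import Chem

from routenet import chem
from routenet.model import Reaction
from routenet.rules import ReactionRule

# Neighbor classes in signature order; H always last.
_CLASS_ORDER = ["C", "Cd", "Ct", "CB", "CO", "O", "N", "S", "F", "Cl", "Br", "I", "H"]
_ORDER_INDEX = {c: i for i, c in enumerate(_CLASS_ORDER)}

SUPPORTED_ELEMENTS = {"C", "H", "O", "N", "S", "F", "Cl", "Br", "I"}


_SIG_PART = re.compile(r"\(([^)]+)\)(\d*)")


def normalize_signature(sig: str) -> str:
    """Canonical spelling of a group signature: neighbor classes in fixed
    order with counts, e.g. ``CO-(O)(C)`` -> ``CO-(C)(O)``."""
    if "-" not in sig:
        return sig
    center, rest = sig.split("-", 1)
    neigh: Counter[str] = Counter()
    for cls, count in _SIG_PART.findall(rest):
        neigh[cls] += int(count) if count else 1
    parts = sorted(neigh.items(), key=lambda kv: _ORDER_INDEX.get(kv[0], 99))
    return center + "-" + "".join(
        f"({c})" if n == 1 else f"({c}){n}" for c, n in parts
    )


class MissingGroupError(KeyError):
    """A molecule contains a group with no table coverage."""

    def __init__(self, signatures: list[str]):
        self.signatures = signatures
        super().__init__(f"no group-table coverage for: {', '.join(signatures)}")


@dataclass
class GroupTable:
    """Benson group contributions in kcal/mol, user-replaceable via CSV."""

    entries: dict[str, float] = field(default_factory=dict)
    ring_corrections: dict[int, float] = field(default_factory=dict)
    molecular: dict[str, float] = field(default_factory=dict)  # canonical SMILES -> ΔHf

    @classmethod
    def from_csv(cls, path: str | Path) -> "GroupTable":
        table = cls()
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                sig = row["signature"].strip()
                val = float(row["value_kcal_per_mol"])
                if sig.startswith("ring:"):
                    table.ring_corrections[int(sig.split(":", 1)[1])] = val
                elif sig.startswith("mol:"):
                    table.molecular[chem.canonicalize(sig.split(":", 1)[1])] = val
                else:
                    table.entries[normalize_signature(sig)] = val
        return table

    @classmethod
    def default(cls) -> "GroupTable":
        with resources.as_file(
            resources.files("routenet.data").joinpath("benson_groups.csv")
        ) as p:
            return cls.from_csv(p)


class ThermoModel(Protocol):
    """Pluggable enthalpy estimator contract.

    ``estimate`` maps a molecule key to ΔHf in kcal/mol or ``None`` when the
    model cannot treat the molecule. Any calculator honoring this contract
    (e.g. an aqueous free-energy service) can replace the Benson model in
    filters and ranking.
    """

    def estimate(self, key: str) -> float | None: ...


# -- decomposition ---------------------------------------------------------

def _carbon_class(atom: Chem.Atom) -> str:
    if atom.GetIsAromatic():
        return "CB"
    for bond in atom.GetBonds():
        other = bond.GetOtherAtom(atom)
        if bond.GetBondType() == Chem.BondType.DOUBLE:
            return "CO" if other.GetSymbol() == "O" else "Cd"
        if bond.GetBondType() == Chem.BondType.TRIPLE:
            return "Ct"
    return "C"


def _atom_class(atom: Chem.Atom) -> str:
    sym = atom.GetSymbol()
    return _carbon_class(atom) if sym == "C" else sym


def _implicit_partner_idxs(atom: Chem.Atom, cls: str) -> set[int]:
    """Indices of neighbors folded into the center class itself."""
    implicit: set[int] = set()
    for bond in atom.GetBonds():
        other = bond.GetOtherAtom(atom)
        if cls == "CB" and bond.GetIsAromatic():
            implicit.add(other.GetIdx())
        elif cls in ("Cd", "Ct") and bond.GetBondType() in (
            Chem.BondType.DOUBLE, Chem.BondType.TRIPLE
        ):
            implicit.add(other.GetIdx())
        elif cls == "CO" and bond.GetBondType() == Chem.BondType.DOUBLE and other.GetSymbol() == "O":
            implicit.add(other.GetIdx())
    return implicit


def decompose_groups(key: str) -> tuple[Counter, Counter]:
    """Benson decomposition of a molecule.

    Returns ``(groups, rings)``: a multiset of group signatures (one per
    polyvalent heavy atom) and a multiset of small-ring sizes (3-5) for strain
    corrections. Carbonyl oxygens and monovalent atoms carry no group of
    their own.
    """
    mol = chem.mol_from_smiles(key)
    bad = chem.elements_of(key) - SUPPORTED_ELEMENTS
    if bad:
        raise MissingGroupError([f"element:{e}" for e in sorted(bad)])

    groups: Counter[str] = Counter()
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym in ("H", "F", "Cl", "Br", "I"):
            continue  # monovalent: folded into neighbor signatures
        cls = _atom_class(atom)
        if sym == "O":
            # Carbonyl oxygen is implicit in the CO center.
            if any(
                b.GetBondType() == Chem.BondType.DOUBLE and b.GetOtherAtom(atom).GetSymbol() == "C"
                for b in atom.GetBonds()
            ):
                continue
            if atom.GetIsAromatic():
                cls = "Oar"  # no coverage in the shipped table
        if sym in ("N", "S") and atom.GetIsAromatic():
            cls = sym + "ar"
        implicit = _implicit_partner_idxs(atom, cls)
        neigh: Counter[str] = Counter()
        for nbr in atom.GetNeighbors():
            if nbr.GetIdx() in implicit:
                continue
            neigh[_atom_class(nbr)] += 1
        if atom.GetTotalNumHs():
            neigh["H"] += atom.GetTotalNumHs()
        parts = sorted(neigh.items(), key=lambda kv: _ORDER_INDEX.get(kv[0], 99))
        sig = cls + "-" + "".join(
            f"({c})" if n == 1 else f"({c}){n}" for c, n in parts
        )
        groups[sig] += 1

    rings: Counter[int] = Counter()
    for ring in Chem.GetSymmSSSR(mol):
        atoms = [mol.GetAtomWithIdx(i) for i in ring]
        if len(ring) in (3, 4, 5) and not any(a.GetIsAromatic() for a in atoms):
            rings[len(ring)] += 1
    return groups, rings


# -- enthalpies ------------------------------------------------------------

def enthalpy_of_formation(key: str, table: GroupTable) -> float | None:
    """ΔHf(gas, 298 K) in kcal/mol by group additivity, or ``None`` when a
    group lacks coverage. Never silently zero."""
    key = chem.canonicalize(key)
    if key in table.molecular:
        return table.molecular[key]
    try:
        groups, rings = decompose_groups(key)
    except MissingGroupError:
        return None
    missing = [g for g in groups if g not in table.entries]
    missing += [f"ring:{r}" for r in rings if r not in table.ring_corrections]
    if missing:
        return None
    total = sum(table.entries[g] * n for g, n in groups.items())
    total += sum(table.ring_corrections[r] * n for r, n in rings.items())
    return total


class BensonModel:
    """Default :class:`ThermoModel`: Benson additivity with the shipped table."""

    def __init__(self, table: GroupTable | None = None):
        self.table = table or GroupTable.default()
        self._cache: dict[str, float | None] = {}

    def estimate(self, key: str) -> float | None:
        if key not in self._cache:
            try:
                self._cache[key] = enthalpy_of_formation(key, self.table)
            except chem.ParseError:
                self._cache[key] = None
        return self._cache[key]


def reaction_enthalpy(
    rxn: Reaction, model: ThermoModel, rule: ReactionRule | None = None
) -> float | None:
    """Stoichiometry-weighted ΔH of reaction in kcal/mol.

    Σ products − Σ reactants plus the rule's additive correction; ``None``
    (unavailable) as soon as any endpoint is unestimable.
    """
    total = 0.0
    for key, n in rxn.product_counts().items():
        hf = model.estimate(key)
        if hf is None:
            return None
        total += n * hf
    for key, n in rxn.reactant_counts().items():
        hf = model.estimate(key)
        if hf is None:
            return None
        total -= n * hf
    if rule is not None:
        total += rule.dh_correction
    return total
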