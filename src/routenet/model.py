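"""Chemical data model: molecules, reactions, and deduplicated networks.

A :class:`Network` is the artifact produced by expansion: two stores keyed by
canonical identity (molecule key; reaction key = rule + sorted endpoint keys)
plus provenance descriptors for the runs that built it. Networks merge by
keyed union, which is what makes the combined forward/retro strategy a plain
set operation.

Molecule keys are canonical SMILES for real chemistry, but the model does not
insist on it: synthetic benchmark networks use opaque keys with explicitly
assigned masses, so pathway search and ranking can be exercised independently
of any chemistry toolkit behavior.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path

from routenet import chem

ROLES = {"starter", "helper", "target", "cofactor", "intermediate"}


@dataclass
class Molecule:
    """A chemical species keyed by canonical structure.

    ``mw`` may be assigned explicitly (synthetic networks); otherwise it is
    derived from the key on first access via :func:`routenet.chem.molecular_weight`.
    """

    key: str
    roles: set[str] = field(default_factory=set)
    generation: int | None = None
    hf_gas_298: float | None = None  # kcal/mol
    price: float | None = None  # currency per kg
    mw: float | None = None  # g/mol

    def __post_init__(self) -> None:
        bad = self.roles - ROLES
        if bad:
            raise ValueError(f"unknown roles {bad} for molecule {self.key!r}")

    @property
    def weight(self) -> float:
        if self.mw is None:
            self.mw = chem.molecular_weight(self.key)
        return self.mw

    def to_dict(self) -> dict:
        d: dict = {"key": self.key, "roles": sorted(self.roles)}
        if self.generation is not None:
            d["generation"] = self.generation
        if self.hf_gas_298 is not None:
            d["hf"] = self.hf_gas_298
        if self.price is not None:
            d["price"] = self.price
        if self.mw is not None:
            d["mw"] = self.mw
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Molecule":
        return cls(
            key=d["key"],
            roles=set(d.get("roles", [])),
            generation=d.get("generation"),
            hf_gas_298=d.get("hf"),
            price=d.get("price"),
            mw=d.get("mw"),
        )


def reaction_key(rule_id: str, reactants: list[str], products: list[str]) -> str:
    """Order-free reaction identity: rule + sorted reactant and product multisets."""
    return f"{rule_id}|{'.'.join(sorted(reactants))}>>{'.'.join(sorted(products))}"


@dataclass(eq=False)
class Reaction:
    """One rule application: reactant and product multisets of molecule keys.

    Identity (equality, hashing) is the order-free reaction key, so symmetric
    template matches collapse to one reaction.
    """

    rule_id: str
    reactants: list[str]
    products: list[str]
    dh_rxn: float | None = None  # kcal/mol
    generation: int = 0
    reported_flag: bool = False

    def __post_init__(self) -> None:
        if not self.reactants or not self.products:
            raise ValueError("reaction must have nonempty reactants and products")
        self.reactants = sorted(self.reactants)
        self.products = sorted(self.products)

    @property
    def key(self) -> str:
        return reaction_key(self.rule_id, self.reactants, self.products)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Reaction) and self.key == other.key

    def __hash__(self) -> int:
        return hash(self.key)

    def reactant_counts(self) -> Counter:
        return Counter(self.reactants)

    def product_counts(self) -> Counter:
        return Counter(self.products)

    def is_balanced(self) -> bool:
        """Elemental multiset equality between the two sides (real structures only)."""
        return chem.formula_counter(self.reactants) == chem.formula_counter(self.products)

    def to_dict(self) -> dict:
        d: dict = {
            "rule_id": self.rule_id,
            "reactants": self.reactants,
            "products": self.products,
            "generation": self.generation,
        }
        if self.dh_rxn is not None:
            d["dh_rxn"] = self.dh_rxn
        if self.reported_flag:
            d["reported"] = True
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Reaction":
        return cls(
            rule_id=d["rule_id"],
            reactants=list(d["reactants"]),
            products=list(d["products"]),
            dh_rxn=d.get("dh_rxn"),
            generation=d.get("generation", 0),
            reported_flag=d.get("reported", False),
        )


class Network:
    """Deduplicated molecule and reaction stores with provenance."""

    def __init__(self) -> None:
        self.molecules: dict[str, Molecule] = {}
        self.reactions: dict[str, Reaction] = {}
        self.provenance: list[dict] = []

    def __repr__(self) -> str:
        return f"<Network: {len(self.molecules)} molecules, {len(self.reactions)} reactions>"

    # -- mutation ---------------------------------------------------------

    def add_molecule(self, mol: Molecule) -> Molecule:
        """Insert or merge a molecule; first-seen generation wins, roles union."""
        existing = self.molecules.get(mol.key)
        if existing is None:
            self.molecules[mol.key] = mol
            return mol
        existing.roles |= mol.roles
        existing.generation = _min_generation(existing.generation, mol.generation)
        if existing.hf_gas_298 is None:
            existing.hf_gas_298 = mol.hf_gas_298
        if existing.price is None:
            existing.price = mol.price
        if existing.mw is None:
            existing.mw = mol.mw
        return existing

    def add_reaction(self, rxn: Reaction) -> Reaction:
        """Insert a reaction, requiring referential closure; duplicates keep the
        earliest generation."""
        for k in rxn.reactants + rxn.products:
            if k not in self.molecules:
                raise KeyError(f"reaction endpoint {k!r} missing from molecule store")
        existing = self.reactions.get(rxn.key)
        if existing is None:
            self.reactions[rxn.key] = rxn
            return rxn
        existing.generation = min(existing.generation, rxn.generation)
        existing.reported_flag = existing.reported_flag or rxn.reported_flag
        if existing.dh_rxn is None:
            existing.dh_rxn = rxn.dh_rxn
        return existing

    # -- queries ----------------------------------------------------------

    def producers(self, key: str) -> list[str]:
        """Keys of reactions having ``key`` among their products (sorted)."""
        return sorted(rk for rk, r in self.reactions.items() if key in r.products)

    def check_closure(self) -> None:
        for rxn in self.reactions.values():
            for k in rxn.reactants + rxn.products:
                if k not in self.molecules:
                    raise AssertionError(f"dangling endpoint {k!r} in {rxn.key}")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "molecules": [self.molecules[k].to_dict() for k in sorted(self.molecules)],
            "reactions": [self.reactions[k].to_dict() for k in sorted(self.reactions)],
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_dict(cls, d: dict) -> "Network":
        net = cls()
        for md in d.get("molecules", []):
            net.add_molecule(Molecule.from_dict(md))
        for rd in d.get("reactions", []):
            net.add_reaction(Reaction.from_dict(rd))
        net.provenance = list(d.get("provenance", []))
        return net

    @classmethod
    def read_json(cls, path: str | Path) -> "Network":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _min_generation(a: int | None, b: int | None) -> int | None:
    if a is None:
        return b
    if b is None:
        return a
    return min(a, b)


def merge_networks(a: Network, b: Network) -> Network:
    """Keyed union of two networks.

    Duplicated molecules/reactions collapse to one entry with the minimum
    generation; provenance lists concatenate. Commutative and associative up
    to provenance ordering.
    """
    out = Network()
    for src in (a, b):
        for mol in src.molecules.values():
            out.add_molecule(replace(mol, roles=set(mol.roles)))
        for rxn in src.reactions.values():
            out.add_reaction(
                Reaction(
                    rule_id=rxn.rule_id,
                    reactants=list(rxn.reactants),
                    products=list(rxn.products),
                    dh_rxn=rxn.dh_rxn,
                    generation=rxn.generation,
                    reported_flag=rxn.reported_flag,
                )
            )
    out.provenance = list(a.provenance) + list(b.provenance)
    return out


# -- .smi molecule lists ---------------------------------------------------

def read_smi(path: str | Path) -> list[str]:
    """Read a .smi file (one SMILES per line, optional tab-separated name),
    returning canonical keys in file order without duplicates."""
    keys: list[str] = []
    seen: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        smi = line.split("\t")[0].split()[0]
        key = chem.canonicalize(smi)
        if key not in seen:
            seen.add(key)
            keys.append(key)
    return keys


def write_smi(keys: list[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{k}\n" for k in keys))
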