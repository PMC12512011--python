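"""Low-level molecular identity and property helpers built on RDKit.

Molecule identity throughout the package is a canonical SMILES string with
stereochemistry stripped: reaction templates are constitutional, so retaining
stereocenters would split one species into spurious duplicates during network
deduplication.
"""

from __future__ import annotations

from collections import Counter
from functools import lru_cache

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

# Template application produces many partial molecules that fail sanitization;
# those are handled explicitly, so RDKit's per-molecule logging is noise here.
RDLogger.DisableLog("rdApp.*")


class ParseError(ValueError):
    """A structure string could not be parsed as a molecule."""


def mol_from_smiles(structure: str) -> Chem.Mol:
    """Parse SMILES into an RDKit Mol, raising :class:`ParseError` on failure."""
    if not isinstance(structure, str) or not structure.strip():
        raise ParseError(f"not a SMILES string: {structure!r}")
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise ParseError(f"unparsable SMILES: {structure!r}")
    return mol


@lru_cache(maxsize=100_000)
def canonicalize(structure: str) -> str:
    """Return the canonical SMILES for ``structure``.

    Deterministic and idempotent; all spellings of one molecular graph map to
    the same string. Stereochemistry (bond and atom) is removed first.
    """
    mol = mol_from_smiles(structure)
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def is_canonical(structure: str) -> bool:
    try:
        return canonicalize(structure) == structure
    except ParseError:
        return False


@lru_cache(maxsize=100_000)
def molecular_weight(structure: str) -> float:
    """Molecular weight in g/mol, implicit hydrogens included."""
    return Descriptors.MolWt(mol_from_smiles(structure))


@lru_cache(maxsize=100_000)
def element_counts(structure: str) -> tuple[tuple[str, int], ...]:
    """Elemental composition of a molecule as sorted (symbol, count) pairs.

    Hydrogens (implicit and explicit) are counted under ``H``.
    """
    mol = mol_from_smiles(structure)
    counts: Counter[str] = Counter()
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym == "H":
            counts["H"] += 1
        else:
            counts[sym] += 1
            counts["H"] += atom.GetTotalNumHs()
    return tuple(sorted(counts.items()))


def formula_counter(structures: list[str]) -> Counter:
    """Summed elemental composition over a list of molecule keys."""
    total: Counter[str] = Counter()
    for s in structures:
        total.update(dict(element_counts(s)))
    return total


def heavy_atom_count(structure: str) -> int:
    return mol_from_smiles(structure).GetNumHeavyAtoms()


def ring_count(structure: str) -> int:
    return mol_from_smiles(structure).GetRingInfo().NumRings()


def elements_of(structure: str) -> set[str]:
    """Set of element symbols present (excluding hydrogen)."""
    return {sym for sym, _ in element_counts(structure) if sym != "H"}
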