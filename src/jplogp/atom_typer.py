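"""Hierarchical atom typing for atomic-contribution logP prediction.

Every atom of a perceived molecule (hydrogens included) is assigned a
six-digit integer code

    A BB C DD  =  A*100000 + BB*1000 + C*100 + DD

where A is the formal charge plus one (so a -1 charge is representable
while the code stays positive), BB is the atomic number (two digits, so
elements beyond Z=99 are out of scope), C is the number of heavy (non-H)
neighbours, and DD is an element-specific local-environment class.

The DD classifiers form six families: carbon, nitrogen, oxygen, hydrogen
and fluorine each get bespoke rules; every other element falls through to
a default rule keyed on aromaticity and polar-neighbour count.  "Polar"
throughout means an S, O, N or P atom.  The numeric DD vocabulary used
here is fixed by this module (see docs/methods.md for the full table) and
is stamped into every coefficient table via :data:`TYPER_VERSION` so that
models and typer revisions cannot silently drift apart.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

from rdkit import Chem

logger = logging.getLogger(__name__)

#: Version tag stamped into coefficient tables; bumped whenever the code
#: vocabulary changes incompatibly.
TYPER_VERSION = "jplogp-typer/1.0"

#: Atomic numbers counted as polar: S, O, N, P.
POLAR_ELEMENTS = frozenset({7, 8, 15, 16})

#: Halogens, used by the fluorine classifier's electron-withdrawing count.
HALOGEN_ELEMENTS = frozenset({9, 17, 35, 53})

MAX_ATOMIC_NUMBER = 99  # two-digit BB field
MIN_FORMAL_CHARGE = -1  # A = charge + 1 must stay non-negative
MAX_FORMAL_CHARGE = 8   # single-digit A


class TyperError(ValueError):
    """Base class for atom-typing failures."""


class ParseError(TyperError):
    """The input structure could not be parsed."""


class UnsupportedElementError(TyperError):
    """An atom's atomic number does not fit the two-digit BB field."""


class ChargeRangeError(TyperError):
    """An atom's formal charge falls outside the representable range."""


@dataclass(frozen=True)
class EnvironmentClass:
    """Resolved local-environment class for one atom.

    ``family`` names the classifier that handled the atom, ``label`` is a
    human-readable description and ``dd`` is the two-digit numeric value
    packed into the atom code.
    """

    family: str
    label: str
    dd: int

    def __post_init__(self) -> None:
        if not 0 <= self.dd <= 99:
            raise TyperError(f"DD value {self.dd} outside two-digit range")


# --------------------------------------------------------------------------
# Perception
# --------------------------------------------------------------------------

def perceive(structure: str | Chem.Mol) -> Chem.Mol:
    """Parse and standardise a structure for typing.

    Accepts a SMILES string or an RDKit molecule (e.g. from an SDF
    supplier).  Salts / mixtures are reduced to the largest covalent
    fragment with a warning, aromaticity is perceived (RDKit default
    model) and hydrogens are materialised as explicit atoms so that the
    hydrogen classifier can contribute counts to the hologram.

    Raises :class:`ParseError` for unparseable input and
    :class:`UnsupportedElementError` if any atom has Z > 99.
    """
    if isinstance(structure, Chem.Mol):
        mol = Chem.Mol(structure)
        try:
            Chem.SanitizeMol(mol)
        except Exception as exc:  # rdkit raises several sanitization types
            raise ParseError(f"structure failed sanitization: {exc}") from exc
    else:
        mol = Chem.MolFromSmiles(structure)
        if mol is None:
            raise ParseError(f"could not parse SMILES: {structure!r}")

    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        logger.warning(
            "input has %d fragments; keeping the largest", len(frags)
        )
        mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())

    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() > MAX_ATOMIC_NUMBER:
            raise UnsupportedElementError(
                f"atomic number {atom.GetAtomicNum()} exceeds the two-digit "
                f"element field (atom {atom.GetIdx()})"
            )
    return Chem.AddHs(mol)


# --------------------------------------------------------------------------
# Shared neighbourhood helpers
# --------------------------------------------------------------------------

_BOND_RANK = {"single": 0, "aromatic": 1, "double": 2, "triple": 3}


def _bond_class(bond: Chem.Bond) -> str:
    if bond.GetIsAromatic():
        return "aromatic"
    order = bond.GetBondType()
    if order == Chem.BondType.SINGLE:
        return "single"
    if order == Chem.BondType.DOUBLE:
        return "double"
    if order == Chem.BondType.TRIPLE:
        return "triple"
    # dative / quadruple etc. sit outside organic scope; treat as single
    return "single"


def _max_bond_class(atom: Chem.Atom) -> str:
    """Highest-order incident bond: single < aromatic < double < triple."""
    best = "single"
    for bond in atom.GetBonds():
        cls = _bond_class(bond)
        if _BOND_RANK[cls] > _BOND_RANK[best]:
            best = cls
    return best


def _hydrogen_count(atom: Chem.Atom) -> int:
    """Attached hydrogens, whether implicit or materialised as neighbours."""
    return atom.GetTotalNumHs(includeNeighbors=True)


def polar_neighbor_count(atom: Chem.Atom, mol: Chem.Mol | None = None) -> int:
    """Number of directly bonded S, O, N or P neighbours."""
    return sum(
        1 for nbr in atom.GetNeighbors() if nbr.GetAtomicNum() in POLAR_ELEMENTS
    )


# --------------------------------------------------------------------------
# Element-family classifiers
# --------------------------------------------------------------------------

def classify_carbon(atom: Chem.Atom, mol: Chem.Mol | None = None) -> EnvironmentClass:
    """Classify a carbon by max bond order and polar-neighbour placement.

    sp3 carbons (all single bonds) split only on presence of a polar
    neighbour.  Aromatic / double / triple carbons are further divided by
    how many polar atoms are attached through the multiple or aromatic
    bond versus through single bonds, since a multiply-bound polar atom
    (pyridine-type) pulls differently from a singly-bound one
    (aniline-type).
    """
    if atom.GetAtomicNum() != 6:
        raise TyperError("classify_carbon applied to a non-carbon atom")
    group = _max_bond_class(atom)
    polar_single = 0
    polar_multi = 0
    for bond in atom.GetBonds():
        nbr = bond.GetOtherAtom(atom)
        if nbr.GetAtomicNum() not in POLAR_ELEMENTS:
            continue
        if _bond_class(bond) == "single":
            polar_single += 1
        else:
            polar_multi += 1

    if group == "single":
        if polar_single:
            return EnvironmentClass("carbon", "sp3 with polar neighbor", 3)
        return EnvironmentClass("carbon", "sp3 no polar neighbor", 2)

    base = {"aromatic": 10, "double": 30, "triple": 50}[group]
    dd = base + 4 * min(polar_multi, 3) + min(polar_single, 3)
    label = (
        f"{group} C, {polar_multi} multiply-bound / "
        f"{polar_single} singly-bound polar"
    )
    return EnvironmentClass("carbon", label, dd)


def classify_nitrogen(atom: Chem.Atom, mol: Chem.Mol | None = None) -> EnvironmentClass:
    """Classify a nitrogen.

    The dominant effect is lone-pair availability: N single-bonded to an
    aromatic atom (aniline-like) or to a carbon carrying a double bond to
    O or S (amide/thioamide-like) is delocalised and grouped together.
    Otherwise N directly bound to a polar atom gets its own class, and the
    remainder split by maximum bond order like carbon.
    """
    if atom.GetAtomicNum() != 7:
        raise TyperError("classify_nitrogen applied to a non-nitrogen atom")

    for bond in atom.GetBonds():
        if _bond_class(bond) != "single":
            continue
        nbr = bond.GetOtherAtom(atom)
        if nbr.GetIsAromatic():
            return EnvironmentClass("nitrogen", "delocalized lone pair (aniline/amide-like)", 1)
        if nbr.GetAtomicNum() == 6:
            for nbond in nbr.GetBonds():
                if (
                    nbond.GetBondType() == Chem.BondType.DOUBLE
                    and nbond.GetOtherAtom(nbr).GetAtomicNum() in (8, 16)
                ):
                    return EnvironmentClass(
                        "nitrogen", "delocalized lone pair (aniline/amide-like)", 1
                    )

    if polar_neighbor_count(atom):
        return EnvironmentClass("nitrogen", "bound to polar atom", 2)

    group = _max_bond_class(atom)
    dd = {"single": 3, "aromatic": 4, "double": 5, "triple": 6}[group]
    return EnvironmentClass("nitrogen", f"{group} N", dd)


def classify_oxygen(atom: Chem.Atom, mol: Chem.Mol | None = None) -> EnvironmentClass:
    """Classify an oxygen.

    O bound to N or to S is split out directly; sp2 oxygens (double bond
    to carbon) are divided by the carbonyl carbon's single-bonded
    heteroatom into amide, acid, ester, thio-equivalent and plain carbonyl
    classes; the rest are hydroxyl, ether or other.
    """
    if atom.GetAtomicNum() != 8:
        raise TyperError("classify_oxygen applied to a non-oxygen atom")

    neighbor_z = [nbr.GetAtomicNum() for nbr in atom.GetNeighbors()]
    if 7 in neighbor_z:
        return EnvironmentClass("oxygen", "bound to nitrogen", 1)
    if 16 in neighbor_z:
        return EnvironmentClass("oxygen", "bound to sulfur", 2)

    carbonyl_carbon = None
    for bond in atom.GetBonds():
        if bond.GetBondType() == Chem.BondType.DOUBLE:
            other = bond.GetOtherAtom(atom)
            if other.GetAtomicNum() == 6:
                carbonyl_carbon = other
                break
    if carbonyl_carbon is not None:
        # resolve the carbonyl's single-bonded heteroatom; N before O/S so
        # carbamates land with amides deterministically
        single_nbrs = []
        for bond in carbonyl_carbon.GetBonds():
            if _bond_class(bond) == "single":
                single_nbrs.append(bond.GetOtherAtom(carbonyl_carbon))
        if any(n.GetAtomicNum() == 7 for n in single_nbrs):
            return EnvironmentClass("oxygen", "sp2 O of amide", 3)
        if any(n.GetAtomicNum() == 16 for n in single_nbrs):
            return EnvironmentClass("oxygen", "sp2 O of thio ester/acid", 7)
        for n in single_nbrs:
            if n.GetAtomicNum() == 8:
                if _hydrogen_count(n) > 0:
                    return EnvironmentClass("oxygen", "sp2 O of carboxylic acid", 4)
                return EnvironmentClass("oxygen", "sp2 O of ester", 5)
        return EnvironmentClass("oxygen", "sp2 O of carbonyl", 6)

    if _hydrogen_count(atom) > 0:
        return EnvironmentClass("oxygen", "hydroxyl", 8)
    if sum(1 for n in atom.GetNeighbors() if n.GetAtomicNum() > 1) == 2:
        return EnvironmentClass("oxygen", "ether", 9)
    return EnvironmentClass("oxygen", "other O", 0)


def classify_fluorine(atom: Chem.Atom, mol: Chem.Mol | None = None) -> EnvironmentClass:
    """Classify a fluorine by its carrier carbon.

    Fluorine is keyed on the hybridisation (max bond order) of the carbon
    it is bound to and the number of additional electron-withdrawing
    substituents (other halogens plus polar atoms) on that carbon, since
    fluorine damps the effect of further withdrawing groups.  F on a
    non-carbon carrier falls into a single residual class.
    """
    if atom.GetAtomicNum() != 9:
        raise TyperError("classify_fluorine applied to a non-fluorine atom")

    carrier = None
    for nbr in atom.GetNeighbors():
        carrier = nbr
        break
    if carrier is None or carrier.GetAtomicNum() != 6:
        return EnvironmentClass("fluorine", "F on non-carbon", 0)

    hyb = {"single": 1, "aromatic": 2, "double": 3, "triple": 4}[_max_bond_class(carrier)]
    ewg = 0
    for nbr in carrier.GetNeighbors():
        if nbr.GetIdx() == atom.GetIdx():
            continue
        z = nbr.GetAtomicNum()
        if z in HALOGEN_ELEMENTS or z in POLAR_ELEMENTS:
            ewg += 1
    dd = 10 * hyb + min(ewg, 9)
    return EnvironmentClass(
        "fluorine", f"F on {_max_bond_class(carrier)} C with {ewg} withdrawing", dd
    )


def classify_hydrogen(atom: Chem.Atom, mol: Chem.Mol | None = None) -> EnvironmentClass:
    """Classify a hydrogen by its carrier atom only (topological distance 1).

    Carbon carriers split by maximum bond order; polar heavy carriers
    (N, O, S, P) share one class; anything else is residual.  No
    beta-position lookups are performed.
    """
    if atom.GetAtomicNum() != 1:
        raise TyperError("classify_hydrogen applied to a non-hydrogen atom")

    carrier = None
    for nbr in atom.GetNeighbors():
        carrier = nbr
        break
    if carrier is None:
        return EnvironmentClass("hydrogen", "free H", 0)
    z = carrier.GetAtomicNum()
    if z == 6:
        dd = {"single": 1, "aromatic": 2, "double": 3, "triple": 4}[_max_bond_class(carrier)]
        return EnvironmentClass("hydrogen", f"H on {_max_bond_class(carrier)} C", dd)
    if z in POLAR_ELEMENTS:
        return EnvironmentClass("hydrogen", "H on polar atom", 5)
    return EnvironmentClass("hydrogen", "H on other atom", 0)


def classify_default(atom: Chem.Atom, mol: Chem.Mol | None = None) -> EnvironmentClass:
    """Fallback classifier for every element without a bespoke family.

    Aromatic atoms take a reserved class; all others are keyed on the
    number of polar neighbours.  Covers Cl, Br, I, S, P, B, metals, ...
    """
    if atom.GetIsAromatic():
        return EnvironmentClass("default", "aromatic atom", 50)
    count = polar_neighbor_count(atom)
    return EnvironmentClass("default", f"{count} polar neighbors", min(count, 9))


_FAMILY_DISPATCH = {
    6: classify_carbon,
    7: classify_nitrogen,
    8: classify_oxygen,
    1: classify_hydrogen,
    9: classify_fluorine,
}


def classify(atom: Chem.Atom, mol: Chem.Mol | None = None) -> EnvironmentClass:
    """Dispatch an atom to its element-family classifier."""
    handler = _FAMILY_DISPATCH.get(atom.GetAtomicNum(), classify_default)
    return handler(atom, mol)


# --------------------------------------------------------------------------
# Code assembly
# --------------------------------------------------------------------------

def type_atom(atom: Chem.Atom, mol: Chem.Mol | None = None) -> int:
    """Assemble the six-digit code A|BB|C|DD for one atom."""
    z = atom.GetAtomicNum()
    if z < 1 or z > MAX_ATOMIC_NUMBER:
        raise UnsupportedElementError(f"atomic number {z} not typable")
    charge = atom.GetFormalCharge()
    if charge < MIN_FORMAL_CHARGE or charge > MAX_FORMAL_CHARGE:
        raise ChargeRangeError(
            f"formal charge {charge} outside [{MIN_FORMAL_CHARGE}, {MAX_FORMAL_CHARGE}]"
        )
    heavy = sum(1 for nbr in atom.GetNeighbors() if nbr.GetAtomicNum() > 1)
    if heavy > 9:
        raise TyperError(f"heavy-neighbor count {heavy} exceeds one digit")
    env = classify(atom, mol)
    return (charge + 1) * 100_000 + z * 1_000 + heavy * 100 + env.dd


def type_molecule(mol: Chem.Mol) -> dict[int, int]:
    """Atom-type hologram of a perceived molecule: code -> occurrence count.

    The sum of the counts equals the total atom count, hydrogens included.
    """
    counts: Counter[int] = Counter()
    for atom in mol.GetAtoms():
        counts[type_atom(atom, mol)] += 1
    return dict(counts)


def type_structure(structure: str | Chem.Mol) -> dict[int, int]:
    """Convenience: perceive then type in one call."""
    return type_molecule(perceive(structure))


def decode(code: int) -> tuple[int, int, int, int]:
    """Split a six-digit code back into (formal charge, Z, heavy count, DD)."""
    a, rest = divmod(code, 100_000)
    z, rest = divmod(rest, 1_000)
    heavy, dd = divmod(rest, 100)
    return a - 1, z, heavy, dd
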