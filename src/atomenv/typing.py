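"""Scheme-dependent atom/bond type keys and their SMARTS primitive encodings.

Two atom typing schemes are supported:

* ``element_only`` — the atomic number is the sole feature, encoded as
  ``[#<Z>]``.  This is the typing the classic "augmented atom" fragment
  studies used.
* ``six_property`` — atoms are characterized by atomic number, formal
  charge, implicit hydrogen count, explicit degree, valence, and aromatic
  membership, encoded as ``[<sym><±charge>h<H>D<deg>v<val>]`` with a
  lowercase element symbol marking aromaticity and the charge always signed
  (``+0`` for uncharged).

Valence is the sum of incident sigma and pi bonds: implicit hydrogen count
plus explicit degree plus the per-bond excess over single-bond order.
Aromatic bonds enter with their resolved Kekulé order; when no Kekulé form
is known they count 1.5 each and the total is rounded.

Bond typing schemes:

* ``four_type`` — single/double/triple/aromatic (``-``, ``=``, ``#``, ``:``);
  the aromatic flag wins over the stored order.
* ``augmented`` — order plus ring/chain membership (``-@``/``-!@`` etc.),
  with aromatic ring bonds as ``:``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

from rdkit import Chem

from .graph import COVALENT, MolGraph
from .preprocess import GENERAL_HUCKEL, SIMPLE_SIXRING

ELEMENT_ONLY = "element_only"
SIX_PROPERTY = "six_property"
FOUR_TYPE = "four_type"
AUGMENTED = "augmented"

_PERIODIC = Chem.GetPeriodicTable()


@dataclass(frozen=True)
class Scheme:
    """A fragmentation configuration.

    The two standard pairings are :meth:`default` (six-property atoms,
    four-type bonds, general Hückel aromaticity, terminal centers excluded)
    and :meth:`augmented` (element-only atoms, order+ring/chain bonds,
    six-ring aromaticity, terminal centers allowed).  Arbitrary mixes are
    permitted but reported as nonstandard.
    """

    atom_scheme: str = SIX_PROPERTY
    bond_scheme: str = FOUR_TYPE
    aromaticity: str | None = GENERAL_HUCKEL
    allow_terminal_centers: bool = False

    def __post_init__(self):
        if self.atom_scheme not in (ELEMENT_ONLY, SIX_PROPERTY):
            raise ValueError(f"unknown atom scheme {self.atom_scheme!r}")
        if self.bond_scheme not in (FOUR_TYPE, AUGMENTED):
            raise ValueError(f"unknown bond scheme {self.bond_scheme!r}")

    @classmethod
    def default(cls) -> "Scheme":
        return cls(SIX_PROPERTY, FOUR_TYPE, GENERAL_HUCKEL, False)

    @classmethod
    def augmented(cls) -> "Scheme":
        return cls(ELEMENT_ONLY, AUGMENTED, SIMPLE_SIXRING, True)

    @property
    def is_standard(self) -> bool:
        return self in (Scheme.default(), Scheme.augmented())

    @property
    def tag(self) -> str:
        terminal = "T" if self.allow_terminal_centers else "t"
        return f"{self.atom_scheme}/{self.bond_scheme}/{self.aromaticity}/{terminal}"


class AtomTypeKey(NamedTuple):
    scheme: str
    atomic_number: int
    formal_charge: int | None = None
    implicit_h_count: int | None = None
    explicit_degree: int | None = None
    valence: int | None = None
    is_aromatic: bool | None = None


class BondTypeKey(NamedTuple):
    scheme: str
    order: int  # 1/2/3; 0 denotes aromatic
    in_ring: bool | None = None  # only meaningful under the augmented scheme

    @property
    def is_aromatic(self) -> bool:
        return self.order == 0


def valence(mol: MolGraph, atom_index: int) -> int:
    """Sum of incident sigma and pi bonds, including implicit hydrogens."""
    atom = mol.atoms[atom_index]
    total = float(atom.implicit_h_count)
    for b in mol.covalent_bonds_of(atom_index):
        total += b.order_contrib
    return int(total + 0.5)


def type_atom(mol: MolGraph, atom_index: int, scheme: Scheme) -> AtomTypeKey:
    """Compute the scheme-dependent type key of one atom.

    Derived fields (degree, valence) are computed from the current covalent
    neighborhood, never cached; the key is a pure function of the atom's
    local environment.
    """
    if not 0 <= atom_index < len(mol.atoms):
        raise IndexError(f"atom index {atom_index} out of range")
    atom = mol.atoms[atom_index]
    if scheme.atom_scheme == ELEMENT_ONLY:
        return AtomTypeKey(ELEMENT_ONLY, atom.atomic_number)
    return AtomTypeKey(
        SIX_PROPERTY,
        atom.atomic_number,
        atom.formal_charge,
        atom.implicit_h_count,
        mol.covalent_degree(atom_index),
        valence(mol, atom_index),
        atom.is_aromatic,
    )


def type_bond(mol: MolGraph, bond_index: int, scheme: Scheme) -> BondTypeKey:
    """Compute the scheme-dependent type key of one bond."""
    bond = mol.bonds[bond_index]
    if bond.bond_class != COVALENT:
        raise ValueError(
            f"non-standard ({bond.bond_class}) bond has no type; filter first"
        )
    if bond.is_aromatic:
        return BondTypeKey(scheme.bond_scheme, 0, True if scheme.bond_scheme == AUGMENTED else None)
    if scheme.bond_scheme == FOUR_TYPE:
        return BondTypeKey(FOUR_TYPE, bond.order)
    return BondTypeKey(AUGMENTED, bond.order, bond.in_ring)


def encode_atom_primitive(key: AtomTypeKey) -> str:
    """SMARTS bracket primitive for an atom type key.

    Six-property keys concatenate element, charge, h, D, v in that fixed
    order for byte-exact output; element-only keys are ``[#<Z>]``.
    """
    if key.scheme == ELEMENT_ONLY:
        return f"[#{key.atomic_number}]"
    if key.atomic_number == 1:
        # SMARTS reserves the bracketed symbol H for hydrogen counts, so
        # retained hydrogen atoms are encoded by atomic number
        return (
            f"[#1{key.formal_charge:+d}h{key.implicit_h_count}"
            f"D{key.explicit_degree}v{key.valence}]"
        )
    try:
        symbol = _PERIODIC.GetElementSymbol(key.atomic_number)
    except Exception:
        symbol = ""
    if not symbol or symbol == "*":
        raise ValueError(f"unknown atomic number {key.atomic_number}")
    if key.is_aromatic:
        symbol = symbol.lower()
    return (
        f"[{symbol}{key.formal_charge:+d}h{key.implicit_h_count}"
        f"D{key.explicit_degree}v{key.valence}]"
    )


_ORDER_SYMBOL = {1: "-", 2: "=", 3: "#"}


def encode_bond_primitive(key: BondTypeKey) -> str:
    """SMARTS bond primitive for a bond type key."""
    if key.is_aromatic:
        return ":"
    symbol = _ORDER_SYMBOL[key.order]
    if key.scheme == AUGMENTED:
        symbol += "@" if key.in_ring else "!@"
    return symbol
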