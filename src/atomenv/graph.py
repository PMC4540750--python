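"""Hydrogen-suppressed molecular graphs.

:class:`MolGraph` is the substrate of every operation in this package: an
ordered list of atoms, a list of bonds between atom indices, plus the record
bookkeeping needed for corpus-level statistics.  Atom indices are stable for
the lifetime of the object; operations refer to atoms by index.

Bonds carry a *bond class*: only ``covalent`` bonds take part in degree,
valence, ring perception and environment growth.  Ionic, complex and dative
bonds are stored but otherwise ignored throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

COVALENT = "covalent"
NON_COVALENT_CLASSES = frozenset({"ionic", "complex", "dative"})


@dataclass
class AtomNode:
    """A heavy atom, or an explicitly retained hydrogen.

    ``implicit_h_count`` is always defined (0 if unset);
    ``h_specified`` records whether the input format carried an explicit
    hydrogen count for this atom (bracket SMILES atoms do, bare organic-subset
    atoms and SDF atoms do not), which decides whether the standard valence
    model may adjust it.
    """

    atomic_number: int
    formal_charge: int = 0
    implicit_h_count: int = 0
    h_specified: bool = False
    is_aromatic: bool = False
    provisional_aromatic: bool = False
    is_explicit_hydrogen_retained: bool = False


@dataclass
class BondEdge:
    """An edge between two atom indices.

    ``order`` is the integer covalent bond order (1-3).  For bonds written as
    aromatic in the input, ``kekule_known`` says whether an alternating
    single/double assignment could be resolved; if not, valence arithmetic
    falls back to counting the bond as 1.5.  ``is_aromatic`` is set only by
    aromaticity perception; ``provisional_aromatic`` preserves the input's
    lowercase/type-4 marks until perception overwrites them.
    """

    i: int
    j: int
    order: int = 1
    kekule_known: bool = True
    is_aromatic: bool = False
    provisional_aromatic: bool = False
    in_ring: bool = False
    bond_class: str = COVALENT

    @property
    def endpoints(self) -> tuple[int, int]:
        return (self.i, self.j)

    @property
    def order_contrib(self) -> float:
        """Bond-order contribution to valence sums.

        Integer Kekulé order when resolved; 1.5 for aromatic-written bonds
        whose alternating assignment could not be recovered.
        """
        return float(self.order) if self.kekule_known else 1.5

    def other(self, idx: int) -> int:
        return self.j if idx == self.i else self.i


@dataclass
class MolGraph:
    """A single structure record as a simple labeled graph."""

    record_id: str
    atoms: list[AtomNode] = field(default_factory=list)
    bonds: list[BondEdge] = field(default_factory=list)
    source_format: str = "builtin"
    rejected: bool = False
    reject_reason: str | None = None

    # -- basic accessors ---------------------------------------------------

    def num_atoms(self) -> int:
        return len(self.atoms)

    def covalent_adjacency(self) -> list[list[tuple[int, int]]]:
        """Per-atom list of ``(neighbor_index, bond_index)`` over covalent bonds."""
        adj: list[list[tuple[int, int]]] = [[] for _ in self.atoms]
        for b_idx, bond in enumerate(self.bonds):
            if bond.bond_class != COVALENT:
                continue
            adj[bond.i].append((bond.j, b_idx))
            adj[bond.j].append((bond.i, b_idx))
        return adj

    def covalent_degree(self, idx: int) -> int:
        return sum(
            1
            for b in self.bonds
            if b.bond_class == COVALENT and idx in (b.i, b.j)
        )

    def covalent_bonds_of(self, idx: int) -> list[BondEdge]:
        return [
            b
            for b in self.bonds
            if b.bond_class == COVALENT and idx in (b.i, b.j)
        ]

    def component_of(self, idx: int) -> set[int]:
        """Atom indices of the covalent connected component containing ``idx``."""
        adj = self.covalent_adjacency()
        seen = {idx}
        stack = [idx]
        while stack:
            cur = stack.pop()
            for nbr, _ in adj[cur]:
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append(nbr)
        return seen

    def copy(self) -> "MolGraph":
        return MolGraph(
            record_id=self.record_id,
            atoms=[replace(a) for a in self.atoms],
            bonds=[replace(b) for b in self.bonds],
            source_format=self.source_format,
            rejected=self.rejected,
            reject_reason=self.reject_reason,
        )

    def validate(self) -> None:
        """Check the simple-graph invariants; raise ``ValueError`` on violation."""
        n = len(self.atoms)
        seen_pairs: set[tuple[int, int]] = set()
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ValueError(f"bond endpoint out of range: {b.i}-{b.j}")
            if b.i == b.j:
                raise ValueError(f"self-loop on atom {b.i}")
            pair = (min(b.i, b.j), max(b.i, b.j))
            if pair in seen_pairs:
                raise ValueError(f"duplicate bond between atoms {pair}")
            seen_pairs.add(pair)


def to_networkx(mol: MolGraph):
    """Covalent graph as a ``networkx.Graph`` (nodes = atom indices)."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(mol.atoms)))
    for b_idx, b in enumerate(mol.bonds):
        if b.bond_class == COVALENT:
            g.add_edge(b.i, b.j, bond_index=b_idx)
    return g


def to_rdkit(mol: MolGraph):
    """Export to an RDKit molecule for SMARTS matching and interop.

    Hydrogen counts are pinned exactly (``NoImplicit``), aromatic flags are
    carried over, and perceived-aromatic bonds are exported with the aromatic
    bond type so RDKit's valence accounting and ``:``/``@`` queries agree
    with this package's arithmetic.  Non-covalent bonds are dropped.
    """
    from rdkit import Chem
    from rdkit.Chem import RWMol, Atom, BondType

    order_map = {1: BondType.SINGLE, 2: BondType.DOUBLE, 3: BondType.TRIPLE}
    rw = RWMol()
    for a in mol.atoms:
        ra = Atom(a.atomic_number)
        ra.SetFormalCharge(a.formal_charge)
        ra.SetNoImplicit(True)
        ra.SetNumExplicitHs(a.implicit_h_count)
        ra.SetIsAromatic(a.is_aromatic)
        rw.AddAtom(ra)
    for b in mol.bonds:
        if b.bond_class != COVALENT:
            continue
        bt = BondType.AROMATIC if b.is_aromatic else order_map[b.order]
        rw.AddBond(b.i, b.j, bt)
        rw.GetBondBetweenAtoms(b.i, b.j).SetIsAromatic(b.is_aromatic)
    out = rw.GetMol()
    out.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(out)
    return out
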