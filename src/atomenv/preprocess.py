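"""Structure normalization: hydrogen suppression, implicit-H assignment,
ring annotation, and aromaticity perception.

The pipeline mirrors how large chemical registries prepare deposited
structures for fragment analysis:

1. :func:`suppress_hydrogens` folds explicit hydrogen atoms into their heavy
   neighbor's implicit count (isotope labels are treated as plain hydrogen;
   hydrogen species without a heavy neighbor — H2, hydride, a lone proton —
   stay as explicit atoms).
2. :func:`assign_implicit_hydrogens` completes unsaturated valences under a
   standard valence model, MDL-style.
3. :func:`annotate_rings` marks every bond that lies on a cycle.
4. :func:`perceive_aromaticity` sets aromatic flags under one of two models:
   ``simple_sixring`` (only six-membered C/N rings, Hückel 6π — the model
   classic "augmented atom" comparisons used) or ``general_huckel`` (5-7
   membered rings of C/N/O/S with standard π-contribution accounting,
   extended to fused systems by iterating to a fixed point).

:func:`preprocess` chains all four.
"""

from __future__ import annotations

import json
import logging
from typing import Iterable

import networkx as nx

from .graph import COVALENT, MolGraph, to_networkx

logger = logging.getLogger(__name__)

SIMPLE_SIXRING = "simple_sixring"
GENERAL_HUCKEL = "general_huckel"
AROMATICITY_MODELS = (SIMPLE_SIXRING, GENERAL_HUCKEL)

ORGANIC_ELEMENTS = frozenset({1, 6, 7, 8, 9, 15, 16, 17, 35, 53})


class ValenceDefaults:
    """Allowed default valences per ``(atomic_number, formal_charge)``.

    The shipped table follows MDL conventions for the organic elements:
    H 1, C 4, N 3, O 2, F 1, P 3/5, S 2/4/6, Cl 1, Br 1, I 1 (charge 0),
    with N+/P+ -> 4 and O-/S- reduced by one.  Every other combination means
    "no hydrogens are added".  Lists are kept sorted ascending.
    """

    _SHIPPED: dict[tuple[int, int], tuple[int, ...]] = {
        (1, 0): (1,),
        (6, 0): (4,),
        (7, 0): (3,),
        (8, 0): (2,),
        (9, 0): (1,),
        (15, 0): (3, 5),
        (16, 0): (2, 4, 6),
        (17, 0): (1,),
        (35, 0): (1,),
        (53, 0): (1,),
        (7, 1): (4,),
        (15, 1): (4,),
        (8, -1): (1,),
        (16, -1): (1,),
    }

    def __init__(self, table: dict[tuple[int, int], tuple[int, ...]] | None = None):
        self.table = {
            key: tuple(sorted(vals))
            for key, vals in (table if table is not None else self._SHIPPED).items()
        }

    @classmethod
    def default(cls) -> "ValenceDefaults":
        return cls()

    @classmethod
    def from_file(cls, path) -> "ValenceDefaults":
        """Load overrides from YAML/JSON: a list of {element, charge, valences}."""
        from rdkit import Chem

        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
        try:
            entries = json.loads(text)
        except json.JSONDecodeError:
            import yaml

            entries = yaml.safe_load(text)
        periodic = Chem.GetPeriodicTable()
        table: dict[tuple[int, int], tuple[int, ...]] = {}
        for entry in entries:
            element = entry["element"]
            z = element if isinstance(element, int) else periodic.GetAtomicNumber(element)
            table[(z, int(entry.get("charge", 0)))] = tuple(
                sorted(int(v) for v in entry["valences"])
            )
        return cls(table)

    def allowed(self, atomic_number: int, charge: int) -> tuple[int, ...]:
        return self.table.get((atomic_number, charge), ())

    def items(self):
        return self.table.items()


def suppress_hydrogens(mol: MolGraph) -> MolGraph:
    """Convert explicit hydrogen atoms into implicit counts on their neighbor.

    A hydrogen is suppressed iff it is neutral and bonded by exactly one
    single covalent bond to one non-hydrogen atom.  Deuterium/tritium labels
    were already discarded at parse time, so isotopic hydrogens fold in like
    any other.  Remaining hydrogen atoms (H2, hydride, lone H) are retained
    with ``is_explicit_hydrogen_retained`` set.
    """
    out = mol.copy()
    adj = out.covalent_adjacency()
    drop: set[int] = set()
    for idx, atom in enumerate(out.atoms):
        if atom.atomic_number != 1 or atom.formal_charge != 0:
            continue
        neighbors = adj[idx]
        if len(neighbors) != 1:
            continue
        nbr, b_idx = neighbors[0]
        bond = out.bonds[b_idx]
        if bond.order != 1 or not bond.kekule_known:
            continue
        if out.atoms[nbr].atomic_number == 1:
            continue
        drop.add(idx)
        out.atoms[nbr].implicit_h_count += atom.implicit_h_count + 1
    for idx, atom in enumerate(out.atoms):
        if atom.atomic_number == 1 and idx not in drop:
            atom.is_explicit_hydrogen_retained = True
    if not drop:
        return out
    remap = {}
    new_atoms = []
    for idx, atom in enumerate(out.atoms):
        if idx in drop:
            continue
        remap[idx] = len(new_atoms)
        new_atoms.append(atom)
    new_bonds = []
    for bond in out.bonds:
        if bond.i in drop or bond.j in drop:
            continue
        bond.i = remap[bond.i]
        bond.j = remap[bond.j]
        new_bonds.append(bond)
    out.atoms = new_atoms
    out.bonds = new_bonds
    return out


def assign_implicit_hydrogens(
    mol: MolGraph, defaults: ValenceDefaults | None = None
) -> MolGraph:
    """Fill unspecified hydrogen counts under the standard valence model.

    For each atom whose input did not pin a hydrogen count, the sigma/pi sum
    ``s`` is taken over covalent bonds (including hydrogens already folded in
    by suppression) and the count is topped up to the smallest default
    valence ``v* >= s`` for the atom's element and charge.  If no default
    reaches ``s`` the atom is left hypervalent with no added hydrogens.
    Atoms whose input carried an explicit count keep it untouched.
    """
    defaults = defaults or ValenceDefaults.default()
    out = mol.copy()
    warned: set[int] = set()
    for idx, atom in enumerate(out.atoms):
        if atom.h_specified:
            continue
        s = atom.implicit_h_count + sum(
            b.order_contrib for b in out.covalent_bonds_of(idx)
        )
        allowed = defaults.allowed(atom.atomic_number, atom.formal_charge)
        if not allowed:
            if (
                atom.atomic_number not in warned
                and (atom.atomic_number, 0) not in defaults.table
            ):
                warned.add(atom.atomic_number)
                logger.warning(
                    "no default valences for element %d (record %s); "
                    "no hydrogens added",
                    atom.atomic_number,
                    mol.record_id,
                )
            continue
        target = next((v for v in allowed if v >= s), None)
        if target is None:
            continue
        atom.implicit_h_count += max(int(target - s + 0.5), 0)
    return out


def annotate_rings(mol: MolGraph) -> MolGraph:
    """Set ``in_ring`` on every bond lying on a cycle of the covalent graph.

    A bond is on a cycle iff it is not a bridge.
    """
    out = mol.copy()
    g = to_networkx(out)
    bridges = set()
    for u, v in nx.bridges(g):
        bridges.add((u, v))
        bridges.add((v, u))
    for b in out.bonds:
        if b.bond_class != COVALENT:
            b.in_ring = False
            continue
        b.in_ring = g.has_edge(b.i, b.j) and (b.i, b.j) not in bridges
    return out


def _ring_pi_contributions(
    mol: MolGraph, ring_atoms: list[int], ring_bond_set: set[int], adj
) -> list[int] | None:
    """Per-atom π-electron contributions for a candidate ring.

    Returns ``None`` if any member disqualifies the ring (triple bond,
    degree > 3, two double bonds, or an sp3 carbon with no π access).
    """
    members = set(ring_atoms)
    contribs: list[int] = []
    for a_idx in ring_atoms:
        incident = [(nbr, b_idx) for nbr, b_idx in adj[a_idx]]
        if len(incident) > 3:
            return None
        doubles_in = doubles_out = 0
        has_unresolved = False
        has_aromatic = False
        for nbr, b_idx in incident:
            bond = mol.bonds[b_idx]
            if bond.kekule_known and bond.order == 3:
                return None
            if bond.is_aromatic:
                has_aromatic = True
            if not bond.kekule_known:
                if b_idx in ring_bond_set or nbr in members:
                    has_unresolved = True
                continue
            if bond.order == 2:
                if nbr in members:
                    doubles_in += 1
                else:
                    doubles_out += 1
        if doubles_in + doubles_out > 1:
            return None
        atom = mol.atoms[a_idx]
        if doubles_in == 1:
            contribs.append(1)
        elif has_aromatic:
            # the atom's π electron lives in an already-aromatic fused ring
            contribs.append(1)
        elif doubles_out == 1:
            contribs.append(0)
        elif has_unresolved:
            # bond written aromatic without resolvable Kekulé form, or the
            # atom already sits in a perceived aromatic ring: one π electron
            contribs.append(1)
        elif atom.atomic_number in (7, 8, 16) and atom.formal_charge <= 0:
            contribs.append(2)  # lone pair donated into the ring
        elif atom.atomic_number == 6 and atom.formal_charge == -1:
            contribs.append(2)
        elif atom.atomic_number == 6 and atom.formal_charge == 1:
            contribs.append(0)
        else:
            return None  # saturated member: ring is not a conjugated system
    return contribs


def _candidate_rings(mol: MolGraph, max_size: int) -> list[tuple[list[int], set[int]]]:
    g = to_networkx(mol)
    bond_index = {}
    for b_idx, b in enumerate(mol.bonds):
        if b.bond_class == COVALENT:
            bond_index[frozenset((b.i, b.j))] = b_idx
    rings = []
    for cycle in nx.simple_cycles(g, length_bound=max_size):
        if len(cycle) < 3:
            continue
        bonds = {
            bond_index[frozenset((cycle[k], cycle[(k + 1) % len(cycle)]))]
            for k in range(len(cycle))
        }
        rings.append((list(cycle), bonds))
    return rings


def perceive_aromaticity(mol: MolGraph, model: str | None) -> MolGraph:
    """Perceive aromatic atoms and bonds under the requested model.

    ``model`` is ``"simple_sixring"``, ``"general_huckel"`` or ``None`` (no
    perception: all aromatic flags are cleared, leaving the Kekulé form).
    Provisional flags from the input are always overwritten.  Perception is
    idempotent: it starts from a clean slate and depends only on the Kekulé
    bond orders.
    """
    if model is not None and model not in AROMATICITY_MODELS:
        raise ValueError(f"unknown aromaticity model {model!r}")
    out = mol.copy()
    for atom in out.atoms:
        atom.is_aromatic = False
    for bond in out.bonds:
        bond.is_aromatic = False
    if model is None:
        return out

    if model == SIMPLE_SIXRING:
        rings = [r for r in _candidate_rings(out, 6) if len(r[0]) == 6]
        allowed_elements = {6, 7}
        required_pi = lambda n: n == 6  # noqa: E731
        sp2_required = True
    else:
        rings = [r for r in _candidate_rings(out, 7) if len(r[0]) >= 5]
        allowed_elements = {6, 7, 8, 16}
        required_pi = lambda n: n % 4 == 2  # noqa: E731
        sp2_required = False

    adj = out.covalent_adjacency()
    changed = True
    while changed:
        changed = False
        for ring_atoms, ring_bonds in rings:
            if all(out.bonds[b].is_aromatic for b in ring_bonds):
                continue
            if any(
                out.atoms[a].atomic_number not in allowed_elements
                for a in ring_atoms
            ):
                continue
            contribs = _ring_pi_contributions(out, ring_atoms, ring_bonds, adj)
            if contribs is None:
                continue
            if sp2_required and any(c == 2 for c in contribs):
                # six-ring model: every member must carry a double bond
                continue
            if not required_pi(sum(contribs)):
                continue
            for a in ring_atoms:
                out.atoms[a].is_aromatic = True
            for b in ring_bonds:
                out.bonds[b].is_aromatic = True
            changed = True
    return out


def preprocess(
    mol: MolGraph,
    aromaticity: str | None = GENERAL_HUCKEL,
    defaults: ValenceDefaults | None = None,
) -> MolGraph:
    """Full normalization pipeline on one record."""
    out = suppress_hydrogens(mol)
    out = assign_implicit_hydrogens(out, defaults)
    out = annotate_rings(out)
    out = perceive_aromaticity(out, aromaticity)
    return out


def preprocess_all(
    mols: Iterable[MolGraph],
    aromaticity: str | None = GENERAL_HUCKEL,
    defaults: ValenceDefaults | None = None,
) -> list[MolGraph]:
    """Normalize a corpus, passing rejected records through untouched."""
    out = []
    for mol in mols:
        out.append(mol if mol.rejected else preprocess(mol, aromaticity, defaults))
    return out
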