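"""Readers and writers: SMILES lines, SDF V2000, and TSV fragment tables.

Parsing deliberately preserves the *deposited* form of a structure: explicit
hydrogens stay explicit, lowercase aromatic marks become provisional flags,
and no aromaticity model is applied.  Normalization is the job of
:mod:`atomenv.preprocess`.

RDKit does the heavy lifting of tokenizing SMILES and V2000 connection
tables; the result is immediately converted into the package's own
:class:`~atomenv.graph.MolGraph`.
"""

from __future__ import annotations

import io as _io
from typing import Iterable, Iterator, TextIO

from rdkit import Chem
from rdkit import RDLogger

from .graph import AtomNode, BondEdge, MolGraph

RDLogger.DisableLog("rdApp.*")  # parse failures are reported as exceptions


class MolParseError(ValueError):
    """Raised for malformed SMILES or SDF input."""


_BOND_ORDERS = {
    Chem.BondType.SINGLE: (1, True, False),
    Chem.BondType.DOUBLE: (2, True, False),
    Chem.BondType.TRIPLE: (3, True, False),
    # aromatic-typed input bond: order unresolved until kekulization
    Chem.BondType.AROMATIC: (1, False, True),
}

_NON_COVALENT = {
    Chem.BondType.IONIC: "ionic",
    Chem.BondType.DATIVE: "dative",
}


def _from_rdkit(rdmol, record_id: str, source_format: str) -> MolGraph:
    mol = MolGraph(record_id=record_id, source_format=source_format)
    for atom in rdmol.GetAtoms():
        z = atom.GetAtomicNum()
        if z == 0:
            mol.rejected = True
            mol.reject_reason = "pseudo-atom"
        mol.atoms.append(
            AtomNode(
                atomic_number=z,
                formal_charge=atom.GetFormalCharge(),
                implicit_h_count=atom.GetNumExplicitHs(),
                h_specified=atom.GetNoImplicit(),
                provisional_aromatic=atom.GetIsAromatic(),
            )
        )
    for bond in rdmol.GetBonds():
        bt = bond.GetBondType()
        if bt in _NON_COVALENT:
            mol.bonds.append(
                BondEdge(
                    bond.GetBeginAtomIdx(),
                    bond.GetEndAtomIdx(),
                    order=1,
                    bond_class=_NON_COVALENT[bt],
                )
            )
            continue
        order, kekule_known, provisional = _BOND_ORDERS.get(bt, (1, True, False))
        mol.bonds.append(
            BondEdge(
                bond.GetBeginAtomIdx(),
                bond.GetEndAtomIdx(),
                order=order,
                kekule_known=kekule_known,
                provisional_aromatic=provisional or bond.GetIsAromatic(),
            )
        )
    return mol


def _resolve_kekule(mol: MolGraph, sanitized) -> None:
    """Copy alternating single/double orders onto aromatic-written bonds.

    ``sanitized`` is an RDKit molecule parsed from the same source (same atom
    ordering) with full sanitization; kekulization may still fail for
    chemically unkekulizable input, in which case orders stay unresolved and
    valence arithmetic falls back to counting those bonds at 1.5.
    """
    if sanitized is None:
        return
    try:
        Chem.Kekulize(sanitized, clearAromaticFlags=True)
    except Exception:
        return
    for b in mol.bonds:
        if b.kekule_known:
            continue
        rb = sanitized.GetBondBetweenAtoms(b.i, b.j)
        if rb is None:
            continue
        as_double = rb.GetBondTypeAsDouble()
        if as_double in (1.0, 2.0, 3.0):
            b.order = int(as_double)
            b.kekule_known = True


def parse_smiles(line: str) -> MolGraph:
    """Parse one SMILES record line: ``<smiles>[whitespace <record id>]``.

    Explicit hydrogens are preserved as written and aromatic lowercase marks
    are recorded as provisional flags; no aromaticity perception happens
    here.  An empty (or whitespace-only) line raises ``MolParseError`` with
    the message ``"empty line"`` so callers can treat it as a skip signal.
    """
    stripped = line.strip()
    if not stripped:
        raise MolParseError("empty line")
    parts = stripped.split(None, 1)
    smiles = parts[0]
    record_id = parts[1].strip() if len(parts) > 1 else smiles
    rdmol = Chem.MolFromSmiles(smiles, sanitize=False)
    if rdmol is None:
        raise MolParseError(f"malformed SMILES {smiles!r}")
    mol = _from_rdkit(rdmol, record_id, "smiles")
    if any(b.provisional_aromatic and not b.kekule_known for b in mol.bonds):
        _resolve_kekule(mol, Chem.MolFromSmiles(smiles, sanitize=True))
    mol.validate()
    return mol


def read_smiles_file(stream: TextIO | str) -> Iterator[MolGraph]:
    """Yield one :class:`MolGraph` per non-empty line of a SMILES file.

    Lines that fail to parse are yielded as rejected records (with
    ``reject_reason`` set) so corpus bookkeeping can count them.
    """
    if isinstance(stream, str):
        stream = _io.StringIO(stream)
    for ordinal, line in enumerate(stream, start=1):
        if not line.strip():
            continue
        try:
            yield parse_smiles(line)
        except MolParseError as exc:
            yield MolGraph(
                record_id=f"REC{ordinal}",
                source_format="smiles",
                rejected=True,
                reject_reason=str(exc),
            )


def read_sdf(stream: TextIO | str) -> Iterator[MolGraph]:
    """Yield one :class:`MolGraph` per V2000 record of an SDF stream.

    Record ids come from the title line, else ``REC<ordinal>`` (1-based).
    ``M  CHG`` lines are applied.  Records containing pseudo-atoms (``*`` or
    other arbitrarily defined atoms) are yielded with ``rejected`` set, not
    silently dropped.  V3000 records raise ``MolParseError``.
    """
    if isinstance(stream, str):
        stream = _io.StringIO(stream)
    text = stream.read()
    if not text.strip():
        return
    blocks: list[str] = []
    current: list[str] = []
    for line in text.splitlines():
        if line.strip() == "$$$$":
            blocks.append("\n".join(current) + "\n")
            current = []
        else:
            current.append(line)
    if current and any(l.strip() for l in current):
        blocks.append("\n".join(current) + "\n")
    for ordinal, block in enumerate(blocks, start=1):
        lines = block.splitlines()
        if len(lines) < 4:
            raise MolParseError(f"truncated SDF record {ordinal}")
        if "V3000" in lines[3]:
            raise MolParseError(
                f"record {ordinal}: V3000 connection tables are not supported"
            )
        title = lines[0].strip()
        record_id = title if title else f"REC{ordinal}"
        rdmol = Chem.MolFromMolBlock(block, sanitize=False, removeHs=False)
        if rdmol is None:
            raise MolParseError(f"unreadable SDF record {ordinal}")
        mol = _from_rdkit(rdmol, record_id, "sdf")
        if any(b.provisional_aromatic and not b.kekule_known for b in mol.bonds):
            _resolve_kekule(
                mol, Chem.MolFromMolBlock(block, sanitize=True, removeHs=False)
            )
        mol.validate()
        yield mol


def write_fragment_table(census, destination) -> None:
    """Write a census as a deterministic TSV fragment table.

    Columns: ``canonical_smarts, radius, incidence_count, occurrence_count,
    is_singleton``; rows sorted by (radius asc, incidence desc, smarts asc).
    Output is byte-identical for identical censuses regardless of the order
    records were processed in.
    """
    rows = []
    for radius in sorted(census.radii()):
        for smarts, (inc, occ) in census.counts_at(radius).items():
            rows.append((radius, -inc, smarts, inc, occ))
    rows.sort()
    header = "canonical_smarts\tradius\tincidence_count\toccurrence_count\tis_singleton\n"
    with open(destination, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(header)
        for radius, _, smarts, inc, occ in rows:
            fh.write(
                f"{smarts}\t{radius}\t{inc}\t{occ}\t{'true' if inc == 1 else 'false'}\n"
            )


def emit_smiles(mol: MolGraph) -> str:
    """Canonical SMILES of the covalent graph (round-trip convenience)."""
    from .graph import to_rdkit

    return Chem.MolToSmiles(to_rdkit(mol))
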