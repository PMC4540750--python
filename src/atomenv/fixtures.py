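"""Worked example molecules and a seeded random structure generator.

The builtin registry holds the small molecules used throughout the
documentation and test suite — classic demonstration cases for aromaticity
perception (aniline), connectivity typing (trimethylamine vs. promazine),
the all-bonds rule (perhydrobenzimidazole), cross-radius key collisions
(dispiro(2.0.2.4)deca-1,5-diene), implausible-structure filtering
(tetra-tert-butylmethane) and valence screening (both nitro and azide
resonance forms, anchored on a methyl carbon).  PubChem CIDs in comments
are documentation only; nothing is fetched.

:func:`generate` produces random connected heavy-atom graphs under degree
and valence constraints: a random spanning tree guarantees connectivity,
extra ring-closure edges and planted aromatic carbocycles add ring content.
Identical seed and parameters give a byte-identical corpus.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .graph import AtomNode, BondEdge, MolGraph
from .io import parse_smiles

BUILTIN_SMILES: dict[str, str] = {
    "benzene": "c1ccccc1",
    "toluene": "Cc1ccccc1",
    "ethanol": "CCO",
    "ethanol_explicit_h": "[H]C([H])([H])C([H])([H])O[H]",
    "aniline": "Nc1ccccc1",  # CID 6115
    "trimethylamine": "CN(C)C",  # CID 1146
    "promazine": "CN(C)CCCN1c2ccccc2Sc2ccccc21",  # CID 4926
    "perhydrobenzimidazole": "C1CCC2NCNC2C1",  # CID 21866348
    "dispiro_deca_diene": "C1CC2(C=C2)C2(C=C2)CC1",  # CID 143166
    "tetra_tert_butylmethane": "CC(C)(C)C(C(C)(C)C)(C(C)(C)C)C(C)(C)C",
    "furan": "c1ccoc1",
    "pyridine": "c1ccncc1",
    "pyrrole": "c1cc[nH]c1",
    "neopentane": "CC(C)(C)C",
    "propane": "CCC",
    "nitro_pentavalent": "CN(=O)=O",
    "nitro_charge_separated": "C[N+](=O)[O-]",
    "azide_cumulated": "CN=[N+]=[N-]",
    "azide_charge_separated": "C[N-][N+]#N",
    "methane": "C",
    "dioxygen": "O=O",
    "dihydrogen": "[H][H]",
    "hydride": "[H-]",
    "deuterated_methanol": "[2H]OC",
    "ammonium": "[NH4+]",
    "cyclohexane": "C1CCCCC1",
    "cyclopropane": "C1CC1",
    "biphenyl": "c1ccc(-c2ccccc2)cc1",
    "naphthalene": "c1ccc2ccccc2c1",
    "phosphorus_pentachloride": "ClP(Cl)(Cl)(Cl)Cl",
    "pentavalent_carbon": "CC(C)(C)(C)C",
}


def list_builtin() -> list[str]:
    return sorted(BUILTIN_SMILES)


def builtin(name: str) -> MolGraph:
    """Parsed, unpreprocessed MolGraph of a registry molecule."""
    try:
        smiles = BUILTIN_SMILES[name]
    except KeyError:
        raise KeyError(
            f"unknown builtin {name!r}; available: {', '.join(list_builtin())}"
        ) from None
    mol = parse_smiles(f"{smiles} {name}")
    mol.source_format = "builtin"
    return mol


def builtin_corpus(names: list[str] | None = None) -> list[MolGraph]:
    return [builtin(n) for n in (names or list_builtin())]


# default valences used to cap bond orders during generation
_GEN_VALENCE = {6: 4, 7: 3, 8: 2, 16: 2, 9: 1, 17: 1}


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the random structure generator.

    Defaults emulate small drug-like organic molecules: a mostly-carbon
    alphabet with N/O/S heteroatoms, 4-14 heavy atoms, tetravalent degree
    cap, about one extra ring closure per three molecules and aromatic
    six-rings planted in a quarter of them.
    """

    n_molecules: int = 100
    elements: tuple[tuple[int, float], ...] = (
        (6, 0.70),
        (7, 0.12),
        (8, 0.14),
        (16, 0.04),
    )
    size_range: tuple[int, int] = (4, 14)
    max_degree: int = 4
    ring_probability: float = 0.3
    aromatic_ring_probability: float = 0.25
    double_bond_probability: float = 0.15
    triple_bond_probability: float = 0.03
    seed: int = 0


def _spare_valence(mol: MolGraph, idx: int) -> int:
    cap = _GEN_VALENCE[mol.atoms[idx].atomic_number]
    used = sum(b.order for b in mol.covalent_bonds_of(idx))
    return cap - used


def _generate_one(params: GeneratorParams, rng: random.Random, ordinal: int) -> MolGraph:
    lo, hi = params.size_range
    if lo < 1 or hi < lo:
        raise ValueError("size range must be >= 1 and ordered")
    if params.max_degree < 1:
        raise ValueError("max degree must be >= 1")
    size = rng.randint(lo, hi)
    if params.max_degree == 1 and size > 2:
        raise ValueError("max degree 1 cannot connect more than 2 atoms")
    mol = MolGraph(record_id=f"SYN{params.seed}_{ordinal}", source_format="synthetic")
    symbols = [z for z, _ in params.elements]
    weights = [w for _, w in params.elements]

    if (
        params.aromatic_ring_probability > 0
        and size >= 6
        and params.max_degree >= 2
        and rng.random() < params.aromatic_ring_probability
    ):
        # plant a benzene ring in Kekulé form; perception will aromatize it
        for _ in range(6):
            mol.atoms.append(AtomNode(atomic_number=6))
        for k in range(6):
            mol.bonds.append(
                BondEdge(k, (k + 1) % 6, order=2 if k % 2 == 0 else 1)
            )

    while len(mol.atoms) < size:
        z = rng.choices(symbols, weights=weights)[0]
        new_idx = len(mol.atoms)
        if new_idx == 0:
            mol.atoms.append(AtomNode(atomic_number=z))
            continue
        candidates = [
            i
            for i in range(new_idx)
            if mol.covalent_degree(i) < params.max_degree
            and _spare_valence(mol, i) >= 1
        ]
        if not candidates:
            break  # all attachment points saturated; keep the smaller molecule
        anchor = rng.choice(candidates)
        mol.atoms.append(AtomNode(atomic_number=z))
        order = 1
        if _spare_valence(mol, anchor) >= 3 and _GEN_VALENCE[z] >= 3 and (
            rng.random() < params.triple_bond_probability
        ):
            order = 3
        elif _spare_valence(mol, anchor) >= 2 and _GEN_VALENCE[z] >= 2 and (
            rng.random() < params.double_bond_probability
        ):
            order = 2
        mol.bonds.append(BondEdge(anchor, new_idx, order=order))
        if len(mol.atoms) < size:
            # keep at least one open attachment point for the next atom
            while order > 1 and not any(
                mol.covalent_degree(i) < params.max_degree
                and _spare_valence(mol, i) >= 1
                for i in range(len(mol.atoms))
            ):
                order -= 1
                mol.bonds[-1].order = order

    if rng.random() < params.ring_probability and len(mol.atoms) >= 3:
        adjacent = {frozenset(b.endpoints) for b in mol.bonds}
        open_atoms = [
            i
            for i in range(len(mol.atoms))
            if mol.covalent_degree(i) < params.max_degree
            and _spare_valence(mol, i) >= 1
        ]
        pairs = [
            (i, j)
            for k, i in enumerate(open_atoms)
            for j in open_atoms[k + 1 :]
            if frozenset((i, j)) not in adjacent
        ]
        if pairs:
            i, j = rng.choice(pairs)
            mol.bonds.append(BondEdge(i, j, order=1))
    mol.validate()
    return mol


def generate(params: GeneratorParams | None = None) -> list[MolGraph]:
    """Generate a deterministic corpus of random molecular graphs.

    Every generated atom respects its element's default valence (bond-order
    sums never exceed it), so generated corpora pass valence validation
    under the default rule table after preprocessing.
    """
    params = params or GeneratorParams()
    rng = random.Random(params.seed)
    return [
        _generate_one(params, rng, ordinal)
        for ordinal in range(1, params.n_molecules + 1)
    ]


def permute_atoms(mol: MolGraph, seed: int) -> MolGraph:
    """Isomorphic copy with atom indices shuffled by a seeded permutation."""
    rng = random.Random(seed)
    n = len(mol.atoms)
    perm = list(range(n))
    rng.shuffle(perm)  # perm[old] = new
    out = mol.copy()
    new_atoms = [None] * n
    for old, new in enumerate(perm):
        new_atoms[new] = out.atoms[old]
    out.atoms = list(new_atoms)
    for b in out.bonds:
        b.i = perm[b.i]
        b.j = perm[b.j]
    out.bonds.sort(key=lambda b: (min(b.i, b.j), max(b.i, b.j)))
    return out
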