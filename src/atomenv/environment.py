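"""Circular atom environments and their canonical SMARTS keys.

An environment of radius ``r`` around a center atom contains every atom at
shortest-path (topological) distance <= r over covalent bonds, and *all*
covalent bonds between included atoms — not only the bonds of the BFS tree.
Including the non-tree bonds closes rings that fall entirely inside the
environment, which separates ring-closure cases from mere branching.

Fragment identity is the canonical SMARTS string of the labeled environment
graph: atoms labeled with their scheme-dependent SMARTS primitives (computed
in the context of the full molecule), bonds with theirs.  Two environments
receive the same key exactly when their labeled graphs are isomorphic; in
particular an environment extracted at radius 1 around one atom can equal an
environment extracted at radius 2 around another.

Canonicalization is implemented here (iterative neighborhood refinement with
backtracking individualization and lexicographic tie-break) so that key
equality is fully specified, deterministic, and independent of atom input
order.
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass

from .graph import COVALENT, MolGraph
from .typing import (
    FOUR_TYPE,
    Scheme,
    encode_atom_primitive,
    encode_bond_primitive,
    type_atom,
    type_bond,
)


@dataclass
class EnvGraph:
    """An extracted circular environment."""

    center_index: int
    radius: int
    member_atoms: frozenset[int]
    member_bonds: frozenset[int]
    covers_whole: bool


@dataclass(frozen=True)
class FragmentKey:
    """Canonical identity of an environment under a scheme."""

    canonical_smarts: str
    radius: int
    scheme_tag: str


# ---------------------------------------------------------------------------
# center eligibility and extraction


def eligible_centers(mol: MolGraph, r: int, scheme: Scheme) -> list[int]:
    """Atom indices eligible as environment centers at radius ``r``.

    At r = 0 every atom is a center (terminal atoms included).  At r > 0,
    mono- and di-atomic records have no centers at all; otherwise terminal
    atoms (covalent degree 1) are excluded unless the scheme allows them,
    and isolated atoms (degree 0) are always excluded.
    """
    if r < 0:
        raise ValueError("radius must be non-negative")
    indices = range(len(mol.atoms))
    if r == 0:
        return list(indices)
    if len(mol.atoms) <= 2:
        return []
    min_degree = 1 if scheme.allow_terminal_centers else 2
    adj = mol.covalent_adjacency()
    return [i for i in indices if len(adj[i]) >= min_degree]


def extract_environment(
    mol: MolGraph, center: int, r: int, all_bonds: bool = True
) -> EnvGraph:
    """Extract the radius-``r`` environment around ``center``.

    ``all_bonds=False`` gives the BFS-tree-only variant (used to demonstrate
    why the all-bonds rule matters); the default follows the all-bonds rule.
    """
    if r < 0:
        raise ValueError("radius must be non-negative")
    if not 0 <= center < len(mol.atoms):
        raise IndexError(f"center index {center} out of range")
    adj = mol.covalent_adjacency()
    if r > 0 and (len(mol.atoms) <= 2 or not adj[center]):
        raise ValueError(
            f"atom {center} is not an eligible center at radius {r}"
        )
    dist = {center: 0}
    parent_bond: dict[int, int] = {}
    queue = deque([center])
    while queue:
        cur = queue.popleft()
        if dist[cur] == r:
            continue
        for nbr, b_idx in sorted(adj[cur]):
            if nbr not in dist:
                dist[nbr] = dist[cur] + 1
                parent_bond[nbr] = b_idx
                queue.append(nbr)
    members = frozenset(dist)
    if all_bonds:
        bonds = frozenset(
            b_idx
            for b_idx, b in enumerate(mol.bonds)
            if b.bond_class == COVALENT and b.i in members and b.j in members
        )
    else:
        bonds = frozenset(parent_bond.values())
    covers = members == frozenset(mol.component_of(center))
    return EnvGraph(center, r, members, bonds, covers)


# ---------------------------------------------------------------------------
# canonicalization


def atom_primitives(mol: MolGraph, scheme: Scheme) -> list[str]:
    """SMARTS primitive of every atom, computed in full-molecule context."""
    return [
        encode_atom_primitive(type_atom(mol, i, scheme))
        for i in range(len(mol.atoms))
    ]


def bond_primitives(mol: MolGraph, scheme: Scheme) -> list[str | None]:
    """SMARTS primitive of every covalent bond (``None`` for non-covalent)."""
    out: list[str | None] = []
    for b_idx, b in enumerate(mol.bonds):
        if b.bond_class != COVALENT:
            out.append(None)
        else:
            out.append(encode_bond_primitive(type_bond(mol, b_idx, scheme)))
    return out


def _is_aromatic_primitive(label: str) -> bool:
    return len(label) > 1 and label[1].isalpha() and label[1].islower()


def _refine(colors: list[int], adj: list[list[tuple[int, int]]]) -> list[int]:
    """Iterative neighborhood refinement of a coloring (Morgan-style)."""
    n = len(colors)
    n_classes = len(set(colors))
    while True:
        sigs = [
            (colors[i], tuple(sorted((e, colors[j]) for j, e in adj[i])))
            for i in range(n)
        ]
        order = {sig: rank for rank, sig in enumerate(sorted(set(sigs)))}
        colors = [order[sig] for sig in sigs]
        new_n = len(order)
        if new_n == n_classes:
            return colors
        n_classes = new_n


def _canonical_string(
    labels: list[str],
    edges: list[tuple[int, int, str]],
    elide_aromatic: bool,
) -> str:
    """Canonical SMARTS of a small labeled graph.

    ``labels`` are atom primitives (graph nodes 0..n-1), ``edges`` carry the
    bond primitive.  Refinement is seeded by the label strings; remaining
    ties are resolved by branching on every member of the first non-singleton
    color class and keeping the lexicographically smallest emission.
    """
    n = len(labels)
    if n == 1:
        return labels[0]
    label_rank = {lab: k for k, lab in enumerate(sorted(set(labels)))}
    edge_rank = {sym: k for k, sym in enumerate(sorted({e for _, _, e in edges}))}
    adj: list[list[tuple[int, int]]] = [[] for _ in range(n)]
    edge_sym: dict[tuple[int, int], str] = {}
    for u, v, sym in edges:
        adj[u].append((v, edge_rank[sym]))
        adj[v].append((u, edge_rank[sym]))
        edge_sym[(u, v)] = edge_sym[(v, u)] = sym

    best: list[str | None] = [None]

    def search(colors: list[int]) -> None:
        colors = _refine(colors, adj)
        cells: dict[int, list[int]] = {}
        for i, c in enumerate(colors):
            cells.setdefault(c, []).append(i)
        target = None
        for c in sorted(cells):
            if len(cells[c]) > 1:
                target = cells[c]
                break
        if target is None:
            emitted = _emit(labels, adj, edge_sym, colors, elide_aromatic)
            if best[0] is None or emitted < best[0]:
                best[0] = emitted
            return
        for atom in target:
            branched = [c * 2 + 1 for c in colors]
            branched[atom] -= 1
            search(branched)

    search([label_rank[lab] for lab in labels])
    assert best[0] is not None
    return best[0]


def _closure_token(digit: int) -> str:
    return str(digit) if digit < 10 else f"%{digit:02d}"


def _emit(
    labels: list[str],
    adj: list[list[tuple[int, int]]],
    edge_sym: dict[tuple[int, int], str],
    colors: list[int],
    elide_aromatic: bool,
) -> str:
    """Depth-first SMARTS emission for a discrete coloring."""
    n = len(labels)
    rank = colors  # discrete: a permutation of 0..n-1
    root = rank.index(0)

    def bond_token(u: int, v: int) -> str:
        sym = edge_sym[(u, v)]
        if (
            elide_aromatic
            and sym == ":"
            and _is_aromatic_primitive(labels[u])
            and _is_aromatic_primitive(labels[v])
        ):
            return ""
        return sym

    # pass 1: DFS tree (children in rank order) and back edges
    visited_order: dict[int, int] = {}
    children: dict[int, list[int]] = {i: [] for i in range(n)}
    back_edges: list[tuple[int, int]] = []

    def dfs(u: int, parent: int) -> None:
        visited_order[u] = len(visited_order)
        for v, _ in sorted(adj[u], key=lambda t: rank[t[0]]):
            if v == parent:
                continue
            if v in visited_order:
                if visited_order[v] < visited_order[u]:
                    back_edges.append((v, u))
            else:
                children[u].append(v)
                dfs(v, u)

    dfs(root, -1)

    # closure digits in emission (DFS first-appearance) order
    closure_digit: dict[frozenset[int], int] = {}
    closures_at: dict[int, list[tuple[int, int]]] = {i: [] for i in range(n)}
    for early, late in back_edges:
        closures_at[early].append((early, late))
        closures_at[late].append((early, late))

    counter = [0]

    def emit_atom(u: int) -> str:
        token = labels[u]
        for early, late in sorted(
            closures_at[u], key=lambda e: (visited_order[e[0]], visited_order[e[1]])
        ):
            edge = frozenset((early, late))
            if edge not in closure_digit:
                counter[0] += 1
                closure_digit[edge] = counter[0]
            token += bond_token(early, late) + _closure_token(closure_digit[edge])
        kids = sorted(children[u], key=lambda v: visited_order[v])
        parts = [token]
        for k, v in enumerate(kids):
            sub = bond_token(u, v) + emit_atom(v)
            parts.append(f"({sub})" if k < len(kids) - 1 else sub)
        return "".join(parts)

    return emit_atom(root)


def canonical_smarts(
    env: EnvGraph,
    mol: MolGraph,
    scheme: Scheme,
    _atom_prims: list[str] | None = None,
    _bond_prims: list[str | None] | None = None,
) -> FragmentKey:
    """Canonical SMARTS key of an environment.

    Atom and bond primitives are computed in the context of the full
    molecule (counts, degree, valence, aromaticity reflect the whole
    structure, not the clipped fragment).  ``_atom_prims``/``_bond_prims``
    let batch callers reuse per-molecule primitive tables.
    """
    aprims = _atom_prims if _atom_prims is not None else atom_primitives(mol, scheme)
    bprims = _bond_prims if _bond_prims is not None else bond_primitives(mol, scheme)
    local = {a: k for k, a in enumerate(sorted(env.member_atoms))}
    labels = [aprims[a] for a in sorted(env.member_atoms)]
    edges = []
    for b_idx in env.member_bonds:
        b = mol.bonds[b_idx]
        sym = bprims[b_idx]
        assert sym is not None
        edges.append((local[b.i], local[b.j], sym))
    edges.sort()
    smarts = _canonical_string(
        labels, edges, elide_aromatic=scheme.bond_scheme == FOUR_TYPE
    )
    return FragmentKey(smarts, env.radius, scheme.tag)


# ---------------------------------------------------------------------------
# per-record fragmentation


def enumerate_environments(mol: MolGraph, radii: list[int], scheme: Scheme):
    """Yield ``(radius, center, EnvGraph, FragmentKey)`` for every eligible
    center at every requested radius."""
    aprims = atom_primitives(mol, scheme)
    bprims = bond_primitives(mol, scheme)
    for r in radii:
        for center in eligible_centers(mol, r, scheme):
            env = extract_environment(mol, center, r)
            key = canonical_smarts(env, mol, scheme, aprims, bprims)
            yield r, center, env, key


def fragment_record(
    mol: MolGraph, radii: list[int], scheme: Scheme
) -> dict[int, Counter]:
    """Multiset of fragment keys per radius for one record.

    r = 0 keys are bare atom-type primitives; higher radii produce one key
    per eligible center, with multiplicity.
    """
    out: dict[int, Counter] = {r: Counter() for r in radii}
    for r, _center, _env, key in enumerate_environments(mol, radii, scheme):
        out[r][key] += 1
    return out


def augmented_prefilter(mol: MolGraph) -> bool:
    """Corpus pre-filter used with the augmented (element-only) scheme.

    Keeps a record iff it has at most 100 heavy atoms and every heavy atom
    has covalent degree between 1 and 4 (isolated atoms fail).
    """
    heavy = [i for i, a in enumerate(mol.atoms) if a.atomic_number > 1]
    if len(heavy) > 100:
        return False
    return all(1 <= mol.covalent_degree(i) <= 4 for i in heavy)
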