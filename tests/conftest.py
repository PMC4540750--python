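import networkx as nx
import pytest
from networkx.algorithms import isomorphism as nx_iso

from atomenv import Scheme, preprocess
from atomenv.environment import atom_primitives, bond_primitives
from atomenv.fixtures import builtin


@pytest.fixture(scope="session")
def scheme():
    return Scheme.default()


@pytest.fixture(scope="session")
def augmented_scheme():
    return Scheme.augmented()


@pytest.fixture(scope="session")
def prep():
    """Session-cached preprocessing of builtin molecules."""
    cache: dict = {}

    def get(name, aromaticity="general_huckel"):
        key = (name, aromaticity)
        if key not in cache:
            cache[key] = preprocess(builtin(name), aromaticity=aromaticity)
        return cache[key]

    return get


def env_labeled_graph(mol, env, sch, aprims=None, bprims=None):
    """The labeled environment graph, for independent isomorphism checks."""
    aprims = aprims if aprims is not None else atom_primitives(mol, sch)
    bprims = bprims if bprims is not None else bond_primitives(mol, sch)
    g = nx.Graph()
    for a in env.member_atoms:
        g.add_node(a, label=aprims[a])
    for b_idx in env.member_bonds:
        b = mol.bonds[b_idx]
        g.add_edge(b.i, b.j, label=bprims[b_idx])
    return g


def labeled_isomorphic(g1, g2):
    """Exact labeled-graph isomorphism, independent of the canonicalizer."""
    if g1.number_of_nodes() != g2.number_of_nodes():
        return False
    if g1.number_of_edges() != g2.number_of_edges():
        return False
    matcher = nx_iso.GraphMatcher(
        g1,
        g2,
        node_match=nx_iso.categorical_node_match("label", None),
        edge_match=nx_iso.categorical_edge_match("label", None),
    )
    return matcher.is_isomorphic()
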