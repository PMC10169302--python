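"""Shared fixtures and independent brute-force oracles.

The oracles here are deliberately primitive (edge-list DFS, exhaustive
quantifier expansion) so they share no code path with the package's
networkx-backed implementations.
"""

from __future__ import annotations

import random
from itertools import product

import pytest

from ontogap.ontology import Ontology
from ontogap.synthetic import OntologyBuilder, make_vulva_fixture, make_thyroid_fixture
from ontogap.ontology import avp


@pytest.fixture(scope="session")
def vulva() -> Ontology:
    return make_vulva_fixture()


@pytest.fixture(scope="session")
def thyroid() -> Ontology:
    return make_thyroid_fixture()


def vulva_shallow() -> Ontology:
    """The vulval-neoplasm subgraph structure without the level-padding chain.

    Small enough for exhaustive closure materialization.
    """
    b = OntologyBuilder()
    b.concept("root", "SNOMED CT Concept (SNOMED RT+CTV3)")
    b.concept("attr", "Concept model attribute (attribute)", ["root"])
    b.concept("isa", "Is a (attribute)", ["attr"])
    b.concept("fs", "Finding site (attribute)", ["attr"])
    b.concept("body", "Body structure (body structure)", ["root"])
    b.concept("vulva", "Vulval structure (body structure)", ["body"])
    b.concept("bart", "Bartholin's gland structure (body structure)", ["vulva"])
    b.concept("finding", "Clinical finding (finding)", ["root"])
    b.concept("nv", "Neoplasm of vulva (disorder)", ["finding"], fully_defined=True)
    b.add_group("nv", avp("fs", "vulva"))
    b.concept("db", "Disorder of Bartholin's gland (disorder)", ["finding"], fully_defined=True)
    b.add_group("db", avp("fs", "bart"))
    b.concept("bnv", "Benign neoplasm of vulva (disorder)", ["nv"], fully_defined=True)
    b.concept("mtv", "Malignant tumor of vulva (disorder)", ["nv"], fully_defined=True)
    b.concept("bnb", "Benign neoplasm of Bartholin's gland (disorder)", ["bnv", "db"], fully_defined=True)
    b.concept("mnb", "Malignant neoplasm of Bartholin's gland (disorder)", ["mtv", "db"], fully_defined=True)
    return b.build()


# ---------------------------------------------------------------------------
# random structures
# ---------------------------------------------------------------------------


def random_dag_ontology(seed: int, n: int = 60, max_parents: int = 3) -> Ontology:
    """A bare rooted random DAG (no attribute relations) for hierarchy tests."""
    rng = random.Random(seed)
    b = OntologyBuilder()
    b.concept("n0", "Node 0 (finding)")
    for i in range(1, n):
        k = rng.randint(1, min(max_parents, i))
        parents = rng.sample([f"n{j}" for j in range(i)], k)
        b.concept(f"n{i}", f"Node {i} (finding)", parents)
    return b.build()


def shallow_defined_ontology(seed: int, n: int = 30) -> Ontology:
    """Random ontology with depth <= 3 and singleton groups.

    Generalization universes stay small enough for exhaustive closure
    materialization, which the derived-definition oracle requires.
    """
    rng = random.Random(seed)
    b = OntologyBuilder()
    b.concept("root", "Concept root (finding)")
    b.concept("attr", "Concept model attribute (attribute)", ["root"])
    b.concept("isa", "Is a (attribute)", ["attr"])
    b.concept("a0", "Attribute 0 (attribute)", ["attr"])
    shallow = ["root"]  # parents drawn here keep the DAG depth <= 3
    plain = []
    for i in range(n - 4):
        parents = rng.sample(shallow, rng.randint(1, min(2, len(shallow))))
        cid = b.concept(
            f"c{i}", f"Concept {i} (finding)", parents, fully_defined=rng.random() < 0.6
        )
        if plain and rng.random() < 0.5:
            b.add_group(cid, avp("a0", rng.choice(plain)))
        plain.append(cid)
        if len(shallow) < 8:
            shallow.append(cid)
    return b.build()


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def _adj(edges: set[tuple[str, str]]) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for child, parent in edges:
        out.setdefault(child, []).append(parent)
    return out


def _dfs(adj: dict[str, list[str]], start: str) -> set[str]:
    out: set[str] = set()
    stack = [start]
    while stack:
        for nxt in adj.get(stack.pop(), ()):
            if nxt not in out:
                out.add(nxt)
                stack.append(nxt)
    return out


def dfs_up(edges: set[tuple[str, str]], start: str) -> set[str]:
    """All nodes reachable by repeatedly following child→parent edges."""
    return _dfs(_adj(edges), start)


def dfs_down(edges: set[tuple[str, str]], start: str) -> set[str]:
    return _dfs(_adj({(p, c) for c, p in edges}), start)


def brute_nonlattice(o: Ontology, a: str, b: str) -> bool:
    """Literal expansion of the non-lattice pair definition over DFS closures."""
    edges = set(o.graph.edges)
    up = _adj(edges)
    down = _adj({(p, c) for c, p in edges})
    common_desc = (_dfs(down, a) | {a}) & (_dfs(down, b) | {b})
    mcd = {c for c in common_desc if not (_dfs(up, c) & common_desc)}
    if len(mcd) > 1:
        return True
    common_anc = (_dfs(up, a) | {a}) & (_dfs(up, b) | {b})
    mca = {c for c in common_anc if not (_dfs(down, c) & common_anc)}
    return len(mca) > 1


def brute_group_more_general(o, g2, g1) -> bool:
    """Existence of a full assignment of g2 pairs onto ge-related g1 pairs."""
    from ontogap.generality import pair_ge

    if g1 == g2:
        return False
    p2s = list(g2.pairs)
    for assignment in product(list(g1.pairs), repeat=len(p2s)):
        if all(pair_ge(o, p2, p1) for p2, p1 in zip(p2s, assignment)):
            return True
    return False
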