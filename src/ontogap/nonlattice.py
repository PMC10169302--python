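"""Non-lattice pair detection and subgraph extraction.

In a lattice, any two nodes have a unique maximal common descendant and a
unique minimal common ancestor.  A pair of concepts sharing more than one
maximal common descendant or minimal common ancestor is a *non-lattice
pair* — a structural anomaly frequently signalling missing concepts or
missing is-a relations.  A non-lattice subgraph is built from a non-lattice
pair by taking the maximal common descendants, reversely computing their
minimal common ancestors, and aggregating every concept and is-a edge on
paths between them.  Its size is its number of concepts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

from .ontology import Ontology, OntologyError


@dataclass(frozen=True)
class NonLatticeSubgraph:
    seed_pair: tuple[str, str]
    mcds: frozenset[str]
    mcas: frozenset[str]
    concepts: frozenset[str]
    edges: frozenset[tuple[str, str]]

    @property
    def size(self) -> int:
        return len(self.concepts)

    def to_json(self, o: Ontology | None = None) -> str:
        payload = {
            "seed_pair": sorted(self.seed_pair),
            "mcds": sorted(self.mcds),
            "mcas": sorted(self.mcas),
            "concepts": sorted(self.concepts),
            "edges": sorted(map(list, self.edges)),
            "size": self.size,
        }
        if o is not None:
            payload["fsns"] = {c: o.fsn(c) for c in sorted(self.concepts)}
        return json.dumps(payload, sort_keys=True)

    def to_dot(self, o: Ontology | None = None) -> str:
        def label(c: str) -> str:
            return (o.fsn(c) if o is not None else c).replace('"', "'")

        lines = ["digraph nonlattice {", "  rankdir=BT;"]
        for c in sorted(self.concepts):
            shape = "box" if c in self.mcas or c in self.mcds else "ellipse"
            lines.append(f'  "{c}" [label="{label(c)}", shape={shape}];')
        for a, b in sorted(self.edges):
            lines.append(f'  "{a}" -> "{b}";')
        lines.append("}")
        return "\n".join(lines)


def maximal_common_descendants(o: Ontology, a: str, b: str) -> set[str]:
    """Common descendants of ``a`` and ``b`` with no ancestor in the common set.

    Shared subsumees are taken reflexively (a concept subsumes itself), the
    lattice meet semantics: for a parent/child pair the child itself is the
    unique maximal common descendant, so tree-shaped hierarchies never
    produce multiple maxima.
    """
    common = (o.descendants(a) | {a}) & (o.descendants(b) | {b})
    return {c for c in common if not (o.ancestors(c) & common)}


def minimal_common_ancestors(o: Ontology, concepts: Iterable[str]) -> set[str]:
    """Common ancestors of all inputs with no descendant in the common set.

    Reflexive, mirroring :func:`maximal_common_descendants` (lattice join
    semantics).
    """
    concepts = list(concepts)
    if not concepts:
        raise ValueError("minimal_common_ancestors requires a non-empty concept set")
    common = o.ancestors(concepts[0]) | {concepts[0]}
    for c in concepts[1:]:
        common &= o.ancestors(c) | {c}
    return {c for c in common if not (o.descendants(c) & common)}


def is_nonlattice_pair(o: Ontology, a: str, b: str) -> bool:
    """More than one maximal common descendant or minimal common ancestor."""
    if a == b:
        return False
    if len(maximal_common_descendants(o, a, b)) > 1:
        return True
    return len(minimal_common_ancestors(o, [a, b])) > 1


def build_subgraph(o: Ontology, a: str, b: str) -> NonLatticeSubgraph:
    """Extract the non-lattice subgraph generated by the pair ``(a, b)``.

    Requires the pair to share at least two maximal common descendants.
    """
    mcds = maximal_common_descendants(o, a, b)
    if len(mcds) < 2:
        raise OntologyError(
            f"({a!r}, {b!r}) shares {len(mcds)} maximal common descendant(s); "
            "a subgraph requires at least two"
        )
    mcas = minimal_common_ancestors(o, mcds)
    below_mca: set[str] = set(mcas)
    for m in mcas:
        below_mca |= o.descendants(m)
    above_mcd: set[str] = set(mcds)
    for d in mcds:
        above_mcd |= o.ancestors(d)
    members = below_mca & above_mcd  # every member lies on an MCA→MCD path
    edges = {(c, p) for c, p in o.graph.edges(members) if c in members and p in members}
    return NonLatticeSubgraph(
        seed_pair=(a, b) if a <= b else (b, a),
        mcds=frozenset(mcds),
        mcas=frozenset(mcas),
        concepts=frozenset(members),
        edges=frozenset(edges),
    )


def enumerate_subgraphs(
    o: Ontology, max_size: int = 10, inclusive: bool = True
) -> list[NonLatticeSubgraph]:
    """All distinct non-lattice subgraphs up to ``max_size`` concepts.

    Only pairs sharing a common descendant can have multiple maximal common
    descendants, so candidate pairs are collected from each concept's
    ancestor set instead of scanning all O(n²) pairs.  Subgraphs are
    deduplicated by concept set; ``inclusive`` selects ``size <= max_size``
    (default) versus strict ``<``.
    """
    if max_size < 2:
        raise ValueError("max_size must be at least 2")
    pairs: set[tuple[str, str]] = set()
    for c in o.concepts:
        anc = sorted(o.ancestors(c))
        pairs.update(combinations(anc, 2))
    seen: dict[frozenset[str], NonLatticeSubgraph] = {}
    for a, b in sorted(pairs):
        if len(maximal_common_descendants(o, a, b)) < 2:
            continue
        sg = build_subgraph(o, a, b)
        if inclusive and sg.size > max_size:
            continue
        if not inclusive and sg.size >= max_size:
            continue
        seen.setdefault(sg.concepts, sg)
    return sorted(seen.values(), key=lambda s: sorted(s.concepts))
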