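"""Candidate concept pairs within non-lattice subgraphs.

A pair (A, B) is a candidate when both lie in the same non-lattice subgraph,
neither is a direct or indirect subtype of the other, both are fully
defined, and both sit at level >= ``min_level`` (longest-path depth; the
default of 10 keeps very general concepts out).  The same pair arising from
overlapping subgraphs is kept once, with provenance of every contributing
subgraph.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

from .nonlattice import NonLatticeSubgraph
from .ontology import Ontology

DEFAULT_MIN_LEVEL = 10


@dataclass(frozen=True)
class CandidatePair:
    a: str
    b: str
    source_subgraphs: tuple[frozenset[str], ...] = ()

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError("a candidate pair must contain two distinct concepts")
        if self.b < self.a:  # canonical unordered form
            a, b = self.a, self.b
            object.__setattr__(self, "a", b)
            object.__setattr__(self, "b", a)

    @property
    def key(self) -> tuple[str, str]:
        return (self.a, self.b)


def is_candidate(
    o: Ontology,
    sg: NonLatticeSubgraph,
    a: str,
    b: str,
    min_level: int = DEFAULT_MIN_LEVEL,
) -> bool:
    o._check(a)
    o._check(b)
    if a == b:
        return False
    if a not in sg.concepts or b not in sg.concepts:
        return False
    if o.is_subtype(a, b) or o.is_subtype(b, a):
        return False
    if not (o.concepts[a].fully_defined and o.concepts[b].fully_defined):
        return False
    return o.level(a) >= min_level and o.level(b) >= min_level


def generate_candidates(
    o: Ontology,
    subgraphs: Sequence[NonLatticeSubgraph],
    min_level: int = DEFAULT_MIN_LEVEL,
) -> list[CandidatePair]:
    """All qualifying unordered pairs across subgraphs, deduplicated.

    The output is sorted by id pair and independent of subgraph order.
    """
    found: dict[tuple[str, str], list[frozenset[str]]] = {}
    for sg in sorted(subgraphs, key=lambda s: sorted(s.concepts)):
        for a, b in combinations(sorted(sg.concepts), 2):
            if is_candidate(o, sg, a, b, min_level):
                found.setdefault((a, b), []).append(sg.concepts)
    return [
        CandidatePair(a, b, tuple(sources))
        for (a, b), sources in sorted(found.items())
    ]


def candidates_tsv(o: Ontology, candidates: Sequence[CandidatePair]) -> str:
    lines = ["a_id\ta_fsn\tb_id\tb_fsn\tn_subgraphs"]
    for c in candidates:
        lines.append(
            f"{c.a}\t{o.fsn(c.a)}\t{c.b}\t{o.fsn(c.b)}\t{len(c.source_subgraphs)}"
        )
    return "\n".join(lines) + "\n"
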