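"""Proposal pipeline for potential missing concepts.

For every candidate pair the reduced intersection of the two derived logical
definitions becomes the logical definition of a potential missing concept —
a concept that would subsume both members of the pair.  Empty intersections
are dropped; a definition already carried by an existing concept is
suppressed; candidates yielding the same definition are merged with combined
provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

from .candidates import CandidatePair
from .derived import DEFAULT_CEILING, DEFAULT_CHAIN_DEPTH, intersect_derived
from .generality import reduce_definition
from .ontology import AttributeGroup, LogicalDefinition, Ontology


@dataclass(frozen=True)
class PotentialMissingConcept:
    definition: LogicalDefinition
    provenance: tuple[CandidatePair, ...]
    predicted_fsn: str | None = None
    validation: object | None = None  # ValidationResult, attached later

    def with_fsn(self, fsn: str) -> "PotentialMissingConcept":
        return replace(self, predicted_fsn=fsn)


@dataclass
class ProposalLog:
    """Stage counts from one :func:`propose` run."""

    candidates: int = 0
    empty_intersections: int = 0
    suppressed_existing: int = 0
    merged_duplicates: int = 0
    proposals: int = 0


def definition_equals(o: Ontology, d1: LogicalDefinition, d2: LogicalDefinition) -> bool:
    """Order-insensitive equality of reduced forms at both levels."""
    return reduce_definition(o, d1) == reduce_definition(o, d2)


def _definition_key(d: LogicalDefinition) -> tuple:
    return tuple(
        sorted(
            tuple(sorted((p.attribute, p.value) for p in g)) for g in d.groups
        )
    )


def existing_reduced_definitions(o: Ontology) -> set[LogicalDefinition]:
    """Reduced own definitions of every concept (primitive ones included)."""
    out: set[LogicalDefinition] = set()
    for c in o.concepts:
        d = o.own_groups(c)
        if d:
            out.add(reduce_definition(o, d))
    return out


def propose(
    o: Ontology,
    candidates: Sequence[CandidatePair],
    depth: int = DEFAULT_CHAIN_DEPTH,
    ceiling: int = DEFAULT_CEILING,
    log: ProposalLog | None = None,
) -> list[PotentialMissingConcept]:
    """Intersect, reduce, suppress existing definitions, deduplicate.

    The proposal list is sorted by canonical definition and independent of
    candidate order.
    """
    log = log if log is not None else ProposalLog()
    log.candidates = len(candidates)
    existing = existing_reduced_definitions(o)
    merged: dict[tuple, tuple[LogicalDefinition, list[CandidatePair]]] = {}
    for cand in sorted(candidates, key=lambda c: c.key):
        d = intersect_derived(o, cand.a, cand.b, depth=depth, ceiling=ceiling)
        if not d:
            log.empty_intersections += 1
            continue
        if d in existing:
            log.suppressed_existing += 1
            continue
        key = _definition_key(d)
        if key in merged:
            merged[key][1].append(cand)
            log.merged_duplicates += 1
        else:
            merged[key] = (d, [cand])
    proposals = [
        PotentialMissingConcept(definition=d, provenance=tuple(cands))
        for _, (d, cands) in sorted(merged.items())
    ]
    log.proposals = len(proposals)
    return proposals


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


def proposal_to_jsonl(pmc: PotentialMissingConcept) -> str:
    payload = {
        "definition": [
            [
                {"attribute": p.attribute, "value": p.value}
                for p in sorted(g, key=lambda p: (p.attribute, p.value))
            ]
            for g in sorted(
                pmc.definition.groups,
                key=lambda g: sorted((p.attribute, p.value) for p in g),
            )
        ],
        "provenance": [[c.a, c.b] for c in pmc.provenance],
        "predicted_fsn": pmc.predicted_fsn,
    }
    return json.dumps(payload, sort_keys=True)


def render_definition(o: Ontology, d: LogicalDefinition) -> str:
    """Human-readable rendering, one numbered group per line."""
    lines = []
    groups = sorted(
        d.groups, key=lambda g: sorted((p.attribute, p.value) for p in g)
    )
    for i, g in enumerate(groups):
        pairs = ", ".join(
            f'({o.concepts[p.attribute].name}, "{o.fsn(p.value)}")'
            for p in sorted(g, key=lambda p: (p.attribute, p.value))
        )
        lines.append(f"{i}\t{{{pairs}}}")
    return "\n".join(lines)
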