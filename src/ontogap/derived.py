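"""Derived logical definitions and their intersection.

A concept's *derived* logical definition aggregates its own attribute groups
with every group that is more general than one of them.  Because a group with
fewer, more general pairs is itself more general, this closure is the family
of all non-empty groups drawn from the generalizations of a concept's own
pairs — far too large to materialize at terminology scale.

Two computations are therefore provided:

* :func:`derived_groups` materializes the closure for *small* ontologies
  (bounded universe) and serves as the exhaustive oracle;
* :func:`intersect_derived` computes the reduced intersection of two derived
  definitions directly, as the pairwise minimal common generalizations of the
  two concepts' own groups — the least-common-generalization route.  The
  resulting definition subsumes both input concepts: it is the definition a
  missing shared parent would have.

A minimal common generalization of two pairs may genuinely be a *set* of
pairs (several incomparable minimal common ancestors of the values — exactly
the non-lattice situation); all minima are kept in one group.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .generality import group_ge, reduce_definition
from .ontology import (
    AttributeGroup,
    AttributeValuePair,
    LogicalDefinition,
    Ontology,
    OntologyError,
    avp,
)

#: default cap on condition-4 (property-chain) rewrite iterations
DEFAULT_CHAIN_DEPTH = 3

#: default generality ceiling: result groups whose every value sits within
#: this many levels of the root are considered vacuous and dropped
DEFAULT_CEILING = 2


class ClosureTooLarge(OntologyError):
    """Raised when materializing a derived definition would explode.

    Use :func:`intersect_derived`, which never materializes the closure.
    """


@dataclass(frozen=True)
class DerivedDefinition:
    concept: str
    groups: frozenset[AttributeGroup]


def generalize_pair(o: Ontology, p: AttributeValuePair) -> set[AttributeValuePair]:
    """All pairs strictly more general than ``p`` obtainable by one rewrite.

    One rewrite replaces the value and/or attribute by any of its ancestors
    (conditions 1-3, which is-a transitivity makes single-step complete), or
    applies one property chain (condition 4).  Chains may compose only
    through repeated application; see :func:`pair_generalizations`.
    """
    out: set[AttributeValuePair] = set()
    attr_anc = o.ancestors(p.attribute) | {p.attribute}
    val_anc = o.ancestors(p.value) | {p.value}
    for ra in attr_anc:
        for va in val_anc:
            out.add(avp(ra, va))
    value_def = o.own_groups(p.value)
    for chain in o.property_chains:
        if p.attribute == chain.first or o.is_subtype(p.attribute, chain.first):
            for grp in value_def:
                for q in grp:
                    if q.attribute == chain.second:
                        out.add(avp(chain.implied, q.value))
    out.discard(p)
    return out


def pair_generalizations(
    o: Ontology, p: AttributeValuePair, depth: int = DEFAULT_CHAIN_DEPTH
) -> frozenset[AttributeValuePair]:
    """Closure of :func:`generalize_pair` under at most ``depth`` iterations."""
    cache: dict = o.__dict__.setdefault("_gen_cache", {})
    key = (p, depth)
    if key in cache:
        return cache[key]
    seen: set[AttributeValuePair] = set()
    frontier = {p}
    for _ in range(max(depth, 1)):
        new: set[AttributeValuePair] = set()
        for q in frontier:
            new |= generalize_pair(o, q)
        new -= seen
        new.discard(p)
        if not new:
            break
        seen |= new
        frontier = new
    result = frozenset(seen)
    cache[key] = result
    return result


def _group_universe(
    o: Ontology, g: AttributeGroup, depth: int
) -> frozenset[AttributeValuePair]:
    """Pairs same-as-or-more-general than some pair of ``g``."""
    out: set[AttributeValuePair] = set()
    for p in g:
        out.add(p)
        out |= pair_generalizations(o, p, depth)
    return frozenset(out)


def derived_groups(
    o: Ontology,
    c: str,
    bound: int = DEFAULT_CHAIN_DEPTH,
    max_universe: int = 14,
) -> DerivedDefinition:
    """Materialize the derived logical definition of ``c`` (oracle only).

    For each own group, every non-empty subset of the group's generalization
    universe is a group of the derived definition.  Raises
    :class:`ClosureTooLarge` when a universe exceeds ``max_universe`` pairs.
    """
    own = o.own_groups(c)
    all_groups: set[AttributeGroup] = set(own.groups)
    for g in own:
        universe = sorted(
            _group_universe(o, g, bound), key=lambda p: (p.attribute, p.value)
        )
        if len(universe) > max_universe:
            raise ClosureTooLarge(
                f"generalization universe of a group of {c!r} has {len(universe)} pairs "
                f"(limit {max_universe}); use intersect_derived instead"
            )
        for k in range(1, len(universe) + 1):
            for subset in combinations(universe, k):
                all_groups.add(AttributeGroup(frozenset(subset)))
    return DerivedDefinition(c, frozenset(all_groups))


def _minimal_pairs(
    o: Ontology, pairs: frozenset[AttributeValuePair], depth: int
) -> frozenset[AttributeValuePair]:
    """Most specific elements of ``pairs`` under the generalization order."""
    gens = {p: pair_generalizations(o, p, depth) for p in pairs}
    minimal = {
        m
        for m in pairs
        if not any(q != m and m in gens[q] and q not in gens[m] for q in pairs)
    }
    if not minimal and pairs:
        minimal = {min(pairs, key=lambda p: (p.attribute, p.value))}
    return frozenset(minimal)


def _vacuous(o: Ontology, g: AttributeGroup, ceiling: int) -> bool:
    return all(o.level(p.value) <= ceiling for p in g)


def intersect_derived(
    o: Ontology,
    a: str,
    b: str,
    depth: int = DEFAULT_CHAIN_DEPTH,
    ceiling: int = DEFAULT_CEILING,
) -> LogicalDefinition:
    """Reduced intersection of the derived logical definitions of ``a``, ``b``.

    For every pair of own groups (g_a, g_b) the common generalization pairs
    are intersected and their minimal (most specific) elements form one
    candidate group; the candidate set is then reduced.  On small ontologies
    this equals materializing both closures, intersecting and reducing.

    Groups whose every value lies within ``ceiling`` levels of the root are
    dropped as vacuous (a shared ancestry near the root carries no usable
    definition); the result may therefore be empty, which is reported as an
    empty :class:`LogicalDefinition`.
    """
    o._check(a)
    o._check(b)
    own_a = o.own_groups(a)
    own_b = o.own_groups(b)
    results: set[AttributeGroup] = set()
    universes_b = {gb: _group_universe(o, gb, depth) for gb in own_b}
    for ga in own_a:
        ua = _group_universe(o, ga, depth)
        for gb in own_b:
            common = ua & universes_b[gb]
            if not common:
                continue
            minimal = _minimal_pairs(o, common, depth)
            grp = AttributeGroup(minimal)
            if not _vacuous(o, grp, ceiling):
                results.add(grp)
    return reduce_definition(o, LogicalDefinition(frozenset(results)))


def intersection_oracle(
    o: Ontology,
    a: str,
    b: str,
    depth: int = DEFAULT_CHAIN_DEPTH,
    ceiling: int = DEFAULT_CEILING,
    max_universe: int = 14,
) -> LogicalDefinition:
    """Closure-intersection-then-reduce route (exhaustive; small inputs only)."""
    da = derived_groups(o, a, depth, max_universe)
    db = derived_groups(o, b, depth, max_universe)
    common = {g for g in da.groups & db.groups if not _vacuous(o, g, ceiling)}
    return reduce_definition(o, LogicalDefinition(frozenset(common)))


def is_ge_some_own_group(o: Ontology, g: AttributeGroup, c: str) -> bool:
    """Does ``g`` subsume (same-as-or-more-general than) an own group of ``c``?"""
    return any(group_ge(o, g, own) for own in o.own_groups(c))
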