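"""Core data model for EL-style terminologies such as SNOMED CT.

A concept is computationally defined by a *logical definition*: a set of
attribute groups, each a set of (attribute, value) pairs whose attribute and
value are themselves concept identifiers.  Following the grouping convention
used throughout this package, every is-a parent contributes its own singleton
group ``{(is-a, parent)}`` in addition to the concept's defining attribute
groups, so the is-a relation is modelled as an ordinary attribute identifier
and generality conditions apply to it uniformly.

The is-a hierarchy is a rooted DAG held in a :class:`networkx.DiGraph` with
edges pointing child → parent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx

#: SNOMED CT identifier of the "Is a" attribute; fixture ontologies may use
#: any identifier via :attr:`Ontology.is_a`.
IS_A = "116680003"


class OntologyError(Exception):
    """Base error for ontology construction and queries."""


class LoadError(OntologyError):
    """Raised when an ontology source cannot be read or fails validation."""


class CycleError(LoadError):
    """Raised when the is-a graph contains a cycle.

    ``cycle`` holds one offending concept-id cycle.
    """

    def __init__(self, cycle: Sequence[str]):
        self.cycle = list(cycle)
        super().__init__(f"is-a graph contains a cycle: {' -> '.join(self.cycle)}")


class UnknownConceptError(OntologyError, KeyError):
    def __init__(self, concept_id: str):
        self.concept_id = concept_id
        super().__init__(f"unknown concept id: {concept_id!r}")


@dataclass(frozen=True)
class AttributeValuePair:
    """An (attribute, value) pair; both sides are concept ids."""

    attribute: str
    value: str


@dataclass(frozen=True)
class AttributeGroup:
    """A non-empty set of attribute-value pairs that jointly apply."""

    pairs: frozenset[AttributeValuePair]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("an attribute group must contain at least one pair")

    def __iter__(self) -> Iterator[AttributeValuePair]:
        return iter(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class LogicalDefinition:
    """A set of attribute groups.  May be empty only as an intersection result."""

    groups: frozenset[AttributeGroup]

    def __iter__(self) -> Iterator[AttributeGroup]:
        return iter(self.groups)

    def __len__(self) -> int:
        return len(self.groups)

    def __bool__(self) -> bool:
        return bool(self.groups)


@dataclass(frozen=True)
class PropertyChain:
    """A property-chain axiom ``first ∘ second ⊑ implied``.

    E.g. Causative agent ∘ Is modification of ⊑ Causative agent.
    """

    first: str
    second: str
    implied: str


def avp(attribute: str, value: str) -> AttributeValuePair:
    return AttributeValuePair(attribute, value)


def group(*pairs: AttributeValuePair) -> AttributeGroup:
    return AttributeGroup(frozenset(pairs))


def definition(*groups_: AttributeGroup) -> LogicalDefinition:
    return LogicalDefinition(frozenset(groups_))


_TAG_OPEN = " ("


def split_semantic_tag(fsn: str) -> tuple[str, str | None]:
    """Split a fully specified name into (base name, semantic tag).

    The semantic tag is the single trailing parenthesized token, e.g.
    ``"Neoplasm of vulva (disorder)" -> ("Neoplasm of vulva", "disorder")``.
    """
    s = fsn.rstrip()
    if s.endswith(")"):
        i = s.rfind("(")
        if i > 0:
            tag = s[i + 1 : -1]
            if tag and "(" not in tag:
                return s[:i].rstrip(), tag
    return s, None


@dataclass
class Concept:
    id: str
    fsn: str
    preferred_term: str = ""
    synonyms: tuple[str, ...] = ()
    fully_defined: bool = False
    active: bool = True

    def __post_init__(self) -> None:
        if not self.fsn:
            raise ValueError(f"concept {self.id!r} has an empty FSN")
        if not self.preferred_term:
            self.preferred_term = split_semantic_tag(self.fsn)[0]

    @property
    def semantic_tag(self) -> str | None:
        return split_semantic_tag(self.fsn)[1]

    @property
    def name(self) -> str:
        """FSN without the semantic tag."""
        return split_semantic_tag(self.fsn)[0]


class Ontology:
    """An is-a DAG plus grouped attribute relationships and property chains.

    Parameters
    ----------
    concepts:
        Mapping of concept id to :class:`Concept`.  Only active concepts
        should be supplied; loaders filter inactive components.
    isa_edges:
        ``(child, parent)`` pairs over concept ids, including edges among
        attribute concepts (the attribute hierarchy is part of the same DAG,
        exactly as in the source terminology).
    attribute_rels:
        Defining non-is-a attribute groups per concept id.
    property_chains:
        Property-chain axioms over attribute concept ids.
    is_a:
        Concept id playing the role of the is-a attribute.
    """

    def __init__(
        self,
        concepts: Mapping[str, Concept],
        isa_edges: Iterable[tuple[str, str]],
        attribute_rels: Mapping[str, Sequence[AttributeGroup]] | None = None,
        property_chains: Sequence[PropertyChain] = (),
        is_a: str = IS_A,
        validate: bool = True,
    ):
        self.concepts: dict[str, Concept] = dict(concepts)
        self.attribute_rels: dict[str, tuple[AttributeGroup, ...]] = {
            c: tuple(gs) for c, gs in (attribute_rels or {}).items() if gs
        }
        self.property_chains: tuple[PropertyChain, ...] = tuple(property_chains)
        self.is_a = is_a
        g = nx.DiGraph()
        g.add_nodes_from(self.concepts)
        g.add_edges_from(isa_edges)  # child -> parent
        self.graph = g
        self._levels: dict[str, int] | None = None
        if validate:
            self.validate()

    # -- construction & validation ------------------------------------------

    def validate(self) -> None:
        g = self.graph
        dangling = [n for n in g.nodes if n not in self.concepts]
        if dangling:
            raise LoadError(f"is-a edges reference unknown concept ids: {sorted(dangling)[:10]}")
        if not self.concepts:
            raise LoadError("ontology contains no concepts")
        if not nx.is_directed_acyclic_graph(g):
            cycle = [a for a, _ in nx.find_cycle(g)]
            raise CycleError(cycle + cycle[:1])
        roots = [n for n in g.nodes if g.out_degree(n) == 0]
        if len(roots) != 1:
            raise LoadError(
                f"expected exactly one root concept (no is-a parent), found {len(roots)}: "
                f"{sorted(roots)[:10]}"
            )
        bad_rows: list[str] = []
        for cid, groups_ in self.attribute_rels.items():
            if cid not in self.concepts:
                bad_rows.append(f"attribute group owner {cid!r}")
            for grp in groups_:
                for p in grp:
                    if p.attribute not in self.concepts:
                        bad_rows.append(f"attribute {p.attribute!r} of {cid!r}")
                    if p.value not in self.concepts:
                        bad_rows.append(f"value {p.value!r} of {cid!r}")
        for ch in self.property_chains:
            for a in (ch.first, ch.second, ch.implied):
                if a not in self.concepts:
                    bad_rows.append(f"property-chain attribute {a!r}")
        if bad_rows:
            raise LoadError(f"dangling id references: {bad_rows[:10]}")

    @cached_property
    def root(self) -> str:
        return next(n for n in self.graph.nodes if self.graph.out_degree(n) == 0)

    # -- hierarchy queries ---------------------------------------------------

    def _check(self, c: str) -> None:
        if c not in self.concepts:
            raise UnknownConceptError(c)

    def parents(self, c: str) -> set[str]:
        self._check(c)
        return set(self.graph.successors(c))

    def children(self, c: str) -> set[str]:
        self._check(c)
        return set(self.graph.predecessors(c))

    def ancestors(self, c: str) -> set[str]:
        """Transitive, non-reflexive is-a closure above ``c``."""
        self._check(c)
        return nx.descendants(self.graph, c)

    def descendants(self, c: str) -> set[str]:
        """Transitive, non-reflexive is-a closure below ``c``."""
        self._check(c)
        return nx.ancestors(self.graph, c)

    def is_subtype(self, a: str, b: str) -> bool:
        """True iff ``a`` is a strict subtype of ``b`` (irreflexive).

        Call sites that need "same as or more general" test equality
        explicitly.
        """
        self._check(a)
        self._check(b)
        return b in self.ancestors(a)

    def level(self, c: str) -> int:
        """Number of hops in the *longest* path from the root to ``c``."""
        self._check(c)
        if self._levels is None:
            levels: dict[str, int] = {}
            # topological order of the child->parent graph reversed puts the
            # root first, so parents are always resolved before children
            for node in reversed(list(nx.topological_sort(self.graph))):
                ps = list(self.graph.successors(node))
                if not ps:
                    levels[node] = 0
                else:
                    levels[node] = 1 + max(levels[p] for p in ps)
            self._levels = levels
        if c not in self._levels:
            raise OntologyError(f"concept {c!r} is not reachable from the root")
        return self._levels[c]

    # -- logical definitions -------------------------------------------------

    def own_groups(self, c: str) -> LogicalDefinition:
        """The concept's own logical definition under the grouping convention.

        One singleton ``{(is-a, parent)}`` group per is-a parent plus each
        defining attribute group.  The root yields only its attribute groups
        (normally none), i.e. a possibly empty definition.
        """
        self._check(c)
        groups_: set[AttributeGroup] = {
            group(avp(self.is_a, p)) for p in self.graph.successors(c)
        }
        groups_.update(self.attribute_rels.get(c, ()))
        return LogicalDefinition(frozenset(groups_))

    @cached_property
    def attribute_ids(self) -> set[str]:
        """Concept ids used as attributes (incl. is-a) and their ancestors."""
        used = {self.is_a}
        for groups_ in self.attribute_rels.values():
            for grp in groups_:
                used.update(p.attribute for p in grp)
        for ch in self.property_chains:
            used.update((ch.first, ch.second, ch.implied))
        closed = set(used)
        for a in used:
            if a in self.concepts:
                closed |= self.ancestors(a)
        return closed

    @property
    def attribute_hierarchy(self) -> set[tuple[str, str]]:
        """Is-a edges restricted to attribute concepts (a filtered view)."""
        attrs = self.attribute_ids
        return {(a, b) for a, b in self.graph.edges if a in attrs and b in attrs}

    @property
    def isa_edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges)

    def fully_defined_ids(self) -> list[str]:
        return [c for c, con in self.concepts.items() if con.fully_defined]

    def fsn(self, c: str) -> str:
        self._check(c)
        return self.concepts[c].fsn

    def __contains__(self, c: str) -> bool:
        return c in self.concepts

    def __len__(self) -> int:
        return len(self.concepts)

    def __repr__(self) -> str:
        return f"<Ontology: {len(self.concepts)} concepts, {self.graph.number_of_edges()} is-a edges>"
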