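"""Fixture and random-ontology generation with planted, recoverable missing
concepts, so every pipeline stage is testable without licensed release data.

``make_vulva_fixture`` and ``make_thyroid_fixture`` encode the two worked
examples used throughout the package: a size-6 non-lattice subgraph around
vulval neoplasms and Bartholin's gland, and a thyroid neoplasm whose
definition shows the grouping convention (two is-a parents in singleton
groups plus one two-pair attribute group).

``random_ontology`` produces seeded DAG terminologies; ``plant_missing_
concept`` grafts a recoverable missing concept into any ontology by
construction, guaranteeing that the proposal pipeline can find it (pruned
variant) and suppress it (full variant).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .candidates import CandidatePair
from .derived import DEFAULT_CEILING, DEFAULT_CHAIN_DEPTH, intersect_derived
from .generality import reduce_definition
from .missing import existing_reduced_definitions
from .ontology import (
    AttributeGroup,
    Concept,
    LogicalDefinition,
    Ontology,
    OntologyError,
    PropertyChain,
    avp,
    group,
)


class PlantingError(OntologyError):
    """No recoverable concept could be planted; retry with another seed."""


class OntologyBuilder:
    """Incremental assembly of an :class:`Ontology`."""

    def __init__(self, is_a: str = "isa"):
        self.is_a = is_a
        self.concepts: dict[str, Concept] = {}
        self.isa_edges: set[tuple[str, str]] = set()
        self.attribute_rels: dict[str, list[AttributeGroup]] = {}
        self.chains: list[PropertyChain] = []

    def concept(
        self,
        cid: str,
        fsn: str,
        parents: tuple[str, ...] | list[str] = (),
        fully_defined: bool = False,
        preferred_term: str = "",
        synonyms: tuple[str, ...] = (),
    ) -> str:
        self.concepts[cid] = Concept(
            id=cid,
            fsn=fsn,
            preferred_term=preferred_term,
            synonyms=synonyms,
            fully_defined=fully_defined,
        )
        for p in parents:
            self.isa_edges.add((cid, p))
        return cid

    def add_group(self, cid: str, *pairs) -> None:
        self.attribute_rels.setdefault(cid, []).append(group(*pairs))

    def chain(self, first: str, second: str, implied: str) -> None:
        self.chains.append(PropertyChain(first, second, implied))

    def build(self) -> Ontology:
        return Ontology(
            dict(self.concepts),
            set(self.isa_edges),
            {c: list(g) for c, g in self.attribute_rels.items()},
            list(self.chains),
            is_a=self.is_a,
        )


def _scaffold(b: OntologyBuilder) -> None:
    """Root, attribute branch and the is-a attribute concept."""
    b.concept("root", "SNOMED CT Concept (SNOMED RT+CTV3)")
    b.concept("attr", "Concept model attribute (attribute)", ["root"])
    b.concept("isa", "Is a (attribute)", ["attr"])


def make_vulva_fixture() -> Ontology:
    """The size-6 non-lattice subgraph around vulval neoplasms.

    The pair ("Neoplasm of vulva", "Disorder of Bartholin's gland") shares
    two maximal common descendants — the benign and the malignant Bartholin's
    gland neoplasms — reached through the two intermediates "Benign neoplasm
    of vulva" and "Malignant tumor of vulva".  A padding chain places the
    pair at level 10 and both members carry defining attribute groups, so
    the pair qualifies as a candidate at the default thresholds.
    """
    b = OntologyBuilder()
    _scaffold(b)
    b.concept("finding_site", "Finding site (attribute)", ["attr"])
    b.concept("assoc_morph", "Associated morphology (attribute)", ["attr"])
    b.concept("body", "Body structure (body structure)", ["root"])
    b.concept("pelvis", "Pelvic structure (body structure)", ["body"])
    b.concept("vulva_struct", "Vulval structure (body structure)", ["pelvis"])
    b.concept("bartholin_struct", "Bartholin's gland structure (body structure)", ["vulva_struct"])
    b.concept("morph", "Morphologically abnormal structure (morphologic abnormality)", ["root"])
    b.concept("neoplasm_m", "Neoplasm (morphologic abnormality)", ["morph"])
    b.concept("benign_m", "Benign neoplasm (morphologic abnormality)", ["neoplasm_m"])
    b.concept("malignant_m", "Malignant neoplasm (morphologic abnormality)", ["neoplasm_m"])
    # padding chain: levels 1..9
    prev = "root"
    for i, (cid, fsn) in enumerate(
        [("clinical_finding", "Clinical finding (finding)"), ("disease", "Disease (disorder)")]
    ):
        b.concept(cid, fsn, [prev])
        prev = cid
    for i in range(3, 10):
        prev = b.concept(f"pad{i}", f"Disorder of pelvic region, stage {i} (disorder)", [prev])
    # the non-lattice subgraph proper, pair at level 10
    b.concept(
        "neoplasm_vulva", "Neoplasm of vulva (disorder)", [prev], fully_defined=True
    )
    b.add_group("neoplasm_vulva", avp("assoc_morph", "neoplasm_m"), avp("finding_site", "vulva_struct"))
    b.concept(
        "disorder_bartholin", "Disorder of Bartholin's gland (disorder)", [prev], fully_defined=True
    )
    b.add_group("disorder_bartholin", avp("finding_site", "bartholin_struct"))
    b.concept(
        "benign_neoplasm_vulva", "Benign neoplasm of vulva (disorder)", ["neoplasm_vulva"], fully_defined=True
    )
    b.add_group("benign_neoplasm_vulva", avp("assoc_morph", "benign_m"), avp("finding_site", "vulva_struct"))
    b.concept(
        "malignant_tumor_vulva", "Malignant tumor of vulva (disorder)", ["neoplasm_vulva"], fully_defined=True
    )
    b.add_group("malignant_tumor_vulva", avp("assoc_morph", "malignant_m"), avp("finding_site", "vulva_struct"))
    b.concept(
        "benign_neoplasm_bartholin",
        "Benign neoplasm of Bartholin's gland (disorder)",
        ["benign_neoplasm_vulva", "disorder_bartholin"],
        fully_defined=True,
    )
    b.add_group(
        "benign_neoplasm_bartholin", avp("assoc_morph", "benign_m"), avp("finding_site", "bartholin_struct")
    )
    b.concept(
        "malignant_neoplasm_bartholin",
        "Malignant neoplasm of greater vestibular (Bartholin's) gland (disorder)",
        ["malignant_tumor_vulva", "disorder_bartholin"],
        fully_defined=True,
    )
    b.add_group(
        "malignant_neoplasm_bartholin",
        avp("assoc_morph", "malignant_m"),
        avp("finding_site", "bartholin_struct"),
    )
    return b.build()

#: the vulval-neoplasm seed pair, exported for examples and tests
VULVA_PAIR = ("neoplasm_vulva", "disorder_bartholin")


def make_thyroid_fixture() -> Ontology:
    """The thyroid concept whose definition has exactly three groups:
    two singleton is-a groups plus one {morphology, finding-site} group.
    """
    b = OntologyBuilder()
    _scaffold(b)
    b.concept("finding_site", "Finding site (attribute)", ["attr"])
    b.concept("assoc_morph", "Associated morphology (attribute)", ["attr"])
    b.concept("body", "Body structure (body structure)", ["root"])
    b.concept("thyroid_struct", "Thyroid structure (body structure)", ["body"])
    b.concept("morph", "Morphologically abnormal structure (morphologic abnormality)", ["root"])
    b.concept(
        "men_category",
        "Malignant epithelial neoplasm - category (morphologic abnormality)",
        ["morph"],
    )
    b.concept("clinical_finding", "Clinical finding (finding)", ["root"])
    b.concept("neoplasm", "Neoplastic disease (disorder)", ["clinical_finding"])
    b.concept(
        "malignant_tumor_thyroid", "Malignant tumor of thyroid gland (disorder)", ["neoplasm"]
    )
    b.concept(
        "malignant_epithelial_neoplasm", "Malignant epithelial neoplasm (disorder)", ["neoplasm"]
    )
    b.concept(
        "men_thyroid",
        "Malignant epithelial neoplasm of thyroid (disorder)",
        ["malignant_tumor_thyroid", "malignant_epithelial_neoplasm"],
        fully_defined=True,
    )
    b.add_group("men_thyroid", avp("assoc_morph", "men_category"), avp("finding_site", "thyroid_struct"))
    return b.build()


def random_ontology(
    n_concepts: int,
    seed: int,
    n_attributes: int = 3,
    max_parents: int = 2,
    p_fully_defined: float = 0.5,
    p_group: float = 0.6,
    n_chains: int = 0,
) -> Ontology:
    """A seeded random terminology: rooted is-a DAG, a small attribute
    hierarchy, grouped attribute relationships, and optional property chains.

    Deterministic for a given argument tuple.
    """
    if n_concepts < 5:
        raise ValueError("need at least 5 concepts")
    if n_attributes < 1:
        raise ValueError("need at least 1 attribute")
    rng = random.Random(seed)
    b = OntologyBuilder()
    _scaffold(b)
    n_attributes = min(n_attributes, max(1, n_concepts - 4))
    attrs = []
    for j in range(n_attributes):
        # occasionally nest attributes so attribute-hierarchy generality fires
        parent = "attr" if not attrs or rng.random() < 0.7 else rng.choice(attrs)
        attrs.append(b.concept(f"a{j}", f"Attribute {j} (attribute)", [parent]))
    tags = ["finding", "disorder", "body structure", "procedure"]
    plain: list[str] = ["root"]
    n_plain = n_concepts - len(b.concepts)
    for i in range(1, n_plain + 1):
        k = 1 if len(plain) < 2 else rng.randint(1, max_parents)
        parents = rng.sample(plain, min(k, len(plain)))
        cid = b.concept(
            f"c{i}",
            f"Concept {i} ({rng.choice(tags)})",
            parents,
            fully_defined=rng.random() < p_fully_defined,
        )
        if rng.random() < p_group and len(plain) > 1:
            for _ in range(rng.randint(1, 2)):
                pairs = {
                    avp(rng.choice(attrs), rng.choice(plain[1:]))
                    for _ in range(rng.randint(1, 2))
                }
                b.attribute_rels.setdefault(cid, []).append(AttributeGroup(frozenset(pairs)))
        plain.append(cid)
    for _ in range(n_chains):
        first, second, implied = (rng.choice(attrs) for _ in range(3))
        b.chain(first, second, implied)
    return b.build()


@dataclass
class PlantResult:
    """Outcome of planting: the ontology without the concept, the same
    ontology with it, and the ground truth for recovery tests."""

    pruned: Ontology
    full: Ontology
    truth: list[tuple[CandidatePair, LogicalDefinition]] = field(default_factory=list)


def plant_missing_concept(
    o: Ontology,
    seed: int,
    min_level: int = 10,
    plants: int = 1,
    depth: int = DEFAULT_CHAIN_DEPTH,
    ceiling: int = DEFAULT_CEILING,
) -> PlantResult:
    """Graft recoverable missing concepts into ``o`` by construction.

    For each plant a fresh unrelated fully defined pair (A, B) is created
    under a shared anchor deep enough to clear ``min_level``, with attribute
    values that share a unique common parent; two primitive common children
    make (A, B) a non-lattice pair.  The pair's reduced intersection D is
    computed on the pruned ontology, checked to be representable and not
    already carried by any existing concept (identifiability), and the full
    ontology adds concept M with exactly the definition D.  Proposing on the
    pruned ontology therefore recovers every truth definition; proposing on
    the full one suppresses them all.
    """
    rng = random.Random(seed)
    b = OntologyBuilder(is_a=o.is_a)
    b.concepts = dict(o.concepts)
    b.isa_edges = set(o.graph.edges)
    b.attribute_rels = {c: list(g) for c, g in o.attribute_rels.items()}
    b.chains = list(o.property_chains)
    root = o.root

    # deep shared anchor for the candidate pair
    anchors = [
        c
        for c in o.concepts
        if c not in o.attribute_ids and o.level(c) >= min_level - 1
    ]
    if anchors:
        anchor = rng.choice(sorted(anchors))
    else:
        prev = root
        base_level = 0
        for i in range(min_level - 1):
            prev = b.concept(f"plant_pad{i}", f"Planted padding {i} (finding)", [prev])
        anchor = prev

    # value branch clear of the generality ceiling
    vprev = root
    for i in range(ceiling + 1):
        vprev = b.concept(f"plant_vpad{i}", f"Planted value region {i} (body structure)", [vprev])

    truth: list[tuple[CandidatePair, LogicalDefinition]] = []
    planted_ms: list[tuple[str, LogicalDefinition]] = []
    for k in range(plants):
        r = b.concept(f"plant_attr{k}", f"Planted attribute {k} (attribute)", ["attr" if "attr" in b.concepts else root])
        v_shared = b.concept(f"plant_vs{k}", f"Planted site {k} (body structure)", [vprev])
        v1 = b.concept(f"plant_v1_{k}", f"Planted site {k}a (body structure)", [v_shared])
        v2 = b.concept(f"plant_v2_{k}", f"Planted site {k}b (body structure)", [v_shared])
        a = b.concept(f"plant_A{k}", f"Planted finding {k}A (disorder)", [anchor], fully_defined=True)
        b.add_group(a, avp(r, v1))
        bb = b.concept(f"plant_B{k}", f"Planted finding {k}B (disorder)", [anchor], fully_defined=True)
        b.add_group(bb, avp(r, v2))
        b.concept(f"plant_C1_{k}", f"Planted finding {k}C1 (disorder)", [a, bb])
        b.concept(f"plant_C2_{k}", f"Planted finding {k}C2 (disorder)", [a, bb])
        truth.append((CandidatePair(a, bb), LogicalDefinition(frozenset())))  # filled below
    pruned = b.build()

    existing = existing_reduced_definitions(pruned)
    full_b = OntologyBuilder(is_a=o.is_a)
    full_b.concepts = dict(pruned.concepts)
    full_b.isa_edges = set(pruned.graph.edges)
    full_b.attribute_rels = {c: list(g) for c, g in pruned.attribute_rels.items()}
    full_b.chains = list(pruned.property_chains)
    final_truth: list[tuple[CandidatePair, LogicalDefinition]] = []
    seen_defs: set[LogicalDefinition] = set()
    for k, (cand, _) in enumerate(truth):
        d = intersect_derived(pruned, cand.a, cand.b, depth=depth, ceiling=ceiling)
        if not d:
            raise PlantingError(f"plant {k}: intersection is empty")
        if d in existing or d in seen_defs:
            raise PlantingError(f"plant {k}: definition not identifiable")
        parents: list[str] = []
        attr_groups: list[AttributeGroup] = []
        for g in d.groups:
            pairs = list(g)
            if any(p.attribute == pruned.is_a for p in pairs):
                if len(pairs) != 1:
                    raise PlantingError(f"plant {k}: mixed or multi-parent is-a group")
                parents.append(pairs[0].value)
            else:
                attr_groups.append(g)
        if not parents:
            raise PlantingError(f"plant {k}: definition has no is-a group to place the concept")
        m = full_b.concept(
            f"plant_M{k}", f"Planted missing concept {k} (disorder)", parents, fully_defined=True
        )
        for g in attr_groups:
            full_b.attribute_rels.setdefault(m, []).append(g)
        seen_defs.add(d)
        final_truth.append((cand, d))
    full = full_b.build()
    for k, (cand, d) in enumerate(final_truth):
        check = full.own_groups(f"plant_M{k}")
        if reduce_definition(full, check) != d:
            raise PlantingError(f"plant {k}: planted definition does not round-trip")
    return PlantResult(pruned=pruned, full=full, truth=final_truth)
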