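"""Readers and writers: RF2 snapshots and the tab-separated fixture dialect.

The fixture dialect is a minimal, licence-free serialization of an
:class:`~ontogap.ontology.Ontology`:

* ``concepts.tsv`` — id, fsn, preferred_term, fully_defined, active
* ``isa.tsv`` — child, parent
* ``groups.tsv`` — concept, group_index, attribute, value
* ``chains.tsv`` — first, second, implied (optional)
* ``synonyms.tsv`` — concept, term (optional)

All files are UTF-8 with a header row.  ``write_fixture`` then
``load_fixture`` round-trips to an equal ontology.
"""

from __future__ import annotations

import re
from collections import defaultdict
from pathlib import Path

import pandas as pd

from .ontology import (
    IS_A,
    AttributeGroup,
    AttributeValuePair,
    Concept,
    LoadError,
    Ontology,
    PropertyChain,
    avp,
)

_BOOL = {"1": True, "0": False, "true": True, "false": False}


def _read_tsv(path: Path, required: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise LoadError(f"missing mandatory fixture file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise LoadError(f"{path} lacks required columns {missing}")
    return df


def load_fixture(tables: str | Path, is_a: str | None = None) -> Ontology:
    """Load an ontology from a fixture-dialect directory."""
    tables = Path(tables)
    cdf = _read_tsv(tables / "concepts.tsv", ["id", "fsn", "preferred_term", "fully_defined", "active"])
    if cdf.empty:
        raise LoadError(f"{tables / 'concepts.tsv'} contains no concepts")
    idf = _read_tsv(tables / "isa.tsv", ["child", "parent"])

    synonyms: dict[str, list[str]] = defaultdict(list)
    syn_path = tables / "synonyms.tsv"
    if syn_path.exists():
        for row in _read_tsv(syn_path, ["concept", "term"]).itertuples(index=False):
            synonyms[row.concept].append(row.term)

    concepts: dict[str, Concept] = {}
    for row in cdf.itertuples(index=False):
        if not _BOOL.get(str(row.active).lower(), True):
            continue
        concepts[row.id] = Concept(
            id=row.id,
            fsn=row.fsn,
            preferred_term=row.preferred_term,
            synonyms=tuple(synonyms.get(row.id, ())),
            fully_defined=_BOOL.get(str(row.fully_defined).lower(), False),
        )

    isa_edges = [(r.child, r.parent) for r in idf.itertuples(index=False)]

    attribute_rels: dict[str, list[AttributeGroup]] = {}
    gpath = tables / "groups.tsv"
    if gpath.exists():
        grouped: dict[tuple[str, str], set[AttributeValuePair]] = defaultdict(set)
        gdf = _read_tsv(gpath, ["concept", "group_index", "attribute", "value"])
        for row in gdf.itertuples(index=False):
            grouped[(row.concept, row.group_index)].add(avp(row.attribute, row.value))
        rels: dict[str, list[AttributeGroup]] = defaultdict(list)
        for (cid, _), pairs in sorted(grouped.items()):
            rels[cid].append(AttributeGroup(frozenset(pairs)))
        attribute_rels = dict(rels)

    chains: list[PropertyChain] = []
    cpath = tables / "chains.tsv"
    if cpath.exists():
        for row in _read_tsv(cpath, ["first", "second", "implied"]).itertuples(index=False):
            chains.append(PropertyChain(row.first, row.second, row.implied))

    if is_a is None:
        # honour a fixture-declared is-a id when such a concept exists
        is_a = IS_A if IS_A in concepts else _guess_is_a(concepts)
    return Ontology(concepts, isa_edges, attribute_rels, chains, is_a=is_a)


def _guess_is_a(concepts: dict[str, Concept]) -> str:
    for cid, c in concepts.items():
        if c.fsn.lower().startswith("is a"):
            return cid
    return IS_A


def write_fixture(o: Ontology, tables: str | Path) -> None:
    """Serialize ``o`` in the fixture dialect (inverse of :func:`load_fixture`)."""
    tables = Path(tables)
    tables.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "id": c.id,
            "fsn": c.fsn,
            "preferred_term": c.preferred_term,
            "fully_defined": int(c.fully_defined),
            "active": int(c.active),
        }
        for c in sorted(o.concepts.values(), key=lambda c: c.id)
    ]
    pd.DataFrame(rows).to_csv(tables / "concepts.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(o.isa_edges), columns=["child", "parent"]).to_csv(
        tables / "isa.tsv", sep="\t", index=False
    )
    grows = []
    for cid in sorted(o.attribute_rels):
        for gi, grp in enumerate(o.attribute_rels[cid], start=1):
            for p in sorted(grp, key=lambda p: (p.attribute, p.value)):
                grows.append({"concept": cid, "group_index": gi, "attribute": p.attribute, "value": p.value})
    pd.DataFrame(grows, columns=["concept", "group_index", "attribute", "value"]).to_csv(
        tables / "groups.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [{"first": ch.first, "second": ch.second, "implied": ch.implied} for ch in o.property_chains],
        columns=["first", "second", "implied"],
    ).to_csv(tables / "chains.tsv", sep="\t", index=False)
    srows = [
        {"concept": c.id, "term": t}
        for c in sorted(o.concepts.values(), key=lambda c: c.id)
        for t in c.synonyms
    ]
    pd.DataFrame(srows, columns=["concept", "term"]).to_csv(tables / "synonyms.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# RF2 snapshot
# ---------------------------------------------------------------------------

FULLY_DEFINED = "900000000000073002"
FSN_TYPE = "900000000000003001"
SYNONYM_TYPE = "900000000000013009"

_CHAIN_RE = re.compile(
    r"SubObjectPropertyOf\(\s*ObjectPropertyChain\(\s*:(\d+)\s+:(\d+)\s*\)\s*:(\d+)\s*\)"
)


def _find_rf2_file(snapshot_dir: Path, stem: str) -> Path:
    hits = sorted(snapshot_dir.rglob(f"{stem}*"))
    if not hits:
        raise LoadError(f"RF2 snapshot is missing a mandatory file matching {stem}* under {snapshot_dir}")
    return hits[0]


def load_rf2(
    snapshot_dir: str | Path,
    merge_group0: bool = False,
    chain_table: str | Path | None = None,
) -> Ontology:
    """Load an RF2 snapshot (concepts, descriptions, inferred relationships).

    Only active components are kept.  ``relationshipGroup`` boundaries become
    :class:`AttributeGroup` boundaries; group-0 rows are ungrouped in RF2 and
    by default each becomes its own singleton group (``merge_group0=True``
    merges them into a single group instead).  Property chains are read from
    an optional ``chains.tsv`` side table and, best effort, from an OWL
    expression refset file if one is present in the snapshot.
    """
    snapshot_dir = Path(snapshot_dir)
    concept_file = _find_rf2_file(snapshot_dir, "sct2_Concept")
    description_file = _find_rf2_file(snapshot_dir, "sct2_Description")
    rel_candidates = [
        p
        for p in sorted(snapshot_dir.rglob("sct2_Relationship*"))
        if "Stated" not in p.name and "Concrete" not in p.name
    ]
    if not rel_candidates:
        raise LoadError(
            f"RF2 snapshot is missing a mandatory inferred relationship file (sct2_Relationship*) under {snapshot_dir}"
        )
    relationship_file = rel_candidates[0]

    cdf = pd.read_csv(concept_file, sep="\t", dtype=str, keep_default_na=False)
    cdf = cdf[cdf["active"] == "1"]
    ddf = pd.read_csv(description_file, sep="\t", dtype=str, keep_default_na=False)
    ddf = ddf[ddf["active"] == "1"]
    rdf = pd.read_csv(relationship_file, sep="\t", dtype=str, keep_default_na=False)
    rdf = rdf[rdf["active"] == "1"]

    active_ids = set(cdf["id"])
    fsns: dict[str, str] = {}
    prefs: dict[str, str] = {}
    syns: dict[str, list[str]] = defaultdict(list)
    for row in ddf.itertuples(index=False):
        if row.conceptId not in active_ids:
            continue
        if row.typeId == FSN_TYPE:
            fsns.setdefault(row.conceptId, row.term)
        elif row.typeId == SYNONYM_TYPE:
            # full language-refset acceptability is out of scope: the first
            # active synonym (file order) serves as the preferred term
            prefs.setdefault(row.conceptId, row.term)
            syns[row.conceptId].append(row.term)

    concepts: dict[str, Concept] = {}
    for row in cdf.itertuples(index=False):
        fsn = fsns.get(row.id, "")
        if not fsn:
            raise LoadError(f"active concept {row.id} has no active FSN in {description_file.name}")
        concepts[row.id] = Concept(
            id=row.id,
            fsn=fsn,
            preferred_term=prefs.get(row.id, ""),
            synonyms=tuple(syns.get(row.id, ())),
            fully_defined=row.definitionStatusId == FULLY_DEFINED,
        )

    dangling = []
    isa_edges: list[tuple[str, str]] = []
    grouped: dict[tuple[str, str], set[AttributeValuePair]] = defaultdict(set)
    ungrouped: dict[str, list[AttributeValuePair]] = defaultdict(list)
    for row in rdf.itertuples(index=False):
        if row.sourceId not in active_ids or row.destinationId not in active_ids:
            dangling.append(f"{row.sourceId}->{row.destinationId}")
            continue
        if row.typeId == IS_A:
            isa_edges.append((row.sourceId, row.destinationId))
        elif row.relationshipGroup == "0" and not merge_group0:
            ungrouped[row.sourceId].append(avp(row.typeId, row.destinationId))
        else:
            grouped[(row.sourceId, row.relationshipGroup)].add(avp(row.typeId, row.destinationId))
    if dangling:
        raise LoadError(f"relationship rows reference inactive/unknown concepts: {dangling[:10]}")

    rels: dict[str, list[AttributeGroup]] = defaultdict(list)
    for (cid, _), pairs in sorted(grouped.items()):
        rels[cid].append(AttributeGroup(frozenset(pairs)))
    for cid, pairs in ungrouped.items():
        for p in sorted(pairs, key=lambda p: (p.attribute, p.value)):
            rels[cid].append(AttributeGroup(frozenset([p])))

    chains: list[PropertyChain] = []
    if chain_table is not None:
        for row in pd.read_csv(chain_table, sep="\t", dtype=str, keep_default_na=False).itertuples(index=False):
            chains.append(PropertyChain(row.first, row.second, row.implied))
    else:
        owl_files = sorted(snapshot_dir.rglob("sct2_sRefset_OWL*"))
        for owl in owl_files:
            text = owl.read_text(encoding="utf-8")
            for m in _CHAIN_RE.finditer(text):
                chains.append(PropertyChain(m.group(1), m.group(2), m.group(3)))

    return Ontology(concepts, isa_edges, dict(rels), chains, is_a=IS_A)
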