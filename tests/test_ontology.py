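"""ontology model, loaders, and hierarchy queries."""

from __future__ import annotations

from pathlib import Path

import pytest

from ontogap.io import load_fixture, load_rf2, write_fixture
from ontogap.ontology import (
    CycleError,
    LoadError,
    Ontology,
    UnknownConceptError,
    split_semantic_tag,
)
from ontogap.synthetic import OntologyBuilder

from conftest import dfs_down, dfs_up, random_dag_ontology

DATA = Path(__file__).parent / "data"


class TestFixtureLoader:
    def test_vulva_minimal_loads_seven_concepts(self):
        o = load_fixture(DATA / "vulva_minimal")
        assert len(o) == 7
        assert o.root == "root"
        assert o.concepts["nv"].fully_defined

    def test_write_then_load_round_trips(self, vulva, tmp_path):
        write_fixture(vulva, tmp_path / "fx")
        o2 = load_fixture(tmp_path / "fx")
        assert o2.concepts == vulva.concepts
        assert o2.isa_edges == vulva.isa_edges
        assert o2.attribute_rels == vulva.attribute_rels
        assert o2.property_chains == vulva.property_chains
        assert o2.is_a == vulva.is_a

    def test_inactive_concepts_are_filtered(self, tmp_path):
        (tmp_path / "concepts.tsv").write_text(
            "id\tfsn\tpreferred_term\tfully_defined\tactive\n"
            "r\tRoot (finding)\tRoot\t0\t1\n"
            "x\tGone (finding)\tGone\t0\t0\n"
        )
        (tmp_path / "isa.tsv").write_text("child\tparent\n")
        o = load_fixture(tmp_path)
        assert len(o) == 1 and "x" not in o

    def test_empty_concept_table_errors(self, tmp_path):
        (tmp_path / "concepts.tsv").write_text("id\tfsn\tpreferred_term\tfully_defined\tactive\n")
        (tmp_path / "isa.tsv").write_text("child\tparent\n")
        with pytest.raises(LoadError, match="no concepts"):
            load_fixture(tmp_path)

    def test_missing_mandatory_file_errors(self, tmp_path):
        (tmp_path / "concepts.tsv").write_text(
            "id\tfsn\tpreferred_term\tfully_defined\tactive\nr\tRoot (finding)\tRoot\t0\t1\n"
        )
        with pytest.raises(LoadError, match="isa.tsv"):
            load_fixture(tmp_path)

    def test_isa_cycle_is_reported(self, tmp_path):
        (tmp_path / "concepts.tsv").write_text(
            "id\tfsn\tpreferred_term\tfully_defined\tactive\n"
            "r\tRoot (finding)\tRoot\t0\t1\n"
            "a\tA (finding)\tA\t0\t1\n"
            "b\tB (finding)\tB\t0\t1\n"
        )
        (tmp_path / "isa.tsv").write_text("child\tparent\na\tb\nb\ta\na\tr\n")
        with pytest.raises(CycleError) as err:
            load_fixture(tmp_path)
        assert set(err.value.cycle) >= {"a", "b"}


RF2_CONCEPT = (
    "id\teffectiveTime\tactive\tmoduleId\tdefinitionStatusId\n"
    "138875005\t20210301\t1\tm\t900000000000074008\n"  # root, primitive
    "116680003\t20210301\t1\tm\t900000000000074008\n"  # Is a
    "404684003\t20210301\t1\tm\t900000000000074008\n"
    "64572001\t20210301\t1\tm\t900000000000073002\n"   # fully defined
    "999000001\t20210301\t0\tm\t900000000000074008\n"  # inactive
    "363698007\t20210301\t1\tm\t900000000000074008\n"  # Finding site
    "123037004\t20210301\t1\tm\t900000000000074008\n"  # Body structure
)
RF2_DESCRIPTION_ROWS = [
    ("138875005", "SNOMED CT Concept (SNOMED RT+CTV3)", "fsn"),
    ("138875005", "SNOMED CT Concept", "syn"),
    ("116680003", "Is a (attribute)", "fsn"),
    ("404684003", "Clinical finding (finding)", "fsn"),
    ("404684003", "Clinical finding", "syn"),
    ("64572001", "Disease (disorder)", "fsn"),
    ("64572001", "Disease", "syn"),
    ("999000001", "Inactive thing (disorder)", "fsn"),
    ("363698007", "Finding site (attribute)", "fsn"),
    ("123037004", "Body structure (body structure)", "fsn"),
]
RF2_RELATIONSHIP = (
    "id\teffectiveTime\tactive\tmoduleId\tsourceId\tdestinationId\trelationshipGroup\ttypeId\tcharacteristicTypeId\tmodifierId\n"
    "1\t20210301\t1\tm\t404684003\t138875005\t0\t116680003\tc\tmod\n"
    "2\t20210301\t1\tm\t116680003\t138875005\t0\t116680003\tc\tmod\n"
    "3\t20210301\t1\tm\t363698007\t138875005\t0\t116680003\tc\tmod\n"
    "4\t20210301\t1\tm\t123037004\t138875005\t0\t116680003\tc\tmod\n"
    "5\t20210301\t1\tm\t64572001\t404684003\t0\t116680003\tc\tmod\n"
    # group pattern {0, 0, 1} on one source concept
    "6\t20210301\t1\tm\t64572001\t123037004\t0\t363698007\tc\tmod\n"
    "7\t20210301\t1\tm\t64572001\t138875005\t0\t363698007\tc\tmod\n"
    "8\t20210301\t1\tm\t64572001\t404684003\t1\t363698007\tc\tmod\n"
    "9\t20210301\t0\tm\t64572001\t123037004\t2\t363698007\tc\tmod\n"  # inactive
)


def _write_rf2(tmp_path: Path) -> Path:
    snap = tmp_path / "Snapshot"
    snap.mkdir()
    (snap / "sct2_Concept_Snapshot.txt").write_text(RF2_CONCEPT)
    desc = ["id\teffectiveTime\tactive\tmoduleId\tconceptId\tlanguageCode\ttypeId\tterm\tcaseSignificanceId"]
    for i, (cid, term, kind) in enumerate(RF2_DESCRIPTION_ROWS):
        type_id = "900000000000003001" if kind == "fsn" else "900000000000013009"
        desc.append(f"d{i}\t20210301\t1\tm\t{cid}\ten\t{type_id}\t{term}\tcs")
    (snap / "sct2_Description_Snapshot.txt").write_text("\n".join(desc) + "\n")
    (snap / "sct2_Relationship_Snapshot.txt").write_text(RF2_RELATIONSHIP)
    (snap / "sct2_sRefset_OWLExpressionSnapshot.txt").write_text(
        "id\towlExpression\n"
        "x\tSubObjectPropertyOf(ObjectPropertyChain(:363698007 :363698007) :363698007)\n"
    )
    return tmp_path


class TestRF2Loader:
    def test_snapshot_loads_with_group_partitioning(self, tmp_path):
        o = load_rf2(_write_rf2(tmp_path))
        assert "999000001" not in o  # inactive concept excluded
        assert o.concepts["64572001"].fully_defined
        assert not o.concepts["404684003"].fully_defined
        assert o.concepts["404684003"].preferred_term == "Clinical finding"
        # group-0 rows self-grouped, group-1 row its own group; inactive row dropped
        groups = o.attribute_rels["64572001"]
        assert sorted(len(g) for g in groups) == [1, 1, 1]
        assert len(o.own_groups("64572001")) == 4  # 1 is-a parent + 3 groups
        # group 0 merged on request
        om = load_rf2(tmp_path, merge_group0=True)
        assert sorted(len(g) for g in om.attribute_rels["64572001"]) == [1, 2]
        # OWL refset property chain picked up
        assert len(o.property_chains) == 1
        assert o.property_chains[0].implied == "363698007"

    def test_missing_relationship_file_errors(self, tmp_path):
        _write_rf2(tmp_path)
        (tmp_path / "Snapshot" / "sct2_Relationship_Snapshot.txt").unlink()
        with pytest.raises(LoadError, match="sct2_Relationship"):
            load_rf2(tmp_path)


class TestHierarchyQueries:
    def test_root_has_no_ancestors(self, vulva):
        assert vulva.ancestors(vulva.root) == set()
        assert vulva.level(vulva.root) == 0

    def test_vulva_ancestors_cover_described_structure(self, vulva):
        assert vulva.ancestors("benign_neoplasm_bartholin") >= {
            "benign_neoplasm_vulva",
            "neoplasm_vulva",
            "disorder_bartholin",
        }

    @pytest.mark.parametrize("seed", range(20))
    def test_closures_match_dfs_oracle(self, seed):
        o = random_dag_ontology(seed, n=40 + 3 * seed)
        edges = set(o.graph.edges)
        for c in o.concepts:
            assert o.ancestors(c) == dfs_up(edges, c)
            assert o.descendants(c) == dfs_down(edges, c)
            for other in o.concepts:
                if other != c:
                    assert o.is_subtype(c, other) == (other in dfs_up(edges, c))

    def test_is_subtype_irreflexive(self, vulva):
        for c in vulva.concepts:
            assert not vulva.is_subtype(c, c)

    def test_unknown_id_raises(self, vulva):
        with pytest.raises(UnknownConceptError):
            vulva.ancestors("nope")
        with pytest.raises(UnknownConceptError):
            vulva.level("nope")

    def test_level_chain_and_diamond(self):
        b = OntologyBuilder()
        b.concept("r", "Root (finding)")
        b.concept("a", "A (finding)", ["r"])
        b.concept("b", "B (finding)", ["a"])
        b.concept("c", "C (finding)", ["b"])
        # diamond with one long side: level follows the longest path
        b.concept("d", "D (finding)", ["r", "c"])
        o = b.build()
        assert o.level("c") == 3
        assert o.level("d") == 4

    @pytest.mark.parametrize("seed", range(10))
    def test_level_monotone_over_parents(self, seed):
        o = random_dag_ontology(seed, n=50)
        for c in o.concepts:
            for p in o.parents(c):
                assert o.level(c) > o.level(p)


class TestOwnGroups:
    def test_thyroid_concept_has_three_groups(self, thyroid):
        d = thyroid.own_groups("men_thyroid")
        assert len(d) == 3
        singletons = [g for g in d if len(g) == 1]
        assert len(singletons) == 2  # the two is-a parents
        (two_pair,) = [g for g in d if len(g) == 2]
        assert {p.attribute for p in two_pair} == {"assoc_morph", "finding_site"}

    def test_group_count_is_parents_plus_attribute_groups(self, vulva, thyroid):
        for o in (vulva, thyroid):
            for c in o.concepts:
                expected = len(o.parents(c)) + len(o.attribute_rels.get(c, ()))
                assert len(o.own_groups(c)) == expected

    def test_single_parent_no_groups_yields_one(self, vulva):
        assert len(vulva.own_groups("pad4")) == 1


def test_semantic_tag_split():
    assert split_semantic_tag("Neoplasm of vulva (disorder)") == ("Neoplasm of vulva", "disorder")
    assert split_semantic_tag("no tag here") == ("no tag here", None)
    assert split_semantic_tag(
        "Malignant neoplasm of greater vestibular (Bartholin's) gland (disorder)"
    ) == ("Malignant neoplasm of greater vestibular (Bartholin's) gland", "disorder")
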