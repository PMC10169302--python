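"""Name normalization and the lexicon / corpus / newer-release matchers."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ontogap.missing import PotentialMissingConcept
from ontogap.ontology import avp, definition, group
from ontogap.synthetic import OntologyBuilder
from ontogap.validation import (
    LexiconAtom,
    build_np_index,
    default_lemmatize,
    load_lexicon_tsv,
    load_mrconso,
    match_lexicon,
    match_release,
    normalize_lexicon,
    normalize_name,
    search_np,
    simple_chunker,
    validate_proposal,
)


@pytest.fixture(scope="module")
def syn_ontology():
    b = OntologyBuilder()
    b.concept("root", "Root (finding)")
    b.concept(
        "indigestion",
        "Indigestion (finding)",
        ["root"],
        preferred_term="Indigestion",
        synonyms=("Dyspepsia",),
    )
    return b.build()


class TestNormalization:
    def test_synonym_replaced_by_preferred_term(self, syn_ontology):
        norm = normalize_name("dyspepsia of stomach", syn_ontology)
        assert "indigestion" in norm.tokens
        assert norm.tokens == ("indigestion", "stomach")

    def test_semantic_tag_held_separately(self):
        norm = normalize_name("Cutaneous infection (disorder)")
        assert norm.tag == "disorder"
        assert norm.tokens == ("cutaneous", "infection")

    def test_whitespace_case_and_plurals(self):
        norm = normalize_name("  Kidney   Diseases ")
        assert norm.tokens == ("kidney", "disease")

    def test_known_limitation_adjective_forms_differ(self):
        # the documented normalization miss: these convey the same meaning
        # but normalize differently
        a = normalize_name("Closure of fistula of sclera (procedure)")
        b = normalize_name("Closure of scleral fistula (procedure)")
        assert a.tokens == ("closure", "fistula", "sclera")
        assert b.tokens == ("closure", "scleral", "fistula")
        assert a.tokens != b.tokens

    @given(st.text(alphabet=st.characters(codec="ascii"), min_size=1, max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_idempotent_on_printable_strings(self, text):
        try:
            once = normalize_name(text)
        except ValueError:
            return
        if not once.tokens:
            return
        rendered = once.key + (f" ({once.tag})" if once.tag else "")
        again = normalize_name(rendered)
        assert again.tokens == once.tokens
        assert again.tag == once.tag

    def test_idempotent_with_synonym_table(self, syn_ontology):
        once = normalize_name("dyspepsia of stomach", syn_ontology)
        again = normalize_name(once.key, syn_ontology)
        assert again.tokens == once.tokens

    def test_irregular_plural_chain(self):
        assert default_lemmatize("children") == "child"
        norm = normalize_name("mens health")  # "mens" -> "men" -> "man"
        assert norm.tokens == ("man", "health")

    def test_empty_name_rejected(self):
        with pytest.raises(ValueError):
            normalize_name("")


class TestLexiconMatching:
    def test_plural_atom_matches_after_lemmatization(self):
        lexicon = [LexiconAtom("A24682086", "C1853193", "HPO", "Cutaneous infections")]
        assert match_lexicon("Cutaneous infection (disorder)", lexicon) == [
            ("A24682086", "C1853193")
        ]

    def test_near_miss_with_extra_token_does_not_match(self):
        lexicon = [LexiconAtom("A1", "C1", "MSH", "Severe cutaneous infection")]
        assert match_lexicon("Cutaneous infection (disorder)", lexicon) == []

    def test_empty_lexicon(self):
        assert match_lexicon("Anything (disorder)", []) == []

    def test_same_verdict_whichever_side_is_prenormalized(self):
        raw = [LexiconAtom("A2", "C2", "MSH", "Kidney Diseases")]
        pre = normalize_lexicon(raw)
        assert match_lexicon("Disease of kidney", raw) == match_lexicon("Disease of kidney", pre) == []
        assert match_lexicon("Kidney disease (disorder)", raw) == match_lexicon(
            "Kidney disease (disorder)", pre
        ) == [("A2", "C2")]

    def test_mrconso_and_tsv_loaders(self, tmp_path):
        rrf = tmp_path / "MRCONSO.RRF"
        rrf.write_text(
            "C0022658|ENG|P|L0|PF|S0|Y|A0427003||||MSH|MH|D007674|Kidney Disease|0|N||\n"
            "C0022658|FRE|P|L1|PF|S1|Y|A9999999||||MSHFRE|MH|D007674|Maladie du rein|0|N||\n"
        )
        atoms = load_mrconso(rrf)
        assert len(atoms) == 1 and atoms[0].aui == "A0427003" and atoms[0].source == "MSH"
        tsv = tmp_path / "lex.tsv"
        tsv.write_text("aui\tcui\tsource\tname\nA1\tC1\tHPO\tCutaneous infections\n")
        assert load_lexicon_tsv(tsv)[0].cui == "C1"


DOCS = [
    ("20072857", "Lung cysts following pulmonary artery operations: diagnostic and therapeutic implications", ""),
    ("999", "", "The fetal thoracic artery was examined in detail."),
]


class TestCorpusMatching:
    def test_whole_phrase_match_found_in_title(self):
        index = build_np_index(DOCS)
        assert search_np(index, "Pulmonary artery operation (procedure)") == ["20072857"]

    def test_substring_of_longer_phrase_does_not_match(self):
        index = build_np_index(DOCS)
        assert search_np(index, "thoracic artery") == []
        assert search_np(index, "fetal thoracic artery") == ["999"]

    def test_empty_corpus(self):
        index = build_np_index([])
        assert search_np(index, "anything") == []

    def test_chunker_failure_skips_document_with_warning(self):
        def broken(text):
            raise RuntimeError("no parse")

        with pytest.warns(UserWarning, match="chunker failed"):
            index = build_np_index(DOCS, chunker=broken)
        assert index.phrases == {}

    def test_custom_chunker_contract(self):
        index = build_np_index([("1", "irrelevant", "")], chunker=lambda t: ["Left Knee Pain"])
        assert search_np(index, "left knee pain (finding)") == ["1"]

    def test_simple_chunker_breaks_on_punctuation_and_function_words(self):
        phrases = simple_chunker("Lung cysts following pulmonary artery operations: implications")
        assert "lung cysts" in phrases
        assert "pulmonary artery operations" in phrases
        assert all("following" not in p for p in phrases)


def _release_pair():
    """Source and newer releases sharing the id space, with one added concept."""

    def build(extra: bool):
        b = OntologyBuilder()
        b.concept("root", "Root (finding)")
        b.concept("attr", "Concept model attribute (attribute)", ["root"])
        b.concept("isa", "Is a (attribute)", ["attr"])
        b.concept("fs", "Finding site (attribute)", ["attr"])
        b.concept("body", "Body structure (body structure)", ["root"])
        b.concept("knee", "Structure of right knee region (body structure)", ["body"])
        b.concept("pain", "Pain of knee region (finding)", ["root"])
        if extra:
            b.concept("new1", "Pain of right knee region (finding)", ["pain"], fully_defined=True)
            b.add_group("new1", avp("fs", "knee"))
        return b.build()

    return build(False), build(True)


class TestReleaseMatching:
    def _proposal(self, fsn):
        return PotentialMissingConcept(
            definition=definition(group(avp("isa", "pain")), group(avp("fs", "knee"))),
            provenance=(),
            predicted_fsn=fsn,
        )

    def test_fsn_and_definition_match(self):
        source, newer = _release_pair()
        res = match_release(self._proposal("Pain of right knee region (finding)"), newer, source)
        assert res.by_release == ("new1", "fsn+definition")
        assert res.validated

    def test_fsn_only_match(self):
        source, newer = _release_pair()
        pmc = PotentialMissingConcept(
            definition=definition(group(avp("isa", "pain"))),
            provenance=(),
            predicted_fsn="Pain of right knee region (finding)",
        )
        assert match_release(pmc, newer, source).by_release == ("new1", "fsn_only")

    def test_definition_only_match(self):
        source, newer = _release_pair()
        res = match_release(self._proposal("Completely different name (finding)"), newer, source)
        assert res.by_release == ("new1", "definition_only")

    def test_tag_difference_is_recorded_but_not_validated(self):
        source, newer = _release_pair()
        pmc = PotentialMissingConcept(
            definition=definition(group(avp("isa", "pain"))),
            provenance=(),
            predicted_fsn="Pain of right knee region (disorder)",
        )
        res = match_release(pmc, newer, source)
        assert res.by_release == ("new1", "tag_differs")
        assert not res.validated

    def test_no_counterpart_yields_empty_fragment(self):
        source, _ = _release_pair()
        res = match_release(self._proposal("Pain of right knee region (finding)"), source, source)
        assert res.by_release is None and not res.validated

    def test_validate_proposal_combines_matchers(self):
        source, newer = _release_pair()
        pmc = self._proposal("Pain of right knee region (finding)")
        lexicon = [LexiconAtom("A1", "C1", "MSH", "Pain of right knee region")]
        index = build_np_index([("7", "Pain of right knee region after surgery", "")],
                               chunker=lambda t: ["Pain of right knee region"])
        res = validate_proposal(pmc, source, lexicon, index, newer)
        assert res.by_lexicon == [("A1", "C1")]
        assert res.by_corpus == ["7"]
        assert res.by_release == ("new1", "fsn+definition")
        assert res.validated
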