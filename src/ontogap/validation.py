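"""Name normalization and the three validation matchers.

Proposed concept names rarely appear verbatim in external sources, so all
matching runs over a shared normalization pipeline: collapse whitespace,
lowercase, lemmatize each token, replace synonyms with the preferred term of
the corresponding ontology concept, then drop stop words.  The semantic tag
is split off first and held separately — lexicon and corpus matching ignore
it, newer-release FSN matching includes it.

Three matchers consume the normalized form:

* a lexicon of atoms (UMLS MRCONSO-style: AUI, CUI, source, string);
* a document corpus, matched against *whole* base noun phrases only, so a
  name buried inside a longer phrase ("thoracic artery" within "fetal
  thoracic artery") does not count;
* a newer ontology release, by normalized FSN and/or logical definition.

Both the lemmatizer and the noun-phrase chunker are pluggable callables with
simple rule-based defaults, keeping the pipeline dependency-free.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd

from .missing import PotentialMissingConcept, definition_equals
from .ontology import Ontology, OntologyError, split_semantic_tag

# a fixed, overridable English stop-word list; deliberately small so that
# informative tokens are never dropped
DEFAULT_STOPWORDS = frozenset(
    """a an and are as at be by for from in into is of on or that the to with
    without""".split()
)

_IRREGULAR_PLURALS = {
    "feet": "foot",
    "teeth": "tooth",
    "men": "man",
    "women": "woman",
    "children": "child",
    "mice": "mouse",
    "nuclei": "nucleus",
    "fungi": "fungus",
    "vertebrae": "vertebra",
    "ganglia": "ganglion",
    "bacteria": "bacterium",
    "criteria": "criterion",
}


def default_lemmatize(token: str) -> str:
    """Rule-based English noun lemmatizer (plural → singular).

    Deliberately conservative; any token→lemma callable may replace it.
    """
    if token in _IRREGULAR_PLURALS:
        return _IRREGULAR_PLURALS[token]
    if len(token) > 3 and token.endswith("ies"):
        return token[:-3] + "y"
    if len(token) > 4 and token.endswith(("ches", "shes", "sses", "xes", "zes")):
        return token[:-2]
    if (
        len(token) > 3
        and token.endswith("s")
        and not token.endswith(("ss", "us", "is"))
    ):
        return token[:-1]
    return token


Lemmatizer = Callable[[str], str]
Chunker = Callable[[str], Sequence[str]]


def _lemma_fix(lemmatize: Lemmatizer, token: str) -> str:
    # iterate to a fixpoint so normalization stays idempotent even when a
    # rule output is itself reducible (e.g. "mens" -> "men" -> "man")
    for _ in range(5):
        out = lemmatize(token)
        if out == token:
            return token
        token = out
    return token

_WORD = re.compile(r"[a-z0-9]+")


@dataclass(frozen=True)
class NormalizedName:
    tokens: tuple[str, ...]
    original: str
    tag: str | None = None

    @property
    def key(self) -> str:
        return " ".join(self.tokens)


def _synonym_map(o: Ontology, lemmatize: Lemmatizer) -> dict[tuple[str, ...], tuple[str, ...]]:
    """Normalized synonym token sequence → normalized preferred-term tokens."""
    out: dict[tuple[str, ...], tuple[str, ...]] = {}
    for c in o.concepts.values():
        pref = tuple(_lemma_fix(lemmatize, t) for t in _WORD.findall(c.preferred_term.lower()))
        if not pref:
            continue
        for syn in c.synonyms:
            key = tuple(_lemma_fix(lemmatize, t) for t in _WORD.findall(syn.lower()))
            if key and key != pref:
                out[key] = pref
    return out


def _replace_synonyms(
    tokens: list[str], table: dict[tuple[str, ...], tuple[str, ...]]
) -> list[str]:
    # longest match first, left to right, repeated to a fixpoint so that
    # normalization stays idempotent even when preferred terms are
    # themselves synonyms of further concepts
    if not table:
        return tokens
    max_len = max(len(k) for k in table)
    for _ in range(5):
        out: list[str] = []
        i = 0
        changed = False
        while i < len(tokens):
            for width in range(min(max_len, len(tokens) - i), 0, -1):
                window = tuple(tokens[i : i + width])
                if window in table:
                    out.extend(table[window])
                    i += width
                    changed = True
                    break
            else:
                out.append(tokens[i])
                i += 1
        tokens = out
        if not changed:
            break
    return tokens


def normalize_name(
    name: str,
    o: Ontology | None = None,
    stopwords: Iterable[str] = DEFAULT_STOPWORDS,
    lemmatize: Lemmatizer = default_lemmatize,
) -> NormalizedName:
    """Normalize a concept name or free-text phrase.

    Pipeline: split off the semantic tag → collapse whitespace → lowercase →
    lemmatize tokens → synonym-to-preferred-term replacement against the
    ontology (when given) → stop-word removal.  Idempotent: normalizing a
    rendered normalized name changes nothing.
    """
    if not name:
        raise ValueError("cannot normalize an empty name")
    base, tag = split_semantic_tag(name)
    tokens = [_lemma_fix(lemmatize, t) for t in _WORD.findall(" ".join(base.split()).lower())]
    if o is not None:
        tokens = _replace_synonyms(tokens, _synonym_map(o, lemmatize))
    stop = set(stopwords)
    tokens = [t for t in tokens if t not in stop]
    return NormalizedName(tuple(tokens), original=name, tag=tag)


# ---------------------------------------------------------------------------
# lexicon (UMLS atoms)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LexiconAtom:
    aui: str
    cui: str
    source: str
    name: str
    normalized: NormalizedName | None = None


def normalize_lexicon(
    lexicon: Sequence[LexiconAtom], o: Ontology | None = None, **kw
) -> list[LexiconAtom]:
    return [
        LexiconAtom(a.aui, a.cui, a.source, a.name, normalize_name(a.name, o, **kw))
        for a in lexicon
    ]


def match_lexicon(
    fsn: str, lexicon: Sequence[LexiconAtom], o: Ontology | None = None, **kw
) -> list[tuple[str, str]]:
    """(aui, cui) of atoms whose normalized name equals the normalized FSN.

    The FSN's semantic tag is ignored.  Atoms lacking a precomputed
    ``normalized`` field are normalized on the fly with the same pipeline.
    """
    target = normalize_name(fsn, o, **kw).tokens
    hits = []
    for atom in lexicon:
        norm = atom.normalized or normalize_name(atom.name, o, **kw)
        if norm.tokens == target:
            hits.append((atom.aui, atom.cui))
    return hits


def load_mrconso(path: str | Path, english_only: bool = True) -> list[LexiconAtom]:
    """Read a pipe-delimited MRCONSO-style file (CUI|LAT|...|AUI|...|SAB|...|STR|...)."""
    atoms = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            f = line.rstrip("\n").split("|")
            if len(f) < 15:
                continue
            if english_only and f[1] != "ENG":
                continue
            atoms.append(LexiconAtom(aui=f[7], cui=f[0], source=f[11], name=f[14]))
    return atoms


def load_lexicon_tsv(path: str | Path) -> list[LexiconAtom]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        LexiconAtom(r.aui, r.cui, r.source, r.name)
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# corpus (noun-phrase index)
# ---------------------------------------------------------------------------


def simple_chunker(text: str) -> list[str]:
    """Heuristic base-noun-phrase extraction: maximal runs of word tokens
    between punctuation and common function words.  A linguistic chunker
    (e.g. a parser's noun_chunks) can be substituted via the same contract.
    """
    breakers = DEFAULT_STOPWORDS | {
        "following", "during", "after", "before", "versus",
        "was", "were", "has", "have", "had", "been", "being",
        "we", "it", "this", "these", "those", "their", "its",
    }
    phrases = []
    for segment in re.split(r"[.,;:()\[\]\"]+", text.lower()):
        run: list[str] = []
        for tok in segment.split():
            word = "".join(_WORD.findall(tok))
            if not word or word in breakers:
                if len(run) >= 1:
                    phrases.append(" ".join(run))
                run = []
            else:
                run.append(word)
        if run:
            phrases.append(" ".join(run))
    return phrases


@dataclass
class CorpusIndex:
    """Inverted index: normalized noun-phrase key → sorted doc ids."""

    phrases: dict[str, list[str]] = field(default_factory=dict)

    def add(self, key: str, doc_id: str) -> None:
        ids = self.phrases.setdefault(key, [])
        if doc_id not in ids:
            ids.append(doc_id)


def build_np_index(
    documents: Iterable[tuple[str, str, str]],
    chunker: Chunker = simple_chunker,
    o: Ontology | None = None,
    **kw,
) -> CorpusIndex:
    """Index every base noun phrase of each (doc_id, title, abstract).

    A chunker failure on a document skips that document with a warning.
    """
    index = CorpusIndex()
    for doc_id, title, abstract in documents:
        try:
            phrases = list(chunker(title)) + list(chunker(abstract))
        except Exception as exc:
            warnings.warn(f"chunker failed on document {doc_id!r}: {exc}")
            continue
        for phrase in phrases:
            if not phrase.strip():
                continue
            norm = normalize_name(phrase, o, **kw)
            if norm.tokens:
                index.add(norm.key, doc_id)
    for ids in index.phrases.values():
        ids.sort()
    return index


def search_np(index: CorpusIndex, fsn: str, o: Ontology | None = None, **kw) -> list[str]:
    """Doc ids whose noun phrases contain the FSN as a whole phrase.

    Only exact normalized-phrase equality matches; substring containment in
    a longer phrase does not.
    """
    norm = normalize_name(fsn, o, **kw)
    return list(index.phrases.get(norm.key, []))


def load_jsonl_corpus(path: str | Path) -> list[tuple[str, str, str]]:
    docs = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                d = json.loads(line)
                docs.append((str(d["id"]), d.get("title", ""), d.get("abstract", "")))
    return docs


# ---------------------------------------------------------------------------
# newer-release matching
# ---------------------------------------------------------------------------

VALID_KINDS = {"fsn+definition", "fsn_only", "definition_only"}


@dataclass
class ValidationResult:
    by_lexicon: list[tuple[str, str]] = field(default_factory=list)
    by_corpus: list[str] = field(default_factory=list)
    by_release: tuple[str, str] | None = None  # (concept id, match kind)

    @property
    def validated(self) -> bool:
        """tag_differs release matches do not count as validated."""
        return bool(
            self.by_lexicon
            or self.by_corpus
            or (self.by_release is not None and self.by_release[1] in VALID_KINDS)
        )


def match_release(
    pmc: PotentialMissingConcept,
    newer: Ontology,
    source: Ontology | None = None,
    **kw,
) -> ValidationResult:
    """Check a proposal against a newer release of the same terminology.

    FSN matching is on the normalized name *with* the semantic tag; a
    name-only match with a differing tag is recorded as ``tag_differs`` and
    does not validate.  Definition matching uses order-insensitive reduced
    equality over shared concept identifiers.
    """
    result = ValidationResult()
    fsn_norm = None
    if pmc.predicted_fsn:
        fsn_norm = normalize_name(pmc.predicted_fsn, source, **kw)
    best: tuple[int, str, str] | None = None  # (rank, concept id, kind)
    ranks = {"fsn+definition": 0, "fsn_only": 1, "definition_only": 2, "tag_differs": 3}
    for cid in newer.concepts:
        kind = None
        name_match = tag_match = False
        if fsn_norm is not None:
            other = normalize_name(newer.fsn(cid), source, **kw)
            name_match = other.tokens == fsn_norm.tokens
            tag_match = other.tag == fsn_norm.tag
        defn = newer.own_groups(cid)
        try:
            def_match = bool(defn) and definition_equals(newer, pmc.definition, defn)
        except OntologyError:
            # the proposal's definition references ids absent from the
            # newer release — no definition match possible
            def_match = False
        if name_match and tag_match and def_match:
            kind = "fsn+definition"
        elif name_match and tag_match:
            kind = "fsn_only"
        elif def_match:
            kind = "definition_only"
        elif name_match and not tag_match:
            kind = "tag_differs"
        if kind is not None:
            entry = (ranks[kind], cid, kind)
            if best is None or entry < best:
                best = entry
    if best is not None:
        result.by_release = (best[1], best[2])
    return result


def validate_proposal(
    pmc: PotentialMissingConcept,
    o: Ontology | None = None,
    lexicon: Sequence[LexiconAtom] | None = None,
    corpus_index: CorpusIndex | None = None,
    newer: Ontology | None = None,
    **kw,
) -> ValidationResult:
    """Run all configured matchers for one proposal."""
    result = ValidationResult()
    if pmc.predicted_fsn and lexicon is not None:
        result.by_lexicon = match_lexicon(pmc.predicted_fsn, lexicon, o, **kw)
    if pmc.predicted_fsn and corpus_index is not None:
        result.by_corpus = search_np(corpus_index, pmc.predicted_fsn, o, **kw)
    if newer is not None:
        result.by_release = match_release(pmc, newer, o, **kw).by_release
    return result
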