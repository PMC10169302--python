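"""Definition serialization, dataset splits, and ROUGE evaluation of namers.

Concept naming is framed as summarization: the logical definition, rendered
as one comma-separated sentence of "AttributeName ValueFSN" phrases, is the
source text and the concept's fully specified name (FSN) the target.  Any
text→text callable can act as the namer (a fine-tuned sequence-to-sequence
model in production, a template or oracle in tests); this module only fixes
the data contract and the evaluation:

* ROUGE-N — clipped n-gram recall against the reference names,
  ``Σ_S Σ_gram Count_match(gram_n) / Σ_S Σ_gram Count(gram_n)``;
* ROUGE-L — longest-common-subsequence recall in the same form;
* exact-match counting under the validation module's name normalization.
"""

from __future__ import annotations

import random
import re
from collections import Counter
from dataclasses import dataclass
from math import floor
from typing import Callable, Sequence

from .ontology import LogicalDefinition, Ontology


@dataclass(frozen=True)
class NamingInstance:
    concept: str
    source_text: str
    target_text: str


@dataclass(frozen=True)
class RougeScores:
    rouge1: float
    rouge2: float
    rougeL: float

    def scaled(self) -> tuple[float, float, float]:
        """Scores ×100, as conventionally reported."""
        return (100 * self.rouge1, 100 * self.rouge2, 100 * self.rougeL)


def serialize_definition(o: Ontology, d: LogicalDefinition) -> str:
    """Render a definition as one sentence.

    Pairs are flattened across groups, separated by commas, and terminated
    with a period.  Attribute names are rendered without their semantic tag
    ("Is a", "Has active ingredient"), values as full FSNs.  Is-a pairs come
    first, then attribute pairs, each block sorted by attribute then value
    id, so serialization is deterministic.
    """
    if not d:
        raise ValueError("cannot serialize an empty definition")
    pairs = sorted(
        {p for g in d for p in g},
        key=lambda p: (p.attribute != o.is_a, p.attribute, p.value),
    )
    phrases = []
    for p in pairs:
        if p.attribute not in o.concepts or p.value not in o.concepts:
            raise KeyError(f"unresolvable id in pair ({p.attribute!r}, {p.value!r})")
        phrases.append(f"{o.concepts[p.attribute].name} {o.fsn(p.value)}")
    return ", ".join(phrases) + "."


def build_instances(o: Ontology, concept_ids: Sequence[str] | None = None) -> list[NamingInstance]:
    """One instance per concept with a non-empty own definition."""
    ids = list(concept_ids) if concept_ids is not None else sorted(o.concepts)
    out = []
    for c in ids:
        d = o.own_groups(c)
        if d:
            out.append(NamingInstance(c, serialize_definition(o, d), o.fsn(c)))
    return out


def split_dataset(
    concept_ids: Sequence[str],
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[list[str], list[str], list[str]]:
    """Shuffled train/validation/test split with floor-sized tail sets.

    ``|valid| = floor(ratios[1]·N)``, ``|test| = floor(ratios[2]·N)``, and
    the training set absorbs the rounding remainder, so N = 361,461 at
    80/10/10 yields 289,169 / 36,146 / 36,146.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    ids = list(concept_ids)
    n = len(ids)
    if n < 10:
        raise ValueError(f"need at least 10 concepts to split, got {n}")
    random.Random(seed).shuffle(ids)
    n_valid = floor(ratios[1] * n)
    n_test = floor(ratios[2] * n)
    n_train = n - n_valid - n_test
    return ids[:n_train], ids[n_train : n_train + n_valid], ids[n_train + n_valid :]


_TOKEN = re.compile(r"[a-z0-9]+")


def tokenize(text: str) -> list[str]:
    """Lowercase alphanumeric tokens; parentheses and punctuation stripped."""
    return _TOKEN.findall(text.lower())


def _ngrams(tokens: Sequence[str], n: int) -> Counter:
    return Counter(tuple(tokens[i : i + n]) for i in range(len(tokens) - n + 1))


def rouge_n(candidate: str, references: Sequence[str], n: int = 1) -> float:
    """Clipped n-gram recall of ``candidate`` against ``references``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    cand = _ngrams(tokenize(candidate), n)
    match = total = 0
    for ref in references:
        ref_counts = _ngrams(tokenize(ref), n)
        total += sum(ref_counts.values())
        match += sum(min(c, cand[g]) for g, c in ref_counts.items())
    return match / total if total else 0.0


def _lcs_len(a: Sequence[str], b: Sequence[str]) -> int:
    # O(|a|·|b|) dynamic programme, single-row
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    for x in a:
        cur = [0]
        for j, y in enumerate(b, 1):
            cur.append(prev[j - 1] + 1 if x == y else max(prev[j], cur[j - 1]))
        prev = cur
    return prev[-1]


def rouge_l(candidate: str, references: Sequence[str]) -> float:
    """LCS-based recall: total LCS length over total reference length."""
    cand = tokenize(candidate)
    match = total = 0
    for ref in references:
        ref_toks = tokenize(ref)
        total += len(ref_toks)
        match += _lcs_len(cand, ref_toks)
    return match / total if total else 0.0


Namer = Callable[[str], str]
Normalizer = Callable[[str], tuple]


@dataclass
class NamerEvaluation:
    rouge: RougeScores
    exact: int
    n: int
    failures: list[tuple[str, str]]  # (concept id, error message)


def evaluate_namer(
    namer: Namer,
    instances: Sequence[NamingInstance],
    normalizer: Normalizer | None = None,
) -> NamerEvaluation:
    """Score a namer on instances: mean per-instance ROUGE plus exact matches.

    Exact matching compares names under ``normalizer`` (defaulting to the
    validation module's ontology-free normalization, tag included).  A namer
    exception on an instance is recorded and that instance scores zero.
    """
    if normalizer is None:
        from .validation import normalize_name

        normalizer = lambda s: (tuple(normalize_name(s).tokens), normalize_name(s).tag)
    r1s, r2s, rls = [], [], []
    exact = 0
    failures: list[tuple[str, str]] = []
    for inst in instances:
        try:
            predicted = namer(inst.source_text)
        except Exception as exc:  # namer contract: failures are survivable
            failures.append((inst.concept, str(exc)))
            r1s.append(0.0)
            r2s.append(0.0)
            rls.append(0.0)
            continue
        refs = [inst.target_text]
        r1s.append(rouge_n(predicted, refs, 1))
        r2s.append(rouge_n(predicted, refs, 2))
        rls.append(rouge_l(predicted, refs))
        if normalizer(predicted) == normalizer(inst.target_text):
            exact += 1
    n = len(instances)
    mean = lambda xs: sum(xs) / len(xs) if xs else 0.0
    return NamerEvaluation(
        rouge=RougeScores(mean(r1s), mean(r2s), mean(rls)),
        exact=exact,
        n=n,
        failures=failures,
    )


def instances_tsv(instances: Sequence[NamingInstance]) -> str:
    lines = ["source_text\ttarget_text"]
    lines += [f"{i.source_text}\t{i.target_text}" for i in instances]
    return "\n".join(lines) + "\n"


class TemplateNamer:
    """Baseline namer: echoes the first is-a value's FSN.

    A transformer namer (the production route: a pre-trained abstractive
    summarizer fine-tuned on definition sentences, AdamW, learning rate
    5e-5, inputs capped at 1024 tokens) plugs into the same text→text
    contract; this baseline keeps the pipeline runnable anywhere.
    """

    def __init__(self, is_a_name: str = "Is a"):
        self.prefix = is_a_name + " "

    def __call__(self, source_text: str) -> str:
        body = source_text.rstrip(".")
        for phrase in body.split(", "):
            if phrase.startswith(self.prefix):
                return phrase[len(self.prefix) :]
        return body.split(", ")[0]
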