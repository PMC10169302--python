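"""Validate a proposed concept name against three external resources.

The same normalization pipeline (whitespace, case, lemmatization,
synonym-to-preferred-term, stop words) runs on both sides of every match:
a lexicon of atoms (AUI/CUI/source/string), base noun phrases chunked from
document titles/abstracts (whole-phrase matches only), and a newer release
of the terminology (by name and/or by logical definition).
"""

from ontogap import build_np_index, match_lexicon, normalize_name, search_np
from ontogap.validation import LexiconAtom

fsn = "Cutaneous infection (disorder)"
print(f"proposed name: {fsn}")
print(f"normalized:    {normalize_name(fsn).tokens} tag={normalize_name(fsn).tag!r}")

lexicon = [
    LexiconAtom("A24682086", "C1853193", "HPO", "Cutaneous infections"),
    LexiconAtom("A0427003", "C0022658", "MSH", "Kidney Disease"),
]
hits = match_lexicon(fsn, lexicon)
print(f"\nlexicon matches (plural folded by lemmatization): {hits}")

docs = [
    ("20072857", "Lung cysts following pulmonary artery operations", ""),
    ("999", "", "The fetal thoracic artery was examined."),
]
index = build_np_index(docs)
print("\ncorpus matches:")
print("  'Pulmonary artery operation (procedure)' ->",
      search_np(index, "Pulmonary artery operation (procedure)"))
print("  'thoracic artery' ->", search_np(index, "thoracic artery"),
      "(substring of a longer phrase: correctly no match)")
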