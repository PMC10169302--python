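# ontogap

Logical-definition-based identification, naming, and validation of potential
**missing concepts** in SNOMED CT-style terminologies.

Large clinical terminologies inevitably lack concepts their structure
implies.  `ontogap` finds them from the terminology's own logic, for
ontology curators and quality-assurance researchers:

1. **Audit** — detect *non-lattice subgraphs*: a pair of concepts sharing
   more than one maximal common descendant (MCD) violates the lattice
   property and frequently marks a defect.  The subgraph spans the minimal
   common ancestors (MCAs) of those MCDs and everything on paths between.
2. **Propose** — for each *candidate pair* (A, B) in a subgraph
   (hierarchically unrelated, both fully defined, both at level ≥ 10),
   intersect their **derived logical definitions**.  A concept's logical
   definition is a set of attribute groups G = {(r, v), …}, with each is-a
   parent in its own singleton group; the derived definition adds every
   group that is *more general*, where (r₂, v₂) ≥ (r₁, v₁) iff
   r₁ = r₂ ∧ v₁ ⊑ v₂, or r₁ ⊑ r₂ ∧ v₁ = v₂, or r₁ ⊑ r₂ ∧ v₁ ⊑ v₂, or a
   property chain rₐ ∘ r_b ⊑ r₂ applies through a pair (r_b, v₂) in v₁'s
   definition.  The reduced intersection is the least common generalization
   of A and B — the logical definition a missing shared parent would carry.
   Definitions already present are suppressed; duplicates are merged.
3. **Name** — each definition serializes to one sentence
   (`"Is a …, Finding site …."`) for any text→text namer (e.g. a fine-tuned
   abstractive summarizer); predicted names are scored with ROUGE-1/2/L
   (clipped n-gram / LCS recall) and normalized exact matching.
4. **Validate** — proposed names are normalized (whitespace, case,
   lemmatization, synonym→preferred-term, stop words) and matched against a
   UMLS-style atom lexicon, base noun phrases of a document corpus
   (whole-phrase only), and a newer terminology release (by FSN and/or
   definition; a semantic-tag-only difference does not validate).

Inputs are RF2 snapshots (`load_rf2`), a simple TSV fixture dialect
(`load_fixture`), or generated terminologies (`ontogap.synthetic`), which
also plant removable concepts with guaranteed recoverability for testing.

## Worked example

`python examples/propose_missing.py` generates a 50-concept terminology,
removes a planted concept M, and runs the full pipeline on both variants:

```
pruned (M removed): 2 subgraphs, 1 candidates, 1 proposal(s)
proposal from (plant_A0, plant_B0):
0	{(Is a, "Concept 31 (procedure)")}
1	{(Planted attribute 0, "Planted site 0 (body structure)")}
-> identical to the removed concept's definition

full (M present): 2 subgraphs, 1 candidates, 0 proposal(s)
```

The pruned run recovers M's exact logical definition — an is-a group naming
its parent plus its defining attribute group — from the candidate pair's
intersection alone; the full run suppresses the same definition because a
concept carrying it already exists.  The other examples audit the packaged
vulval-neoplasm fixture (one subgraph of size 6 with two MCDs),
build naming data and score a baseline namer, and demonstrate the three
validation matchers.

The same stages run from the shell:

```sh
ontogap fixtures fx/                    # write packaged example fixtures
ontogap audit   --ontology fx/vulva      # 1 non-lattice subgraphs
ontogap propose --ontology fx/vulva      # subgraphs -> candidates -> proposals
ontogap name-data --ontology fx/vulva    # naming TSVs + 80/10/10 splits
ontogap validate --ontology fx/vulva ... # lexicon / corpus / newer release
```

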