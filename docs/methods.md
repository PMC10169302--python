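# Methods

## The model

An EL-style terminology is a rooted is-a DAG over concepts plus, per
concept, a set of *attribute groups*: each group a non-empty set of
(attribute, value) pairs whose attribute and value are themselves concept
identifiers.  Attributes live in the same DAG (SNOMED CT models them as
concepts under a model-attribute branch), so a single subsumption relation
serves concepts, attributes, and values.  Under the grouping convention
used throughout, every is-a parent contributes a singleton group
`{(is-a, parent)}`; a concept's *own logical definition* is those singleton
groups plus its defining attribute groups.  Only active components and the
inferred (not stated) relationship view are loaded from RF2.

### Generality

A pair (r₂, v₂) is **strictly more general** than (r₁, v₁) when one of four
conditions holds: equal attributes with v₁ ⊑ v₂; r₁ ⊑ r₂ with equal values;
r₁ ⊑ r₂ and v₁ ⊑ v₂; or v₁'s own definition carries a pair (r_b, v₂) such
that a property-chain axiom rₐ ∘ r_b ⊑ r₂ exists with r₁ = rₐ or r₁ ⊑ rₐ.
⊑ is strict subsumption; "same or more general" adds equality explicitly.
Condition 4 consults the value's *own* groups, not its closure; chained
modifications compose only through repeated rewriting, capped by
`chain_depth` (default 3 iterations; conditions 1–3 are already complete
after one step because is-a is transitive).  Transitivity is never assumed
across condition 4: all generality queries are computed directly.

A group G₂ is strictly more general than G₁ ≠ G₂ when every pair of G₂ is
same-or-more-general than some pair of G₁.  Consequently a group with
*fewer*, more general pairs is more general — dropping a conjunct loosens a
definition — and the derived definition of a concept is the (astronomically
large) family of all groups subsuming one of its own groups.

### Reduction

`reduce_definition` first normalizes each group by dropping pairs strictly
more general than a sibling pair (they are implied by the conjunction),
which also unifies the one systematic mutual-generality case ({p} versus
{p, q} with q above p); it then removes every group that is strictly more
general than another group in the normalized set and not also more specific
than it.  Testing against the full set makes the result independent of
processing order, and a canonical-minimum guard keeps the result non-empty
should a pathological condition-4 generality cycle ever empty it.
Reduction is idempotent.

### Intersection as least common generalization

The definition proposed for a candidate pair (A, B) is the reduced
intersection of their derived definitions.  Materializing closures is
intractable, so `intersect_derived` computes, for every own-group pair
(g_a, g_b), the set P of pairs same-or-more-general than a pair of g_a
*and* of g_b, keeps P's most specific elements as one candidate group, and
reduces the collection.  Every common group subsumes one of these minimal
groups, so the result equals closure-intersection-then-reduce; the bounded
materialization (`derived_groups`, non-empty subsets of each own group's
generalization universe) is retained purely as the exhaustive oracle and
refuses universes beyond `max_universe` pairs.  A minimal common
generalization may legitimately hold several pairs — several incomparable
minimal common ancestors of the values, precisely the non-lattice
situation — and all minima are kept in one group.

Intersections always share near-root structure (everything is a
`Concept`), so a **generality ceiling** drops result groups whose every
value lies within `generality_ceiling` levels of the root (default 2).
This extends the spirit of the level threshold below to the result side;
without it every candidate pair would yield a vacuous `{(is-a, root)}`
proposal.  An intersection emptied by the ceiling is reported as empty and
dropped with a counter, not an error.

### Non-lattice subgraphs and candidates

Common-descendant and common-ancestor sets are computed over the
*reflexive* subsumption closure (lattice meet/join semantics): for a
parent/child pair the child itself is the unique maximal common
descendant.  With the strict closure every such pair in a plain tree would
count as non-lattice, which contradicts the motivation.  The public
`ancestors`/`descendants` queries remain strict.

A non-lattice pair shares > 1 maximal common descendant or > 1 minimal
common ancestor.  Subgraph extraction follows the MCD route: MCDs of the
seed pair, then the MCAs of those MCDs, then all concepts and is-a edges on
MCA→MCD paths; size = concept count.  Enumeration seeds only pairs sharing
≥ 2 MCDs (collected from per-concept ancestor sets rather than all O(n²)
pairs) and deduplicates by frozen concept set.  The size threshold
(`max_subgraph_size`, default 10) is inclusive by default; a strict-<
variant is a flag.

Candidate pairs within a subgraph must be hierarchically unrelated, both
fully defined, and both at longest-path level ≥ `min_level` (default 10,
keeping very general concepts out).  Pairs recurring across overlapping
subgraphs are kept once with full provenance.

### Proposal, suppression, deduplication

Each candidate's reduced intersection becomes a potential missing concept
unless empty or equal (order-insensitively, after reduction) to the own
definition of *any* existing concept — primitive concepts included, a
deliberately conservative suppression.  Proposals with equal definitions
merge, concatenating provenance.  The proposal list is canonically sorted
and independent of candidate order.

## Naming

Definitions serialize to one sentence: pairs flattened across groups,
rendered `"AttributeName ValueFSN"`, comma-separated, period-terminated;
attribute names lose their semantic tag; is-a pairs come first, then
attribute pairs, each sorted by attribute then value id (a canonical
order makes serialization deterministic and injective wherever definitions are discriminating — sibling primitives
sharing one parent legitimately collide).  Group boundaries are flattened,
matching the conventional serialized rendering.

`split_dataset` shuffles ids with a seeded RNG; validation and test take
⌊ratio·N⌋ each and training absorbs the remainder, so 361,461 concepts at
80/10/10 split 289,169 / 36,146 / 36,146.

ROUGE-N is clipped n-gram recall — matches between candidate and reference
counts, clipped per reference, divided by total reference n-grams — and
ROUGE-L the analogous LCS recall (sum of LCS lengths over references /
total reference tokens; the multi-reference form is this package's choice,
mirroring the recall form).  Tokenization for scoring: lowercase, split on
non-alphanumerics, parentheses stripped.  Namers are arbitrary text→text
callables; the packaged `TemplateNamer` (echo the first is-a value) is a
floor baseline that keeps the pipeline runnable without GPU-scale
dependencies — fine-tuning an abstractive summarizer (AdamW, lr 5e-5,
inputs ≤ 1024 tokens, best checkpoint by validation loss) plugs into the
same contract and is out of the package's scope.  A namer exception scores
that instance 0 and is recorded; the run continues.

## Name normalization and validation

Pipeline order (fixed): split off the
semantic tag → collapse whitespace → lowercase → lemmatize → replace
synonyms with the owning concept's preferred term → remove stop words.
The lemmatizer is a pluggable token→lemma callable; the default is a
conservative rule-based English plural folder (irregulars table + suffix
rules), iterated to a fixpoint so normalization is idempotent.  Synonym
replacement scans longest-first, left-to-right, and repeats to a fixpoint
(bounded) so chained synonym→preferred mappings cannot break idempotence.
The stop-word list is small, packaged, and overridable.

Lexicon matching compares normalized token sequences exactly, tag ignored.
Corpus matching indexes every base noun phrase (pluggable chunker; the
default is a heuristic splitter on punctuation and function words — a
linguistic chunker is strictly better and drops in via the same contract)
under its normalized key; only whole-phrase equality matches, so a name
inside a longer phrase does not validate.  Newer-release matching compares
normalized FSN (tag *included*) and/or reduced definitions over the shared
id space; kinds are fsn+definition, fsn_only, definition_only, and
tag_differs, the last recorded but never counted as validated.  A
documented limitation: derivational variants ("fistula of sclera" versus
"scleral fistula") normalize differently and are missed.

## Synthetic data

`random_ontology(n, seed, …)` emulates the structural features the method
consumes: a rooted is-a DAG with 1–2 parents per concept, a small attribute
hierarchy (occasionally nested, so attribute-subtype generality fires),
1–2 attribute groups of 1–2 pairs on ~60% of concepts, ~50% fully defined,
and optional property chains.  It does not emulate realistic term
distributions, semantic-tag inventories, subhierarchy sizes, or
SNOMED-scale density; passing tests demonstrate the algorithms' contracts,
not real-release yield rates.

`plant_missing_concept` is constructive by design: it grafts a fresh
unrelated fully defined pair (A, B) under a shared anchor deep enough to
clear `min_level` (padding chains are added if the host is too shallow),
gives A and B attribute values sharing a unique common parent placed below
the generality ceiling, and adds two primitive common children so (A, B)
forms a non-lattice pair of size 4.  The truth definition is *computed* by
running the intersection on the pruned ontology, checked for
identifiability (no existing concept carries it) and representability
(is-a pairs only in singleton groups), and the full variant adds M with
exactly that definition.  Construction — rather than searching for natural
plantable sites — is what guarantees 100% recovery at every seed.  Fresh
planted identifiers are namespaced (`plant_*`) and never collide with
generated ones.

## Numerical and procedural choices

- Longest-path levels are computed by one topological-order pass and
  memoized; level(root) = 0.
- Pair-generalization closures are cached per ontology and depth.
- Deduplication keys (subgraph concept sets, canonical candidate order,
  sorted definition keys) make every stage's output independent of
  iteration order; pipeline outputs are byte-identical across runs for a
  fixed (config, seed).
- RF2 group 0 holds ungrouped attributes; each group-0 row becomes its own
  singleton group by default (`merge_group0` merges them instead — the
  grouping convention's treatment of ungrouped rows is genuinely open).
- RF2 preferred terms: the first active synonym in file order stands in for
  full language-refset acceptability, which is out of scope; the fixture
  dialect carries preferred terms explicitly.
- Property chains come from a `chains.tsv` side table always, and
  best-effort from an OWL-expression refset (`SubObjectPropertyOf(
  ObjectPropertyChain(:a :b) :c)` patterns) when present.

## Known limitations

- Conditions 1–3 are complete and transitive; condition 4 composes only by
  repeated application up to `chain_depth`, and the exhaustive oracle is
  only consulted on chain-free or single-step instances where the
  single-application relation and the closure coincide.
- The exhaustive closure oracle is exponential in the generalization
  universe and refuses instances beyond `max_universe` pairs; it exists to
  validate `intersect_derived` on small inputs, never for production use.
- The heuristic noun-phrase chunker over-segments on unusual syntax; for
  real corpus validation substitute a parser-backed chunker.
- No description-logic classification is performed: subsumption is the
  asserted/inferred is-a graph, stated OWL semantics and concrete domains
  are out of scope, and proposals are reported for curator review, never
  auto-inserted.
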