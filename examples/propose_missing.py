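"""Recover a deliberately removed concept from hierarchy structure alone.

A random terminology is generated, a fully defined concept M is planted and
then removed (its children re-parented), and the proposal pipeline is run:
non-lattice subgraphs → candidate pairs → intersection of derived logical
definitions.  The recovered proposal's definition equals M's exactly; on the
un-pruned terminology the same definition is suppressed because M exists.
"""

from ontogap import enumerate_subgraphs, generate_candidates, propose, random_ontology
from ontogap.missing import render_definition
from ontogap.synthetic import plant_missing_concept

base = random_ontology(50, seed=7)
res = plant_missing_concept(base, seed=7, min_level=10)
(pair, truth_definition), = res.truth

for label, ontology in (("pruned (M removed)", res.pruned), ("full (M present)", res.full)):
    subgraphs = enumerate_subgraphs(ontology, max_size=10)
    candidates = generate_candidates(ontology, subgraphs, min_level=10)
    proposals = propose(ontology, candidates)
    print(f"\n{label}: {len(subgraphs)} subgraphs, {len(candidates)} candidates, "
          f"{len(proposals)} proposal(s)")
    for p in proposals:
        provenance = ", ".join(f"({c.a}, {c.b})" for c in p.provenance)
        print(f"proposal from {provenance}:")
        print(render_definition(ontology, p.definition))
        if p.definition == truth_definition:
            print("-> identical to the removed concept's definition")
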