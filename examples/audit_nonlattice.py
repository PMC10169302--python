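"""Detect non-lattice subgraphs in a small terminology.

Builds the packaged vulval-neoplasm fixture, finds every non-lattice
subgraph up to 10 concepts, and prints the structure of each: the seed
pair, its maximal common descendants (MCDs), and the minimal common
ancestors (MCAs) that bound the subgraph.  More than one MCD for a pair is
the structural anomaly that signals a possible missing concept.
"""

from ontogap import enumerate_subgraphs, make_vulva_fixture

ontology = make_vulva_fixture()
subgraphs = enumerate_subgraphs(ontology, max_size=10)

print(f"{len(subgraphs)} non-lattice subgraph(s) of size <= 10 in {len(ontology)} concepts")
for sg in subgraphs:
    a, b = sg.seed_pair
    print(f"\nseed pair: {ontology.fsn(a)}  /  {ontology.fsn(b)}")
    print(f"size: {sg.size} concepts")
    print("maximal common descendants:")
    for c in sorted(sg.mcds):
        print(f"  - {ontology.fsn(c)}")
    print("minimal common ancestors:")
    for c in sorted(sg.mcas):
        print(f"  - {ontology.fsn(c)}")
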