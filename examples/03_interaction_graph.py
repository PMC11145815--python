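"""Build the spatial interaction graph of a complex and summarize it.

Nodes are heavy atoms (ligand + pocket); covalent edges carry the bond
order; non-covalent edges connect every atom pair within 4.5 Angstrom.
Each node carries a 19-dim feature (element/degree one-hots, formal
charge, ligand flag).
"""

from collections import Counter

from deeplip import GraphConfig, SyntheticSpec, build_complex_graph, generate_dataset

(sample,), _ = generate_dataset(SyntheticSpec(n_samples=1, seed=9))

for threshold in (3.0, 4.5, 6.0):
    g = build_complex_graph(sample, GraphConfig(distance_threshold=threshold))
    by_type = Counter(t for _, _, t, _ in g.edges)
    print(f"threshold {threshold} A: {g.n_nodes} nodes "
          f"({int(g.ligand_mask.sum())} ligand), "
          f"{len(g.edges)} directed edges -> {dict(by_type)}")
# Covalent edge counts are threshold-independent; the non-covalent count
# grows monotonically with the distance cutoff, which is what the graph
# stage of the model propagates messages over.
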