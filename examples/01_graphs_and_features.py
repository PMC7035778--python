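"""Build the directed chemical graph of caffeine and inspect its features.

Each bond becomes two opposed directed edges, so 15 bonds give 30 edges;
atom vectors are 139-bit one-hot blocks, bond vectors 11 bits.
"""

import molmpn as m

graph = m.mol_to_graph("CN1C=NC2=C1C(=O)N(C)C(=O)N2C")
print(f"caffeine: {graph.n_atoms} heavy atoms, {graph.n_bonds} bonds, "
      f"{graph.n_edges} directed edges")
print(f"atom feature matrix {graph.atom_features.shape}, "
      f"edge feature matrix {graph.edge_features.shape}")
e = 0
print(f"edge {e}: atom {graph.edge_source[e]} -> atom {graph.edge_target[e]}, "
      f"reverse edge {graph.edge2revedge[e]}")
# the reverse of the reverse is the edge itself — a fixed-point-free involution
assert graph.edge2revedge[graph.edge2revedge[e]] == e
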