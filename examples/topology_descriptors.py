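"""Describing classifier topologies as networks.

Parses two topology strings — a perceptron with one hidden layer and a
linear network — builds their layered graphs and prints both this package's
computed descriptors and, for registry entries, the fixture values printed
by the original MI-NODES tool (which used an undocumented convention; the
two are deliberately kept side by side, never merged).
"""

import numpy as np

from netnet import parse_topology, reference_registry, topology_graph

for spec in ("MLP 18:18-8-1:1", "LNN 16:16-1:1"):
    topo = parse_topology(spec)
    graph = topology_graph(topo)
    print(f"{topo.name}: layers {topo.layer_sizes}, "
          f"{graph.n} neurons, {graph.n_edges} connections")
    print("  computed annSh_k:", np.round(topo.descriptors, 4))

print()
print("registry fixture values (MI-NODES convention):")
for topo in reference_registry():
    print(f"  {topo.name:22s} AUROC {topo.auroc}  Sh_k {topo.printed_descriptors}")
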