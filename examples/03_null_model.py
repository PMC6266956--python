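"""Contrast the real network's APCC structure with a degree-preserving null.

In the real co-expression network the hub APCC distribution is trimodal
(party / date / fight-club hubs); shuffling edges while preserving every
node's degree destroys the anti-correlated periphery, leaving a single
low-positive peak and no switch genes.
"""

import swimnet as sw
from swimnet.cartography import histogram_modes
from swimnet.synthetic import SimulationConfig, generate_expression

matrix, _ = generate_expression(SimulationConfig(seed=1))
deg = sw.differential_expression(matrix, 1.5, 0.05)
sub = matrix.subset_genes(deg["gene_id"])
net = sw.build_network(sw.correlation_matrix(sub), 0.71)
part = sw.kmeans_partition(sub.values, 3, replicates=100, seed=1)

for label, graph in [("observed", net), ("randomized", sw.degree_preserving_randomization(net, seed=0))]:
    cart = sw.build_cartography(graph, part)
    hubs = cart[cart["hub_class"].isin(["date", "party", "fight-club"])]
    modes = histogram_modes(hubs["apcc"])
    n_switch = int(cart["is_switch"].sum())
    print(f"{label:>11}: {len(modes)} APCC mode(s) at {[round(m, 2) for m in modes]}, "
          f"{n_switch} switch genes")

print(
    "\nThe negative mode (the fight-club hubs, i.e. the planted regulators) "
    "exists only in the observed network: anti-correlated hubs are a real "
    "feature of the data, not a by-product of its degree sequence."
)
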