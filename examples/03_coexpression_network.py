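"""Build a weighted co-expression network and score subgenome hub bias.

Simulates latent-factor modules whose planted hubs are drawn mostly from
subgenome A, runs bicor -> signed-hybrid adjacency -> unsigned TOM ->
module detection -> KME hubs, and summarises hubs and top-100-neighbour
composition per subgenome.
"""

import numpy as np
import pandas as pd

import polybias as pb

expr, truth = pb.simulate_modules(
    n_genes=400, n_modules=3,
    hub_subgenome_weights={"A": 0.7, "B": 0.15, "C": 0.15},
    noise_sd=0.6, seed=11, hub_quantile=0.7, loading_range=(0.4, 1.6),
)
x = expr.data.to_numpy()
net = pb.build_network(x, power=6, kme_threshold=0.9)

n_modules = len(set(net.labels) - {0})
print(f"detected {n_modules} modules over {len(net.gene_ids)} genes "
      f"(soft power {net.power}); {int(net.hubs.sum())} hub genes with KME > 0.9")

subs = pd.Series([truth.gene_subgenome[g] for g in expr.genes], index=expr.genes)
planted = np.array([truth.hub_flags[g] for g in expr.genes])
print("planted hub labels:", subs[planted].value_counts().to_dict())
print("detected hub labels:", subs[net.hubs].value_counts().to_dict())

comp = pb.neighbor_composition(net.tom, subs.to_numpy(), gene_ids=list(expr.genes), k=100)
print("mean intra-subgenome share of each gene's top-100 neighbours (%):")
print(comp.groupby("subgenome")["pct_intra"].mean().round(1).to_string())

print(f"\nplanted-hub sensitivity: {100 * net.hubs[planted].mean():.0f}%")
print("Overrepresentation of one subgenome among hubs is the network-level")
print("signature of subgenome expression dominance.")
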