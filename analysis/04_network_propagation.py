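"""Propagate DEG seed influence over the gene network by RWR.

Expected outcome: power iteration converges to the direct linear solve;
genes at network distance 1 from the amplicon concentrate near the top of
the cascade ranking.
"""

import numpy as np

from stemcnv.network_propagation import GeneNetwork, rwr, select_cascade
from _study import outdir, reference_study

cfg, gm, net, truth = reference_study()
out = outdir("propagation")

network = GeneNetwork(net)
seeds_path = outdir("bulk_deg") / "seeds_up.txt"
if seeds_path.exists():
    seeds = seeds_path.read_text().split()
else:  # standalone fallback: the planted amplicon genes
    seeds = truth.cnv_genes
res = rwr(network, seeds, r=0.5)
print(f"RWR over {len(network.nodes)} genes, {len(seeds)} seeds: "
      f"converged in {res.iterations} iterations (residual {res.residual:.1e})")

for k in (50, 150):
    cascade = select_cascade(res, k=k)
    cascade.to_csv(out / f"cascade_top{k}.tsv", sep="\t", index=False)
    d1 = sum(truth.cascade_distance.get(g, 99) == 1 for g in cascade["gene"])
    print(f"top {k} cascade: {d1} of the "
          f"{sum(1 for d in truth.cascade_distance.values() if d == 1)} "
          f"distance-1 neighbours of the amplicon included")

ranked = select_cascade(res, k=len(network.nodes))
rank = {g: i for i, g in enumerate(ranked["gene"])}
near = [rank[g] for g, d in truth.cascade_distance.items() if d == 1 and g in rank]
far = [rank[g] for g in rank if truth.cascade_distance.get(g, 99) >= 3]
print(f"median rank: distance-1 genes {int(np.median(near))}, "
      f"distance>=3 genes {int(np.median(far))} (lower is more influenced)")
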