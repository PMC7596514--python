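"""Bulk differential expression: RLE normalization, NB Wald test, VST.

Expected outcome: the amplicon genes cluster around the dosage log2FC of
log2(3/2) = 0.585; the headline partition (|log2FC| >= 0.3, FDR < 0.05) is
dominated by planted genes; the looser raw-p seed rule yields the up/down
seed lists for network propagation.
"""

import numpy as np

import stemcnv.bulk_expression as be
import stemcnv.synthetic_data as sd
from _study import outdir, reference_study

cfg, gm, net, truth = reference_study()
out = outdir("bulk_deg")

counts, groups = sd.simulate_bulk_counts(cfg, truth, gm)
counts = be.prefilter_genes(counts)
sf = be.rle_size_factors(counts)
res = be.nb_wald_test(counts, groups, size_factors=sf)
headline = be.classify_deg(res, lfc_thresh=0.3, fdr=0.05)
seeds = be.classify_deg(res, lfc_thresh=0.3, use_raw_p=True)
v = be.vst(counts, size_factors=sf, groups=groups)
dist = be.sample_distances(v)

headline.to_csv(out / "deg_table.tsv", sep="\t")
v.to_csv(out / "vst_matrix.tsv", sep="\t")
dist.distances.to_csv(out / "sample_distances.tsv", sep="\t")
seed_lists = {d: sorted(seeds.index[seeds["direction"] == d]) for d in ("up", "down")}
for d, genes in seed_lists.items():
    (out / f"seeds_{d}.txt").write_text("\n".join(genes) + "\n")

print(f"tested {int(res['tested'].sum())} genes; size factors "
      f"{sf.min():.3f}-{sf.max():.3f}")
cnv_lfc = res.loc[truth.cnv_genes, "log2fc"]
print(f"amplicon genes: mean log2FC {cnv_lfc.mean():.3f} "
      f"(dosage truth {cfg.dosage_log2fc:.3f})")
print(f"headline DEGs (|lfc|>=0.3, q<0.05): "
      f"{int((headline['direction'] == 'up').sum())} up, "
      f"{int((headline['direction'] == 'down').sum())} down")
print(f"propagation seeds (p<0.055): {len(seed_lists['up'])} up, "
      f"{len(seed_lists['down'])} down")
print(f"PCA PC1 variance ratio: {dist.explained_variance_ratio[0]:.2f}")
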