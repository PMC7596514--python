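"""Generate the reference synthetic isogenic study and write its inputs.

A single-copy gain of a 1.5 Mb amplicon (copy number 3 vs 2) is planted in
the case lines: CNV calls on three platforms, bulk RNA-seq counts with the
dosage effect and its network-attenuated cascade, two single-cell lines
with a shifted cluster, a lineage signature panel with skewed expression,
and triplicate qPCR Ct tables.  The planted truth is saved alongside.
"""

import json

import networkx as nx

import stemcnv.synthetic_data as sd
from _study import outdir, reference_study

cfg, gm, net, truth = reference_study()
out = outdir("study")

calls = sd.simulate_platform_calls(cfg, truth)
bulk, groups = sd.simulate_bulk_counts(cfg, truth, gm)
panel, ter, ter_groups, ct = sd.simulate_panel_and_qpcr(cfg, truth, gm)

gm.to_csv(out / "gene_model.bed", sep="\t", index=False, header=False)
nx.to_pandas_edgelist(net).to_csv(out / "network_edges.tsv", sep="\t", index=False)
calls.to_csv(out / "cnv_calls.tsv", sep="\t", index=False)
bulk.to_csv(out / "bulk_counts.tsv", sep="\t")
groups.to_csv(out / "bulk_groups.tsv", sep="\t")
panel.to_csv(out / "panel.tsv", sep="\t", index=False)
ter.to_csv(out / "teratoma_counts.tsv", sep="\t")
ct.to_csv(out / "ct_table.tsv", sep="\t", index=False)
(out / "truth.json").write_text(json.dumps({
    "cnv_genes": truth.cnv_genes,
    "cascade_log2fc": truth.cascade_log2fc,
    "sc_control_proportions": truth.sc_control_proportions,
    "sc_case_proportions": truth.sc_case_proportions,
    "panel_direction": truth.panel_direction,
}, indent=2, sort_keys=True) + "\n")

print(f"genes: {len(gm)} on {gm['chrom'].nunique()} chromosomes")
print(f"amplicon {cfg.cnv_chrom}:{cfg.cnv_start:,}-{cfg.cnv_end:,} "
      f"contains {len(truth.cnv_genes)} genes: {', '.join(truth.cnv_genes)}")
print(f"cascade truth: {len(truth.cascade_log2fc) - len(truth.cnv_genes)} "
      f"genes within distance {cfg.cascade_max_distance} of the amplicon")
print(f"CNV calls: {len(calls)} rows ({int((calls['origin'] == 'planted').sum())} "
      f"planted, {int((calls['origin'] != 'planted').sum())} decoys)")
print(f"bulk counts: {bulk.shape[0]} genes x {bulk.shape[1]} samples")
print(f"outputs under {out}")
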