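"""Single-cell heterogeneity of the two embryoid-body lines.

QC, normalization, integration, SNN/Jaccard clustering, and the per-line
cluster-proportion comparison.  Expected outcome: clusters match the
planted programs (ARI ~1) and the shifted cluster's case-minus-control
proportion difference recovers the planted +0.20.
"""

import anndata as ad
import numpy as np
import pandas as pd

import stemcnv.sc_heterogeneity as sch
import stemcnv.synthetic_data as sd
from stemcnv.pipeline import _planted_shift_estimate
from _study import outdir, reference_study

cfg, gm, net, truth = reference_study()
out = outdir("sc_heterogeneity")

adatas = sd.simulate_sc_counts(cfg, truth, gm)
processed = []
for line in ("control", "case"):
    filt, rep = sch.qc_filter(adatas[line])
    print(f"{line}: {rep['input_cells']} cells -> {rep['output_cells']} after QC "
          f"(low-feature {rep['removed_low_features']}, "
          f"high-mito {rep['removed_high_mito']})")
    processed.append(sch.normalize_log(filt))

joint = sch.integrate(processed, n_hvg=500, n_pcs=20, seed=cfg.seed)
labels = sch.cluster_snn(joint.obsm["X_pca"], k_neighbors=20, seed=cfg.seed)
from sklearn.metrics import adjusted_rand_score
ari = adjusted_rand_score(joint.obs["true_cluster"], labels)
print(f"{len(np.unique(labels))} clusters; ARI vs planted labels {ari:.2f}")

props = sch.cluster_proportions(labels, joint.obs["line"].to_numpy())
props.to_csv(out / "proportions.tsv", sep="\t", index=False)
wide = props.pivot(index="cluster", columns="sample", values="fraction")
print("cluster fractions (control vs case):")
for c in wide.index:
    print(f"  cluster {c}: {wide.loc[c, 'control']:.3f} vs {wide.loc[c, 'case']:.3f}")

est = _planted_shift_estimate(
    labels, joint.obs["line"].to_numpy(), joint.obs["true_cluster"].to_numpy(),
    cfg.sc_shift_cluster,
)
true = (truth.sc_case_proportions[cfg.sc_shift_cluster]
        - truth.sc_control_proportions[cfg.sc_shift_cluster])
print(f"planted shift {true:+.2f}, estimated {est:+.3f}")

markers = sch.cluster_markers(ad.concat(processed, join="inner"), labels)
markers.to_csv(out / "markers.tsv", sep="\t", index=False)
print(f"{len(markers)} cluster markers at adj p<=0.05, logFC>=0.1")
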