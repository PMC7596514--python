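# Methods

This note documents the models, parameter choices, and numerical decisions
behind `stemcnv`, and what the synthetic studies do and do not show about
real data.

## The synthetic study

The generator emulates an isogenic hPSC case/control design: cell lines
sharing one genetic background, the case lines carrying a clonal single-copy
gain (copy number 3 vs diploid 2) of a 1.5 Mb amplicon. Defaults, all
overridable in `SyntheticStudyConfig`:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 600 | genes across 5 chromosomes (60 Mb each) |
| `cnv_region` | chr20:30,000,000–31,500,000 | planted amplicon, 8 resident genes |
| `cnv_copy_number` | 3 | heterozygous gain |
| `dosage_log2fc` | log₂(3/2) ≈ 0.585 | expression effect on amplicon genes |
| `cascade_decay` | 0.5 | per-network-step attenuation of the effect |
| `n_samples_per_group` | 6 | bulk RNA-seq samples per arm |
| `nb_dispersion` | 0.02 | NB dispersion (≈14% biological CV, isogenic lines) |
| `sc_n_cells_per_line` | 1000 | cells per single-cell line |
| `sc_shift` | 0.20 | proportion shift of one cluster in the case line |
| `panel_skew` | ectoderm −1, C/PNS −1, endoderm −0.5, meso 0, extraembryonic +0.5, undiff +0.5 | planted lineage log₂FC |
| `qpcr_sd` | 0.2 | Ct replicate noise (cycles) |

Design choices worth stating:

* **Cascade model.** Downstream expression effects are modelled as
  exponential attenuation along network shortest paths from amplicon genes:
  |log₂FC| = dosage × decay^d up to distance 3, with a random sign per gene
  (regulatory cascades amplify in both directions). This is a generative
  stand-in chosen so that network propagation is the matched recovery tool;
  no claim is made that real cascades decay exponentially.
* **Breakpoint jitter.** Platform breakpoint uncertainty scales with
  inter-marker spacing, so jitter is drawn as *outward* extension in
  platform-stratified bands (aCGH 0.6–1.0×, SNP/CytoScan 0.3–0.6×,
  WES 0–0.3× of `breakpoint_jitter`). Per-sample calls therefore nest
  across platforms, the structure the containment merge rule expects.
  Decoy false-positive calls are planted one per QC-filter class so each
  filter's removal is observable.
* **Mitochondrial tagging.** Mito genes are identified by the `MT-` name
  prefix; the generator plants configurable fractions of cells violating
  each QC rule (defaults: 1% low-feature, 2% high-mito, 0% high-feature —
  with 600 genes the 6000-feature ceiling cannot bind, so planted
  high-feature violators are only meaningful when `n_genes` exceeds it).
* **Mosaicism is not modelled**: case lines carry the gain clonally.
  Ct base values are arbitrary (25) since ΔΔCt is offset-invariant.
* Every generator draws from its own seeded stream derived from the single
  study seed, so each output is a pure function of (config, seed).

## Stage-by-stage notes

**CNV consensus.** Coordinates are 0-based half-open (BED). The same-event
relation is strict containment (configurable reciprocal-overlap fallback,
default off, threshold 0.5 — containment alone can chain distinct events
through a wide spanning call, which the fallback does not fix but makes
explicit). Pair matching between control and case call sets is greedy by
largest reciprocal overlap, ties to the leftmost start, one partner per
call, per platform. The core interval of a component is the intersection of
members; for pathological chains with empty intersection it degenerates to a
zero-length interval at the maximal start. Centromere exclusion takes a
BED table of centromeric intervals (none is bundled). The manual
false-positive curation step of array workflows is replaced by the explicit
rule set so the pipeline is reproducible.

**Bulk DE.** RLE factors use only genes with all-positive counts. Dispersion
is per-gene method-of-moments on normalized counts, pooled within-group
(Bessel-corrected), floored at 1e-8; the common dispersion for the VST is
the median of per-gene values. The Wald statistic uses the NB Fisher
information Σ μ/(1+αμ) per group; because the plug-in dispersion at 6-vs-6
makes a normal reference anti-conservative (measured null fraction
p < 0.05 ≈ 0.082), the statistic is referenced to Student t with n − 2 df
(measured ≈ 0.053, inside the 0.035–0.065 band), converging to the normal
as n grows. No fold-change shrinkage; a 0.5 pseudo-count guards zero group
totals. PCA uses the top 500 most-variable VST genes (common default; the
subset is configurable).

**Propagation.** The walk operator is the column-normalized adjacency;
isolated nodes get a self-loop so mass is conserved (checked to 1e-12 per
iteration). Restart probability defaults to 0.5 and seeds are weighted
uniformly — deliberately agnostic choices, both configurable. Cascaded
genes exclude the seeds themselves (the DEG lists and cascade lists are
distinct query lists downstream); `select_cascade(..., include_seeds=True)`
reverses this. Library defaults for k are the classic 500/1500; the
pipeline's desk-scale default is 50/150 against the 600-gene network.

**Enrichment.** ORA is the exact hypergeometric upper tail. GSEA uses the
weighted KS statistic (weight 1) with a gene-label permutation null
(sample permutation is undefined for a preranked list), 1000 permutations
by default (250 in the pipeline config), one-tailed on the observed ES sign
with +1 smoothing. Raw p-values (not BH-adjusted) enter the cross-list
average; both are emitted. A gene set missing from a query list is imputed
as p = 1 in the average — conservative, and flagged via
`n_lists_observed`.

**Single cell.** HVG selection fits a degree-2 polynomial to log₁₀ variance
vs log₁₀ mean of counts and ranks genes by the standardized residual. The
integration is deliberately simple — shared HVGs, per-dataset gene
standardization, joint PCA (20 components by default, with the explained
variance ratios emitted as the elbow diagnostic), optional global
mutual-nearest-neighbour shift — not a reimplementation of CCA-anchor
integration; its acceptance surface is proportion-shift recovery, not
equivalence with any particular toolkit. SNN edges carry Jaccard weights of
k = 20 neighbour sets (self excluded), pruned below 1/15; communities come
from seeded Leiden modularity optimization, relabelled by size for
determinism. The two-proportion z-test attached to the proportion table is
an auxiliary descriptive aid. Cluster markers use one-vs-rest Wilcoxon
rank-sum with BH within cluster and the natural-log fold change of mean
expm1 expression (pseudo-count 1).

**Lineage scores.** The "regularized log" transform is approximated by
log₂(RLE-normalized + 1); empirical-Bayes shrinkage of true rlog is out of
scope and the divergence is accepted because only between-group contrasts
of moderately expressed panel genes are consumed. The panel is user-supplied
(gene → lineage TSV); the repository ships only synthetic panels.
Comparison groups are config-driven sample subsets (e.g. isogenic halves A
and B plus the pooled group C).

**qPCR.** Amplification efficiency is fixed at 2 (the ΔΔCt assumption); the
copy-number reference assay plays the arithmetic role of an endogenous
reference. Replicate SEMs (sd/√n) propagate in quadrature on the Ct scale.

**Pipeline.** One YAML config; all stage RNGs derive from the study seed via
fixed spawn keys, so reruns are byte-identical (the report carries no
timing; wall times live in the manifest). The headline DEG partition uses
|log₂FC| ≥ 0.3 at FDR < 0.05 for the synthetic effect sizes, while
propagation seeds use the looser raw-p rule (p < 0.055) — mirroring the
distinction between a headline DEG table and a permissive seed-gene rule.

## Problem sizes

Tests and the acceptance script run on the defaults above: 600-gene
studies, 2000-gene null panels over 10 seeds for calibration, 20 seeds for
the single-cell and lineage recovery rates, 200 random instances for the
consensus oracle, 100 graphs for the RWR oracle, 500 replicates for GSEA
null uniformity. These sizes were chosen as the smallest at which the
Monte-Carlo error of each rate is well below its acceptance margin.

## What passing does and does not show

The synthetic data are NB/Poisson with clean cluster structure, no batch
effects beyond a global shift, no ambient RNA, doublets, GC bias, isoform
complexity, or mosaicism, and the network is a small-world stand-in rather
than a curated interactome. Passing recovery tests therefore demonstrates
that the implementations are correct and well-calibrated under their own
model assumptions — not that the pipeline's defaults are optimal for any
particular real dataset. Known limitations: the containment rule's
transitivity caveat above; the rlog approximation; the simplified
integration; and FDR calibration is verified at the simulated dispersion
range, not under strong outlier contamination.
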