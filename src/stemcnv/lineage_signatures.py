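"""Lineage-signature scoring of teratoma (or any bulk) expression.

A signature panel labels marker genes with one of six lineages (ectoderm,
C/PNS, mesoderm, endoderm, extraembryonic, undifferentiated).  Expression is
RLE-normalized and log-transformed; per-gene log2 fold changes between case
and control arms are computed for one or more comparison groups (e.g.
isogenic-only vs pooled), aggregated per lineage (median log2FC, fraction
downregulated), and checked for cross-group sign concordance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple
import warnings

import numpy as np
import pandas as pd

from .bulk_expression import rle_size_factors

__all__ = [
    "LINEAGE_VOCAB",
    "read_panel",
    "detect_panel",
    "rld_normalize",
    "lineage_log2fc",
    "LineageScore",
]

LINEAGE_VOCAB = (
    "ectoderm",
    "C/PNS",
    "mesoderm",
    "endoderm",
    "extraembryonic",
    "undifferentiated",
)


def read_panel(path) -> pd.DataFrame:
    """Read a panel TSV (gene, lineage) and validate the label vocabulary."""
    panel = pd.read_csv(path, sep="\t")
    return validate_panel(panel)


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    if not {"gene", "lineage"} <= set(panel.columns):
        raise ValueError("panel needs columns gene, lineage")
    bad = set(panel["lineage"]) - set(LINEAGE_VOCAB)
    if bad:
        raise ValueError(f"unknown lineage labels: {sorted(bad)}")
    dup = panel["gene"].duplicated()
    if dup.any():
        raise ValueError(f"panel genes labelled twice: {sorted(panel['gene'][dup])}")
    return panel


def detect_panel(
    panel: pd.DataFrame, counts: pd.DataFrame
) -> Tuple[pd.DataFrame, Dict]:
    """Panel genes present in the (prefiltered) count matrix.

    Returns (detected panel subset, report with detection rate and missing
    gene names).  Zero detected genes is an error.
    """
    validate_panel(panel)
    present = panel["gene"].isin(counts.index)
    detected = panel[present].reset_index(drop=True)
    missing = sorted(panel.loc[~present, "gene"])
    if detected.empty:
        raise ValueError("no panel gene detected in the count matrix")
    report = {
        "panel_size": int(len(panel)),
        "n_detected": int(len(detected)),
        "detection_rate": float(len(detected) / len(panel)),
        "missing_genes": missing,
    }
    return detected, report


def rld_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(RLE-normalized count + 1).

    A transparent stand-in for regularized-log transforms: RLE size factors
    absorb depth differences, the shifted log stabilizes low counts.
    """
    sf = rle_size_factors(counts)
    norm = counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    return pd.DataFrame(np.log2(norm + 1.0), index=counts.index, columns=counts.columns)


@dataclass
class LineageScore:
    per_gene: pd.DataFrame  # gene, lineage, group, log2fc, significant
    per_lineage: pd.DataFrame  # lineage, group, n_detected, median_log2fc, frac_down
    concordance: pd.DataFrame  # gene, lineage, concordant
    concordance_rate: float


def lineage_log2fc(
    transformed: pd.DataFrame,
    groups: pd.Series,
    panel: pd.DataFrame,
    comparison_groups: Optional[Mapping[str, Tuple[Sequence[str], Sequence[str]]]] = None,
    significance: Optional[pd.Series] = None,
) -> LineageScore:
    """Per-gene and per-lineage log2 fold changes across comparison groups.

    ``comparison_groups`` maps a group name to (case_samples,
    control_samples); the default single group "all" uses the case/control
    labels of ``groups``.  log2fc = mean(case) - mean(control) on the log2
    scale.  ``significance`` optionally carries per-gene boolean flags
    imported from a differential-expression run on the same samples.
    Concordance is the fraction of panel genes whose fold-change sign agrees
    across every comparison group in which the gene is measurable.
    """
    validate_panel(panel)
    if comparison_groups is None:
        case = list(groups.index[groups == "case"])
        ctrl = list(groups.index[groups == "control"])
        comparison_groups = {"all": (case, ctrl)}

    detected = panel[panel["gene"].isin(transformed.index)]
    rows = []
    for name, (case_samples, ctrl_samples) in comparison_groups.items():
        case_samples = [s for s in case_samples if s in transformed.columns]
        ctrl_samples = [s for s in ctrl_samples if s in transformed.columns]
        if len(case_samples) == 0 or len(ctrl_samples) == 0:
            warnings.warn(f"comparison group {name!r} has an empty arm; skipped")
            continue
        sub = transformed.loc[detected["gene"]]
        lfc = sub[case_samples].mean(axis=1) - sub[ctrl_samples].mean(axis=1)
        for gene, lin in zip(detected["gene"], detected["lineage"]):
            rows.append(
                {
                    "gene": gene,
                    "lineage": lin,
                    "group": name,
                    "log2fc": float(lfc[gene]),
                    "significant": bool(significance.get(gene, False))
                    if significance is not None
                    else None,
                }
            )
    per_gene = pd.DataFrame(rows)
    if per_gene.empty:
        raise ValueError("no comparison group could be evaluated")

    per_lineage = (
        per_gene.groupby(["lineage", "group"])
        .agg(
            n_detected=("gene", "nunique"),
            median_log2fc=("log2fc", "median"),
            frac_down=("log2fc", lambda v: float((np.asarray(v) < 0).mean())),
        )
        .reset_index()
    )

    sign = per_gene.pivot(index="gene", columns="group", values="log2fc").apply(np.sign)
    concordant = sign.nunique(axis=1) == 1
    conc = pd.DataFrame(
        {
            "gene": concordant.index,
            "concordant": concordant.values,
        }
    ).merge(panel[["gene", "lineage"]], on="gene", how="left")
    return LineageScore(
        per_gene=per_gene,
        per_lineage=per_lineage,
        concordance=conc[["gene", "lineage", "concordant"]],
        concordance_rate=float(concordant.mean()),
    )
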