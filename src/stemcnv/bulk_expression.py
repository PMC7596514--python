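"""Bulk RNA-seq differential expression for two-group designs.

Median-of-ratios (RLE) size factors, a per-gene negative-binomial Wald test
with method-of-moments dispersion, closed-form variance-stabilizing
transform at a common dispersion, and sample-distance / PCA summaries.

The NB model: counts K_gj ~ NB(mean s_j * q_gG(j), dispersion alpha_g) with
a log-link two-group mean.  The Wald statistic is the group log fold change
over its Fisher-information standard error, referenced to a Student t with
n - 2 degrees of freedom (the plug-in dispersion makes the normal reference
anti-conservative at typical group sizes; the t reference restores type-I
control and converges to the normal as n grows).  q-values are
Benjamini-Hochberg within the tested genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "prefilter_genes",
    "rle_size_factors",
    "nb_wald_test",
    "classify_deg",
    "vst",
    "sample_distances",
    "DISPERSION_FLOOR",
]

DISPERSION_FLOOR = 1e-8


def prefilter_genes(
    counts: pd.DataFrame, min_reads: int = 5, min_samples: int = 1
) -> pd.DataFrame:
    """Keep genes with count > min_reads in at least min_samples samples."""
    if counts.empty:
        raise ValueError("empty count matrix")
    keep = (counts > min_reads).sum(axis=1) >= min_samples
    if not keep.any():
        raise ValueError(
            "prefilter removed every gene; review min_reads/min_samples"
        )
    return counts.loc[keep]


def rle_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Relative log expression size factors (median-of-ratios).

    s_j = median over genes of counts[g, j] / geometric-mean_g, using only
    genes with all-positive counts.
    """
    arr = counts.to_numpy(dtype=float)
    usable = (arr > 0).all(axis=1)
    if not usable.any():
        raise ValueError("no gene with all-positive counts; cannot compute RLE factors")
    log_arr = np.log(arr[usable])
    log_geomean = log_arr.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(log_arr - log_geomean, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _mom_dispersion(norm: np.ndarray, group_idx: List[np.ndarray]) -> np.ndarray:
    """Per-gene method-of-moments dispersion from within-group residuals.

    alpha = (s2 - m) / m^2 with s2 the pooled within-group variance of the
    normalized counts (Bessel-corrected) and m their overall mean, floored.
    """
    n_total = sum(len(ix) for ix in group_idx)
    ss = np.zeros(norm.shape[0])
    for ix in group_idx:
        sub = norm[:, ix]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = ss / (n_total - len(group_idx))
    m = norm.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - m) / np.square(m)
    alpha = np.where(np.isfinite(alpha), alpha, DISPERSION_FLOOR)
    return np.maximum(alpha, DISPERSION_FLOOR)


def nb_wald_test(
    counts: pd.DataFrame,
    groups: pd.Series,
    size_factors: Optional[pd.Series] = None,
    reference: str = "control",
) -> pd.DataFrame:
    """Negative-binomial Wald test per gene, case vs control.

    Returns a frame indexed by gene with columns base_mean, log2fc, se, p, q,
    tested, dispersion.  All-zero genes are reported with ``tested=False``
    and NaN statistics.  No fold-change shrinkage is applied; a pseudo-count
    of 0.5 stabilizes the reported log2fc when a group total is zero.
    """
    groups = groups.loc[counts.columns]
    levels = [g for g in pd.unique(groups) if g != reference]
    if len(levels) != 1:
        raise ValueError("exactly two groups (reference + one other) required")
    other = levels[0]
    idx_ref = np.where(groups.values == reference)[0]
    idx_case = np.where(groups.values == other)[0]
    if len(idx_ref) < 2 or len(idx_case) < 2:
        raise ValueError("each group needs at least 2 samples")

    if size_factors is None:
        size_factors = rle_size_factors(counts)
    sf = size_factors.loc[counts.columns].to_numpy(dtype=float)
    arr = counts.to_numpy(dtype=float)
    tested = arr.sum(axis=1) > 0
    norm = arr / sf[None, :]

    alpha = _mom_dispersion(norm, [idx_ref, idx_case])
    pseudo_q = 0.5 / sf.sum()

    def group_q(ix: np.ndarray) -> np.ndarray:
        # MLE of the group mean parameter under equal weights: sum k / sum s
        return arr[:, ix].sum(axis=1) / sf[ix].sum()

    q_ref = group_q(idx_ref)
    q_case = group_q(idx_case)
    q_ref_s = np.maximum(q_ref, pseudo_q)
    q_case_s = np.maximum(q_case, pseudo_q)
    log2fc = np.log2(q_case_s / q_ref_s)

    def info(q: np.ndarray, ix: np.ndarray) -> np.ndarray:
        mu = q[:, None] * sf[ix][None, :]
        return (mu / (1.0 + alpha[:, None] * mu)).sum(axis=1)

    var_log = 1.0 / info(q_ref_s, idx_ref) + 1.0 / info(q_case_s, idx_case)
    se_log2 = np.sqrt(var_log) / np.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = log2fc / se_log2
    df_resid = len(idx_ref) + len(idx_case) - 2
    p = 2.0 * stats.t.sf(np.abs(z), df_resid)

    res = pd.DataFrame(
        {
            "base_mean": norm.mean(axis=1),
            "log2fc": log2fc,
            "se": se_log2,
            "p": p,
            "dispersion": alpha,
            "tested": tested,
        },
        index=counts.index,
    )
    res.loc[~tested, ["log2fc", "se", "p"]] = np.nan
    q = np.full(len(res), np.nan)
    if tested.any():
        q[tested] = multipletests(res.loc[tested, "p"].values, method="fdr_bh")[1]
    res["q"] = q
    return res


def classify_deg(
    records: pd.DataFrame, lfc_thresh: float = 1.0, fdr: float = 0.05,
    use_raw_p: bool = False, p_thresh: float = 0.055,
) -> pd.DataFrame:
    """Assign up/down/ns directions.

    Default rule: |log2FC| >= lfc_thresh and BH q < fdr.  ``use_raw_p``
    switches to the raw p-value variant (p < p_thresh) exposed as a preset.
    """
    records = records.copy()
    if use_raw_p:
        sig = records["p"] < p_thresh
    else:
        sig = records["q"] < fdr
    sig = sig.fillna(False)
    direction = np.where(
        sig & (records["log2fc"] >= lfc_thresh), "up",
        np.where(sig & (records["log2fc"] <= -lfc_thresh), "down", "ns"),
    )
    records["direction"] = direction
    return records


def vst(
    counts: pd.DataFrame,
    size_factors: Optional[pd.Series] = None,
    dispersion: Optional[float] = None,
    groups: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Closed-form variance-stabilizing transform at common dispersion alpha.

    v(x) = (2 / sqrt(alpha)) * asinh(sqrt(alpha * x)) applied to normalized
    counts; monotone increasing with v(0) = 0.  When ``dispersion`` is not
    given, the median of the per-gene method-of-moments dispersions is used.
    """
    if size_factors is None:
        size_factors = rle_size_factors(counts)
    sf = size_factors.loc[counts.columns].to_numpy(dtype=float)
    norm = counts.to_numpy(dtype=float) / sf[None, :]
    if dispersion is None:
        if groups is not None:
            gidx = [np.where(groups.loc[counts.columns].values == g)[0]
                    for g in pd.unique(groups)]
        else:
            gidx = [np.arange(norm.shape[1])]
        alphas = _mom_dispersion(norm, gidx)
        dispersion = float(np.median(alphas[alphas > DISPERSION_FLOOR])) \
            if (alphas > DISPERSION_FLOOR).any() else DISPERSION_FLOOR
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    v = (2.0 / np.sqrt(dispersion)) * np.arcsinh(np.sqrt(dispersion * norm))
    return pd.DataFrame(v, index=counts.index, columns=counts.columns)


@dataclass
class DistanceSummary:
    distances: pd.DataFrame
    linkage: np.ndarray
    pca: pd.DataFrame
    explained_variance_ratio: np.ndarray


def sample_distances(
    vst_matrix: pd.DataFrame, n_top_genes: int = 500, n_components: int = 2
) -> DistanceSummary:
    """Euclidean sample distances, average-linkage dendrogram, and PCA.

    PCA uses the centred VST values of the top ``n_top_genes`` most-variable
    genes (the common heatmap/PCA convention).
    """
    if vst_matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    x = vst_matrix.to_numpy(dtype=float).T  # samples x genes
    d = squareform(pdist(x, metric="euclidean"))
    dist = pd.DataFrame(d, index=vst_matrix.columns, columns=vst_matrix.columns)
    link = hierarchy.linkage(pdist(x), method="average")

    var = vst_matrix.var(axis=1)
    top = var.sort_values(ascending=False, kind="mergesort").index[:n_top_genes]
    sub = vst_matrix.loc[top].to_numpy(dtype=float).T
    sub = sub - sub.mean(axis=0, keepdims=True)
    from sklearn.decomposition import PCA

    n_components = min(n_components, min(sub.shape) - 1) or 1
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(sub)
    pca_df = pd.DataFrame(
        coords,
        index=vst_matrix.columns,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return DistanceSummary(dist, link, pca_df, pca.explained_variance_ratio_)


def dendrogram_top_split(linkage: np.ndarray, labels: Iterable[str]) -> Tuple[set, set]:
    """Sample labels on each side of the top split of a dendrogram."""
    labels = list(labels)
    n = len(labels)
    tree = hierarchy.to_tree(linkage)
    left = set(tree.get_left().pre_order(lambda leaf: labels[leaf.id]))
    right = set(tree.get_right().pre_order(lambda leaf: labels[leaf.id]))
    assert left | right == set(labels) and len(left) + len(right) == n
    return left, right
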