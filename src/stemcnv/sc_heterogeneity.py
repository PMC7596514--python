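"""Single-cell embryoid-body heterogeneity analysis.

QC filtering on feature counts and mitochondrial fraction, library-size
log-normalization, mean-variance highly-variable-gene selection, a
simplified two-sample integration (shared HVGs, per-dataset gene
standardization, joint PCA, optional mutual-nearest-neighbour shift
correction), SNN/Jaccard graph clustering, one-vs-rest Wilcoxon cluster
markers, and the per-line cluster-proportion comparison

    proportion[line, cluster] = n_cells(line, cluster) / n_cells(line)

that quantifies how a CNV shifts the differentiated-cell distribution
between isogenic lines.

Expression containers are AnnData (cells x genes); raw counts are kept in
``layers["counts"]`` once normalized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple
import warnings

import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

try:  # AnnData is the in-memory container throughout
    import anndata as ad
except ImportError:  # pragma: no cover
    ad = None

__all__ = [
    "qc_metrics",
    "qc_filter",
    "normalize_log",
    "select_hvg",
    "integrate",
    "cluster_snn",
    "cluster_proportions",
    "cluster_markers",
]


def _dense(x) -> np.ndarray:
    return x.toarray() if sparse.issparse(x) else np.asarray(x)


def qc_metrics(adata, mito_prefix: str = "MT-") -> None:
    """Annotate obs with n_features and pct_mito (in percent)."""
    x = _dense(adata.X)
    adata.obs["n_features"] = (x > 0).sum(axis=1)
    mito = adata.var_names.str.startswith(mito_prefix)
    total = x.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(total > 0, 100.0 * x[:, mito].sum(axis=1) / total, 0.0)
    adata.obs["pct_mito"] = pct


def qc_filter(
    adata,
    min_features: int = 200,
    max_features: int = 6000,
    max_pct_mito: float = 7.5,
    mito_prefix: str = "MT-",
):
    """Remove cells failing QC; returns (filtered AnnData, per-rule tally).

    Retains cells with min_features <= n_features <= max_features and
    pct_mito strictly below max_pct_mito.  The tally counts each removed
    cell once per violated rule plus a ``removed_total`` of distinct cells.
    """
    if "n_features" not in adata.obs or "pct_mito" not in adata.obs:
        qc_metrics(adata, mito_prefix)
    nf = adata.obs["n_features"].to_numpy()
    pm = adata.obs["pct_mito"].to_numpy()
    low = nf < min_features
    high = nf > max_features
    mito = pm >= max_pct_mito
    keep = ~(low | high | mito)
    if not keep.any():
        raise ValueError("no cells survive QC")
    report = {
        "input_cells": int(adata.n_obs),
        "removed_low_features": int(low.sum()),
        "removed_high_features": int(high.sum()),
        "removed_high_mito": int(mito.sum()),
        "removed_total": int((~keep).sum()),
        "output_cells": int(keep.sum()),
    }
    return adata[keep].copy(), report


def normalize_log(adata, scale: float = 1e4):
    """ln(1 + scale * x / library_size) per cell; counts kept in a layer."""
    x = _dense(adata.X).astype(float)
    libs = x.sum(axis=1)
    if (libs <= 0).any():
        raise ValueError("cells with zero library size must be QC-removed first")
    out = adata.copy()
    out.layers["counts"] = x.copy()
    out.X = np.log1p(scale * x / libs[:, None])
    return out


def select_hvg(adata, n: int = 2000, min_mean: float = 1e-8) -> List[str]:
    """Highly variable genes from the count mean-variance trend.

    A second-degree polynomial is fit to log10 variance vs log10 mean of the
    raw counts; genes are ranked by the residual of their observed log
    variance above the trend (standardized by the residual spread).  Ties
    break by gene identifier.
    """
    counts = adata.layers.get("counts", None)
    counts = _dense(counts) if counts is not None else _dense(adata.X)
    mean = counts.mean(axis=0)
    var = counts.var(axis=0, ddof=1)
    ok = (mean > min_mean) & (var > 0)
    if n >= int(ok.sum()):
        warnings.warn("n >= number of variable genes; returning all")
        genes = adata.var_names[ok]
        return sorted(genes)
    lm = np.log10(mean[ok])
    lv = np.log10(var[ok])
    coef = np.polyfit(lm, lv, 2)
    resid = lv - np.polyval(coef, lm)
    resid_std = resid / max(resid.std(), 1e-12)
    df = pd.DataFrame(
        {"gene": adata.var_names[ok], "score": resid_std}
    ).sort_values(["score", "gene"], ascending=[False, True], kind="mergesort")
    return list(df["gene"].head(n))


def _standardize_genes(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0, keepdims=True)
    sd = x.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def integrate(
    adatas: Sequence,
    n_hvg: int = 2000,
    n_pcs: int = 20,
    mnn_correct: bool = True,
    mnn_k: int = 10,
    seed: int = 0,
):
    """Joint embedding of two (or more) normalized datasets.

    Shared HVGs (union of per-dataset HVG lists restricted to genes present
    everywhere), per-dataset gene standardization, concatenation, PCA to
    ``n_pcs`` components, and an optional mutual-nearest-neighbour global
    shift correction of each later dataset onto the first.  Returns an
    AnnData with ``obsm["X_pca"]`` and per-cell sample-of-origin in
    ``obs["sample"]`` (taken from ``obs["line"]`` when present).
    """
    if len(adatas) < 2:
        raise ValueError("integration needs at least 2 datasets")
    shared_genes = set(adatas[0].var_names)
    for a in adatas[1:]:
        shared_genes &= set(a.var_names)
    hvg: set = set()
    for a in adatas:
        hvg |= set(select_hvg(a, n=n_hvg))
    genes = sorted(hvg & shared_genes)
    if not genes:
        raise ValueError("no shared highly variable genes")

    blocks = []
    obs_frames = []
    for i, a in enumerate(adatas):
        sub = _dense(a[:, genes].X).astype(float)
        blocks.append(_standardize_genes(sub))
        obs = a.obs.copy()
        if "sample" not in obs:
            obs["sample"] = obs["line"] if "line" in obs else f"dataset{i}"
        obs_frames.append(obs)
    x = np.vstack(blocks)
    from sklearn.decomposition import PCA

    pca = PCA(n_components=min(n_pcs, min(x.shape) - 1), svd_solver="full",
              random_state=seed)
    emb = pca.fit_transform(x)

    sizes = [b.shape[0] for b in blocks]
    offsets = np.cumsum([0] + sizes)
    if mnn_correct:
        from sklearn.neighbors import NearestNeighbors

        ref = emb[offsets[0]:offsets[1]]
        for i in range(1, len(blocks)):
            tgt = emb[offsets[i]:offsets[i + 1]]
            k = min(mnn_k, len(ref), len(tgt))
            nn_rt = NearestNeighbors(n_neighbors=k).fit(tgt)
            nn_tr = NearestNeighbors(n_neighbors=k).fit(ref)
            _, ind_r = nn_rt.kneighbors(ref)  # ref -> tgt neighbours
            _, ind_t = nn_tr.kneighbors(tgt)  # tgt -> ref neighbours
            pairs = []
            tgt_nb = [set(row) for row in ind_t]
            for ri, row in enumerate(ind_r):
                for tj in row:
                    if ri in tgt_nb[tj]:
                        pairs.append((ri, tj))
            if pairs:
                ridx = np.array([p[0] for p in pairs])
                tidx = np.array([p[1] for p in pairs])
                shift = (ref[ridx] - tgt[tidx]).mean(axis=0)
                emb[offsets[i]:offsets[i + 1]] += shift

    obs = pd.concat(obs_frames)
    obs.index = [f"{s}_{i}" for i, s in enumerate(obs["sample"])]
    joint = ad.AnnData(
        X=x, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene"))
    )
    joint.obsm["X_pca"] = emb
    joint.uns["pca_explained_variance_ratio"] = pca.explained_variance_ratio_
    return joint


def snn_graph(
    embedding: np.ndarray, k_neighbors: int = 20, prune: float = 1.0 / 15.0
) -> sparse.csr_matrix:
    """Shared-nearest-neighbour graph with Jaccard edge weights.

    kNN (Euclidean, self excluded); edge weight between two cells is the
    Jaccard index of their neighbour sets; weights below ``prune`` drop.
    """
    from sklearn.neighbors import NearestNeighbors

    n = embedding.shape[0]
    if k_neighbors >= n:
        raise ValueError("k_neighbors must be < number of cells")
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(embedding)
    _, ind = nn.kneighbors(embedding)
    ind = ind[:, 1:]  # drop self
    rows = np.repeat(np.arange(n), k_neighbors)
    b = sparse.csr_matrix(
        (np.ones(n * k_neighbors), (rows, ind.ravel())), shape=(n, n)
    )
    shared = (b @ b.T).tocoo()
    jac = shared.data / (2 * k_neighbors - shared.data)
    mask = (jac >= prune) & (shared.row != shared.col)
    g = sparse.csr_matrix(
        (jac[mask], (shared.row[mask], shared.col[mask])), shape=(n, n)
    )
    return g


def cluster_snn(
    embedding: np.ndarray,
    k_neighbors: int = 20,
    resolution: float = 1.0,
    prune: float = 1.0 / 15.0,
    seed: int = 0,
) -> np.ndarray:
    """Community detection on the SNN graph (Leiden, modularity-style).

    Labels are relabelled by decreasing cluster size so the output is stable
    across runs with the same seed.
    """
    import igraph as ig
    import leidenalg

    g = snn_graph(embedding, k_neighbors=k_neighbors, prune=prune)
    coo = sparse.triu(g, k=1).tocoo()
    graph = ig.Graph(
        n=g.shape[0],
        edges=list(zip(coo.row.tolist(), coo.col.tolist())),
        edge_attrs={"weight": coo.data.tolist()},
    )
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
    )
    labels = np.asarray(part.membership)
    order = pd.Series(labels).value_counts(sort=True).index
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[l] for l in labels])


def cluster_proportions(
    labels: Sequence[int], sample_of_origin: Sequence[str]
) -> pd.DataFrame:
    """Per-sample cluster proportion table with auxiliary two-proportion test.

    Rows: (cluster, sample, n_cells, fraction); fractions within a sample
    sum to 1.  With exactly two samples the frame also carries the
    case-minus-control fraction difference and a two-proportion z-test per
    cluster (descriptive aid, not a headline statistic).
    """
    labels = np.asarray(labels)
    origin = np.asarray(sample_of_origin)
    if labels.size == 0:
        raise ValueError("no cells given; every sample needs nonzero cells")
    samples = sorted(pd.unique(origin))
    for s in samples:
        if (origin == s).sum() == 0:
            raise ValueError(f"sample {s} has zero cells")
    clusters = sorted(pd.unique(labels))
    rows = []
    for s in samples:
        total = int((origin == s).sum())
        for c in clusters:
            n = int(((origin == s) & (labels == c)).sum())
            rows.append(
                {"cluster": c, "sample": s, "n_cells": n, "fraction": n / total}
            )
    df = pd.DataFrame(rows)
    if len(samples) == 2:
        s0, s1 = samples
        wide = df.pivot(index="cluster", columns="sample", values="fraction")
        counts = df.pivot(index="cluster", columns="sample", values="n_cells")
        totals = {s: int((origin == s).sum()) for s in samples}
        diff = wide[s1] - wide[s0]
        zs, ps = [], []
        for c in clusters:
            x = np.array([counts.loc[c, s1], counts.loc[c, s0]])
            n = np.array([totals[s1], totals[s0]])
            pool = x.sum() / n.sum()
            se = np.sqrt(pool * (1 - pool) * (1 / n[0] + 1 / n[1]))
            z = (x[0] / n[0] - x[1] / n[1]) / se if se > 0 else 0.0
            zs.append(z)
            ps.append(2 * stats.norm.sf(abs(z)))
        aux = pd.DataFrame(
            {"cluster": clusters, "fraction_diff": diff.values, "z": zs, "p": ps}
        )
        df = df.merge(aux, on="cluster", how="left")
    return df


def cluster_markers(
    adata_norm,
    labels: Sequence[int],
    min_cells: int = 3,
    adj_p_max: float = 0.05,
    logfc_min: float = 0.1,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum markers per cluster.

    logFC is the natural-log fold change of mean expm1 expression with
    pseudo-count 1; BH adjustment across genes within each cluster; markers
    pass adj p <= ``adj_p_max`` and logFC >= ``logfc_min``.  Clusters with
    fewer than ``min_cells`` cells are skipped with a warning.
    """
    labels = np.asarray(labels)
    x = _dense(adata_norm.X)
    expm = np.expm1(x)
    rows = []
    for c in sorted(pd.unique(labels)):
        mask = labels == c
        if mask.sum() < min_cells:
            warnings.warn(f"cluster {c} has <{min_cells} cells; markers skipped")
            continue
        xin, xout = x[mask], x[~mask]
        res = stats.mannwhitneyu(xin, xout, axis=0, alternative="two-sided")
        p = np.asarray(res.pvalue)
        logfc = np.log(
            (expm[mask].mean(axis=0) + 1.0) / (expm[~mask].mean(axis=0) + 1.0)
        )
        adj = multipletests(p, method="fdr_bh")[1]
        keep = (adj <= adj_p_max) & (logfc >= logfc_min)
        for gi in np.where(keep)[0]:
            rows.append(
                {
                    "gene": adata_norm.var_names[gi],
                    "cluster": c,
                    "logfc": float(logfc[gi]),
                    "p": float(p[gi]),
                    "adj_p": float(adj[gi]),
                }
            )
    return pd.DataFrame(rows, columns=["gene", "cluster", "logfc", "p", "adj_p"])
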