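"""Synthetic isogenic case/control studies with a planted CNV gain.

Every downstream stage of the pipeline (consensus calling, bulk differential
expression, network propagation, enrichment, single-cell heterogeneity,
lineage scoring, qPCR quantification) is exercised against data generated
here, with the planted truth recorded in a sidecar so recovery can be
checked exactly.

The emulated design: isogenic pluripotent stem-cell lines with and without a
heterozygous single-copy gain (copy number 3 vs diploid 2) of a ~1.5 Mb
amplicon.  Genes inside the amplicon receive a dosage-driven log2 fold
change of log2(3/2); genes at network distance d from an amplicon gene
receive an attenuated "cascade" effect dosage * decay^d with a random sign,
mimicking downstream regulatory propagation.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SyntheticStudyConfig",
    "PlantedTruth",
    "generate_gene_model",
    "generate_network",
    "make_truth",
    "simulate_platform_calls",
    "simulate_bulk_counts",
    "simulate_sc_counts",
    "simulate_gene_sets",
    "simulate_panel_and_qpcr",
]

LINEAGES = (
    "ectoderm",
    "C/PNS",
    "mesoderm",
    "endoderm",
    "extraembryonic",
    "undifferentiated",
)

#: spawn keys for the per-generator RNG streams (one stream per operation so
#: each generator is a pure function of (config, seed))
_STREAMS = {
    "gene_model": 1,
    "network": 2,
    "truth": 3,
    "cnv_calls": 4,
    "bulk": 5,
    "sc": 6,
    "panel": 7,
    "qpcr": 8,
    "gene_sets": 9,
}


def _rng(config: "SyntheticStudyConfig", stream: str) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=int(config.seed), spawn_key=(_STREAMS[stream],))
    return np.random.default_rng(ss)


def _default_panel_skew() -> Dict[str, float]:
    # mirrors the directional pattern of a gained-amplicon line: neural
    # lineages suppressed, extraembryonic/undifferentiated markers elevated
    return {
        "ectoderm": -1.0,
        "C/PNS": -1.0,
        "mesoderm": 0.0,
        "endoderm": -0.5,
        "extraembryonic": 0.5,
        "undifferentiated": 0.5,
    }


def _default_qc_violation_frac() -> Dict[str, float]:
    return {"low_features": 0.01, "high_features": 0.0, "high_mito": 0.02}


def _default_marker_density() -> Dict[str, float]:
    # markers per kb; array platforms dense, exome capture sparse
    return {"aCGH": 0.5, "SNP": 1.0, "CytoScanHD": 0.4, "WES": 0.05}


@dataclass
class SyntheticStudyConfig:
    """All knobs of one synthetic study; defaults are the reference study."""

    seed: int = 0
    # genome / gene model
    n_genes: int = 600
    n_chromosomes: int = 4
    chrom_length: int = 60_000_000
    cnv_chrom: str = "chr20"
    cnv_start: int = 30_000_000
    cnv_end: int = 31_500_000
    n_cnv_genes: int = 8
    n_mito_genes: int = 10
    # planted effect
    cnv_copy_number: int = 3
    dosage_log2fc: float = math.log2(1.5)
    cascade_decay: float = 0.5
    cascade_max_distance: int = 3
    # network
    network_k: int = 6
    network_rewire_p: float = 0.1
    # CNV call simulation
    platforms: Tuple[str, ...] = ("aCGH", "SNP", "WES")
    breakpoint_jitter: int = 50_000
    fp_per_sample: int = 3
    marker_density: Dict[str, float] = field(default_factory=_default_marker_density)
    cnv_log2ratio_sd: float = 0.05
    # bulk RNA-seq
    n_samples_per_group: int = 6
    nb_dispersion: float = 0.02
    baseline_log_mean: float = 5.5
    baseline_log_sd: float = 1.0
    size_factor_log_sd: float = 0.2
    # single-cell
    sc_n_cells_per_line: int = 1000
    sc_n_clusters: int = 5
    sc_program_size: int = 40
    sc_program_strength: float = 8.0
    sc_shift_cluster: int = 0
    sc_shift: float = 0.20
    sc_lib_log_mean: float = math.log(3000.0)
    sc_lib_log_sd: float = 0.3
    sc_mito_frac: float = 0.02
    sc_qc_violation_frac: Dict[str, float] = field(
        default_factory=_default_qc_violation_frac
    )
    # lineage panel / teratoma-like bulk
    panel_genes_per_lineage: int = 10
    panel_skew: Dict[str, float] = field(default_factory=_default_panel_skew)
    n_teratomas_per_arm: int = 6
    # qPCR
    qpcr_sd: float = 0.2
    ct_base: float = 25.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_chromosomes <= 0:
            raise ValueError("n_chromosomes must be positive")
        if not (0 <= self.cnv_start < self.cnv_end):
            raise ValueError("cnv_region must satisfy 0 <= start < end")
        if self.cnv_end > self.chrom_length:
            raise ValueError(
                "cnv_region extends beyond its chromosome "
                f"({self.cnv_end} > {self.chrom_length})"
            )
        if self.n_samples_per_group < 2:
            raise ValueError("n_samples_per_group must be >= 2")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not (0.0 < self.cascade_decay < 1.0):
            raise ValueError("cascade_decay must lie in (0, 1)")
        if self.qpcr_sd < 0:
            raise ValueError("qpcr_sd must be >= 0")
        if self.n_cnv_genes < 4:
            raise ValueError("need at least 4 genes inside the CNV region")
        extra = self.n_cnv_genes + self.n_mito_genes
        if self.n_genes < extra + self.sc_n_clusters * self.sc_program_size:
            raise ValueError("n_genes too small for the requested structure")

    # -- cluster proportions -------------------------------------------------
    def cluster_proportions(self) -> Tuple[np.ndarray, np.ndarray]:
        """Per-line cluster proportion simplex vectors (control, case).

        The case line shifts ``sc_shift`` of probability mass into
        ``sc_shift_cluster``; the remaining clusters shrink proportionally.
        """
        k = self.sc_n_clusters
        base = np.linspace(2.0, 1.0, k)
        control = base / base.sum()
        case = control.copy()
        j = self.sc_shift_cluster
        if not 0 <= j < k:
            raise ValueError("sc_shift_cluster out of range")
        shifted = control[j] + self.sc_shift
        if shifted >= 1.0:
            raise ValueError("sc_shift too large")
        others = np.delete(control, j)
        case = np.empty(k)
        case[j] = shifted
        rest = 1.0 - shifted
        idx = [i for i in range(k) if i != j]
        case[idx] = others * rest / others.sum()
        assert abs(control.sum() - 1) < 1e-9 and abs(case.sum() - 1) < 1e-9
        return control, case

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticStudyConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass
class PlantedTruth:
    """Sidecar of everything the generators planted."""

    cnv_genes: List[str]
    cascade_log2fc: Dict[str, float]  # gene -> expected bulk log2FC (incl. cnv genes)
    cascade_distance: Dict[str, int]  # gene -> network distance from a cnv gene
    sc_control_proportions: List[float]
    sc_case_proportions: List[float]
    panel_direction: Dict[str, int]  # lineage -> sign of the planted skew
    decoy_calls: List[dict] = field(default_factory=list)

    def expected_log2fc(self, gene: str) -> float:
        return self.cascade_log2fc.get(gene, 0.0)


# ---------------------------------------------------------------------------
# gene model & network
# ---------------------------------------------------------------------------

def generate_gene_model(config: SyntheticStudyConfig) -> pd.DataFrame:
    """Gene model table (BED-like, 0-based half-open).

    Columns: chrom, start, end, gene, strand.  Deterministic for a fixed
    seed.  ``n_cnv_genes`` genes are placed evenly inside the configured CNV
    region; ``n_mito_genes`` genes carry the ``MT-`` name prefix so the
    mitochondrial QC filter is exercisable.
    """
    config.validate()
    rng = _rng(config, "gene_model")
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    if config.cnv_chrom not in chroms:
        chroms.append(config.cnv_chrom)

    rows: List[tuple] = []
    # genes planted inside the CNV region (candidate stand-ins)
    region_len = config.cnv_end - config.cnv_start
    slot = region_len // config.n_cnv_genes
    for i in range(config.n_cnv_genes):
        start = config.cnv_start + i * slot + slot // 4
        end = min(start + slot // 2, config.cnv_end)
        rows.append((config.cnv_chrom, start, end, f"CNVG{i + 1:02d}", "+"))
    # mitochondrial-tagged genes
    for i in range(config.n_mito_genes):
        start = 1_000_000 + i * 20_000
        rows.append(("chr1", start, start + 10_000, f"MT-G{i + 1:02d}", "+"))
    # background genes
    n_rest = config.n_genes - config.n_cnv_genes - config.n_mito_genes
    chrom_idx = rng.integers(0, len(chroms), size=n_rest)
    lengths = rng.integers(5_000, 100_000, size=n_rest)
    strands = rng.choice(["+", "-"], size=n_rest)
    for i in range(n_rest):
        chrom = chroms[chrom_idx[i]]
        start = int(rng.integers(0, config.chrom_length - lengths[i]))
        # keep background genes off the planted amplicon so its gene content
        # stays exactly the configured candidate set
        if chrom == config.cnv_chrom and not (
            start + lengths[i] <= config.cnv_start or start >= config.cnv_end
        ):
            start = (start + region_len) % (config.chrom_length - int(lengths[i]))
            if not (start + lengths[i] <= config.cnv_start or start >= config.cnv_end):
                start = 0
        rows.append((chrom, start, start + int(lengths[i]), f"G{i + 1:04d}", strands[i]))

    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene", "strand"])
    order = {c: i for i, c in enumerate(chroms)}
    df = df.sort_values(
        ["chrom", "start", "gene"], key=lambda s: s.map(order) if s.name == "chrom" else s
    ).reset_index(drop=True)
    return df


def generate_network(
    config: SyntheticStudyConfig, gene_model: pd.DataFrame
) -> nx.Graph:
    """Undirected gene interaction network over the gene model.

    A small-world (Watts-Strogatz) topology over the genes, unit weights;
    stands in for a protein-protein interaction network.
    """
    rng = _rng(config, "network")
    genes = list(gene_model["gene"])
    g = nx.watts_strogatz_graph(
        len(genes), k=config.network_k, p=config.network_rewire_p,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    mapping = dict(enumerate(genes))
    g = nx.relabel_nodes(g, mapping)
    nx.set_edge_attributes(g, 1.0, "weight")
    return g


def make_truth(
    config: SyntheticStudyConfig,
    gene_model: pd.DataFrame,
    network: nx.Graph,
) -> PlantedTruth:
    """Derive the planted truth sidecar from the gene model and network."""
    rng = _rng(config, "truth")
    in_region = gene_model[
        (gene_model["chrom"] == config.cnv_chrom)
        & (gene_model["end"] > config.cnv_start)
        & (gene_model["start"] < config.cnv_end)
    ]
    cnv_genes = sorted(in_region["gene"])

    dist: Dict[str, int] = {}
    for g in cnv_genes:
        for node, d in nx.single_source_shortest_path_length(
            network, g, cutoff=config.cascade_max_distance
        ).items():
            if node not in dist or d < dist[node]:
                dist[node] = d

    lfc: Dict[str, float] = {}
    for gene in sorted(dist):
        d = dist[gene]
        if d == 0:
            lfc[gene] = config.dosage_log2fc
        else:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            lfc[gene] = sign * config.dosage_log2fc * config.cascade_decay**d
    control_p, case_p = config.cluster_proportions()
    return PlantedTruth(
        cnv_genes=cnv_genes,
        cascade_log2fc=lfc,
        cascade_distance=dist,
        sc_control_proportions=list(control_p),
        sc_case_proportions=list(case_p),
        panel_direction={
            lin: int(np.sign(config.panel_skew.get(lin, 0.0))) for lin in LINEAGES
        },
    )


# ---------------------------------------------------------------------------
# CNV call tables
# ---------------------------------------------------------------------------

_CALL_COLUMNS = [
    "chrom", "start", "end", "type", "platform", "sample",
    "log2ratio", "n_markers", "call_prob", "origin",
]

#: decoy classes, each designed to fail one QC filter
_DECOY_CLASSES = (
    "fp_sub5kb_snp",       # SNP call < 5 kb
    "fp_few_markers_snp",  # SNP call with < 5 markers
    "fp_low_prob_wes",     # WES call with call probability < 0.9
    "fp_low_ratio_wes",    # WES call with |log2ratio| < 0.5
    "fp_sex_chrom",        # call on chrX/chrY (any platform)
)


def _markers(config: SyntheticStudyConfig, platform: str, length: int) -> int:
    dens = config.marker_density.get(platform, 0.1)
    return max(1, int(round(length / 1000.0 * dens)))


#: relative breakpoint-extension band per platform (fraction of
#: breakpoint_jitter).  Boundary uncertainty scales with inter-marker
#: spacing, so lower-resolution platforms extend further outward and the
#: per-sample calls form a nested chain across platforms.
_JITTER_BANDS = {
    "aCGH": (0.6, 1.0),
    "SNP": (0.3, 0.6),
    "CytoScanHD": (0.3, 0.6),
    "WES": (0.0, 0.3),
}


def simulate_platform_calls(
    config: SyntheticStudyConfig, truth: PlantedTruth
) -> pd.DataFrame:
    """Per-platform per-sample CNV call tables.

    Case samples carry the planted gain on every platform with breakpoint
    jitter (outward extension up to ``breakpoint_jitter`` bp, stratified by
    platform resolution so the per-sample calls nest); decoy false-positive
    calls (one per QC-filter class, cycled) are injected into both groups at
    ``fp_per_sample`` per sample and recorded in the truth sidecar.
    """
    config.validate()
    unknown = set(config.platforms) - {"aCGH", "SNP", "WES", "CytoScanHD"}
    if unknown:
        raise ValueError(f"unknown platforms: {sorted(unknown)}")
    region_len = config.cnv_end - config.cnv_start
    if config.breakpoint_jitter * 2 >= region_len:
        raise ValueError("breakpoint_jitter larger than the CNV region")
    rng = _rng(config, "cnv_calls")
    truth.decoy_calls = []

    samples = [
        (f"control{i + 1}", "control") for i in range(config.n_samples_per_group)
    ] + [(f"case{i + 1}", "case") for i in range(config.n_samples_per_group)]

    rows: List[dict] = []
    ratio = math.log2(config.cnv_copy_number / 2.0)
    for sample, group in samples:
        if group == "case":
            for platform in config.platforms:
                j = config.breakpoint_jitter
                lo, hi = _JITTER_BANDS.get(platform, (0.0, 1.0))
                if j:
                    ext_l = int(rng.uniform(lo * j, hi * j))
                    ext_r = int(rng.uniform(lo * j, hi * j))
                else:
                    ext_l = ext_r = 0
                start = max(0, config.cnv_start - ext_l)
                end = min(config.chrom_length, config.cnv_end + ext_r)
                noise = rng.normal(0, config.cnv_log2ratio_sd) if config.cnv_log2ratio_sd else 0.0
                rows.append(dict(
                    chrom=config.cnv_chrom, start=start, end=end, type="gain",
                    platform=platform, sample=sample,
                    log2ratio=ratio + noise,
                    n_markers=_markers(config, platform, end - start),
                    call_prob=0.99 if platform == "WES" else float("nan"),
                    origin="planted",
                ))
        for i in range(config.fp_per_sample):
            cls = _DECOY_CLASSES[int(rng.integers(0, len(_DECOY_CLASSES)))]
            row = _make_decoy(config, rng, cls, sample)
            rows.append(row)
            truth.decoy_calls.append(dict(row))

    df = pd.DataFrame(rows, columns=_CALL_COLUMNS)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def _make_decoy(
    config: SyntheticStudyConfig, rng: np.random.Generator, cls: str, sample: str
) -> dict:
    chrom = f"chr{int(rng.integers(1, config.n_chromosomes + 1))}"
    typ = "gain" if rng.random() < 0.5 else "loss"
    sign = 1.0 if typ == "gain" else -1.0
    if cls == "fp_sub5kb_snp":
        length, platform, ratio, prob, markers = 4_000, "SNP", sign * 0.6, float("nan"), 6
    elif cls == "fp_few_markers_snp":
        length, platform, ratio, prob, markers = 20_000, "SNP", sign * 0.6, float("nan"), 3
    elif cls == "fp_low_prob_wes":
        length, platform, ratio, prob = 50_000, "WES", sign * 0.6, 0.8
        markers = _markers(config, "WES", length)
    elif cls == "fp_low_ratio_wes":
        length, platform, ratio, prob = 50_000, "WES", sign * 0.3, 0.95
        markers = _markers(config, "WES", length)
    elif cls == "fp_sex_chrom":
        chrom = "chrX" if rng.random() < 0.5 else "chrY"
        platform = config.platforms[int(rng.integers(0, len(config.platforms)))]
        length, ratio = 200_000, sign * 0.6
        prob = 0.95 if platform == "WES" else float("nan")
        markers = _markers(config, platform, length)
    else:  # pragma: no cover
        raise ValueError(cls)
    start = int(rng.integers(0, config.chrom_length - length))
    return dict(
        chrom=chrom, start=start, end=start + length, type=typ, platform=platform,
        sample=sample, log2ratio=float(ratio), n_markers=int(markers),
        call_prob=float(prob), origin=cls,
    )


# ---------------------------------------------------------------------------
# bulk counts
# ---------------------------------------------------------------------------

def _nb_draw(
    rng: np.random.Generator, mu: np.ndarray, alpha: float
) -> np.ndarray:
    """NB(mu, alpha) with var = mu + alpha*mu^2 (gamma-Poisson mixture)."""
    n = 1.0 / alpha
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def simulate_bulk_counts(
    config: SyntheticStudyConfig,
    truth: PlantedTruth,
    gene_model: pd.DataFrame,
) -> Tuple[pd.DataFrame, pd.Series]:
    """Bulk RNA-seq counts (genes x samples) with the planted dosage effect.

    Counts are NB with mean baseline * size_factor * 2^log2FC(case) and
    dispersion ``nb_dispersion``; size factors are log-normal with sd
    ``size_factor_log_sd``.
    """
    config.validate()
    rng = _rng(config, "bulk")
    genes = list(gene_model["gene"])
    n = config.n_samples_per_group
    samples = [f"control{i + 1}" for i in range(n)] + [f"case{i + 1}" for i in range(n)]
    groups = pd.Series(["control"] * n + ["case"] * n, index=samples, name="group")

    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, len(genes))
    sf = rng.lognormal(0.0, config.size_factor_log_sd, len(samples))
    lfc = np.array([truth.expected_log2fc(g) for g in genes])

    mu = baseline[:, None] * sf[None, :]
    case_mask = (groups.values == "case")[None, :]
    mu = mu * np.where(case_mask, 2.0 ** lfc[:, None], 1.0)
    counts = _nb_draw(rng, mu, config.nb_dispersion)
    return pd.DataFrame(counts, index=genes, columns=samples), groups


# ---------------------------------------------------------------------------
# single-cell counts
# ---------------------------------------------------------------------------

def simulate_sc_counts(
    config: SyntheticStudyConfig,
    truth: PlantedTruth,
    gene_model: pd.DataFrame,
):
    """Per-line single-cell counts as AnnData (cells x genes).

    Cells are drawn from the per-line cluster proportions; each cluster has a
    gene program (disjoint blocks of ``sc_program_size`` genes boosted by
    ``sc_program_strength``); library sizes are log-normal; mitochondrial
    genes contribute ``sc_mito_frac`` of expression; a configurable fraction
    of cells is planted to violate each QC rule.  The case line additionally
    carries the CNV dosage on the amplicon genes.

    Returns a dict ``{"control": AnnData, "case": AnnData}`` with
    ``obs["true_cluster"]`` and ``obs["line"]``.
    """
    import anndata as ad

    config.validate()
    rng = _rng(config, "sc")
    genes = list(gene_model["gene"])
    n_genes = len(genes)
    mito = np.array([g.startswith("MT-") for g in genes])
    cnv = np.array([g in set(truth.cnv_genes) for g in genes])

    # disjoint program gene blocks, excluding mito and cnv genes
    eligible = np.where(~mito & ~cnv)[0]
    programs = [
        eligible[i * config.sc_program_size:(i + 1) * config.sc_program_size]
        for i in range(config.sc_n_clusters)
    ]

    base = rng.lognormal(1.0, 0.5, n_genes)
    base[mito] = 0.0
    profiles = []
    for k in range(config.sc_n_clusters):
        prof = base.copy()
        prof[programs[k]] *= config.sc_program_strength
        prof = prof / prof.sum() * (1.0 - config.sc_mito_frac)
        prof[mito] = config.sc_mito_frac / mito.sum()
        profiles.append(prof)
    profiles = np.array(profiles)  # clusters x genes

    props = {
        "control": np.asarray(truth.sc_control_proportions),
        "case": np.asarray(truth.sc_case_proportions),
    }
    out = {}
    for line in ("control", "case"):
        p = props[line]
        if abs(p.sum() - 1) > 1e-9:
            raise ValueError("cluster proportions must sum to 1")
        n_cells = config.sc_n_cells_per_line
        labels = rng.choice(config.sc_n_clusters, size=n_cells, p=p)
        libs = rng.lognormal(config.sc_lib_log_mean, config.sc_lib_log_sd, n_cells)

        frac = config.sc_qc_violation_frac
        qc_flags = np.array(["ok"] * n_cells, dtype=object)
        pool = rng.permutation(n_cells)
        cursor = 0
        for rule in ("low_features", "high_features", "high_mito"):
            k = int(round(frac.get(rule, 0.0) * n_cells))
            idx = pool[cursor:cursor + k]
            cursor += k
            qc_flags[idx] = rule

        prof_cells = profiles[labels]  # cells x genes
        if line == "case":
            dosage = np.ones(n_genes)
            dosage[cnv] = config.cnv_copy_number / 2.0
            prof_cells = prof_cells * dosage[None, :]
            prof_cells = prof_cells / prof_cells.sum(axis=1, keepdims=True)

        libs = libs.copy()
        libs[qc_flags == "low_features"] = 40.0
        libs[qc_flags == "high_features"] = 200_000.0
        pm = prof_cells.copy()
        high_m = qc_flags == "high_mito"
        if high_m.any():
            pm[high_m] = pm[high_m] * (1 - 0.25) / (1 - config.sc_mito_frac)
            pm[np.ix_(high_m, mito)] = 0.25 / mito.sum()

        counts = rng.poisson(pm * libs[:, None]).astype(np.int32)
        obs = pd.DataFrame(
            {
                "line": line,
                "true_cluster": labels,
                "qc_planted": qc_flags,
            },
            index=[f"{line}_cell{i + 1}" for i in range(n_cells)],
        )
        var = pd.DataFrame(index=pd.Index(genes, name="gene"))
        adata = ad.AnnData(X=counts, obs=obs, var=var)
        out[line] = adata
    return out


# ---------------------------------------------------------------------------
# gene-set collections
# ---------------------------------------------------------------------------

def simulate_gene_sets(
    config: SyntheticStudyConfig,
    truth: PlantedTruth,
    gene_model: pd.DataFrame,
    n_random_sets: int = 15,
    set_size: int = 40,
    planted_fraction: float = 0.6,
    collections: Sequence[str] = ("GOBP", "KEGG", "Reactome"),
) -> Dict[str, Dict[str, List[str]]]:
    """Gene-set collections with one planted set per direction per collection.

    The planted sets draw ``planted_fraction`` of their members from the
    cascade truth of the matching sign (cnv + cascade genes), so enrichment
    ranking should place them first.
    """
    rng = _rng(config, "gene_sets")
    genes = list(gene_model["gene"])
    up = sorted(g for g, v in truth.cascade_log2fc.items() if v > 0)
    down = sorted(g for g, v in truth.cascade_log2fc.items() if v < 0)
    out: Dict[str, Dict[str, List[str]]] = {}
    for coll in collections:
        sets: Dict[str, List[str]] = {}
        for direction, pool in (("up", up), ("down", down)):
            k_pl = min(int(round(set_size * planted_fraction)), len(pool))
            members = list(rng.choice(pool, size=k_pl, replace=False))
            filler = [g for g in genes if g not in set(members)]
            members += list(rng.choice(filler, size=set_size - k_pl, replace=False))
            sets[f"{coll}_planted_{direction}"] = sorted(members)
        for i in range(n_random_sets):
            members = list(rng.choice(genes, size=set_size, replace=False))
            sets[f"{coll}_random{i + 1:02d}"] = sorted(members)
        out[coll] = sets
    return out


# ---------------------------------------------------------------------------
# lineage panel + qPCR
# ---------------------------------------------------------------------------

def simulate_panel_and_qpcr(
    config: SyntheticStudyConfig,
    truth: PlantedTruth,
    gene_model: pd.DataFrame,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.Series, pd.DataFrame]:
    """Lineage signature panel, teratoma-like bulk counts, and Ct tables.

    Returns ``(panel, teratoma_counts, teratoma_groups, ct_table)``.

    * panel: TSV-ready frame (gene, lineage), genes drawn outside the CNV
      region and the mito set.
    * teratoma_counts: NB counts with the per-lineage ``panel_skew`` applied
      to panel genes in the case arm (plus the CNV dosage on amplicon genes).
    * ct_table: long frame (sample, group, assay, role, context, replicate,
      ct) in triplicate; copy-number context uses Ct = base - log2(copies)
      with a constant reference assay, expression context plants the cascade
      log2FC of a few validation genes.
    """
    config.validate()
    rng = _rng(config, "panel")
    genes = list(gene_model["gene"])
    excluded = set(truth.cnv_genes) | {g for g in genes if g.startswith("MT-")}
    eligible = [g for g in genes if g not in excluded]
    need = config.panel_genes_per_lineage * len(LINEAGES)
    picks = rng.choice(eligible, size=need, replace=False)
    panel = pd.DataFrame(
        {
            "gene": picks,
            "lineage": np.repeat(list(LINEAGES), config.panel_genes_per_lineage),
        }
    ).sort_values(["lineage", "gene"]).reset_index(drop=True)
    skew = panel["lineage"].map(lambda l: config.panel_skew.get(l, 0.0)).values

    # teratoma-like bulk counts
    n = config.n_teratomas_per_arm
    samples = [f"terC{i + 1}" for i in range(n)] + [f"terA{i + 1}" for i in range(n)]
    groups = pd.Series(["control"] * n + ["case"] * n, index=samples, name="group")
    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, len(genes))
    sf = rng.lognormal(0.0, config.size_factor_log_sd, len(samples))
    lfc = np.zeros(len(genes))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g, s in zip(panel["gene"], skew):
        lfc[gene_pos[g]] = s
    for g in truth.cnv_genes:
        lfc[gene_pos[g]] = config.dosage_log2fc
    mu = baseline[:, None] * sf[None, :]
    case_mask = (groups.values == "case")[None, :]
    mu = mu * np.where(case_mask, 2.0 ** lfc[:, None], 1.0)
    counts = _nb_draw(rng, mu, config.nb_dispersion)
    ter = pd.DataFrame(counts, index=genes, columns=samples)

    ct = _simulate_ct(config, truth)
    return panel, ter, groups, ct


def _simulate_ct(config: SyntheticStudyConfig, truth: PlantedTruth) -> pd.DataFrame:
    rng = _rng(config, "qpcr")
    rows: List[dict] = []

    def emit(sample, group, assay, role, context, quantity_log2):
        for rep in range(1, 4):  # triplicate
            noise = rng.normal(0.0, config.qpcr_sd) if config.qpcr_sd > 0 else 0.0
            rows.append(dict(
                sample=sample, group=group, assay=assay, role=role,
                context=context, replicate=rep,
                ct=config.ct_base - quantity_log2 + noise,
            ))

    # copy-number context: one case and one control line, target assays on
    # the first four amplicon genes, reference assay with constant quantity
    targets = truth.cnv_genes[:4]
    for sample, group, copies in (
        ("line_ctrl", "control", 2), ("line_case", "case", config.cnv_copy_number)
    ):
        for t in targets:
            emit(sample, group, t, "target", "copy_number", math.log2(copies))
        emit(sample, group, "RNaseP_ref", "reference", "copy_number", math.log2(2.0))

    # expression context: validation genes with the planted cascade log2FC
    val_genes = [g for g in sorted(truth.cascade_log2fc) if g not in truth.cnv_genes][:4]
    for sample, group in (("expr_ctrl", "control"), ("expr_case", "case")):
        for g in val_genes:
            q = truth.cascade_log2fc[g] if group == "case" else 0.0
            emit(sample, group, g, "target", "expression", q)
        emit(sample, group, "GAPDH_ref", "reference", "expression", 0.0)

    return pd.DataFrame(rows)
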