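"""End-to-end orchestration of a synthetic isogenic CNV study.

``run_all`` executes, in dependency order: simulation → CNV consensus →
bulk differential expression → network propagation → enrichment ranking →
single-cell heterogeneity → lineage-signature scoring → qPCR
quantification, writing per-stage tables under the output directory plus a
consolidated ``report.json`` and a ``manifest.json`` (config hash, seeds,
per-stage status and wall time).  All randomness derives from the single
study seed, so two runs of the same config produce identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__
from . import bulk_expression as be
from . import cnv_consensus as cc
from . import enrichment as en
from . import lineage_signatures as ls
from . import network_propagation as npg
from . import qpcr_quant as qq
from . import sc_heterogeneity as sch
from . import synthetic_data as sd

__all__ = ["PipelineConfig", "run_all", "load_config"]


@dataclass
class PipelineConfig:
    """Single config for the whole study, one section per stage.

    The DEG thresholds for the *headline* partition follow the FDR rule
    (|log2FC| >= deg_lfc_thresh and q < deg_fdr); propagation seeds use the
    raw-p preset (p < seed_p_thresh at the same fold-change cut), mirroring
    the distinction between a headline DEG table and the looser seed-gene
    rule feeding network propagation.  Cascade sizes default to desk scale
    (the classic choices 500/1500 remain the library defaults and apply to
    genome-sized networks).
    """

    synthetic: sd.SyntheticStudyConfig = field(default_factory=sd.SyntheticStudyConfig)
    # consensus
    min_support: int = 2
    # bulk DEG
    deg_lfc_thresh: float = 0.3
    deg_fdr: float = 0.05
    seed_lfc_thresh: float = 0.3
    seed_p_thresh: float = 0.055
    # propagation
    rwr_restart: float = 0.5
    cascade_sizes: Tuple[int, int] = (50, 150)
    # enrichment
    gsea_n_perm: int = 250
    enrich_top_n: int = 5
    enrich_alpha: float = 0.05
    # single cell
    sc_n_hvg: int = 500
    sc_n_pcs: int = 20
    sc_k_neighbors: int = 20
    sc_resolution: float = 1.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cascade_sizes"] = list(self.cascade_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        syn = d.pop("synthetic", {})
        if isinstance(syn, dict):
            syn = sd.SyntheticStudyConfig.from_dict(syn)
        known = {f.name for f in dataclasses.fields(cls)} - {"synthetic"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "cascade_sizes" in d:
            d["cascade_sizes"] = tuple(d["cascade_sizes"])
        return cls(synthetic=syn, **d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj


def run_all(config: PipelineConfig, outdir) -> Tuple[dict, dict]:
    """Run every stage; returns (manifest, report) and writes both as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    syn = config.synthetic
    syn.validate()
    manifest: dict = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": syn.seed,
        "stages": {},
        "outputs": [],
    }
    report: dict = {"seed": syn.seed, "config_hash": config.config_hash()}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except Exception as exc:
                manifest["stages"][name] = {
                    "status": "failed", "error": f"{type(exc).__name__}: {exc}",
                    "wall_time_s": round(time.perf_counter() - t0, 3),
                }
                _write_json(outdir / "manifest.json", manifest)
                raise
            manifest["stages"][name] = {
                "status": "ok", "wall_time_s": round(time.perf_counter() - t0, 3),
            }
        return deco

    state: dict = {}

    @stage("simulate")
    def _simulate():
        gm = sd.generate_gene_model(syn)
        net = sd.generate_network(syn, gm)
        truth = sd.make_truth(syn, gm, net)
        calls = sd.simulate_platform_calls(syn, truth)
        bulk, groups = sd.simulate_bulk_counts(syn, truth, gm)
        adatas = sd.simulate_sc_counts(syn, truth, gm)
        gene_sets = sd.simulate_gene_sets(syn, truth, gm)
        panel, ter, ter_groups, ct = sd.simulate_panel_and_qpcr(syn, truth, gm)
        state.update(
            gm=gm, net=net, truth=truth, calls=calls, bulk=bulk, groups=groups,
            adatas=adatas, gene_sets=gene_sets, panel=panel, ter=ter,
            ter_groups=ter_groups, ct=ct,
        )
        _write_tsv(outdir / "gene_model.bed", gm, header=False)
        _write_tsv(outdir / "cnv_calls.tsv", calls)
        _write_tsv(outdir / "bulk_counts.tsv", bulk, index=True)
        _write_tsv(outdir / "panel.tsv", panel)
        _write_tsv(outdir / "ct_table.tsv", ct)
        truth_json = {
            "cnv_genes": truth.cnv_genes,
            "cascade_log2fc": truth.cascade_log2fc,
            "sc_control_proportions": truth.sc_control_proportions,
            "sc_case_proportions": truth.sc_case_proportions,
            "panel_direction": truth.panel_direction,
        }
        _write_json(outdir / "truth.json", _jsonable(truth_json), track=manifest)

    @stage("cnv_consensus")
    def _consensus():
        calls = cc.calls_from_frame(state["calls"])
        filtered = cc.filter_calls(calls)
        by_sample: Dict[str, list] = {}
        for c in filtered:
            by_sample.setdefault(c.sample, []).append(c)
        n = syn.n_samples_per_group
        all_events = []
        venn_rows = []
        for i in range(n):
            ctrl = by_sample.get(f"control{i + 1}", [])
            case = by_sample.get(f"case{i + 1}", [])
            parts = cc.pair_compare(ctrl, case)
            events = cc.build_consensus(parts["acquired"], min_support=config.min_support)
            for e in events:
                e.acquired = True
                cc.annotate_event(
                    e, state["gm"],
                    candidate_region=(syn.cnv_chrom, syn.cnv_start, syn.cnv_end),
                    candidate_genes=state["truth"].cnv_genes,
                )
            all_events.append((f"case{i + 1}", events))
            venn_rows.append({
                "pair": f"control{i + 1}/case{i + 1}",
                "acquired": len(parts["acquired"]),
                "shared": len(parts["shared"]),
                "lost": len(parts["lost"]),
            })
        frames = []
        for sample, events in all_events:
            f = cc.events_to_frame(events)
            f.insert(0, "case_sample", sample)
            frames.append(f)
        events_df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        _write_tsv(outdir / "consensus_events.tsv", events_df)
        _write_tsv(outdir / "pair_venn.tsv", pd.DataFrame(venn_rows))
        sig = events_df[events_df["significant"]] if not events_df.empty else events_df
        report["cnv_consensus"] = {
            "n_case_samples": n,
            "significant_events_per_sample": (
                sig.groupby("case_sample").size().to_dict() if not sig.empty else {}
            ),
            "significant_in_core_region": int(
                (sig["in_core_region"]).sum() if not sig.empty else 0
            ),
            "planted_region_recovered_in_all_cases": bool(
                not sig.empty
                and set(sig[sig["in_core_region"]]["case_sample"]) ==
                {f"case{i + 1}" for i in range(n)}
            ),
        }
        state["events"] = events_df

    @stage("bulk_deg")
    def _bulk():
        counts = be.prefilter_genes(state["bulk"])
        sf = be.rle_size_factors(counts)
        res = be.nb_wald_test(counts, state["groups"], size_factors=sf)
        headline = be.classify_deg(res, config.deg_lfc_thresh, config.deg_fdr)
        seeds = be.classify_deg(
            res, config.seed_lfc_thresh, use_raw_p=True, p_thresh=config.seed_p_thresh
        )
        v = be.vst(counts, size_factors=sf, groups=state["groups"])
        dist = be.sample_distances(v)
        _write_tsv(outdir / "deg_table.tsv", headline, index=True)
        _write_tsv(outdir / "vst_matrix.tsv", v, index=True)
        _write_tsv(outdir / "sample_distances.tsv", dist.distances, index=True)
        state.update(deg=headline, seed_deg=seeds, counts=counts, vst=v)
        truth = state["truth"]
        called_up = set(headline.index[headline["direction"] == "up"])
        called_down = set(headline.index[headline["direction"] == "down"])
        true_up = {g for g, v_ in truth.cascade_log2fc.items()
                   if v_ >= config.deg_lfc_thresh}
        true_down = {g for g, v_ in truth.cascade_log2fc.items()
                     if v_ <= -config.deg_lfc_thresh}
        called = called_up | called_down
        truthset = true_up | true_down
        report["bulk_deg"] = {
            "n_tested": int(headline["tested"].sum()),
            "n_up": len(called_up),
            "n_down": len(called_down),
            "seed_n_up": int((seeds["direction"] == "up").sum()),
            "seed_n_down": int((seeds["direction"] == "down").sum()),
            "mean_log2fc_cnv_genes": float(
                headline.loc[truth.cnv_genes, "log2fc"].mean()
            ),
            "deg_precision_vs_truth": float(
                len(called & truthset) / len(called)) if called else None,
            "deg_recall_vs_truth": float(
                len(called & truthset) / len(truthset)) if truthset else None,
            "top_dendrogram_split_matches_groups": _split_matches(
                dist, state["groups"]
            ),
        }

    @stage("network_propagation")
    def _propagate():
        network = npg.GeneNetwork(state["net"])
        seeds = state["seed_deg"]
        cascades: Dict[str, pd.DataFrame] = {}
        info = {}
        for direction in ("up", "down"):
            seed_genes = sorted(seeds.index[seeds["direction"] == direction])
            seed_genes = [g for g in seed_genes if g in set(network.nodes)]
            if not seed_genes:
                info[direction] = {"n_seeds": 0, "note": "no seed genes; skipped"}
                continue
            res = npg.rwr(network, seed_genes, r=config.rwr_restart)
            for k in config.cascade_sizes:
                casc = npg.select_cascade(res, k=k)
                cascades[f"{direction}_{k}"] = casc
                _write_tsv(outdir / f"cascade_{direction}_{k}.tsv", casc)
            info[direction] = {
                "n_seeds": len(seed_genes),
                "iterations": res.iterations,
                "residual": res.residual,
            }
        state["cascades"] = cascades
        state["seed_lists"] = {
            d: sorted(seeds.index[seeds["direction"] == d]) for d in ("up", "down")
        }
        report["network_propagation"] = info

    @stage("enrichment")
    def _enrich():
        universe = list(state["counts"].index)
        ctrl = state["groups"].index[state["groups"] == "control"]
        case = state["groups"].index[state["groups"] == "case"]
        norm = state["counts"] / be.rle_size_factors(state["counts"])
        ranking = np.log2(
            (norm[case].mean(axis=1) + 1.0) / (norm[ctrl].mean(axis=1) + 1.0)
        )
        records = []
        gsea_frames = []
        for coll, sets in state["gene_sets"].items():
            for direction in ("up", "down"):
                lists = {"deg": state["seed_lists"][direction]}
                for k in config.cascade_sizes:
                    key = f"{direction}_{k}"
                    if key in state["cascades"]:
                        lists[f"cascade_{k}"] = list(state["cascades"][key]["gene"])
                for lname, genes in lists.items():
                    if not genes:
                        continue
                    df = en.ora_collection(genes, sets, universe)
                    df["collection"] = coll
                    df["list"] = lname
                    df["direction"] = direction
                    records.append(df)
            g = en.gsea_preranked(
                ranking, sets, n_perm=config.gsea_n_perm,
                seed=syn.seed + 104729,
            )
            g["collection"] = coll
            gsea_frames.append(g)
        ora_df = pd.concat(records, ignore_index=True)
        ranked = {}
        for direction in ("up", "down"):
            sub = ora_df[ora_df["direction"] == direction]
            ranked[direction] = en.average_p_rank(
                sub, top_n=config.enrich_top_n, alpha=config.enrich_alpha
            )
            _write_tsv(outdir / f"enrichment_{direction}.tsv", ranked[direction])
        gsea_df = pd.concat(gsea_frames, ignore_index=True)
        _write_tsv(outdir / "gsea.tsv", gsea_df)
        top_terms = {}
        planted_first = {}
        for direction, rk in ranked.items():
            tops = rk[rk["rank"] == 1]
            top_terms[direction] = {
                r.collection: r.set for r in tops.itertuples()
            }
            planted_first[direction] = bool(
                all(s.endswith(f"planted_{direction}") for s in top_terms[direction].values())
            ) if len(top_terms[direction]) else False
        report["enrichment"] = {
            "top_set_by_collection": top_terms,
            "planted_set_ranked_first": planted_first,
            "n_gsea_significant": int((gsea_df["q"] < 0.05).sum()),
        }
        state["enrichment_ranked"] = ranked

    @stage("sc_heterogeneity")
    def _sc():
        processed = []
        qc_reports = {}
        for line in ("control", "case"):
            a = state["adatas"][line]
            filt, rep = sch.qc_filter(a)
            qc_reports[line] = rep
            processed.append(sch.normalize_log(filt))
        joint = sch.integrate(
            processed, n_hvg=config.sc_n_hvg, n_pcs=config.sc_n_pcs, seed=syn.seed
        )
        labels = sch.cluster_snn(
            joint.obsm["X_pca"], k_neighbors=config.sc_k_neighbors,
            resolution=config.sc_resolution, seed=syn.seed,
        )
        props = sch.cluster_proportions(labels, joint.obs["line"].to_numpy())
        _write_tsv(outdir / "sc_proportions.tsv", props)
        labels_df = pd.DataFrame(
            {"cell": joint.obs_names, "line": joint.obs["line"].to_numpy(),
             "cluster": labels}
        )
        _write_tsv(outdir / "sc_labels.tsv", labels_df)
        _write_json(outdir / "sc_qc.json", qc_reports, track=manifest)

        import anndata as ad
        full = ad.concat(processed, join="inner")
        markers = sch.cluster_markers(full, labels)
        _write_tsv(outdir / "sc_markers.tsv", markers)

        truth = state["truth"]
        shift = _planted_shift_estimate(
            labels, joint.obs["line"].to_numpy(),
            joint.obs["true_cluster"].to_numpy(), syn.sc_shift_cluster,
        )
        true_shift = (
            truth.sc_case_proportions[syn.sc_shift_cluster]
            - truth.sc_control_proportions[syn.sc_shift_cluster]
        )
        report["sc_heterogeneity"] = {
            "qc": qc_reports,
            "n_clusters": int(len(np.unique(labels))),
            "n_markers": int(len(markers)),
            "planted_shift_true": float(true_shift),
            "planted_shift_estimate": None if shift is None else float(shift),
            "shift_sign_recovered": (
                None if shift is None else bool(np.sign(shift) == np.sign(true_shift))
            ),
        }

    @stage("lineage_signatures")
    def _lineage():
        flt = be.prefilter_genes(state["ter"])
        detected, det_report = ls.detect_panel(state["panel"], flt)
        transformed = ls.rld_normalize(flt)
        deg = be.nb_wald_test(flt, state["ter_groups"])
        sig = (deg["q"] < 0.05).fillna(False)
        n = syn.n_teratomas_per_arm
        half = n // 2
        cgroups = {
            "A": ([f"terA{i + 1}" for i in range(half)],
                  [f"terC{i + 1}" for i in range(half)]),
            "B": ([f"terA{i + 1}" for i in range(half, n)],
                  [f"terC{i + 1}" for i in range(half, n)]),
            "C": ([f"terA{i + 1}" for i in range(n)],
                  [f"terC{i + 1}" for i in range(n)]),
        }
        score = ls.lineage_log2fc(
            transformed, state["ter_groups"], state["panel"], cgroups, significance=sig
        )
        _write_tsv(outdir / "lineage_per_gene.tsv", score.per_gene)
        _write_tsv(outdir / "lineage_per_lineage.tsv", score.per_lineage)
        med = score.per_lineage.pivot(
            index="lineage", columns="group", values="median_log2fc"
        )
        truth = state["truth"]
        direction_ok = {
            lin: bool(np.all(np.sign(med.loc[lin]) == truth.panel_direction[lin]))
            for lin in med.index
            if truth.panel_direction.get(lin, 0) != 0
        }
        report["lineage_signatures"] = {
            "detection": det_report,
            "median_log2fc": {
                lin: {g: float(v) for g, v in med.loc[lin].items()} for lin in med.index
            },
            "direction_matches_truth": direction_ok,
            "concordance_rate": score.concordance_rate,
        }

    @stage("qpcr")
    def _qpcr():
        res = qq.analyze_ct_table(state["ct"])
        _write_tsv(outdir / "qpcr_results.tsv", res)
        cn = res[res["context"] == "copy_number"]
        report["qpcr"] = {
            "mean_copy_number_estimate": float(cn["copy_number"].mean()),
            "true_copy_number": syn.cnv_copy_number,
            "n_assays": int(len(cn)),
        }

    _write_json(outdir / "report.json", _jsonable(report), track=manifest)
    _write_json(outdir / "manifest.json", _jsonable(manifest))
    return manifest, report


def _split_matches(dist: "be.DistanceSummary", groups: pd.Series) -> bool:
    left, right = be.dendrogram_top_split(dist.linkage, dist.distances.index)
    g = {s: groups[s] for s in dist.distances.index}
    sides = [set(g[s] for s in side) for side in (left, right)]
    return bool(all(len(side) == 1 for side in sides))


def _planted_shift_estimate(labels, lines, true_clusters, shift_cluster) -> Optional[float]:
    """Case-minus-control proportion difference of the detected cluster that
    best matches the planted shifted cluster (majority vote over true labels)."""
    labels = np.asarray(labels)
    mask = np.asarray(true_clusters) == shift_cluster
    if not mask.any():
        return None
    matched = pd.Series(labels[mask]).mode().iloc[0]
    est = {}
    for line in ("control", "case"):
        sel = np.asarray(lines) == line
        if sel.sum() == 0:
            return None
        est[line] = float((labels[sel] == matched).mean())
    return est["case"] - est["control"]


def _write_tsv(path: Path, df: pd.DataFrame, index: bool = False, header: bool = True):
    df.to_csv(path, sep="\t", index=index, header=header)


def _write_json(path: Path, obj, track: Optional[dict] = None):
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")
    if track is not None:
        track.setdefault("outputs", []).append(path.name)
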