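"""End-to-end orchestration of the synthetic differentiation analysis.

``run_pipeline`` drives the stages — synthesize → qc → cluster → classify /
pseudotime → fano → de → coexpr — from a single configuration mapping (or
YAML file), with one global seed from which every stage derives its own
substream by stable hashing of the stage name (adding a stage therefore
does not perturb the randomness of the others).  The returned run report
is a plain JSON-serialisable dictionary of stage parameters and headline
outputs; a rerun with the same configuration and seed reproduces it
bit-identically.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import yaml

from . import clustering, coexpression, diffexpr, pseudotime, qc, synthetic, variability
from .io import write_json, write_matrix

logger = logging.getLogger("commitdyn")

STAGE_ORDER = ("synthesize", "qc", "cluster", "classify", "fano", "de", "coexpr")

DEFAULT_CONFIG = {
    "seed": 0,
    "outdir": None,
    "stages": {name: True for name in STAGE_ORDER},
    "synthesize": {"n_cells_per_time": 120},
    "qc": {"min_total": 2000, "downsample_target": 2000, "top_frac": 0.05},
    "cluster": {"k_range": [2, 3, 4], "n_boot": 30, "threshold": 0.75},
    "classify": {"bin_size": 50},
    "fano": {"k": 2, "n_repeats": 5},
    "de": {
        "n_boot": 2000, "fdr": 0.05, "min_fc": 2.0, "min_expr": 1.0,
        "n_early": 10, "n_late": 10, "n_null": 200,
    },
    "coexpr": {"expr_threshold": 1.0, "edge_threshold": 0.8},
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (stable across Python runs)."""
    tag = zlib.crc32(stage.encode()) % 2**31
    return int(np.random.SeedSequence([int(global_seed), tag]).generate_state(1)[0] % 2**31)


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(source) -> dict:
    if source is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    if isinstance(source, (str, Path)):
        source = yaml.safe_load(Path(source).read_text()) or {}
    return _merge(DEFAULT_CONFIG, source)


def report_hash(report: dict) -> str:
    return hashlib.sha256(
        json.dumps(report, sort_keys=True, default=str).encode()
    ).hexdigest()


def run_pipeline(config=None) -> dict:
    """Execute the enabled stages in dependency order and return the run report."""
    cfg = load_config(config)
    seed = int(cfg["seed"])
    outdir = Path(cfg["outdir"]) if cfg.get("outdir") else None
    report: dict = {"seed": seed, "stages_run": []}
    state: dict = {}

    for stage in STAGE_ORDER:
        if not cfg["stages"].get(stage, False):
            continue
        deps = _STAGE_DEPS[stage]
        missing = [d for d in deps if d not in report["stages_run"]]
        if missing:
            raise RuntimeError(f"stage {stage!r} requires {missing} to run first")
        logger.info("running stage %s", stage)
        try:
            _STAGE_FUNCS[stage](cfg, seed, state, report, outdir)
        except Exception as err:  # noqa: BLE001 - annotate failing stage
            raise RuntimeError(f"stage {stage!r} failed: {err}") from err
        report["stages_run"].append(stage)

    report["report_hash"] = report_hash(report)
    if outdir is not None:
        write_json(report, outdir / "run_report.json")
    return report


def _stage_synthesize(cfg, seed, state, report, outdir):
    pars = cfg["synthesize"]
    sc = synthetic.TimecourseConfig(
        n_cells_per_time=int(pars["n_cells_per_time"]),
        seed=stage_seed(seed, "synthesize"),
    )
    adata, truth = synthetic.generate_timecourse_umi(sc)
    state["umi"], state["truth"] = adata, truth
    if outdir is not None:
        write_matrix(adata, outdir / "umi_counts")
        truth.cells.to_csv(outdir / "ground_truth_cells.tsv", sep="\t")
    report["synthesize"] = {
        "n_cells": int(adata.n_obs),
        "n_genes": int((~adata.var["is_spikein"]).sum()),
        "n_spikeins": int(adata.var["is_spikein"].sum()),
        "median_umi_per_cell": float(np.median(qc.cell_totals(adata))),
    }


def _stage_qc(cfg, seed, state, report, outdir):
    pars = cfg["qc"]
    filtered, frep = qc.filter_cells_by_umi(state["umi"], int(pars["min_total"]))
    ref = (filtered.obs["time_h"] == filtered.obs["time_h"].min()).to_numpy()
    norm = qc.normalize_by_reference_median(filtered, ref)
    sel = qc.select_variable_genes(norm, top_frac=float(pars["top_frac"]))
    z = qc.standardize_cv(norm, sel)
    ds = qc.downsample_umi(
        filtered, int(pars["downsample_target"]), seed=stage_seed(seed, "qc")
    )
    cal = qc.calibrate_spikeins(filtered)
    state.update(filtered=filtered, norm=norm, selection=sel, z=z, downsampled=ds)
    if outdir is not None:
        write_matrix(norm, outdir / "normalized")
        sel.stats.to_csv(outdir / "gene_selection.tsv", sep="\t")
        write_json(
            {"slope": cal.slope, "efficiency": cal.efficiency}, outdir / "spike_calibration.json"
        )
    mean_umi = float(qc.cell_totals(filtered).mean())
    report["qc"] = {
        "n_retained": frep.n_retained,
        "n_discarded": frep.n_discarded,
        "n_detected_genes": frep.n_detected_genes,
        "counting_error": qc.counting_error(mean_umi, frep.n_retained).epsilon,
        "n_variable_genes": len(sel.selected),
        "spike_slope": cal.slope,
        "spike_efficiency": cal.efficiency,
    }


def _stage_cluster(cfg, seed, state, report, outdir):
    pars = cfg["cluster"]
    z = state["z"]
    final_t = z.obs["time_h"].max()
    zf = z[z.obs["time_h"] == final_t]
    k = clustering.choose_robust_k(
        zf, pars["k_range"], n_boot=int(pars["n_boot"]),
        seed=stage_seed(seed, "cluster"), threshold=float(pars["threshold"]),
    )
    k_used = max(k, 2)  # downstream anchors need two lineage clusters
    asg = clustering.kmeans_correlation(
        zf, k_used, seed=stage_seed(seed, "cluster") + 1
    )
    stab = clustering.bootstrap_jaccard_stability(
        zf, k_used, n_boot=int(pars["n_boot"]), seed=stage_seed(seed, "cluster") + 2
    )
    state["final_clusters"] = (zf.obs_names, asg)
    report["cluster"] = {
        "final_time_h": float(final_t),
        "robust_k": int(k),
        "k_used": int(k_used),
        "mean_jaccard": [float(j) for j in stab.mean_jaccard],
        "verdicts": stab.verdicts,
    }


def _stage_classify(cfg, seed, state, report, outdir):
    pars = cfg["classify"]
    norm, sel = state["norm"], state["selection"]
    cells, asg = state["final_clusters"]
    # identify the XEN-like cluster by its mean XEN-marker expression
    norm_final = norm[list(cells)]
    xen_markers = [g for g in ("Gata6", "Pdgfra") if g in norm.var_names]
    xen_score = np.asarray(norm_final[:, xen_markers].X).mean(axis=1)
    means = [xen_score[asg.labels == c + 1].mean() for c in range(asg.k)]
    xen_cluster = int(np.argmax(means)) + 1
    ect_cluster = int(np.argmin(means)) + 1
    anchors = {
        "mESC-like": (norm.obs["time_h"] == norm.obs["time_h"].min()).to_numpy(),
        "XEN-like": list(np.asarray(cells)[asg.labels == xen_cluster]),
        "ectoderm-like": list(np.asarray(cells)[asg.labels == ect_cluster]),
    }
    centroids = pseudotime.compute_centroids(norm, anchors, genes=sel.selected)
    cls = pseudotime.classify_by_correlation(norm, centroids)
    pt = pseudotime.pseudotime_order(cls)
    freq = pseudotime.class_frequencies(cls)
    panels = {
        "pluripotency": [g for g in ("Rex1", "Tbx3") if g in norm.var_names],
        "epiblast": [g for g in ("Pou3f1", "Fgf5") if g in norm.var_names],
        "neuroectoderm": [g for g in ("Pax6", "Gbx2") if g in norm.var_names],
        "xen": xen_markers,
    }
    panels = {k: v for k, v in panels.items() if v}
    profiles = {}
    for branch in ("ect", "xen"):
        n_branch = int(pt[f"in_{branch}_branch"].sum())
        if n_branch >= int(pars["bin_size"]):
            profiles[branch] = pseudotime.bin_profiles(
                norm, pt, branch=branch, bin_size=int(pars["bin_size"]),
                panels=panels, genes=sel.selected + [g for p in panels.values() for g in p],
            )
    state.update(classification=cls, pt=pt)
    if outdir is not None:
        pt.to_csv(outdir / "pseudotime.tsv", sep="\t")
    truth = state["truth"].cells.loc[pt.index]
    agree_final = float(
        np.mean(
            pt.loc[truth["time_h"] == truth["time_h"].max(), "label"].map(
                {"mESC-like": "pluripotent", "ectoderm-like": "ectoderm", "XEN-like": "xen"}
            )
            == truth.loc[truth["time_h"] == truth["time_h"].max(), "label"]
        )
    )
    report["classify"] = {
        "class_frequencies": {str(t): row.to_dict() for t, row in freq.iterrows()},
        "final_label_agreement": agree_final,
        "n_bins": {b: len(p.cells_per_bin) for b, p in profiles.items()},
        "mean_tau_by_time": pt.groupby("time_h")["tau"].mean().round(6).to_dict(),
    }


def _stage_fano(cfg, seed, state, report, outdir):
    pars = cfg["fano"]
    ds, sel = state["downsampled"], state["selection"]
    genes = [g for g in sel.selected if g in ds.var_names]
    out = {}
    for t, sub in [
        (float(t), ds[ds.obs["time_h"] == t]) for t in sorted(ds.obs["time_h"].unique())
    ]:
        pop = variability.fano_per_gene(sub, genes)
        entry = {"population": pop.summary, "n_cells": int(sub.n_obs)}
        if sub.n_obs > 3 * int(pars["k"]):
            wc = variability.within_cluster_fano(
                sub, genes, k=int(pars["k"]), n_repeats=int(pars["n_repeats"]),
                seed=stage_seed(seed, "fano"),
            )
            entry["within_cluster"] = wc.summary
        out[str(t)] = entry
    report["fano"] = out


def _stage_de(cfg, seed, state, report, outdir):
    pars = cfg["de"]
    adata, truth = synthetic.generate_regulator_rpkm(
        n_early=int(pars["n_early"]), n_late=int(pars["n_late"]),
        n_null=int(pars["n_null"]), seed=stage_seed(seed, "de-data"),
    )
    gates = diffexpr.gate_by_marker(
        adata, cells=(adata.obs["time_h"] > 0).to_numpy()
    )
    regulators = [
        g for g in adata.var_names
        if truth.gene_class[g] in ("early", "late", "effect")
    ]
    results = {}
    for target_label in ("xen_like", "ect_like"):
        target = list(gates.index[gates == target_label])
        pool = list(gates.index[gates == "null_pool"])
        rec = diffexpr.bootstrap_null_de(
            adata, target, pool, n_boot=int(pars["n_boot"]),
            seed=stage_seed(seed, f"de-{target_label}"),
        )
        sig, _ = diffexpr.apply_de_filters(
            rec, fdr=float(pars["fdr"]), min_fc=float(pars["min_fc"]),
            min_expr=float(pars["min_expr"]), regulator_set=regulators,
        )
        results[target_label] = sig
    all_sig = sorted(set(results["xen_like"]) | set(results["ect_like"]))
    el = diffexpr.classify_early_late(adata, all_sig)
    state.update(regulator_data=(adata, truth), de_significant=results, early_late=el)
    report["de"] = {
        "n_significant": {k: len(v) for k, v in results.items()},
        "early": sorted(el.index[el["class"] == "early"]),
        "late": sorted(el.index[el["class"] == "late"]),
    }


def _stage_coexpr(cfg, seed, state, report, outdir):
    pars = cfg["coexpr"]
    adata, truth = state["regulator_data"]
    genes = [g for g in adata.var_names if truth.gene_class[g] in ("early", "late")]
    cm = coexpression.coexpression_fraction(
        adata, genes, expr_threshold=float(pars["expr_threshold"]), time_point=0.0
    )
    net = coexpression.build_network(cm, edge_threshold=float(pars["edge_threshold"]))
    final_t = float(adata.obs["time_h"].max())
    pm = coexpression.pearson_matrix(adata, genes, time_point=final_t)
    if outdir is not None:
        cm.fractions.to_csv(outdir / "coexpression_0h.tsv", sep="\t")
        net.edges.to_csv(outdir / "coexpression_edges.tsv", sep="\t", index=False)
    report["coexpr"] = {
        "n_edges": int(len(net.edges)),
        "n_isolated": int((net.degrees == 0).sum()),
        "mean_abs_pearson_final": float(np.nanmean(np.abs(pm.to_numpy()[np.triu_indices(len(genes), 1)]))),
    }


_STAGE_FUNCS = {
    "synthesize": _stage_synthesize,
    "qc": _stage_qc,
    "cluster": _stage_cluster,
    "classify": _stage_classify,
    "fano": _stage_fano,
    "de": _stage_de,
    "coexpr": _stage_coexpr,
}

_STAGE_DEPS = {
    "synthesize": (),
    "qc": ("synthesize",),
    "cluster": ("qc",),
    "classify": ("cluster",),
    "fano": ("qc",),
    "de": (),
    "coexpr": ("de",),
}
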