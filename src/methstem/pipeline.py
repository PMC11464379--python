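"""Pipeline configuration and stage orchestration.

A single nested config drives every stage; defaults are the field-standard
analysis constants (QC cutoffs 50,000 CpG sites and 1,500 genes; smoothing
bandwidth 1,000 bp CpG / 500 bp GpC; variance scan bandwidth 2,000, step 10,
threshold 0.2; shrinkage 1; PCA observation fractions 20%/40%; step-fit
improvement 15% with 100 covered cells; LMR test 30 cells per group at FDR
0.05; correlation minimum 5 cells within 2 Mb; differential scan bandwidth
2,000, step 100, 6 cells, FDR 0.05). Unknown config keys are rejected.
Stages run in dependency order and every output file carries a provenance
header with the config hash and seed, so reruns are byte-identical.
"""

from __future__ import annotations

import copy
import hashlib
import json
import os
import sys

import numpy as np
import pandas as pd

from . import assoc, differential, meth_io, trajectory, vmr_scan
from ._stats import log_normalize
from .synthetic_data import SimConfig, simulate_dataset, write_dataset

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "sim": {},  # SimConfig field overrides
    "qc": {"min_cpg_sites": 50_000, "min_genes": 1_500, "tss_margin": 0.1},
    "smooth": {"bandwidth_cpg": 1000, "bandwidth_gpc": 500},
    "scan": {"bandwidth": 2000, "bandwidth_gpc": 1000, "step": 10,
             "var_threshold": 0.2, "min_cells": 10, "shrinkage": 0.0},
    "matrix": {"shrinkage": 1.0, "promoter_half_width": 1000},
    "pca": {"k": 10, "min_obs_fraction": 0.2, "min_obs_fraction_acc": 0.4,
            "exclude_components": []},
    "waves": {"min_improvement": 0.15, "min_cells_per_region": 100,
              "min_side": 3, "wave_window": [250, 400]},
    "lmr": {"min_cells": 30, "fdr": 0.05},
    "score": {"margin": 0.0},
    "correlate": {"min_cells": 5, "window_mb": 2.0},
    "diff": {"bandwidth": 2000, "step": 100, "min_cells": 6, "fdr": 0.05},
}

#: scaled-down problem for the one-command demo: a 2 x 2 Mb genome with 240
#: cells cannot reach 50,000 covered CpGs per cell, so the demo block scales
#: the QC cutoffs with its genome while every analysis constant keeps its
#: standard value.
DEMO_CONFIG: dict = {
    "seed": 0,
    "sim": {"n_chroms": 2, "chrom_len_bp": 2_000_000, "n_cells": 240,
            "n_variable_regions": 60, "n_genes": 60,
            # astrocyte-enriched sampling, as in the GLAST+ FACS design
            "states": [["astrocyte", 0.35], ["qNSC", 0.20], ["aNSC", 0.10],
                       ["TAP", 0.20], ["neuroblast", 0.15]],
            "level_pairs": [[0.0, 1.0], [1.0, 0.0]],
            "lmr_low": 0.0, "lmr_high": 1.0},
    "qc": {"min_cpg_sites": 4_000, "min_genes": 10},
}


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, val in override.items():
        if key not in defaults:
            raise KeyError(f"unknown config key: {path}{key}")
        if isinstance(defaults[key], dict) and key != "sim":
            if not isinstance(val, dict):
                raise TypeError(f"config key {path}{key} must be a mapping")
            out[key] = _merge(defaults[key], val, f"{path}{key}.")
        else:
            out[key] = val
    return out


def load_config(overrides: dict | None = None) -> dict:
    """Full config from defaults plus overrides; unknown keys rejected.
    ``sim`` overrides are validated against SimConfig fields."""
    cfg = _merge(DEFAULT_CONFIG, overrides or {})
    valid_sim = set(SimConfig.__dataclass_fields__)
    unknown = set(cfg["sim"]) - valid_sim
    if unknown:
        raise KeyError(f"unknown sim config keys: {sorted(unknown)}")
    return cfg


def _hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:12]


def _log(stage: str, out_dir: str, **fields) -> None:
    line = json.dumps({"stage": stage, **fields}, sort_keys=True)
    print(line, file=sys.stderr)
    with open(os.path.join(out_dir, "pipeline_log.jsonl"), "a") as fh:
        fh.write(line + "\n")


def _write(df: pd.DataFrame, path: str, prov: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {prov}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: dict | None = None, out_dir: str = "methstem_out",
                 write_cov_files: bool = False) -> dict:
    """Run simulate -> qc -> smooth -> scan -> matrix -> pca -> waves -> lmr
    -> score -> correlate on a synthetic dataset, writing one table per stage.

    Returns the in-memory artifacts keyed by stage. Deterministic for a fixed
    config (the seed lives in the config; no wall-clock anywhere).
    """
    cfg = load_config(config)
    os.makedirs(out_dir, exist_ok=True)
    log_path = os.path.join(out_dir, "pipeline_log.jsonl")
    if os.path.exists(log_path):
        os.remove(log_path)
    prov = f"methstem config={_hash(cfg)} seed={cfg['seed']}"
    art: dict = {"config": cfg}

    # --- simulate ------------------------------------------------------
    sim_cfg = SimConfig(**{**cfg["sim"], "seed": cfg["seed"]})
    ds = simulate_dataset(sim_cfg)
    art["dataset"] = ds
    if write_cov_files:
        write_dataset(ds, os.path.join(out_dir, "dataset"))
    ds.truth.cells.to_csv(os.path.join(out_dir, "cell_metadata.tsv"),
                          sep="\t", index=False)
    _log("simulate", out_dir, n_cells=len(ds.meth_cells),
         n_regions=len(ds.truth.regions), seed=cfg["seed"])

    # --- qc ------------------------------------------------------------
    lognorm_all = pd.DataFrame(log_normalize(ds.counts.to_numpy()),
                               index=ds.counts.index, columns=ds.counts.columns)
    tss = ds.truth.genes[["gene_id", "chrom", "tss", "strand"]]
    qc_report, kept = meth_io.cell_qc(
        ds.meth_cells, ds.counts, tss,
        min_cpg_sites=cfg["qc"]["min_cpg_sites"],
        min_genes=cfg["qc"]["min_genes"], tss_margin=cfg["qc"]["tss_margin"])
    _write(qc_report, os.path.join(out_dir, "qc_report.tsv"), prov)
    if not kept:
        raise RuntimeError("stage qc: no cell passed QC; check qc thresholds "
                           "against the simulated genome size")
    kept_ids = [c.cell_id for c in kept]
    meta = ds.truth.cells.set_index("cell_id").loc[kept_ids].reset_index()
    _log("qc", out_dir, n_pass=len(kept), n_fail=len(qc_report) - len(kept))

    # --- smooth --------------------------------------------------------
    track = meth_io.smooth_ensemble(kept, "CpG",
                                    bandwidth_bp=cfg["smooth"]["bandwidth_cpg"])
    _log("smooth", out_dir, context="CpG",
         bandwidth=cfg["smooth"]["bandwidth_cpg"])

    # --- scan ----------------------------------------------------------
    windows = vmr_scan.scan_variance_windows(
        kept, track, bandwidth_bp=cfg["scan"]["bandwidth"],
        step_bp=cfg["scan"]["step"], var_threshold=cfg["scan"]["var_threshold"],
        min_cells=cfg["scan"]["min_cells"], shrinkage=cfg["scan"]["shrinkage"])
    vmrs = vmr_scan.merge_windows_to_vmrs(windows)
    vmr_regions = [
        meth_io.GenomicRegion(r.chrom, r.start, r.end, label=f"VMR_{i:04d}")
        for i, r in enumerate(vmrs.regions)]
    meth_io.write_bed(vmr_regions, os.path.join(out_dir, "vmrs.bed"),
                      scores=[f"{v:.3f}" for v in vmrs.peak_variance],
                      provenance=prov)
    art["vmrs"] = vmrs
    _log("scan", out_dir, n_windows=len(windows), n_vmrs=len(vmr_regions))
    if not vmr_regions:
        raise RuntimeError("stage scan: no VMR detected")

    # --- matrix --------------------------------------------------------
    matrix = meth_io.quantify_regions(kept, vmr_regions, track=track,
                                      shrinkage=cfg["matrix"]["shrinkage"])
    art["matrix"] = matrix
    _log("matrix", out_dir, n_regions=len(vmr_regions), n_cells=len(kept))

    # --- pca -----------------------------------------------------------
    k = min(cfg["pca"]["k"], len(kept) - 1, len(vmr_regions))
    pca = trajectory.iterative_pca(
        matrix, k=k, min_obs_fraction=cfg["pca"]["min_obs_fraction"])
    keep_comp = [i for i in range(k)
                 if i not in set(cfg["pca"]["exclude_components"])]
    scores = pd.DataFrame(
        pca.cell_scores[:, keep_comp], columns=[f"PC{i + 1}" for i in keep_comp])
    scores.insert(0, "cell_id", kept_ids)
    _write(scores, os.path.join(out_dir, "pca_scores.tsv"), prov)
    art["pca"] = pca
    _log("pca", out_dir, k=k, n_iterations=pca.n_iterations,
         converged=pca.converged)

    # --- waves ---------------------------------------------------------
    fits = trajectory.fit_region_steps(matrix, meta,
                                       min_side=cfg["waves"]["min_side"])
    events = trajectory.call_methylation_events(
        fits, min_improvement=cfg["waves"]["min_improvement"],
        min_cells_per_region=cfg["waves"]["min_cells_per_region"])
    _write(events, os.path.join(out_dir, "methylation_events.tsv"), prov)
    wave_window = sim_cfg.rank_window("wave2")
    wave = trajectory.select_wave_events(events, wave_window, vmr_regions,
                                         ds.truth.gene_bodies())
    _write(wave, os.path.join(out_dir, "wave_events.tsv"), prov)
    art["events"] = events
    _log("waves", out_dir, n_events=int(events.is_event.sum()),
         n_wave=len(wave), wave_window=list(wave_window))

    # --- lmr -----------------------------------------------------------
    astro_ids = meta.loc[meta.state == "astrocyte", "cell_id"].tolist()
    nsc_ids = meta.loc[meta.state != "astrocyte", "cell_id"].tolist()
    lmrs = differential.wilcoxon_lmrs(
        matrix, astro_ids, nsc_ids, min_cells=cfg["lmr"]["min_cells"],
        alpha=cfg["lmr"]["fdr"], gene_bodies=ds.truth.gene_bodies())
    _write(lmrs, os.path.join(out_dir, "lmr_table.tsv"), prov)
    art["lmrs"] = lmrs
    _log("lmr", out_dir,
         n_astro=int((lmrs.label == "astrocyte_LMR").sum()),
         n_nsc=int((lmrs.label == "NSC_LMR").sum()))

    # --- score ---------------------------------------------------------
    def _regions_of(label):
        sub = lmrs[lmrs.label == label]
        return [meth_io.GenomicRegion(r.chrom, int(r.start), int(r.end),
                                      label=r.region_id)
                for r in sub.itertuples()]
    astro_set = _regions_of("astrocyte_LMR")
    nsc_set = _regions_of("NSC_LMR")
    if astro_set and nsc_set:
        m_astro = meth_io.quantify_regions(kept, astro_set, track=track,
                                           shrinkage=cfg["matrix"]["shrinkage"])
        m_nsc = meth_io.quantify_regions(kept, nsc_set, track=track,
                                         shrinkage=cfg["matrix"]["shrinkage"])
        score = differential.methylation_score(m_astro, m_nsc,
                                               margin=cfg["score"]["margin"])
        score = score.rename(columns={"state": "methylome_state"})
        score = score.merge(meta[["cell_id", "state", "pseudotime_rank"]],
                            on="cell_id")
        _write(score, os.path.join(out_dir, "methylation_score.tsv"), prov)
        art["score"] = score
        _log("score", out_dir, n_astro_like=int(
            (score.methylome_state == "astrocyte_methylome").sum()))
    else:
        _log("score", out_dir, skipped="one LMR set empty")

    # --- correlate -----------------------------------------------------
    lognorm = lognorm_all[kept_ids]
    assign = assoc.nearest_gene(vmr_regions, ds.truth.gene_bodies())
    corr = assoc.correlate_feature_expression(
        matrix, lognorm, assign, min_cells=cfg["correlate"]["min_cells"])
    _write(corr, os.path.join(out_dir, "vmr_expression_correlation.tsv"), prov)
    art["correlation"] = corr
    _log("correlate", out_dir, n_tested=len(corr),
         n_significant=int((corr.adj_p < 0.05).sum()) if len(corr) else 0)
    return art
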