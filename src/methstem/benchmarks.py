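"""Ground-truth recovery and calibration studies on synthetic data.

Each function simulates a dataset with known structure, runs the relevant
pipeline stage from scratch, and returns summary metrics: exactness of the
step-fit optimizer against brute-force enumeration, changepoint recovery
error and event-calling operating characteristics, VMR scan recall/precision,
iterative-PCA fidelity, LMR-test FDR and power, methylome-state
classification accuracy, the direction of expression change in
TSS-downstream methylation bins, the distance histogram mode, and the null
calibration of the differential scan. These are the quantitative checks the
package's claims rest on; the numbers are recomputed, never stored.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import assoc, differential, meth_io, trajectory, vmr_scan
from ._stats import log_normalize
from .meth_io import CpGCallSet, GenomicRegion, RegionMatrix
from .synthetic_data import SimConfig, simulate_dataset, simulate_step_series

__all__ = [
    "step_fit_oracle_agreement", "changepoint_recovery", "vmr_scan_recovery",
    "iterative_pca_fidelity", "lmr_calibration", "methylome_state_accuracy",
    "tss_binning_direction", "distance_histogram_mode", "diff_scan_calibration",
]


# ---------------------------------------------------------------------------
# 1. step-fit optimizer vs exhaustive enumeration
# ---------------------------------------------------------------------------

def _brute_force_step(values, ranks, min_side=3):
    ok = ~np.isnan(values)
    order = np.argsort(ranks[ok], kind="stable")
    v = values[ok][order]
    r = np.asarray(ranks[ok])[order]
    n = len(v)
    best = None
    for i in range(1, n):
        if i < min_side or n - i < min_side or r[i] == r[i - 1]:
            continue
        sse = (((v[:i] - v[:i].mean()) ** 2).sum()
               + ((v[i:] - v[i:].mean()) ** 2).sum())
        if best is None or sse < best[0] - 1e-12:
            best = (sse, (r[i - 1] + r[i]) / 2.0)
    return best


def step_fit_oracle_agreement(n_series: int = 200, seed: int = 0) -> dict:
    """Fraction of random noisy series (n <= 50, with missingness) where the
    closed-form step fit exactly matches brute-force enumeration."""
    rng = np.random.default_rng(seed)
    n_checked = n_agree = 0
    for _ in range(n_series):
        n = int(rng.integers(8, 51))
        v = rng.normal(size=n)
        v[rng.random(n) < 0.2] = np.nan
        ranks = rng.permutation(n) + 1
        fit = trajectory.fit_step_function(v, ranks)
        oracle = _brute_force_step(v, ranks)
        if oracle is None:
            n_checked += 1
            n_agree += not fit.valid
            continue
        n_checked += 1
        n_agree += (fit.valid
                    and abs(fit.sse_step - oracle[0]) <= 1e-9
                    and fit.s == oracle[1])
    return {"agreement_fraction": n_agree / n_checked, "n": n_checked}


# ---------------------------------------------------------------------------
# 2. changepoint recovery
# ---------------------------------------------------------------------------

def changepoint_recovery(n_regions: int = 500, n_cells: int = 500,
                         level_gap: float = 0.6, seed: int = 0) -> dict:
    """Recovery of planted change points and event-calling error rates.

    Regions step by ``level_gap`` at a known rank under Bernoulli site noise;
    an equal-sized cohort of constant regions measures the false-event rate
    of the 15%-improvement criterion.
    """
    values, ranks, cps, _ = simulate_step_series(
        n_regions=n_regions, n_cells=n_cells, level_gap=level_gap, seed=seed)
    errors, improvements, n_obs = [], [], []
    for j in range(n_regions):
        fit = trajectory.fit_step_function(values[:, j], ranks)
        errors.append(abs(fit.s - cps[j] + 0.5))
        improvements.append(fit.improvement)
        n_obs.append(fit.n_obs)
    errors = np.array(errors)
    improvements = np.array(improvements)
    n_obs = np.array(n_obs)
    usable = n_obs >= 100
    recall = float(np.mean(improvements[usable] >= 0.15))

    null_vals, null_ranks, _, _ = simulate_step_series(
        n_regions=n_regions, n_cells=n_cells, constant=True, seed=seed + 1)
    false_rate = float(np.mean([
        trajectory.fit_step_function(null_vals[:, j], null_ranks).improvement
        >= 0.15 for j in range(n_regions)]))
    return {
        "median_abs_changepoint_error_ranks": float(np.median(errors[usable])),
        "event_recall": recall,
        "false_event_rate": false_rate,
        "n": int(usable.sum()),
    }


# ---------------------------------------------------------------------------
# 3. VMR scan recovery
# ---------------------------------------------------------------------------

def _scan_config(n_regions, seed):
    return SimConfig(
        n_chroms=1, chrom_len_bp=5_000_000, n_cells=100,
        n_variable_regions=n_regions, n_genes=0, seed=seed,
        class_proportions=(("variable_other", 1.0),),
        lmr_low=0.0, lmr_high=1.0,  # bimodal across cells: between-cell sd 0.5
        coverage_fraction_range=(0.4, 0.8),
    )


def vmr_scan_recovery(n_regions: int = 20, seed: int = 0) -> dict:
    """Recall/precision/Jaccard of the variance scan against planted regions,
    plus the VMR count on an exchangeable-cell null genome."""
    ds = simulate_dataset(_scan_config(n_regions, seed))
    track = meth_io.smooth_ensemble(ds.meth_cells, "CpG", 1000)
    windows = vmr_scan.scan_variance_windows(ds.meth_cells, track,
                                             2000, 10, 0.2, 10)
    vmrs = vmr_scan.merge_windows_to_vmrs(windows)

    def jaccard(a, b):
        inter = max(0, min(a.end, b.end) - max(a.start, b.start))
        union = (a.end - a.start) + (b.end - b.start) - inter
        return inter / union if union else 0.0

    truth = ds.truth.region_list()
    matched_truth = sum(
        any(jaccard(t, r) >= 0.5 for r in vmrs.regions) for t in truth)
    matched_pred = sum(
        any(jaccard(t, r) >= 0.5 for t in truth) for r in vmrs.regions)
    recall = matched_truth / len(truth)
    precision = matched_pred / len(vmrs.regions) if len(vmrs.regions) else 0.0
    jaccards = [max((jaccard(t, r) for r in vmrs.regions), default=0.0)
                for t in truth]

    null_ds = simulate_dataset(_scan_config(0, seed + 1))
    null_track = meth_io.smooth_ensemble(null_ds.meth_cells, "CpG", 1000)
    null_windows = vmr_scan.scan_variance_windows(
        null_ds.meth_cells, null_track, 2000, 10, 0.2, 10)
    return {
        "recall": float(recall),
        "precision": float(precision),
        "mean_jaccard": float(np.mean(jaccards)),
        "null_vmr_count": int(len(vmr_scan.merge_windows_to_vmrs(null_windows))),
        "n": n_regions,
    }


# ---------------------------------------------------------------------------
# 4. iterative PCA
# ---------------------------------------------------------------------------

def iterative_pca_fidelity(seed: int = 0) -> dict:
    """Complete-data agreement with direct PCA and subspace recovery under
    30% missingness on a planted rank-2 structure."""
    rng = np.random.default_rng(seed)
    n, p, k = 150, 60, 2
    U = rng.normal(size=(n, k))
    V = rng.normal(size=(p, k))
    X = U @ V.T + 0.02 * rng.normal(size=(n, p))

    res = trajectory.iterative_pca(X, k=k, min_obs_fraction=0.0,
                                   center_cells=False)
    # direct-PCA oracle: plain SVD of the column-centred complete matrix
    Xc = X - X.mean(axis=0)
    Uo, So, Vto = np.linalg.svd(Xc, full_matrices=False)
    direct_scores = Uo[:, :k] * So[:k]
    comp_r = [abs(np.corrcoef(res.cell_scores[:, j], direct_scores[:, j])[0, 1])
              for j in range(k)]

    Xm = X.copy()
    Xm[rng.random(X.shape) < 0.3] = np.nan
    resm = trajectory.iterative_pca(Xm, k=k, min_obs_fraction=0.0,
                                    center_cells=False)
    from scipy.linalg import subspace_angles
    angle = float(np.rad2deg(subspace_angles(resm.feature_loadings,
                                             Vto[:k].T).max()))
    return {"min_component_abs_r": float(min(comp_r)),
            "missing_subspace_angle_deg": angle, "n": n}


# ---------------------------------------------------------------------------
# 5. LMR calibration
# ---------------------------------------------------------------------------

def _binomial_matrix(rng, levels, n_cells, sites=8):
    """cells x regions raw methylation fractions from per-site Bernoulli."""
    n_regions = levels.shape[1] if levels.ndim == 2 else len(levels)
    k = np.maximum(rng.poisson(sites, size=(n_cells, n_regions)), 1)
    return rng.binomial(k, levels) / k


def lmr_calibration(n_vmrs: int = 1000, frac_diff: float = 0.10,
                    delta: float = 0.4, n_per_group: int = 100,
                    n_replicates: int = 5, seed: int = 0) -> dict:
    """Realized FDR and power of Wilcoxon+BH LMR calling on planted
    differential VMRs, plus the significant fraction on a pure null.

    FDR is an expectation (E[false-discovery proportion]); with ~5 expected
    false positives per experiment a single realization is dominated by
    Poisson noise, so the FDP and power are averaged over ``n_replicates``
    independent experiments of the stated size.
    """
    rng = np.random.default_rng(seed)
    n_diff = int(n_vmrs * frac_diff)
    base = 0.5 - delta / 2
    cells = ([f"a{i}" for i in range(n_per_group)]
             + [f"b{i}" for i in range(n_per_group)])
    regions = [GenomicRegion("chr1", j * 1000, j * 1000 + 500, label=f"v{j}")
               for j in range(n_vmrs)]

    def one_experiment(lv_a, lv_b):
        raw = np.vstack([
            _binomial_matrix(rng, np.tile(lv_a, (n_per_group, 1)), n_per_group),
            _binomial_matrix(rng, np.tile(lv_b, (n_per_group, 1)), n_per_group),
        ])
        mat = RegionMatrix(regions=regions, cells=cells, values=raw - 0.5,
                           n_obs=np.full(raw.shape, 8, dtype=int), raw_mean=raw)
        table = differential.wilcoxon_lmrs(mat, cells[:n_per_group],
                                           cells[n_per_group:], min_cells=30)
        return table.label != "ns"

    lv_a = np.full(n_vmrs, 0.5)
    lv_b = np.full(n_vmrs, 0.5)
    lv_a[:n_diff] = base
    lv_b[:n_diff] = base + delta
    fdps, powers = [], []
    for _ in range(n_replicates):
        called = one_experiment(lv_a, lv_b)
        fdps.append(called[n_diff:].sum() / max(called.sum(), 1))
        powers.append(called[:n_diff].sum() / n_diff)

    null_called = one_experiment(np.full(n_vmrs, 0.5), np.full(n_vmrs, 0.5))
    return {
        "realized_fdr": float(np.mean(fdps)),
        "power": float(np.mean(powers)),
        "null_significant_fraction": float(null_called.mean()),
        "n": n_vmrs,
    }


# ---------------------------------------------------------------------------
# 6. methylome-state score
# ---------------------------------------------------------------------------

def methylome_state_accuracy(n_per_pop: int = 100, n_lmrs: int = 60,
                             seed: int = 0) -> dict:
    """Classification accuracy on simulated astrocyte (astro-LMR 0.2 /
    NSC-LMR 0.8) vs NSC (0.8 / 0.2) populations, >= 50 covered LMRs/cell."""
    rng = np.random.default_rng(seed)
    cells = [f"x{i}" for i in range(2 * n_per_pop)]

    def lmr_matrix(level_pop1, level_pop2):
        raw = np.vstack([
            _binomial_matrix(rng, np.full((n_per_pop, n_lmrs), level_pop1),
                             n_per_pop, sites=5),
            _binomial_matrix(rng, np.full((n_per_pop, n_lmrs), level_pop2),
                             n_per_pop, sites=5),
        ])
        regions = [GenomicRegion("chr1", j * 200, j * 200 + 100, label=f"l{j}")
                   for j in range(n_lmrs)]
        return RegionMatrix(regions=regions, cells=cells, values=raw - 0.5,
                            n_obs=np.full(raw.shape, 5, dtype=int),
                            raw_mean=raw)

    astro_mat = lmr_matrix(0.2, 0.8)   # astro LMRs: low in astrocytes
    nsc_mat = lmr_matrix(0.8, 0.2)     # NSC LMRs: low in the NSC lineage
    res = differential.methylation_score(astro_mat, nsc_mat)
    truth = np.array(["astrocyte_methylome"] * n_per_pop
                     + ["NSC_methylome"] * n_per_pop)
    return {"accuracy": float((res.state.to_numpy() == truth).mean()),
            "n": 2 * n_per_pop}


# ---------------------------------------------------------------------------
# 7 & 8. TSS-downstream binning and distance histogram (shared dataset)
# ---------------------------------------------------------------------------

def _coupled_dataset(seed: int):
    cfg = SimConfig(
        n_chroms=1, chrom_len_bp=2_000_000, n_cells=200,
        n_variable_regions=40, n_genes=40, seed=seed,
        states=(("astrocyte", 0.35), ("qNSC", 0.20), ("aNSC", 0.10),
                ("TAP", 0.20), ("neuroblast", 0.15)),
        level_pairs=((0.05, 0.95), (0.95, 0.05)),
        lmr_low=0.05, lmr_high=0.95,
        coverage_fraction_range=(0.4, 0.8),
        coupling_sign=-1, coupling_effect=2.5,
    )
    ds = simulate_dataset(cfg)
    track = meth_io.smooth_ensemble(ds.meth_cells, "CpG", 1000)
    lognorm = pd.DataFrame(log_normalize(ds.counts.to_numpy()),
                           index=ds.counts.index, columns=ds.counts.columns)
    return ds, track, lognorm


def tss_binning_direction(seed: int = 0) -> dict:
    """With methylation silencing expression, the fraction of significantly
    binned genes (|dmeth| >= 10%) whose expression moves opposite to
    methylation."""
    ds, track, lognorm = _coupled_dataset(seed)
    tss = ds.truth.genes[["gene_id", "chrom", "tss", "strand"]]
    intervals = differential.tss_downstream_regions(tss)
    tss_mat = meth_io.quantify_regions(ds.meth_cells, intervals, track=track)
    meta = ds.truth.cells
    group_a = meta.loc[meta.state == "astrocyte", "cell_id"].tolist()
    group_b = meta.loc[meta.state != "astrocyte", "cell_id"].tolist()
    table, _ = differential.tss_downstream_bins(tss_mat, lognorm,
                                                group_a, group_b)
    strong = table[table.significant & (table.dmeth.abs() >= 0.10)
                   & (table.expr_direction != "ns")]
    opposite = (np.sign(strong.dexpr) != np.sign(strong.dmeth)).mean()
    return {"opposite_direction_fraction": float(opposite), "n": len(strong)}


def distance_histogram_mode(seed: int = 0) -> dict:
    """Mode bin of the significant-correlation distance histogram when
    coupled regions sit 3 kb downstream of their TSSs."""
    ds, track, lognorm = _coupled_dataset(seed)
    linked = ds.truth.genes[ds.truth.genes.linked_region != ""]
    region_ids = set(linked.linked_region)
    regions = [r for r in ds.truth.region_list() if r.label in region_ids]
    mat = meth_io.quantify_regions(ds.meth_cells, regions, track=track)
    tss = ds.truth.genes[["gene_id", "chrom", "tss", "strand"]]
    _, hist = assoc.distance_histogram(mat, tss, lognorm, bin_bp=2000)
    total = hist.n_negative + hist.n_positive
    mode = hist.loc[total.idxmax()]
    return {"mode_bin_start_kb": float(mode.bin_start / 1000),
            "mode_bin_end_kb": float(mode.bin_end / 1000),
            "n": int(total.sum())}


# ---------------------------------------------------------------------------
# 9. differential scan calibration
# ---------------------------------------------------------------------------

def diff_scan_calibration(seed: int = 0) -> dict:
    """Null calibration (exchangeable groups) and planted-DMR recovery of the
    windowed two-group scan."""
    rng = np.random.default_rng(seed)
    length = 1_000_000
    pos = np.sort(rng.choice(length, size=length // 100, replace=False))

    def make_cells(n, prefix, dmr=None, p_in=0.5, background=0.5):
        level = np.full(len(pos), background)
        if dmr is not None:
            level[(pos >= dmr[0]) & (pos < dmr[1])] = p_in
        cells = []
        for i in range(n):
            obs = rng.random(len(pos)) < 0.6
            meth = (rng.random(len(pos)) < level).astype(np.int64)
            cells.append(CpGCallSet(
                f"{prefix}{i:03d}", "CpG",
                {"chr1": (pos[obs], meth[obs], np.ones(obs.sum(), np.int64))}))
        return cells

    null_a = make_cells(50, "na")
    null_b = make_cells(50, "nb")
    track = meth_io.smooth_ensemble(null_a + null_b, "CpG", 1000)
    null_res = vmr_scan.diff_scan(null_a, null_b, track)
    n_win = len(null_res.windows)
    null_frac = float((null_res.windows.adj_p < 0.05).mean()) if n_win else 0.0
    mc_bound = 0.05 + 3 * np.sqrt(0.05 * 0.95 / max(n_win, 1))

    dmr = (500_000, 502_000)
    pl_a = make_cells(50, "pa", dmr=dmr, p_in=0.2)
    pl_b = make_cells(50, "pb", dmr=dmr, p_in=0.7)
    track2 = meth_io.smooth_ensemble(pl_a + pl_b, "CpG", 1000)
    res = vmr_scan.diff_scan(pl_a, pl_b, track2)
    hit = res.regions[(res.regions.start < dmr[1]) & (res.regions.end > dmr[0])]
    recovered = len(hit) >= 1 and (hit.direction == "hyper_in_b").all()
    return {
        "null_significant_fraction": null_frac,
        "null_bound": float(mc_bound),
        "planted_dmr_recovered": bool(recovered),
        "n": n_win,
    }
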