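"""Sliding-window detection of variably methylated regions and condition DMRs.

A window of fixed width slides along each chromosome in small steps. In each
window every covered cell contributes the shrunken mean of its residuals from
the smoothed ensemble track; windows where the between-cell variance of these
values exceeds a threshold (0.2 by convention for CpG methylation, with a
2,000 bp window stepped by 10 bp) are flagged and merged into variably
methylated regions (VMRs; VARs for the GpC layer). The same machinery with a
two-group Wilcoxon rank-sum test per window (2,000 bp windows stepped by
100 bp, at least 6 covered cells per group, BH-adjusted at FDR 0.05) yields
differentially methylated regions between conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._stats import bh_adjust, rank_sum_test
from .meth_io import CpGCallSet, GenomicRegion, SmoothedTrack

__all__ = ["VMRSet", "DiffScanResult", "scan_variance_windows",
           "merge_windows_to_vmrs", "diff_scan"]


@dataclass
class VMRSet:
    regions: list[GenomicRegion]
    peak_variance: np.ndarray
    n_cells_covered: np.ndarray

    def __len__(self):
        return len(self.regions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": [r.chrom for r in self.regions],
            "start": [r.start for r in self.regions],
            "end": [r.end for r in self.regions],
            "peak_variance": self.peak_variance,
            "n_cells_covered": self.n_cells_covered,
        })


@dataclass
class DiffScanResult:
    """Merged differential regions plus the per-window test table."""
    regions: pd.DataFrame   # chrom,start,end,mean_a,mean_b,difference,min_adj_p,direction
    windows: pd.DataFrame   # per tested window: means, p, adj_p
    status: str = "ok"      # "ok" or a warning, e.g. groups too small


def _residual_matrix(cells: Sequence[CpGCallSet], track: SmoothedTrack,
                     chrom: str):
    """Union site grid on one chromosome plus a cells x sites residual matrix
    (NaN where unobserved) and a parallel raw call-value matrix."""
    all_pos = [cell.calls[chrom][0] for cell in cells if chrom in cell.calls]
    if not all_pos:
        return None
    sites = np.unique(np.concatenate(all_pos))
    smoothed = track.at(chrom, sites)
    n_cells = len(cells)
    resid = np.full((n_cells, len(sites)), np.nan, dtype=np.float64)
    raw = np.full((n_cells, len(sites)), np.nan, dtype=np.float64)
    for ci, cell in enumerate(cells):
        if chrom not in cell.calls:
            continue
        pos, meth, total = cell.calls[chrom]
        idx = np.searchsorted(sites, pos)
        vals = meth.astype(float) / np.maximum(total, 1)
        raw[ci, idx] = vals
        resid[ci, idx] = vals - smoothed[idx]
    return sites, resid, raw


def _window_cell_means(sites, matrix, starts, width, shrinkage):
    """Per-cell shrunken window means for all window start positions.

    Returns (means, counts): means is cells x windows with NaN where a cell
    has no site in the window; counts the per-cell observed-site counts.
    """
    filled = np.nan_to_num(matrix, nan=0.0)
    cs = np.concatenate([np.zeros((matrix.shape[0], 1)), np.cumsum(filled, axis=1)], axis=1)
    obs = ~np.isnan(matrix)
    cs_n = np.concatenate([np.zeros((matrix.shape[0], 1), dtype=np.int64),
                           np.cumsum(obs, axis=1)], axis=1)
    lo = np.searchsorted(sites, starts, side="left")
    hi = np.searchsorted(sites, starts + width, side="left")
    counts = cs_n[:, hi] - cs_n[:, lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        means = (cs[:, hi] - cs[:, lo]) / (counts + shrinkage)
    means[counts == 0] = np.nan
    return means, counts


def scan_variance_windows(
    cells: Sequence[CpGCallSet], track: SmoothedTrack,
    bandwidth_bp: int = 2000, step_bp: int = 10,
    var_threshold: float = 0.2, min_cells: int = 10,
    shrinkage: float = 0.0, chunk: int = 100_000,
) -> pd.DataFrame:
    """Flag genome windows whose between-cell variance exceeds the threshold.

    Windows are [start, start + bandwidth_bp) with starts on a step_bp grid.
    Each cell with at least one observed site in the window contributes its
    mean residual from the smoothed ensemble; windows covered by at least
    ``min_cells`` cells and with sample variance (n-1 denominator) >=
    ``var_threshold`` are returned, sorted by position.

    The scan statistic is deliberately *unshrunken* (shrinkage 0): a fully
    bimodal region yields between-cell variance f(1-f) (0.25 when balanced),
    putting the conventional 0.2 threshold on a coverage-independent scale;
    shrinkage would deflate the variance by (n/(n+1))^2 per cell and make
    the same threshold unreachable at sparse coverage.
    """
    out = []
    for chrom in sorted(track.track):
        prepared = _residual_matrix(cells, track, chrom)
        if prepared is None:
            continue
        sites, resid, _ = prepared
        first = (int(sites[0]) - bandwidth_bp) // step_bp * step_bp
        starts_all = np.arange(max(0, first), int(sites[-1]) + 1, step_bp)
        for block in range(0, len(starts_all), chunk):
            starts = starts_all[block:block + chunk]
            means, counts = _window_cell_means(sites, resid, starts,
                                               bandwidth_bp, shrinkage)
            covered = counts > 0
            n_cov = covered.sum(axis=0)
            ok = n_cov >= max(min_cells, 2)
            if not ok.any():
                continue
            with np.errstate(invalid="ignore"):
                var = np.nanvar(means[:, ok], axis=0, ddof=1)
            flag = var >= var_threshold
            for s, v, nc in zip(starts[ok][flag], var[flag], n_cov[ok][flag]):
                out.append((chrom, int(s), int(s) + bandwidth_bp, float(v), int(nc)))
    return pd.DataFrame(out, columns=["chrom", "start", "end",
                                      "variance", "n_cells_covered"])


def merge_windows_to_vmrs(windows: pd.DataFrame) -> VMRSet:
    """Merge overlapping or book-ended flagged windows into VMRs.

    Peak variance is the maximum over merged members; coverage the maximum
    member coverage. The operation is idempotent.
    """
    if len(windows) == 0:
        return VMRSet([], np.array([]), np.array([], dtype=int))
    windows = windows.sort_values(["chrom", "start", "end"])
    regions, peaks, covs = [], [], []
    cur = None
    for w in windows.itertuples():
        if cur is not None and w.chrom == cur[0] and w.start <= cur[2]:
            cur[2] = max(cur[2], w.end)
            cur[3] = max(cur[3], w.variance)
            cur[4] = max(cur[4], w.n_cells_covered)
        else:
            if cur is not None:
                regions.append(GenomicRegion(cur[0], cur[1], cur[2]))
                peaks.append(cur[3]); covs.append(cur[4])
            cur = [w.chrom, w.start, w.end, w.variance, w.n_cells_covered]
    regions.append(GenomicRegion(cur[0], cur[1], cur[2]))
    peaks.append(cur[3]); covs.append(cur[4])
    return VMRSet(regions, np.asarray(peaks), np.asarray(covs, dtype=int))


def diff_scan(
    cells_a: Sequence[CpGCallSet], cells_b: Sequence[CpGCallSet],
    track: SmoothedTrack, bandwidth_bp: int = 2000, step_bp: int = 100,
    min_cells: int = 6, fdr: float = 0.05, shrinkage: float = 1.0,
) -> DiffScanResult:
    """Windowed two-group differential methylation scan.

    Per window with at least ``min_cells`` covered cells in each group, a
    two-sided Wilcoxon rank-sum test compares the groups' per-cell shrunken
    window means; p-values are BH-adjusted over all tested windows and
    significant windows merged into regions. The reported group means and
    difference are raw mean methylation fractions, so |difference| <= 1.
    """
    all_cells = list(cells_a) + list(cells_b)
    na = len(cells_a)
    win_rows = []
    for chrom in sorted(track.track):
        prepared = _residual_matrix(all_cells, track, chrom)
        if prepared is None:
            continue
        sites, resid, raw = prepared
        first = (int(sites[0]) - bandwidth_bp) // step_bp * step_bp
        starts = np.arange(max(0, first), int(sites[-1]) + 1, step_bp)
        means, counts = _window_cell_means(sites, resid, starts,
                                           bandwidth_bp, shrinkage)
        raw_means, _ = _window_cell_means(sites, raw, starts, bandwidth_bp, 0.0)
        cov_a = (counts[:na] > 0).sum(axis=0)
        cov_b = (counts[na:] > 0).sum(axis=0)
        testable = (cov_a >= min_cells) & (cov_b >= min_cells)
        for wi in np.nonzero(testable)[0]:
            xa = means[:na, wi]; xa = xa[~np.isnan(xa)]
            xb = means[na:, wi]; xb = xb[~np.isnan(xb)]
            ra = raw_means[:na, wi]; rb = raw_means[na:, wi]
            mean_a = float(np.nanmean(ra)); mean_b = float(np.nanmean(rb))
            win_rows.append((chrom, int(starts[wi]), int(starts[wi]) + bandwidth_bp,
                             mean_a, mean_b, mean_b - mean_a,
                             rank_sum_test(xa, xb)))
    windows = pd.DataFrame(win_rows, columns=[
        "chrom", "start", "end", "mean_a", "mean_b", "difference", "p"])
    if len(windows) == 0:
        empty = windows.assign(adj_p=[])
        return DiffScanResult(
            regions=pd.DataFrame(columns=["chrom", "start", "end", "mean_a",
                                          "mean_b", "difference", "min_adj_p",
                                          "direction"]),
            windows=empty,
            status="warning: no window with enough covered cells in both groups",
        )
    windows["adj_p"] = bh_adjust(windows["p"].to_numpy())
    sig = windows[windows.adj_p < fdr]
    reg_rows = []
    if len(sig):
        merged = merge_windows_to_vmrs(
            sig.rename(columns={"adj_p": "variance"})
               .assign(n_cells_covered=0)[["chrom", "start", "end",
                                           "variance", "n_cells_covered"]]
        )
        for r in merged.regions:
            member = sig[(sig.chrom == r.chrom) & (sig.start < r.end)
                         & (sig.end > r.start)]
            diff = float(member.difference.mean())
            reg_rows.append((r.chrom, r.start, r.end,
                             float(member.mean_a.mean()),
                             float(member.mean_b.mean()), diff,
                             float(member.adj_p.min()),
                             "hyper_in_b" if diff > 0 else "hypo_in_b"))
    regions = pd.DataFrame(reg_rows, columns=[
        "chrom", "start", "end", "mean_a", "mean_b", "difference",
        "min_adj_p", "direction"])
    return DiffScanResult(regions=regions, windows=windows, status="ok")
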