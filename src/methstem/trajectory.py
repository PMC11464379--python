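"""Trajectory analysis: missing-value PCA, pseudotime bins, methylation waves.

Single-cell methylation matrices are mostly missing, so ordinary PCA does not
apply directly. ``iterative_pca`` centres each cell, fills missing entries
with feature means and alternates rank-k reconstruction with refilling until
the imputed values stop changing. Along an externally supplied pseudotime
(integer cell ranks), each region's methylation is modelled as a step
function — a change point s and two constant levels — fit by exhaustive
least squares; a change point is called a (de)methylation *event* when the
step fit beats the constant fit by at least 15% of the squared-residual sum
and the region is observed in enough cells. Event change points cluster into
waves; a rank window (e.g. ranks 250-400 for the late-TAP demethylation
wave) selects the regions of one wave together with their gene-level
expression and accessibility read-outs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .meth_io import GenomicRegion, RegionMatrix

__all__ = ["IterativePCAResult", "ChangePointFit", "BinnedLayerMatrix",
           "iterative_pca", "bin_pseudotime", "fit_step_function",
           "call_methylation_events", "select_wave_events"]


@dataclass
class IterativePCAResult:
    cell_scores: np.ndarray       # cells x k
    feature_loadings: np.ndarray  # features x k
    explained_variance: np.ndarray
    n_iterations: int
    converged: bool
    kept_features: np.ndarray     # indices of features passing the filter


@dataclass
class ChangePointFit:
    region_id: str
    s: float                 # change point; cells with rank < s are 'before'
    level_before: float
    level_after: float
    sse_step: float
    sse_const: float
    improvement: float       # 1 - sse_step/sse_const, in [0, 1]
    n_obs: int
    valid: bool              # False when too few observations for any split

    @property
    def direction(self) -> str:
        return "methylation" if self.level_after > self.level_before else "demethylation"


@dataclass
class BinnedLayerMatrix:
    bins: pd.DataFrame                    # cell_id, rank, bin
    layer_means: dict[str, np.ndarray]    # layer -> bins x features
    correlation: dict[str, np.ndarray]    # layer -> bins x bins Pearson matrix


# ---------------------------------------------------------------------------
# iterative missing-value PCA
# ---------------------------------------------------------------------------

def iterative_pca(
    matrix: RegionMatrix | np.ndarray, k: int = 10,
    min_obs_fraction: float = 0.2, tol: float = 1e-4, max_iter: int = 50,
    center_cells: bool = True,
) -> IterativePCAResult:
    """PCA that estimates missing values iteratively.

    Features (regions) observed in fewer than ``min_obs_fraction`` of cells
    are dropped (0.2 is the convention for methylation, 0.4 for
    accessibility). Each cell's observed values are centred to remove
    technical per-cell offsets. Missing entries start at the feature mean;
    then rank-k SVD reconstruction and refilling alternate until the relative
    Frobenius change of the imputed entries falls below ``tol``. Deterministic
    (no random initialization). On complete data this reduces to ordinary
    PCA.
    """
    X = matrix.values if isinstance(matrix, RegionMatrix) else np.asarray(matrix, float)
    X = X.copy()
    obs = ~np.isnan(X)
    keep = obs.mean(axis=0) >= min_obs_fraction
    if keep.sum() < k:
        raise ValueError(
            f"only {int(keep.sum())} features observed in >= "
            f"{min_obs_fraction:.0%} of cells; need at least k={k}"
        )
    X = X[:, keep]
    obs = obs[:, keep]
    if center_cells:
        cell_means = np.nanmean(np.where(obs, X, np.nan), axis=1, keepdims=True)
        X = X - cell_means
    col_means = np.nanmean(np.where(obs, X, np.nan), axis=0)
    miss = ~obs
    X[miss] = np.broadcast_to(col_means, X.shape)[miss]

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = X.mean(axis=0)
        Xc = X - mu
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        recon = (U[:, :k] * S[:k]) @ Vt[:k] + mu
        if not miss.any():
            converged = True
            break
        old = X[miss]
        new = recon[miss]
        X[miss] = new
        denom = np.linalg.norm(old)
        change = np.linalg.norm(new - old) / denom if denom > 0 else 0.0
        if change < tol:
            converged = True
            break
    mu = X.mean(axis=0)
    U, S, Vt = np.linalg.svd(X - mu, full_matrices=False)
    scores = U[:, :k] * S[:k]
    loadings = Vt[:k].T
    explained = (S[:k] ** 2) / max(X.shape[0] - 1, 1)
    return IterativePCAResult(
        cell_scores=scores, feature_loadings=loadings,
        explained_variance=explained, n_iterations=it, converged=converged,
        kept_features=np.nonzero(keep)[0],
    )


# ---------------------------------------------------------------------------
# pseudotime binning
# ---------------------------------------------------------------------------

def bin_pseudotime(
    cells: pd.DataFrame, layers: dict[str, np.ndarray] | None = None,
    mean_bin_size: int = 10, purity_keys: Sequence[str] = (),
) -> BinnedLayerMatrix:
    """Bin cells along pseudotime rank (mean ``mean_bin_size`` cells per bin).

    Bins are contiguous in rank. With ``purity_keys`` (e.g. cluster and
    tissue columns of ``cells``) a bin never spans a change of any key:
    bin boundaries are additionally cut at every key change, and each
    homogeneous segment is split into roughly mean-sized bins. ``layers``
    maps a layer name to a cells x features matrix aligned with ``cells``
    (NaN allowed); per-bin feature means and the bin x bin Pearson
    correlation matrix are returned per layer.
    """
    order = np.argsort(cells["pseudotime_rank"].to_numpy())
    n = len(cells)
    if purity_keys:
        key_vals = cells.iloc[order][list(purity_keys)].astype(str).agg("|".join, axis=1).to_numpy()
        seg_starts = [0] + [i for i in range(1, n) if key_vals[i] != key_vals[i - 1]] + [n]
    else:
        seg_starts = [0, n]
    bin_of = np.empty(n, dtype=int)
    b = 0
    for s0, s1 in zip(seg_starts[:-1], seg_starts[1:]):
        seg_n = s1 - s0
        n_bins = max(1, round(seg_n / mean_bin_size))
        edges = np.linspace(s0, s1, n_bins + 1).round().astype(int)
        for lo, hi in zip(edges[:-1], edges[1:]):
            if hi > lo:
                bin_of[lo:hi] = b
                b += 1
    bins = pd.DataFrame({
        "cell_id": cells["cell_id"].to_numpy()[order],
        "rank": cells["pseudotime_rank"].to_numpy()[order],
        "bin": bin_of,
    })
    layer_means, correlation = {}, {}
    if layers:
        for name, mat in layers.items():
            mat = np.asarray(mat, float)[order]
            means = np.full((b, mat.shape[1]), np.nan)
            for bi in range(b):
                with np.errstate(invalid="ignore"):
                    means[bi] = np.nanmean(mat[bin_of == bi], axis=0)
            layer_means[name] = means
            dfm = pd.DataFrame(means.T)
            correlation[name] = dfm.corr(method="pearson").to_numpy()
    return BinnedLayerMatrix(bins=bins, layer_means=layer_means,
                             correlation=correlation)


# ---------------------------------------------------------------------------
# step-function changepoint fit
# ---------------------------------------------------------------------------

def fit_step_function(
    values: np.ndarray, ranks: np.ndarray, min_side: int = 3,
    region_id: str = "",
) -> ChangePointFit:
    """Least-squares step-function fit of a measure along pseudotime.

    The model is parametrized by a change point s and two constant levels
    taken before and after s. All breakpoints between consecutive distinct
    ranks with at least ``min_side`` observations on each side are searched
    exhaustively; levels are the side means, s the midpoint between the
    flanking ranks, and ties in SSE are broken toward the smallest s.
    Missing values are ignored. Returns an invalid fit when no admissible
    breakpoint exists.
    """
    values = np.asarray(values, float)
    ranks = np.asarray(ranks, float)
    ok = ~np.isnan(values)
    v = values[ok]
    r = ranks[ok]
    n = v.size
    order = np.argsort(r, kind="stable")
    v = v[order]
    r = r[order]

    if n > 0:
        mean_all = v.mean()
        sse_const = float(((v - mean_all) ** 2).sum())
    else:
        mean_all, sse_const = np.nan, np.nan
    invalid = ChangePointFit(region_id, np.nan, np.nan, np.nan,
                             np.nan, sse_const, 0.0, n, False)
    if n < 2 * min_side:
        return invalid

    cs = np.cumsum(v)
    cs2 = np.cumsum(v ** 2)
    total, total2 = cs[-1], cs2[-1]
    i = np.arange(1, n)  # split after the i-th observation
    sse_left = cs2[:-1] - cs[:-1] ** 2 / i
    nr = n - i
    sse_right = (total2 - cs2[:-1]) - (total - cs[:-1]) ** 2 / nr
    admissible = (i >= min_side) & (nr >= min_side) & (r[1:] > r[:-1])
    if not admissible.any():
        return invalid
    sse = np.where(admissible, sse_left + sse_right, np.inf)
    best = int(np.argmin(sse))  # argmin takes the first minimum: smallest s
    sse_step = float(sse[best])
    level_before = float(cs[best] / (best + 1))
    level_after = float((total - cs[best]) / (n - best - 1))
    s = float((r[best] + r[best + 1]) / 2.0)
    sse_step = min(sse_step, sse_const)  # guard fp noise
    # a numerically constant series has no step to find: require sse_const to
    # exceed round-off on the scale of the data before reporting improvement
    tiny = 1e-12 * max(1.0, float((v ** 2).sum()))
    improvement = 1.0 - sse_step / sse_const if sse_const > tiny else 0.0
    return ChangePointFit(region_id, s, level_before, level_after,
                          sse_step, float(sse_const), float(improvement),
                          n, True)


def fit_region_steps(
    matrix: RegionMatrix, cells: pd.DataFrame, min_side: int = 3,
    use_raw: bool = False,
) -> list[ChangePointFit]:
    """Step fits for every region of a matrix against the cells' pseudotime
    ranks (``cells`` aligned with ``matrix.cells``)."""
    ranks = cells.set_index("cell_id").loc[matrix.cells, "pseudotime_rank"].to_numpy()
    source = matrix.raw_mean if use_raw else matrix.values
    return [
        fit_step_function(source[:, j], ranks, min_side=min_side,
                          region_id=matrix.regions[j].label or f"region_{j}")
        for j in range(len(matrix.regions))
    ]


def call_methylation_events(
    fits: Sequence[ChangePointFit], min_improvement: float = 0.15,
    min_cells_per_region: int = 100,
) -> pd.DataFrame:
    """Label step fits as (de)methylation events.

    A fit is an event when valid, observed in at least
    ``min_cells_per_region`` cells, and its step fit improves on the constant
    fit by at least ``min_improvement`` (default 15%) of the squared-residual
    sum. Returns one row per fit with the is_event flag and direction.
    """
    rows = []
    for f in fits:
        is_event = bool(f.valid and f.n_obs >= min_cells_per_region
                        and f.improvement >= min_improvement)
        rows.append((f.region_id, f.s, f.level_before, f.level_after,
                     f.sse_step, f.sse_const, f.improvement, f.n_obs,
                     is_event, f.direction if f.valid else ""))
    return pd.DataFrame(rows, columns=[
        "region_id", "s", "level_before", "level_after", "sse_step",
        "sse_const", "improvement", "n_obs", "is_event", "direction"])


def select_wave_events(
    events: pd.DataFrame, rank_window: tuple[float, float],
    regions: Sequence[GenomicRegion], gene_bodies: Sequence[GenomicRegion],
) -> pd.DataFrame:
    """Events whose change point falls in a rank window and whose region
    intersects a gene body (the wave read-out, e.g. ranks 250-400 for the
    late demethylation wave). Returns the event rows with the intersecting
    gene(s) attached, one row per (event, gene)."""
    lo, hi = rank_window
    by_id = {r.label: r for r in regions if r.label}
    rows = []
    sel = events[events.is_event & (events.s >= lo) & (events.s <= hi)]
    for ev in sel.itertuples():
        reg = by_id.get(ev.region_id)
        if reg is None:
            continue
        for g in gene_bodies:
            if g.chrom == reg.chrom and g.start < reg.end and reg.start < g.end:
                rows.append((*ev[1:], g.label))
    return pd.DataFrame(rows, columns=list(events.columns) + ["gene_id"])
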