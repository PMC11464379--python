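"""Correlation of epigenetic features with gene expression.

Each variably methylated/accessible region is assigned its nearest gene body
(signed distance in the gene's orientation, following the ``bedtools closest
-D b`` convention) and its per-cell values are Pearson-correlated with the
gene's log-normalized expression across cells, pairwise-complete over the
cells where the feature is observed. Adjustment for multiple testing is
BH within each feature family (VMR methylation, VAR accessibility, promoter
methylation/accessibility are separate families). The 2-Mb analysis instead
correlates *all* features within 2 Mb of each TSS and histograms the
TSS-relative positions of the significant correlations by sign.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust
from .meth_io import GenomicRegion, RegionMatrix

__all__ = ["nearest_gene", "correlate_feature_expression", "distance_histogram"]


def _signed_distance(feature: GenomicRegion, gene: GenomicRegion) -> int:
    """Signed feature-gene distance per the bedtools closest -D b convention:
    0 when overlapping, negative when the feature lies upstream of the gene
    with respect to the gene's strand."""
    if feature.chrom != gene.chrom:
        raise ValueError("cross-chromosome distance undefined")
    if feature.start < gene.end and gene.start < feature.end:
        return 0
    if feature.end <= gene.start:       # feature left of gene
        gap = gene.start - feature.end
        return -gap if gene.strand != "-" else gap
    gap = feature.start - gene.end      # feature right of gene
    return gap if gene.strand != "-" else -gap


def nearest_gene(
    features: Sequence[GenomicRegion], gene_bodies: Sequence[GenomicRegion],
) -> pd.DataFrame:
    """Nearest gene body per feature with signed distance.

    Ties in absolute distance are broken by the first gene in sorted
    (chrom, start) order. Features on chromosomes without genes get no
    assignment (empty gene id, NaN distance).
    """
    if not gene_bodies:
        raise ValueError("gene list is empty")
    genes_sorted = sorted(gene_bodies, key=lambda g: (g.chrom, g.start, g.end))
    by_chrom: dict[str, list[GenomicRegion]] = {}
    for g in genes_sorted:
        by_chrom.setdefault(g.chrom, []).append(g)
    rows = []
    for fi, f in enumerate(features):
        gs = by_chrom.get(f.chrom)
        if not gs:
            rows.append((f.label or f"feature_{fi}", f.chrom, f.start, f.end,
                         "", np.nan))
            continue
        best = None
        for g in gs:  # sorted order; strict < keeps the first gene on ties
            d = _signed_distance(f, g)
            if best is None or abs(d) < abs(best[1]):
                best = (g, d)
        rows.append((f.label or f"feature_{fi}", f.chrom, f.start, f.end,
                     best[0].label or "", int(best[1])))
    return pd.DataFrame(rows, columns=["feature_id", "chrom", "start", "end",
                                       "gene_id", "distance"])


def _pearson_test(x: np.ndarray, y: np.ndarray, min_cells: int):
    """Pairwise-complete two-sided Pearson test; returns (r, p, n, flag)."""
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < min_cells:
        return np.nan, np.nan, n, "insufficient_cells"
    xs, ys = x[ok], y[ok]
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        return np.nan, 1.0, n, "zero_variance"
    r, p = stats.pearsonr(xs, ys)
    return float(r), float(p), n, ""


def correlate_feature_expression(
    matrix: RegionMatrix, expression_lognorm: pd.DataFrame,
    assignment: pd.DataFrame, min_cells: int = 5,
) -> pd.DataFrame:
    """Pearson correlation of each feature with its assigned gene's expression.

    ``assignment`` is the nearest_gene table (feature_id, gene_id, distance);
    feature values are the matrix's shrunken residuals, expression the
    log-normalized values of the same cells. Features observed in fewer than
    ``min_cells`` cells, or assigned to unmeasured genes, are skipped.
    BH adjustment is computed over the tested features of this call — call
    once per feature family.
    """
    feat_index = {(r.label or f"feature_{j}"): j
                  for j, r in enumerate(matrix.regions)}
    expr_cells = [c for c in matrix.cells if c in expression_lognorm.columns]
    if expr_cells != list(matrix.cells):
        raise ValueError("expression is missing cells present in the matrix")
    E = expression_lognorm[list(matrix.cells)]
    rows = []
    for a in assignment.itertuples():
        j = feat_index.get(a.feature_id)
        if j is None or not a.gene_id or a.gene_id not in E.index:
            continue
        r, p, n, flag = _pearson_test(
            matrix.values[:, j], E.loc[a.gene_id].to_numpy(float), min_cells)
        if flag == "insufficient_cells":
            continue
        rows.append((a.feature_id, a.gene_id, a.distance, r, p, n, flag))
    table = pd.DataFrame(rows, columns=["feature_id", "gene_id", "distance",
                                        "r", "p", "n_cells", "flag"])
    if len(table):
        table["adj_p"] = bh_adjust(table.p.to_numpy())
    else:
        table["adj_p"] = []
    return table


def distance_histogram(
    matrix: RegionMatrix, tss_list: pd.DataFrame,
    expression_lognorm: pd.DataFrame, window_mb: float = 2.0,
    bin_bp: int = 2000, min_cells: int = 5, alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Histogram of TSS-relative positions of significant correlations.

    All features whose midpoint lies within ``window_mb`` Mb of a TSS are
    correlated with that TSS's gene (all pairs, not nearest-only), p-values
    BH-adjusted within this family, and the TSS-strand-oriented signed
    positions of pairs with adjusted p < ``alpha`` are histogrammed in
    ``bin_bp`` bins, split by correlation sign. Returns (pair table,
    histogram); the histogram counts sum to the number of significant pairs.
    """
    window = int(window_mb * 1_000_000)
    mids = np.array([(r.start + r.end) // 2 for r in matrix.regions])
    chroms = np.array([r.chrom for r in matrix.regions])
    rows = []
    for t in tss_list.itertuples():
        if t.gene_id not in expression_lognorm.index:
            continue
        expr = expression_lognorm.loc[t.gene_id, list(matrix.cells)].to_numpy(float)
        near = np.nonzero((chroms == t.chrom) & (np.abs(mids - t.tss) <= window))[0]
        for j in near:
            rel = int(mids[j] - t.tss)
            if getattr(t, "strand", "+") == "-":
                rel = -rel
            r, p, n, flag = _pearson_test(matrix.values[:, j], expr, min_cells)
            if flag == "insufficient_cells":
                continue
            rows.append((matrix.regions[j].label or f"feature_{j}",
                         t.gene_id, rel, r, p, n))
    pairs = pd.DataFrame(rows, columns=["feature_id", "gene_id",
                                        "tss_distance", "r", "p", "n_cells"])
    if len(pairs) == 0:
        hist = pd.DataFrame(columns=["bin_start", "bin_end",
                                     "n_negative", "n_positive"])
        return pairs, hist
    pairs["adj_p"] = bh_adjust(pairs.p.to_numpy())
    sig = pairs[pairs.adj_p < alpha]
    edges = np.arange(-window, window + bin_bp, bin_bp)
    neg, _ = np.histogram(sig.loc[sig.r < 0, "tss_distance"], bins=edges)
    pos, _ = np.histogram(sig.loc[sig.r >= 0, "tss_distance"], bins=edges)
    hist = pd.DataFrame({"bin_start": edges[:-1], "bin_end": edges[1:],
                         "n_negative": neg, "n_positive": pos})
    hist = hist[(hist.n_negative > 0) | (hist.n_positive > 0)].reset_index(drop=True)
    return pairs, hist
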