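"""Group-wise differential methylation and methylome-state classification.

Low-methylation regions (LMRs) are VMRs significantly hypomethylated in one
of two cell groups (two-sided Wilcoxon rank-sum on shrunken residuals,
BH-adjusted p < 0.05, at least 30 covered cells per group). Two antagonistic
LMR sets — astrocyte LMRs and NSC LMRs — define the per-cell *methylation
score*: the difference between a cell's mean raw methylation over astrocyte
LMRs and over NSC LMRs, which classifies each methylome as astrocyte-like
(score < 0: astrocyte LMRs unmethylated) or NSC-like (score > 0). The module
also bins genes by methylation change in the +2 kb..+5 kb interval downstream
of the TSS against their expression change, selects per-cluster marker genes
(Wilcoxon, gene-body VMR required), annotates regions with overlapping
genomic feature classes, and computes mean-expression signatures of gene
sets (e.g. reactive-astrocyte panels).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._stats import bh_adjust, log_normalize, rank_sum_test
from .meth_io import GenomicRegion, RegionMatrix

__all__ = ["wilcoxon_lmrs", "bh_adjust", "tss_downstream_bins",
           "methylation_score", "marker_genes", "annotate_region_features",
           "reactive_signature", "tss_downstream_regions", "log_normalize"]


def _group_indices(cells: Sequence[str], group: Sequence[str]) -> np.ndarray:
    index = {c: i for i, c in enumerate(cells)}
    missing = [g for g in group if g not in index]
    if missing:
        raise KeyError(f"cells not in matrix: {missing[:5]}")
    return np.array([index[g] for g in group], dtype=int)


def wilcoxon_lmrs(
    matrix: RegionMatrix, group_a: Sequence[str], group_b: Sequence[str],
    min_cells: int = 30, alpha: float = 0.05,
    label_a: str = "astrocyte_LMR", label_b: str = "NSC_LMR",
    gene_bodies: Sequence[GenomicRegion] = (),
) -> pd.DataFrame:
    """Two-group LMR discovery over VMRs.

    Group A is the astrocyte-side group by convention: a VMR significantly
    (BH-adjusted p < ``alpha``) *lower* in group A is labelled ``label_a``,
    lower in group B ``label_b``, otherwise ``ns``. Only VMRs covered in at
    least ``min_cells`` cells per group are tested (others appear with NaN
    p). Overlapping gene bodies are attached as a comma-joined column.
    """
    ia = _group_indices(matrix.cells, group_a)
    ib = _group_indices(matrix.cells, group_b)
    if set(ia) & set(ib):
        raise ValueError("groups must be disjoint")
    n = len(matrix.regions)
    p = np.full(n, np.nan)
    mean_a = np.full(n, np.nan)
    mean_b = np.full(n, np.nan)
    raw_a = np.full(n, np.nan)
    raw_b = np.full(n, np.nan)
    for j in range(n):
        va = matrix.values[ia, j]; va = va[~np.isnan(va)]
        vb = matrix.values[ib, j]; vb = vb[~np.isnan(vb)]
        if len(va) < min_cells or len(vb) < min_cells:
            continue
        p[j] = rank_sum_test(va, vb)
        mean_a[j] = va.mean(); mean_b[j] = vb.mean()
        with np.errstate(invalid="ignore"):
            raw_a[j] = np.nanmean(matrix.raw_mean[ia, j])
            raw_b[j] = np.nanmean(matrix.raw_mean[ib, j])
    adj = bh_adjust(p)
    label = np.array(["ns"] * n, dtype=object)
    sig = adj < alpha
    label[sig & (mean_a < mean_b)] = label_a
    label[sig & (mean_b < mean_a)] = label_b
    genes = [""] * n
    if gene_bodies:
        for j, r in enumerate(matrix.regions):
            hits = [g.label for g in gene_bodies
                    if g.chrom == r.chrom and g.start < r.end and r.start < g.end]
            genes[j] = ",".join(h for h in hits if h)
    return pd.DataFrame({
        "region_id": [r.label or f"region_{j}" for j, r in enumerate(matrix.regions)],
        "chrom": [r.chrom for r in matrix.regions],
        "start": [r.start for r in matrix.regions],
        "end": [r.end for r in matrix.regions],
        "mean_a": mean_a, "mean_b": mean_b,
        "raw_mean_a": raw_a, "raw_mean_b": raw_b,
        "difference": mean_b - mean_a,
        "p": p, "adj_p": adj, "label": label, "genes": genes,
    })


# ---------------------------------------------------------------------------
# TSS-downstream methylation vs expression binning
# ---------------------------------------------------------------------------

def tss_downstream_regions(tss_list: pd.DataFrame,
                           downstream=(2000, 5000)) -> list[GenomicRegion]:
    """The +2 kb..+5 kb interval downstream of each TSS, strand-aware.

    A minus-strand TSS at position t yields [t - 5000, t - 2000). Unstranded
    TSS entries are rejected.
    """
    lo, hi = downstream
    out = []
    for row in tss_list.itertuples():
        strand = getattr(row, "strand", None)
        if strand == "+":
            start, end = int(row.tss) + lo, int(row.tss) + hi
        elif strand == "-":
            start, end = int(row.tss) - hi, int(row.tss) - lo
        else:
            raise ValueError(f"TSS for {row.gene_id} has no strand")
        out.append(GenomicRegion(row.chrom, max(0, start), end,
                                 strand=strand, label=row.gene_id))
    return out


def tss_downstream_bins(
    tss_matrix: RegionMatrix, expression_lognorm: pd.DataFrame,
    group_a: Sequence[str], group_b: Sequence[str],
    min_cells: int = 5, alpha: float = 0.05, min_diff: float = 0.05,
    bin_width: float = 0.10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bin genes by TSS-downstream methylation change vs expression change.

    ``tss_matrix`` quantifies the +2..+5 kb downstream intervals (one region
    per gene, region labels = gene ids). Per gene with coverage in at least
    ``min_cells`` cells per group, methylation difference (group B - group A,
    raw mean fraction) and expression difference (log-normalized) are each
    Wilcoxon-tested and BH-adjusted. A gene is NS when its adjusted
    methylation p exceeds ``alpha`` or |difference| < ``min_diff`` (5%).
    Genes are binned by the methylation difference rounded to the nearest
    ``bin_width`` (10 percentage points); the second returned frame gives
    per-bin counts of expression-up / -down / NS genes.
    """
    ia = _group_indices(tss_matrix.cells, group_a)
    ib = _group_indices(tss_matrix.cells, group_b)
    rows = []
    for j, reg in enumerate(tss_matrix.regions):
        gene = reg.label
        ra = tss_matrix.raw_mean[ia, j]; ra = ra[~np.isnan(ra)]
        rb = tss_matrix.raw_mean[ib, j]; rb = rb[~np.isnan(rb)]
        if len(ra) < min_cells or len(rb) < min_cells or gene not in expression_lognorm.index:
            continue
        meth_p = rank_sum_test(ra, rb)
        dmeth = float(rb.mean() - ra.mean())
        ea = expression_lognorm.loc[gene, list(group_a)].to_numpy(float)
        eb = expression_lognorm.loc[gene, list(group_b)].to_numpy(float)
        expr_p = rank_sum_test(ea, eb)
        dexpr = float(eb.mean() - ea.mean())
        rows.append((gene, dmeth, meth_p, dexpr, expr_p))
    table = pd.DataFrame(rows, columns=["gene_id", "dmeth", "meth_p",
                                        "dexpr", "expr_p"])
    if len(table) == 0:
        return table, pd.DataFrame(columns=["meth_bin", "up", "down", "ns", "n"])
    table["meth_adj_p"] = bh_adjust(table.meth_p.to_numpy())
    table["expr_adj_p"] = bh_adjust(table.expr_p.to_numpy())
    ns = (table.meth_adj_p > alpha) | (table.dmeth.abs() < min_diff)
    table["significant"] = ~ns
    table["meth_bin"] = np.where(
        ns, 0.0, (table.dmeth / bin_width).round() * bin_width)
    expr_dir = np.where(table.expr_adj_p <= alpha,
                        np.where(table.dexpr > 0, "up", "down"), "ns")
    table["expr_direction"] = expr_dir
    bins = (table.groupby("meth_bin")["expr_direction"]
            .value_counts().unstack(fill_value=0)
            .reindex(columns=["up", "down", "ns"], fill_value=0)
            .reset_index())
    bins["n"] = bins[["up", "down", "ns"]].sum(axis=1)
    return table, bins


# ---------------------------------------------------------------------------
# methylome-state score
# ---------------------------------------------------------------------------

def methylation_score(
    astro_matrix: RegionMatrix, nsc_matrix: RegionMatrix,
    margin: float = 0.0,
) -> pd.DataFrame:
    """Per-cell methylome-state score from the two LMR sets.

    The score is the difference between a cell's mean raw methylation over
    all astrocyte LMRs and over all NSC LMRs (means, so duplicating an LMR
    does not change the score). A cell with score < -margin has an
    astrocyte-like methylome (its astrocyte LMRs are unmethylated), score >
    +margin an NSC-like methylome, otherwise indeterminate. Cells covering
    neither set are flagged with zero coverage.
    """
    if len(astro_matrix.regions) == 0 or len(nsc_matrix.regions) == 0:
        raise ValueError("both LMR sets must be non-empty")
    if astro_matrix.cells != nsc_matrix.cells:
        raise ValueError("LMR matrices must share the same cells")
    import warnings
    with warnings.catch_warnings():
        # cells covering no LMR yield an all-NaN row: NaN score, flagged below
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean_astro = np.nanmean(astro_matrix.raw_mean, axis=1)
        mean_nsc = np.nanmean(nsc_matrix.raw_mean, axis=1)
    n_cov = ((astro_matrix.n_obs > 0).sum(axis=1)
             + (nsc_matrix.n_obs > 0).sum(axis=1))
    score = mean_astro - mean_nsc
    state = np.where(score < -margin, "astrocyte_methylome",
                     np.where(score > margin, "NSC_methylome", "indeterminate"))
    state = np.where(np.isnan(score), "indeterminate", state)
    return pd.DataFrame({
        "cell_id": astro_matrix.cells,
        "mean_astro_lmr_meth": mean_astro,
        "mean_nsc_lmr_meth": mean_nsc,
        "score": score, "state": state,
        "n_lmrs_covered": n_cov,
        "zero_coverage": n_cov == 0,
    })


# ---------------------------------------------------------------------------
# marker genes
# ---------------------------------------------------------------------------

def marker_genes(
    expression_lognorm: pd.DataFrame, cluster_labels: Mapping[str, str],
    vmr_gene_map: set[str] | Sequence[str], top_n: int = 100,
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Top differentially expressed genes per cluster, restricted to genes
    with a VMR in their gene body.

    Per cluster, each gene is Wilcoxon-tested (cluster cells vs all others)
    on log-normalized expression, BH-adjusted; genes with adjusted p <
    ``alpha`` that are in ``vmr_gene_map`` are ranked by log-fold-change of
    means and the top ``top_n`` returned.
    """
    vmr_genes = set(vmr_gene_map)
    cells = [c for c in expression_lognorm.columns if c in cluster_labels]
    labels = np.array([cluster_labels[c] for c in cells])
    X = expression_lognorm[cells].to_numpy(float)
    out = {}
    for cluster in pd.unique(labels):
        inside = labels == cluster
        if inside.all() or not inside.any():
            out[cluster] = pd.DataFrame(columns=["gene_id", "lfc", "p", "adj_p"])
            continue
        p = np.array([rank_sum_test(X[g, inside], X[g, ~inside])
                      for g in range(X.shape[0])])
        adj = bh_adjust(p)
        mean_in = X[:, inside].mean(axis=1)
        mean_out = X[:, ~inside].mean(axis=1)
        lfc = np.log2((np.expm1(mean_in) + 1) / (np.expm1(mean_out) + 1))
        df = pd.DataFrame({
            "gene_id": expression_lognorm.index, "lfc": lfc, "p": p, "adj_p": adj,
        })
        df = df[(df.adj_p < alpha) & df.gene_id.isin(vmr_genes) & (df.lfc > 0)]
        out[cluster] = (df.reindex(df.lfc.abs().sort_values(ascending=False).index)
                        .head(top_n).reset_index(drop=True))
    return out


# ---------------------------------------------------------------------------
# region feature annotation
# ---------------------------------------------------------------------------

def annotate_region_features(
    regions: Sequence[GenomicRegion], annotation: Sequence[GenomicRegion],
) -> tuple[pd.DataFrame, pd.Series]:
    """Assign every overlapping annotation class to each region.

    ``annotation`` is any set of labelled intervals (promoters, exons,
    introns, UTRs, cCREs ...); a region takes *all* labels it overlaps, or
    ``intergenic`` if none. Returns the per-region label lists and the counts
    per class (a region contributes to every class it overlaps).
    """
    rows = []
    counts: dict[str, int] = {}
    for r in regions:
        labels = sorted({a.label or "unlabelled" for a in annotation
                         if a.chrom == r.chrom and a.start < r.end and r.start < a.end})
        if not labels:
            labels = ["intergenic"]
        for lab in labels:
            counts[lab] = counts.get(lab, 0) + 1
        rows.append((r.chrom, r.start, r.end, ",".join(labels)))
    table = pd.DataFrame(rows, columns=["chrom", "start", "end", "classes"])
    return table, pd.Series(counts).sort_index()


def reactive_signature(
    expression_lognorm: pd.DataFrame, gene_set: Sequence[str],
) -> pd.Series:
    """Per-cell mean log-normalized expression over a gene set."""
    present = [g for g in gene_set if g in expression_lognorm.index]
    missing = [g for g in gene_set if g not in expression_lognorm.index]
    if not present:
        raise KeyError(f"no gene of the set is measured; missing: {missing}")
    return expression_lognorm.loc[present].mean(axis=0)
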