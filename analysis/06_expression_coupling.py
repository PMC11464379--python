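"""Methylation-expression coupling: nearest-gene correlations, the
TSS-downstream binning, and the distance histogram of significant
correlations.

Gene-body methylation silences expression in this cohort (coupling sign -1),
so VMR methylation correlates negatively with nearest-gene expression, genes
that gain methylation downstream of the TSS lose expression, and significant
correlations pile up ~3 kb downstream of the TSS where the coupled regions
were planted.
"""

import numpy as np

from common import load_study, results_path
from methstem import assoc, differential, meth_io

ds, track, lognorm = load_study()

linked = ds.truth.genes[ds.truth.genes.linked_region != ""]
region_ids = set(linked.linked_region)
regions = [r for r in ds.truth.region_list() if r.label in region_ids]
matrix = meth_io.quantify_regions(ds.meth_cells, regions, track=track)

assign = assoc.nearest_gene(regions, ds.truth.gene_bodies())
corr = assoc.correlate_feature_expression(matrix, lognorm, assign, min_cells=5)
corr.to_csv(results_path("06_nearest_gene_correlation.tsv"), sep="\t",
            index=False)

tss = ds.truth.genes[["gene_id", "chrom", "tss", "strand"]]
intervals = differential.tss_downstream_regions(tss)
tss_mat = meth_io.quantify_regions(ds.meth_cells, intervals, track=track)
meta = ds.truth.cells
table, bins = differential.tss_downstream_bins(
    tss_mat, lognorm,
    meta.loc[meta.state == "astrocyte", "cell_id"].tolist(),
    meta.loc[meta.state != "astrocyte", "cell_id"].tolist())
table.to_csv(results_path("06_tss_downstream_genes.tsv"), sep="\t", index=False)
bins.to_csv(results_path("06_tss_downstream_bins.tsv"), sep="\t", index=False)

pairs, hist = assoc.distance_histogram(matrix, tss, lognorm, bin_bp=2000)
hist.to_csv(results_path("06_distance_histogram.tsv"), sep="\t", index=False)

sig = corr[corr.adj_p < 0.05]
print(f"nearest-gene correlations: {len(sig)}/{len(corr)} significant, "
      f"{(sig.r < 0).mean():.0%} negative (repressive)")
strong = table[table.significant & (table.dmeth.abs() >= 0.10)
               & (table.expr_direction != "ns")]
opp = (np.sign(strong.dexpr) != np.sign(strong.dmeth)).mean()
print(f"TSS-downstream bins: {len(strong)} strongly shifted genes, "
      f"{opp:.0%} with opposite expression change")
total = hist.n_negative + hist.n_positive
mode = hist.loc[total.idxmax()]
print(f"distance histogram mode: [{int(mode.bin_start)}, {int(mode.bin_end)}) bp "
      f"({int(total.max())} of {int(total.sum())} significant pairs)")
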