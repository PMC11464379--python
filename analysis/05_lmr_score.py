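"""LMR discovery and the per-cell methylome-state score.

VMRs are tested astrocytes vs NSC lineage (Wilcoxon, >= 30 covered cells per
group, BH < 0.05); regions hypomethylated in astrocytes become astrocyte
LMRs and vice versa. The methylation score (mean astro-LMR methylation minus
mean NSC-LMR methylation) then classifies every cell's methylome.
"""

import numpy as np

from common import load_study, results_path
from methstem import differential, meth_io, vmr_scan

ds, track, _ = load_study()

windows = vmr_scan.scan_variance_windows(ds.meth_cells, track, 2000, 10, 0.2, 10)
vmrs = vmr_scan.merge_windows_to_vmrs(windows)
regions = [meth_io.GenomicRegion(r.chrom, r.start, r.end, label=f"VMR_{i:04d}")
           for i, r in enumerate(vmrs.regions)]
matrix = meth_io.quantify_regions(ds.meth_cells, regions, track=track)

meta = ds.truth.cells
astro = meta.loc[meta.state == "astrocyte", "cell_id"].tolist()
nsc = meta.loc[meta.state != "astrocyte", "cell_id"].tolist()
lmrs = differential.wilcoxon_lmrs(matrix, astro, nsc, min_cells=30,
                                  gene_bodies=ds.truth.gene_bodies())
lmrs.to_csv(results_path("05_lmr_table.tsv"), sep="\t", index=False)


def as_regions(label):
    sub = lmrs[lmrs.label == label]
    return [meth_io.GenomicRegion(r.chrom, int(r.start), int(r.end),
                                  label=r.region_id) for r in sub.itertuples()]


astro_set, nsc_set = as_regions("astrocyte_LMR"), as_regions("NSC_LMR")
m_astro = meth_io.quantify_regions(ds.meth_cells, astro_set, track=track)
m_nsc = meth_io.quantify_regions(ds.meth_cells, nsc_set, track=track)
score = differential.methylation_score(m_astro, m_nsc)
score = score.rename(columns={"state": "methylome_state"}).merge(
    meta[["cell_id", "state", "pseudotime_rank"]], on="cell_id")
score.to_csv(results_path("05_methylation_score.tsv"), sep="\t", index=False)

truth = np.where(score.state == "astrocyte",
                 "astrocyte_methylome", "NSC_methylome")
print(f"{len(astro_set)} astrocyte LMRs, {len(nsc_set)} NSC LMRs "
      f"(of {len(lmrs)} tested VMRs)")
print(f"methylome-state dichotomy: {(score.methylome_state == truth).mean():.1%} "
      "of cells classified to their lineage side")
print("median score per state:")
print(score.groupby("state").score.median().round(3).to_string())
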