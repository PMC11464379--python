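"""Simulate the synthetic scNMT-seq cohort and summarize its ground truth.

240 cells along the astrocyte -> qNSC -> aNSC -> TAP -> neuroblast
trajectory on a 2 x 2 Mb genome: sparse binary CpG calls (25-60% site
coverage per cell), 60 planted regions (two antagonistic LMR sets, two
(de)methylation waves, trajectory-free bimodal regions), promoter
hypomethylation at every TSS, and negative-binomial expression silenced by
gene-body methylation.
"""

import pandas as pd

from common import load_study, results_path

ds, track, lognorm = load_study()

cells = ds.truth.cells.state.value_counts().rename_axis("state").reset_index(name="n_cells")
regions = (ds.truth.regions.region_class.value_counts()
           .rename_axis("region_class").reset_index(name="n_regions"))
coverage = pd.DataFrame({
    "metric": ["n_cells", "n_cpg_sites", "n_gpc_sites", "median_sites_per_cell",
               "n_genes", "n_coupled_genes"],
    "value": [
        len(ds.meth_cells),
        sum(len(s) for s in ds.cpg_sites.values()),
        sum(len(s) for s in ds.gpc_sites.values()),
        int(pd.Series([c.n_sites for c in ds.meth_cells]).median()),
        len(ds.truth.genes),
        int((ds.truth.genes.linked_region != "").sum()),
    ],
})

cells.to_csv(results_path("01_cell_states.tsv"), sep="\t", index=False)
regions.to_csv(results_path("01_region_classes.tsv"), sep="\t", index=False)
coverage.to_csv(results_path("01_dataset_summary.tsv"), sep="\t", index=False)

print(coverage.to_string(index=False))
print()
print("cell states:\n" + cells.to_string(index=False))
print()
print("planted region classes:\n" + regions.to_string(index=False))
print(f"\nsmoothed ensemble global methylation: {track.global_mean:.3f}")
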