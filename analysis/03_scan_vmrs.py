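"""Sliding-window variance scan for VMRs, checked against the planted truth.

A 2,000 bp window stepped by 10 bp flags positions where the between-cell
variance of per-cell mean residuals exceeds 0.2; flagged windows merge into
VMRs. The script reports how many planted regions were recovered and at what
overlap.
"""

import pandas as pd

from common import load_study, results_path
from methstem import meth_io, vmr_scan

ds, track, _ = load_study()

windows = vmr_scan.scan_variance_windows(ds.meth_cells, track,
                                         bandwidth_bp=2000, step_bp=10,
                                         var_threshold=0.2, min_cells=10)
vmrs = vmr_scan.merge_windows_to_vmrs(windows)
vmrs.to_frame().to_csv(results_path("03_vmrs.tsv"), sep="\t", index=False)
meth_io.write_bed(
    [meth_io.GenomicRegion(r.chrom, r.start, r.end, label=f"VMR_{i:04d}")
     for i, r in enumerate(vmrs.regions)],
    results_path("03_vmrs.bed"),
    scores=[f"{v:.3f}" for v in vmrs.peak_variance])


def jaccard(a, b):
    inter = max(0, min(a.end, b.end) - max(a.start, b.start))
    return inter / ((a.end - a.start) + (b.end - b.start) - inter) if inter else 0.0


rows = []
for t in ds.truth.region_list():
    best = max((jaccard(t, r) for r in vmrs.regions), default=0.0)
    cls = ds.truth.regions.set_index("region_id").loc[t.label, "region_class"]
    rows.append((t.label, cls, best, best >= 0.5))
recovery = pd.DataFrame(rows, columns=["region_id", "region_class",
                                       "best_jaccard", "recovered"])
recovery.to_csv(results_path("03_scan_recovery.tsv"), sep="\t", index=False)

print(f"{len(windows)} flagged windows -> {len(vmrs)} VMRs")
print("recovery by planted class (Jaccard >= 0.5):")
print(recovery.groupby("region_class").recovered.mean().to_string())
print("(early-changepoint wave-1 regions sit below the 0.2 variance cap "
      "f(1-f): only a minority of cells differ, so the scan cannot see them)")
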