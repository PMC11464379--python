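"""Shared study configuration for the numbered analysis scripts.

One synthetic cohort (deterministic, seed fixed here) is used by every
script; each script re-simulates it on the fly (a few seconds) so the
scripts are self-contained and nothing large is kept on disk. Outputs go to
results/ as small TSV/BED tables.
"""

import os

import pandas as pd

from methstem._stats import log_normalize
from methstem.synthetic_data import SimConfig, simulate_dataset
from methstem import meth_io

RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")

STUDY_CONFIG = SimConfig(
    n_chroms=2, chrom_len_bp=2_000_000, n_cells=240,
    n_variable_regions=60, n_genes=60, seed=11,
    states=(("astrocyte", 0.35), ("qNSC", 0.20), ("aNSC", 0.10),
            ("TAP", 0.20), ("neuroblast", 0.15)),
    level_pairs=((0.0, 1.0), (1.0, 0.0)), lmr_low=0.0, lmr_high=1.0,
    coverage_fraction_range=(0.25, 0.6),
    coupling_sign=-1, coupling_effect=2.5,
)


def load_study():
    """Simulate the study cohort and its smoothed CpG ensemble track."""
    ds = simulate_dataset(STUDY_CONFIG)
    track = meth_io.smooth_ensemble(ds.meth_cells, "CpG", bandwidth_bp=1000)
    lognorm = pd.DataFrame(log_normalize(ds.counts.to_numpy()),
                           index=ds.counts.index, columns=ds.counts.columns)
    return ds, track, lognorm


def results_path(name: str) -> str:
    os.makedirs(RESULTS, exist_ok=True)
    return os.path.join(RESULTS, name)
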