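"""Shared fixtures: a small synthetic dataset with its smoothed track and
region matrix, reused across module tests (session-scoped, fixed seed)."""

import numpy as np
import pytest

from methstem import meth_io
from methstem.synthetic_data import SimConfig, simulate_dataset

SMALL_CFG = SimConfig(
    n_chroms=1, chrom_len_bp=1_000_000, n_cells=120, n_variable_regions=20,
    n_genes=20, seed=7,
    states=(("astrocyte", 0.35), ("qNSC", 0.20), ("aNSC", 0.10),
            ("TAP", 0.20), ("neuroblast", 0.15)),
    level_pairs=((0.0, 1.0), (1.0, 0.0)), lmr_low=0.0, lmr_high=1.0,
    coverage_fraction_range=(0.4, 0.8),
)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(SMALL_CFG)


@pytest.fixture(scope="session")
def small_track(small_dataset):
    return meth_io.smooth_ensemble(small_dataset.meth_cells, "CpG",
                                   bandwidth_bp=1000)


@pytest.fixture(scope="session")
def small_matrix(small_dataset, small_track):
    return meth_io.quantify_regions(
        small_dataset.meth_cells, small_dataset.truth.region_list(),
        track=small_track)


def make_flat_cells(values, positions=None, chrom="chr1", context="CpG"):
    """Cells with constant binary call values at shared positions: cell i's
    calls all equal values[i]. Handy for exact-variance constructions."""
    if positions is None:
        positions = np.arange(100, 4100, 100)
    cells = []
    for i, v in enumerate(values):
        meth = np.full(len(positions), int(v), dtype=np.int64)
        cells.append(meth_io.CpGCallSet(
            f"flat_{i:03d}", context,
            {chrom: (np.asarray(positions), meth, np.ones_like(meth))}))
    return cells
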