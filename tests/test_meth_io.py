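"""I/O, QC, smoothing, shrunken residuals and anchor profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from methstem import meth_io
from methstem._stats import tricube
from methstem.meth_io import (
    CpGCallSet, GenomicRegion, anchor_profile, cell_qc, promoter_regions,
    pseudobulk_smooth_track, quantify_regions, read_cov_file, shrunken_residuals,
    smooth_ensemble, write_cov_file,
)
from conftest import make_flat_cells


def _cell(positions, meth, total=None, cell_id="c0", context="CpG", chrom="chr1"):
    positions = np.asarray(positions)
    meth = np.asarray(meth, dtype=np.int64)
    total = np.ones_like(meth) if total is None else np.asarray(total, np.int64)
    return CpGCallSet(cell_id, context, {chrom: (positions, meth, total)})


# ---------------------------------------------------------------------------
# coverage files
# ---------------------------------------------------------------------------

class TestCovFiles:
    def test_one_based_to_zero_based(self, tmp_path):
        p = tmp_path / "c.cov"
        p.write_text("chr1\t101\t101\t100.0\t3\t0\n")
        cs = read_cov_file(p, "CpG")
        pos, meth, total = cs.calls["chr1"]
        assert pos[0] == 100 and meth[0] == 3 and total[0] == 3

    def test_empty_file_gives_empty_set(self, tmp_path):
        p = tmp_path / "c.cov"
        p.write_text("")
        assert read_cov_file(p, "CpG").n_sites == 0

    def test_header_only_round_trip(self, tmp_path):
        empty = CpGCallSet("e", "CpG", {})
        path = tmp_path / "e.CpG.cov"
        write_cov_file(empty, path)
        assert read_cov_file(path, "CpG").n_sites == 0

    def test_malformed_line_reports_position(self, tmp_path):
        p = tmp_path / "c.cov"
        p.write_text("chr1\t10\t10\t0.0\t0\t1\nchr1\tnotanumber\t11\t0.0\t0\t1\n")
        with pytest.raises(ValueError, match="malformed"):
            read_cov_file(p, "CpG")

    def test_mixed_context_rejected(self, tmp_path):
        cell = _cell([5, 9], [1, 0], context="GpC")
        path = tmp_path / "x.GpC.cov"
        write_cov_file(cell, path)
        with pytest.raises(ValueError, match="context"):
            read_cov_file(path, "CpG")

    def test_round_trip_preserves_counts(self, tmp_path):
        cell = _cell([0, 10, 25], [2, 0, 1], [3, 1, 2])
        path = tmp_path / "c0.CpG.cov"
        write_cov_file(cell, path)
        back = read_cov_file(path, "CpG")
        for k in range(3):
            assert np.array_equal(back.calls["chr1"][k], cell.calls["chr1"][k])


def test_call_set_invariants_enforced():
    with pytest.raises(ValueError, match="increasing"):
        _cell([10, 10], [0, 0])
    with pytest.raises(ValueError, match="n_total"):
        _cell([10, 20], [2, 0], [1, 1])


# ---------------------------------------------------------------------------
# cell QC
# ---------------------------------------------------------------------------

class TestCellQC:
    def _expr(self, cells, n_genes):
        return pd.DataFrame(
            np.ones((2000, len(cells)), dtype=int),
            columns=[c.cell_id for c in cells],
        ).where(lambda df: df.index.to_series().lt(n_genes), 0)

    def test_site_count_cutoff_is_strict(self):
        pos = np.arange(49_999) * 10
        cell_low = _cell(pos, np.ones(len(pos)), cell_id="low")
        pos2 = np.arange(50_000) * 10
        cell_ok = _cell(pos2, np.ones(len(pos2)), cell_id="ok")
        report, kept = cell_qc([cell_low, cell_ok], None, None)
        assert report.set_index("cell_id")["pass"].to_dict() == {
            "low": False, "ok": True}
        assert [c.cell_id for c in kept] == ["ok"]

    def test_gene_count_cutoff_is_strict(self):
        pos = np.arange(60_000) * 10
        cells = [_cell(pos, np.ones(len(pos)), cell_id=f"c{i}") for i in range(2)]
        expr = pd.DataFrame(0, index=range(2000), columns=["c0", "c1"])
        expr.loc[:1498, "c0"] = 1   # 1,499 genes: below the 1,500 minimum
        expr.loc[:1499, "c1"] = 1   # 1,500 genes: passes
        report, kept = cell_qc(cells, expr, None)
        assert report.set_index("cell_id")["pass"].to_dict() == {
            "c0": False, "c1": True}

    def test_tss_dip_required(self):
        # flat methylome fails the profile check; dipped methylome passes
        pos = np.arange(0, 600_000, 10)
        tss = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"], "tss": [300_000]})
        flat = _cell(pos, np.ones(len(pos)), cell_id="flat")
        dip_meth = np.ones(len(pos), dtype=np.int64)
        dip_meth[np.abs(pos - 300_000) <= 200] = 0
        dipped = _cell(pos, dip_meth, cell_id="dipped")
        report, _ = cell_qc([flat, dipped], None, tss, min_cpg_sites=1000)
        ok = report.set_index("cell_id")["tss_profile_ok"].to_dict()
        assert ok == {"flat": False, "dipped": True}

    def test_all_passing_leaves_dataset_unchanged(self, small_dataset):
        cells = small_dataset.meth_cells[:10]
        report, kept = cell_qc(cells, None, None, min_cpg_sites=100)
        assert kept == cells and report["pass"].all()


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

class TestSmoothing:
    def test_constant_signal_preserved_exactly(self):
        cells = make_flat_cells([1, 1, 1])
        track = smooth_ensemble(cells, "CpG", bandwidth_bp=1000)
        assert np.all(track.track["chr1"][1] == 1.0)

    def test_single_isolated_site_pooled_rate(self):
        cells = [_cell([10_000], [1], [2], cell_id="a"),
                 _cell([10_000], [1], [2], cell_id="b")]
        track = smooth_ensemble(cells, "CpG", bandwidth_bp=1000)
        assert track.track["chr1"][1][0] == pytest.approx(0.5)

    def test_linear_ramp_matches_direct_weighted_average(self):
        # oracle: brute-force tricube-weighted mean per site
        rng = np.random.default_rng(0)
        pos = np.sort(rng.choice(20_000, size=300, replace=False))
        rate = pos / 20_000
        meth = (rng.random(300) < rate).astype(np.int64)
        cell = _cell(pos, meth)
        bw = 1500.0
        track = smooth_ensemble([cell], "CpG", bandwidth_bp=bw)
        got = track.track["chr1"][1]
        for i in range(0, 300, 17):
            w = tricube(pos - pos[i], bw)
            expect = (w * meth).sum() / w.sum()
            assert got[i] == pytest.approx(expect, abs=1e-12)

    @settings(deadline=None, max_examples=25)
    @given(st.floats(0.0, 1.0), st.integers(2, 30))
    def test_mass_preservation_property(self, c, n):
        # constant c in -> constant c out, for any site layout
        pos = np.arange(n) * 137 + 11
        meth = np.full(n, int(round(c * 1000)), dtype=np.int64)
        total = np.full(n, 1000, dtype=np.int64)
        track = smooth_ensemble([_cell(pos, meth, total)], "CpG", 500.0)
        np.testing.assert_allclose(track.track["chr1"][1],
                                   meth[0] / 1000.0, atol=1e-12)

    def test_pseudobulk_constant_and_identical_group(self):
        cells = make_flat_cells([1, 1, 1])
        single = pseudobulk_smooth_track(cells[:1], bandwidth_bp=1000)
        group = pseudobulk_smooth_track(cells, bandwidth_bp=1000)
        np.testing.assert_allclose(group.track["chr1"][1],
                                   single.track["chr1"][1])
        mixed = [_cell(np.arange(0, 3000, 100), 4 * np.ones(30), 5 * np.ones(30))]
        track = pseudobulk_smooth_track(mixed, bandwidth_bp=1000)
        np.testing.assert_allclose(track.track["chr1"][1], 0.8)

    def test_pseudobulk_step_crossing_near_boundary(self):
        pos = np.arange(0, 20_000, 50)
        meth = (pos >= 10_000).astype(np.int64)
        track = pseudobulk_smooth_track([_cell(pos, meth)], bandwidth_bp=1000)
        p, v = track.track["chr1"]
        crossing = p[np.argmin(np.abs(v - 0.5))]
        assert abs(crossing - 10_000) <= 1000


# ---------------------------------------------------------------------------
# shrunken residuals / region matrix
# ---------------------------------------------------------------------------

class TestShrunkenResiduals:
    def _flat_track(self, value=0.5, upto=100_000):
        pos = np.array([0, upto])
        return meth_io.SmoothedTrack("CpG", 1000.0,
                                     {"chr1": (pos, np.array([value, value]))},
                                     global_mean=value)

    def test_cell_matching_ensemble_gives_zero(self):
        cells = make_flat_cells([1, 0])
        track = smooth_ensemble(cells, "CpG", 1000)  # ensemble = 0.5
        regions = [GenomicRegion("chr1", 0, 5000)]
        v, n, raw = shrunken_residuals(cells[0], track, regions, shrinkage=0.0)
        assert v[0] == pytest.approx(0.5)  # 1 - 0.5 everywhere
        cellmix = _cell(np.arange(100, 4100, 100), [1, 0] * 20)
        v2, _, _ = shrunken_residuals(cellmix, track, regions, shrinkage=0.0)
        assert v2[0] == pytest.approx(0.0)

    def test_single_site_shrinkage_formula(self):
        track = self._flat_track(0.5)
        cell = _cell([1000], [1])
        v, n, raw = shrunken_residuals(cell, track,
                                       [GenomicRegion("chr1", 0, 2000)],
                                       shrinkage=1.0)
        assert v[0] == pytest.approx(0.25)  # (1 - 0.5) / (1 + 1)
        assert n[0] == 1 and raw[0] == 1.0

    def test_zero_shrinkage_is_plain_mean_residual(self):
        track = self._flat_track(0.25)
        cell = _cell([10, 20, 30], [1, 1, 0])
        v, _, _ = shrunken_residuals(cell, track,
                                     [GenomicRegion("chr1", 0, 100)],
                                     shrinkage=0.0)
        expect = np.mean([0.75, 0.75, -0.25])
        assert v[0] == pytest.approx(expect)

    def test_uncovered_region_is_missing_not_zero(self):
        track = self._flat_track()
        cell = _cell([10], [1])
        v, n, raw = shrunken_residuals(
            cell, track, [GenomicRegion("chr1", 5000, 6000)], 1.0)
        assert np.isnan(v[0]) and n[0] == 0 and np.isnan(raw[0])

    def test_magnitude_grows_with_n_obs_at_fixed_mean_residual(self):
        track = self._flat_track(0.5)
        vals = []
        for n_sites in (1, 4, 16, 64):
            cell = _cell(np.arange(n_sites) * 10, np.ones(n_sites))
            v, _, _ = shrunken_residuals(cell, track,
                                         [GenomicRegion("chr1", 0, 1000)], 1.0)
            vals.append(v[0])
        assert np.all(np.diff(vals) > 0)
        assert np.all(np.abs(vals) < 1)

    def test_quantify_matches_per_cell_loop_and_order_invariance(
            self, small_dataset, small_track, small_matrix):
        regions = small_dataset.truth.region_list()
        for ci in (0, 7, 55):
            v, n, raw = shrunken_residuals(
                small_dataset.meth_cells[ci], small_track, regions, 1.0)
            np.testing.assert_array_equal(small_matrix.values[ci], v)
            np.testing.assert_array_equal(small_matrix.n_obs[ci], n)
        # reversed region order quantifies identically per region
        rev = quantify_regions(small_dataset.meth_cells[:5], regions[::-1],
                               track=small_track)
        fwd = quantify_regions(small_dataset.meth_cells[:5], regions,
                               track=small_track)
        np.testing.assert_array_equal(rev.values[:, ::-1], fwd.values)

    def test_promoter_regions_are_2kb_wide(self):
        tss = pd.DataFrame({"gene_id": ["g1"], "chrom": ["chr1"],
                            "tss": [10_000], "strand": ["+"]})
        regs = promoter_regions(tss)
        assert regs[0].width == 2000
        assert (regs[0].start, regs[0].end) == (9_000, 11_000)


# ---------------------------------------------------------------------------
# anchor profiles
# ---------------------------------------------------------------------------

class TestAnchorProfile:
    def test_site_lands_in_expected_bin(self):
        cell = _cell([1075], [1])
        anchors = pd.DataFrame({"chrom": ["chr1"], "pos": [1000],
                                "strand": ["+"]})
        prof = anchor_profile(cell, anchors, window_bp=500, bin_bp=50)
        hit = prof[prof.n_calls > 0]
        assert list(hit.bin_start) == [50] and list(hit.bin_end) == [100]

    def test_minus_strand_anchor_flips_orientation(self):
        cell = _cell([1100], [1])
        anchors = pd.DataFrame({"chrom": ["chr1"], "pos": [1000],
                                "strand": ["-"]})
        prof = anchor_profile(cell, anchors, window_bp=500, bin_bp=50)
        hit = prof[prof.n_calls > 0]
        assert list(hit.bin_start) == [-100]

    def test_planted_tss_dip_minimum_at_centre(self, small_dataset):
        tss = small_dataset.truth.genes.rename(columns={"tss": "pos"})
        prof = anchor_profile(small_dataset.meth_cells,
                              tss[["chrom", "pos", "strand"]],
                              window_bp=2000, bin_bp=100)
        centre = prof.bin_start.to_numpy() + 50
        low_bin = centre[np.nanargmin(prof.mean_methylation.to_numpy())]
        assert abs(low_bin) <= 500  # inside the hypomethylated promoter
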