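"""LMR discovery, BH, TSS-downstream binning, methylome score, markers."""

import numpy as np
import pandas as pd
import pytest

from methstem._stats import bh_adjust, log_normalize
from methstem.differential import (
    annotate_region_features, marker_genes, methylation_score,
    reactive_signature, tss_downstream_bins, tss_downstream_regions,
    wilcoxon_lmrs,
)
from methstem.meth_io import GenomicRegion, RegionMatrix


def make_matrix(values, n_obs=None, cells=None, raw=None, chrom="chr1"):
    values = np.asarray(values, float)
    n, p = values.shape
    regions = [GenomicRegion(chrom, j * 1000, j * 1000 + 500, label=f"r{j}")
               for j in range(p)]
    if n_obs is None:
        n_obs = np.where(np.isnan(values), 0, 5).astype(int)
    raw = values if raw is None else np.asarray(raw, float)
    cells = cells or [f"c{i}" for i in range(n)]
    return RegionMatrix(regions=regions, cells=cells, values=values,
                        n_obs=np.asarray(n_obs), raw_mean=raw)


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_all_ones_stay_one(self):
        np.testing.assert_array_equal(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_adding_null_never_lowers_adjusted_p(self):
        base = np.array([0.001, 0.04, 0.2, 0.6])
        before = bh_adjust(base)
        after = bh_adjust(np.append(base, 0.99))[:4]
        assert np.all(after >= before - 1e-15)


class TestWilcoxonLMRs:
    def _two_pop(self, n=40, p_diff=12, p_null=28, delta=0.5, seed=0):
        rng = np.random.default_rng(seed)
        p = p_diff + p_null
        a = 0.5 + 0.05 * rng.normal(size=(n, p))
        b = 0.5 + 0.05 * rng.normal(size=(n, p))
        b[:, :p_diff] += delta
        values = np.vstack([a, b])
        cells = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)]
        return make_matrix(values, cells=cells), [f"a{i}" for i in range(n)], \
            [f"b{i}" for i in range(n)], p_diff

    def test_under_covered_vmr_not_tested(self):
        mat, ga, gb, _ = self._two_pop(n=40)
        mat.n_obs[:11, 0] = 0          # 29 covered cells in group A
        mat.values[:11, 0] = np.nan
        table = wilcoxon_lmrs(mat, ga, gb, min_cells=30)
        assert np.isnan(table.p.iloc[0])
        assert table.label.iloc[0] == "ns"
        assert table.p.notna().iloc[1]

    def test_identical_groups_give_no_lmrs(self):
        rng = np.random.default_rng(1)
        vals = np.tile(rng.normal(size=(1, 10)), (60, 1))
        cells = [f"c{i}" for i in range(60)]
        mat = make_matrix(vals, cells=cells)
        table = wilcoxon_lmrs(mat, cells[:30], cells[30:], min_cells=10)
        assert (table.label == "ns").all()

    def test_differential_vmrs_detected_with_direction(self):
        mat, ga, gb, p_diff = self._two_pop()
        table = wilcoxon_lmrs(mat, ga, gb, min_cells=30)
        # group A mean lower in the first p_diff regions -> astrocyte label
        assert (table.label.iloc[:p_diff] == "astrocyte_LMR").all()
        assert (table.label.iloc[p_diff:] == "ns").mean() > 0.9

    def test_group_swap_flips_labels_and_signs(self):
        mat, ga, gb, _ = self._two_pop()
        t1 = wilcoxon_lmrs(mat, ga, gb, min_cells=30)
        t2 = wilcoxon_lmrs(mat, gb, ga, min_cells=30)
        np.testing.assert_allclose(t1.p, t2.p)
        np.testing.assert_allclose(t1.difference, -t2.difference)
        swapped = t2.label.replace({"astrocyte_LMR": "NSC_LMR",
                                    "NSC_LMR": "astrocyte_LMR"})
        assert (t1.label == swapped).all()

    def test_overlapping_gene_bodies_assigned(self):
        mat, ga, gb, _ = self._two_pop(n=35)
        genes = [GenomicRegion("chr1", 0, 1600, strand="+", label="gX")]
        table = wilcoxon_lmrs(mat, ga, gb, min_cells=30, gene_bodies=genes)
        assert table.genes.iloc[0] == "gX"   # region r0 = [0, 500)
        assert table.genes.iloc[2] == ""     # region r2 = [2000, 2500)


class TestTSSDownstream:
    def test_minus_strand_interval_arithmetic(self):
        tss = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"],
                            "tss": [10_000], "strand": ["-"]})
        (reg,) = tss_downstream_regions(tss)
        assert (reg.start, reg.end) == (5_000, 8_000)

    def test_unstranded_tss_rejected(self):
        tss = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"],
                            "tss": [10_000], "strand": [None]})
        with pytest.raises(ValueError, match="strand"):
            tss_downstream_regions(tss)

    def _coupled_setup(self, dmeth, n=30, seed=0):
        rng = np.random.default_rng(seed)
        raw_a = np.clip(0.3 + 0.02 * rng.normal(size=(n, 1)), 0, 1)
        raw_b = np.clip(0.3 + dmeth + 0.02 * rng.normal(size=(n, 1)), 0, 1)
        raw = np.vstack([raw_a, raw_b])
        cells = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)]
        regions = [GenomicRegion("chr1", 0, 3000, strand="+", label="g0")]
        mat = RegionMatrix(regions=regions, cells=cells,
                           values=raw - 0.5, n_obs=np.full((2 * n, 1), 6),
                           raw_mean=raw)
        expr = pd.DataFrame(
            np.r_[rng.normal(2.0, 0.1, n), rng.normal(1.0, 0.1, n)][None, :],
            index=["g0"], columns=cells)
        return mat, expr, cells[:n], cells[n:]

    def test_small_difference_is_ns_despite_tiny_p(self):
        mat, expr, ga, gb = self._coupled_setup(dmeth=0.04)
        table, bins = tss_downstream_bins(mat, expr, ga, gb)
        assert table.meth_adj_p.iloc[0] < 0.05      # tiny p ...
        assert not table.significant.iloc[0]        # ... but |d| < 5% -> NS
        assert table.meth_bin.iloc[0] == 0.0

    def test_coupled_gene_binned_with_opposite_expression(self):
        mat, expr, ga, gb = self._coupled_setup(dmeth=0.42)
        table, bins = tss_downstream_bins(mat, expr, ga, gb)
        row = table.iloc[0]
        assert row.significant and row.meth_bin == pytest.approx(0.4)
        assert row.expr_direction == "down"
        assert bins.set_index("meth_bin").loc[0.4, "down"] == 1


class TestMethylationScore:
    def _mat(self, raw, cells):
        raw = np.asarray(raw, float)
        regions = [GenomicRegion("chr1", j * 100, j * 100 + 50, label=f"l{j}")
                   for j in range(raw.shape[1])]
        return RegionMatrix(regions=regions, cells=cells, values=raw - 0.5,
                            n_obs=np.where(np.isnan(raw), 0, 3).astype(int),
                            raw_mean=raw)

    def test_ideal_astrocyte_scores_minus_one(self):
        cells = ["c0"]
        astro = self._mat([[0.0, 0.0]], cells)
        nsc = self._mat([[1.0, 1.0, 1.0]], cells)
        res = methylation_score(astro, nsc)
        assert res.score.iloc[0] == pytest.approx(-1.0)
        assert res.state.iloc[0] == "astrocyte_methylome"

    def test_symmetric_cell_scores_zero(self):
        cells = ["c0"]
        res = methylation_score(self._mat([[0.5]], cells),
                                self._mat([[0.5]], cells))
        assert res.score.iloc[0] == pytest.approx(0.0)
        assert res.state.iloc[0] == "indeterminate"

    def test_duplicating_lmrs_does_not_change_score(self):
        cells = ["c0", "c1"]
        astro = [[0.2, 0.4], [0.9, 0.7]]
        nsc = [[0.8], [0.1]]
        base = methylation_score(self._mat(astro, cells), self._mat(nsc, cells))
        dup = methylation_score(self._mat(np.hstack([astro, astro]), cells),
                                self._mat(nsc, cells))
        np.testing.assert_allclose(base.score, dup.score)

    def test_zero_coverage_cell_flagged_indeterminate(self):
        cells = ["c0"]
        res = methylation_score(self._mat([[np.nan]], cells),
                                self._mat([[np.nan]], cells))
        assert res.state.iloc[0] == "indeterminate"
        assert bool(res.zero_coverage.iloc[0])

    def test_empty_lmr_set_rejected(self):
        mat = self._mat([[0.5]], ["c0"])
        empty = RegionMatrix(regions=[], cells=["c0"],
                             values=np.empty((1, 0)),
                             n_obs=np.empty((1, 0), int),
                             raw_mean=np.empty((1, 0)))
        with pytest.raises(ValueError, match="non-empty"):
            methylation_score(mat, empty)

    def test_simulated_populations_fully_separated(self):
        rng = np.random.default_rng(8)
        n, m = 60, 60  # cells per population, LMRs per set
        def pop(a_level, n_cells):
            return np.clip(rng.binomial(5, a_level, size=(n_cells, m)) / 5, 0, 1)
        cells = [f"x{i}" for i in range(2 * n)]
        astro_raw = np.vstack([pop(0.2, n), pop(0.8, n)])
        nsc_raw = np.vstack([pop(0.8, n), pop(0.2, n)])
        res = methylation_score(self._mat(astro_raw, cells),
                                self._mat(nsc_raw, cells))
        assert (res.state.iloc[:n] == "astrocyte_methylome").all()
        assert (res.state.iloc[n:] == "NSC_methylome").all()


class TestMarkersAndAnnotation:
    def test_planted_markers_recovered_and_vmr_filter_enforced(self):
        rng = np.random.default_rng(5)
        n_cells, n_genes = 300, 60
        counts = rng.negative_binomial(2, 2 / 22, size=(n_genes, n_cells))
        labels = {f"c{i}": ("A" if i < 100 else "B") for i in range(n_cells)}
        planted = [f"g{j}" for j in range(20)]
        counts[:20, :100] *= 6   # cluster-A-specific genes
        expr = pd.DataFrame(log_normalize(counts),
                            index=[f"g{j}" for j in range(n_genes)],
                            columns=list(labels))
        with_vmr = {f"g{j}" for j in range(n_genes) if j != 3}
        res = marker_genes(expr, labels, with_vmr, top_n=100)
        got = set(res["A"].gene_id)
        assert set(planted) - {"g3"} <= got
        assert "g3" not in got  # no gene-body VMR -> never a marker

    def test_identical_cluster_gives_empty_markers(self):
        expr = pd.DataFrame(np.ones((5, 40)),
                            index=[f"g{j}" for j in range(5)],
                            columns=[f"c{i}" for i in range(40)])
        labels = {f"c{i}": ("A" if i < 20 else "B") for i in range(40)}
        res = marker_genes(expr, labels, {f"g{j}" for j in range(5)})
        assert len(res["A"]) == 0

    def test_annotation_collects_all_overlapping_classes(self):
        ann = [GenomicRegion("chr1", 0, 1000, label="promoter"),
               GenomicRegion("chr1", 800, 2000, label="exon"),
               GenomicRegion("chr1", 2000, 5000, label="intron")]
        regions = [GenomicRegion("chr1", 900, 1100),    # promoter + exon
                   GenomicRegion("chr1", 2500, 2600),   # intron only
                   GenomicRegion("chr1", 8000, 9000)]   # intergenic
        table, counts = annotate_region_features(regions, ann)
        assert table.classes.tolist() == ["exon,promoter", "intron", "intergenic"]
        assert counts.to_dict() == {"exon": 1, "promoter": 1, "intron": 1,
                                    "intergenic": 1}

    def test_annotation_counts_match_quadratic_oracle(self):
        rng = np.random.default_rng(9)
        ann = [GenomicRegion("chr1", int(s), int(s) + int(w), label=f"f{k % 4}")
               for k, (s, w) in enumerate(zip(rng.integers(0, 50_000, 30),
                                              rng.integers(100, 3000, 30)))]
        regions = [GenomicRegion("chr1", int(s), int(s) + 500)
                   for s in rng.integers(0, 50_000, 40)]
        _, counts = annotate_region_features(regions, ann)
        oracle: dict = {}
        for r in regions:
            labs = {a.label for a in ann if a.start < r.end and r.start < a.end}
            for lab in (labs or {"intergenic"}):
                oracle[lab] = oracle.get(lab, 0) + 1
        assert counts.to_dict() == oracle


class TestSignature:
    def test_single_gene_set_equals_gene(self):
        expr = pd.DataFrame([[1.0, 2.0], [5.0, 6.0]], index=["a", "b"],
                            columns=["c0", "c1"])
        sig = reactive_signature(expr, ["b"])
        np.testing.assert_allclose(sig, [5.0, 6.0])

    def test_all_zero_counts_give_zero_signature(self):
        expr = pd.DataFrame(log_normalize(np.zeros((3, 4))),
                            index=list("abc"), columns=list("wxyz"))
        np.testing.assert_allclose(reactive_signature(expr, ["a", "c"]), 0.0)

    def test_missing_genes_named_in_error(self):
        expr = pd.DataFrame([[1.0]], index=["a"], columns=["c0"])
        with pytest.raises(KeyError, match="zzz"):
            reactive_signature(expr, ["zzz"])

    def test_planted_up_module_detected(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(10, size=(20, 200))
        counts[:5, 100:] = rng.poisson(40, size=(5, 100))
        expr = pd.DataFrame(log_normalize(counts),
                            index=[f"g{j}" for j in range(20)],
                            columns=[f"c{i}" for i in range(200)])
        sig = reactive_signature(expr, [f"g{j}" for j in range(5)])
        from scipy.stats import ranksums
        assert ranksums(sig[100:], sig[:100]).pvalue < 0.01
        assert sig[100:].mean() > sig[:100].mean()
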