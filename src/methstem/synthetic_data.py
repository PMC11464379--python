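"""Synthetic scNMT-seq generator with known trajectory and region structure.

Emulates the data layers of a single-cell nucleosome/methylome/transcriptome
experiment on the adult neural-stem-cell lineage: sparse per-cell binary CpG
calls with per-cell coverage heterogeneity, planted variably methylated
regions whose level steps at a known pseudotime rank (two waves of
(de)methylation), two antagonistic low-methylation region (LMR) sets
(astrocyte-low vs NSC-low), a GpC accessibility layer on a disjoint site
grid, and negative-binomial expression coupled (usually anti-correlated) to
gene-body region methylation. Everything downstream — smoothing, shrunken
residuals, variance scans, changepoint fits, LMR tests, methylome scores —
is validated against the ground truth this module writes.

The latent pseudotime is the integer rank order of cells. Cell states occupy
contiguous rank blocks in lineage order (parenchymal astrocytes first, then
qNSC -> aNSC -> TAP -> neuroblast), a deliberate linearization of the real
branched lineage: it makes the astrocyte/NSC contrast coincide with a rank
boundary so LMR classes can be expressed as step functions too.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .meth_io import CpGCallSet, GenomicRegion, write_cov_file, read_cov_file

__all__ = ["SimConfig", "SyntheticTruth", "SyntheticDataset",
           "simulate_genome", "simulate_methylomes", "simulate_expression",
           "simulate_dataset", "simulate_step_series", "write_dataset",
           "read_dataset"]

REGION_CLASSES = ("background", "astrocyte_LMR", "NSC_LMR",
                  "wave1", "wave2", "variable_other")


@dataclass
class SimConfig:
    """Generator parameters. Defaults mirror the study conditions: 540 cells
    along the lineage, a second demethylation wave between pseudotime ranks
    250 and 400, ~100 bp CpG spacing, near-binary single-cell methylation."""

    n_chroms: int = 2
    chrom_len_bp: int = 2_000_000
    cpg_spacing_mean_bp: int = 100
    gpc_spacing_mean_bp: int = 60
    n_cells: int = 540
    #: ordered (state, occupancy proportion) along pseudotime
    states: tuple = (
        ("astrocyte", 0.15), ("qNSC", 0.25), ("aNSC", 0.15),
        ("TAP", 0.30), ("neuroblast", 0.15),
    )
    coverage_fraction_range: tuple = (0.25, 0.6)
    n_variable_regions: int = 60
    region_len_bp: int = 2_000
    #: (before, after) level pairs sampled for wave-1 regions
    level_pairs: tuple = ((0.1, 0.9), (0.9, 0.1))
    background_level: float = 0.75
    accessibility_background: float = 0.35
    #: mix of planted region classes (background fills the rest of the genome)
    class_proportions: tuple = (
        ("astrocyte_LMR", 0.2), ("NSC_LMR", 0.2),
        ("wave1", 0.25), ("wave2", 0.25), ("variable_other", 0.1),
    )
    lmr_low: float = 0.15
    lmr_high: float = 0.85
    #: change-point rank windows for the two (de)methylation waves,
    #: expressed on the 540-cell rank scale and rescaled with n_cells
    wave1_rank_window: tuple = (60, 200)
    wave2_rank_window: tuple = (250, 400)
    n_genes: int = 80
    #: distance from a coupled gene's TSS to the centre of its linked region
    coupled_tss_offset_bp: int = 3_000
    #: promoters are constitutively hypomethylated (and accessible): CpG level
    #: and GpC level within +/-promoter_halfwidth_bp of every TSS
    promoter_level: float = 0.1
    promoter_acc_level: float = 0.7
    promoter_halfwidth_bp: int = 500
    nb_mean: float = 20.0
    nb_dispersion: float = 2.0
    coupling_effect: float = 2.0
    coupling_sign: int = -1
    seed: int = 0

    def __post_init__(self):
        fracs = [self.background_level, self.accessibility_background,
                 self.lmr_low, self.lmr_high, self.promoter_level,
                 self.promoter_acc_level, *self.coverage_fraction_range]
        for pair in self.level_pairs:
            fracs.extend(pair)
        if any(not (0.0 <= f <= 1.0) for f in fracs):
            raise ValueError("all methylation/coverage fractions must be in [0, 1]")
        props = [p for _, p in self.states]
        if abs(sum(props) - 1.0) > 1e-9 or any(p <= 0 for p in props):
            raise ValueError("state proportions must be positive and sum to 1")
        if self.chrom_len_bp <= self.region_len_bp:
            raise ValueError("chrom_len_bp must exceed region_len_bp")
        if self.coupling_sign not in (-1, 0, 1):
            raise ValueError("coupling_sign must be -1, 0 or +1")
        if abs(sum(p for _, p in self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")

    def rank_window(self, which: str) -> tuple[int, int]:
        """Wave rank windows, rescaled from the 540-cell reference scale."""
        lo, hi = self.wave1_rank_window if which == "wave1" else self.wave2_rank_window
        scale = self.n_cells / 540.0
        lo, hi = int(round(lo * scale)), int(round(hi * scale))
        return max(2, lo), min(self.n_cells - 1, max(3, hi))


@dataclass
class SyntheticTruth:
    """Ground truth: cell states/ranks, region classes with change points and
    levels, the per-cell x per-region true methylation level matrix, and the
    gene->region coupling map."""

    cells: pd.DataFrame     # cell_id, state, pseudotime_rank, tissue, condition
    regions: pd.DataFrame   # region_id, chrom, start, end, region_class,
                            # change_point_rank (NaN if none), level_before, level_after
    genes: pd.DataFrame     # gene_id, chrom, start, end, strand, tss,
                            # linked_region (or ""), coupling_sign
    level_matrix: np.ndarray = field(repr=False)  # n_cells x n_regions

    def region_list(self) -> list[GenomicRegion]:
        return [GenomicRegion(r.chrom, int(r.start), int(r.end),
                              label=r.region_id)
                for r in self.regions.itertuples()]

    def gene_bodies(self) -> list[GenomicRegion]:
        return [GenomicRegion(g.chrom, int(g.start), int(g.end),
                              strand=g.strand, label=g.gene_id)
                for g in self.genes.itertuples()]

    def tss_table(self) -> pd.DataFrame:
        return self.genes[["gene_id", "chrom", "tss", "strand"]].rename(
            columns={"tss": "tss"})


@dataclass
class SyntheticDataset:
    config: SimConfig
    truth: SyntheticTruth
    cpg_sites: dict[str, np.ndarray]
    gpc_sites: dict[str, np.ndarray]
    meth_cells: list[CpGCallSet]
    acc_cells: list[CpGCallSet]
    counts: pd.DataFrame  # genes x cells


# ---------------------------------------------------------------------------
# genome & truth
# ---------------------------------------------------------------------------

def _draw_sites(rng, chrom_len: int, spacing_mean: int) -> np.ndarray:
    n_expect = int(chrom_len / spacing_mean * 1.3) + 50
    gaps = rng.geometric(1.0 / spacing_mean, size=n_expect)
    pos = np.cumsum(gaps)
    while pos[-1] < chrom_len:
        more = np.cumsum(rng.geometric(1.0 / spacing_mean, size=n_expect)) + pos[-1]
        pos = np.concatenate([pos, more])
    return pos[pos < chrom_len]


def simulate_genome(cfg: SimConfig) -> tuple[dict, dict, SyntheticTruth]:
    """Draw CpG/GpC site grids, place regions and genes, assign cell states.

    CpG positions per chromosome follow geometric spacing with the configured
    mean; the GpC accessibility grid is drawn independently and made disjoint
    from the CpG grid. Variable regions are placed without overlap in evenly
    spaced slots (an explicit error is raised if the genome cannot hold them),
    each assigned a class, level pair and — for trajectory classes — a true
    change-point rank. Coupled genes are placed so the gene body contains the
    linked region and the region centre sits ``coupled_tss_offset_bp``
    downstream of the TSS.
    """
    rng = np.random.default_rng(cfg.seed)
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    cpg_sites = {c: _draw_sites(rng, cfg.chrom_len_bp, cfg.cpg_spacing_mean_bp)
                 for c in chroms}
    gpc_sites = {}
    for c in chroms:
        g = _draw_sites(rng, cfg.chrom_len_bp, cfg.gpc_spacing_mean_bp)
        gpc_sites[c] = np.setdiff1d(g, cpg_sites[c])

    # --- cells: contiguous state blocks along pseudotime rank
    counts = np.array([p for _, p in cfg.states])
    sizes = np.floor(counts * cfg.n_cells).astype(int)
    sizes[-1] = cfg.n_cells - sizes[:-1].sum()
    state_of_rank = np.repeat([s for s, _ in cfg.states], sizes)
    ranks = np.arange(1, cfg.n_cells + 1)
    order = rng.permutation(cfg.n_cells)  # cell ids are not rank-ordered
    cell_ids = [f"cell_{i:04d}" for i in range(cfg.n_cells)]
    cell_rank = np.empty(cfg.n_cells, dtype=int)
    cell_rank[order] = ranks
    cell_state = np.array(state_of_rank)[cell_rank - 1]
    tissue = np.where(
        (cell_state == "astrocyte") & (cell_rank % 2 == 0), "striatum", "vSVZ"
    )
    cells_df = pd.DataFrame({
        "cell_id": cell_ids, "state": cell_state,
        "pseudotime_rank": cell_rank, "tissue": tissue, "condition": "naive",
    })

    # rank boundary between parenchymal astrocytes and the NSC lineage
    astro_boundary = int(sizes[0]) + 1  # first NSC-lineage rank

    # --- non-overlapping region placement in jittered slots
    slot = cfg.region_len_bp * 3
    slots_per_chrom = (cfg.chrom_len_bp - cfg.region_len_bp) // slot
    total_slots = slots_per_chrom * cfg.n_chroms
    if cfg.n_variable_regions > total_slots:
        raise ValueError(
            f"cannot place {cfg.n_variable_regions} non-overlapping regions of "
            f"{cfg.region_len_bp} bp in {cfg.n_chroms} x {cfg.chrom_len_bp} bp"
        )
    chosen = np.sort(rng.choice(total_slots, size=cfg.n_variable_regions,
                                replace=False))
    class_labels = [c for c, _ in cfg.class_proportions]
    class_p = np.array([p for _, p in cfg.class_proportions])
    n_per_class = np.floor(class_p * cfg.n_variable_regions).astype(int)
    while n_per_class.sum() < cfg.n_variable_regions:
        n_per_class[int(np.argmax(class_p))] += 1
        class_p = class_p * 0.999  # only to break repeated argmax ties
    assigned = np.repeat(class_labels, n_per_class)
    rng.shuffle(assigned)

    w1 = cfg.rank_window("wave1")
    w2 = cfg.rank_window("wave2")
    rows = []
    for i, (slot_idx, rclass) in enumerate(zip(chosen, assigned)):
        chrom = chroms[slot_idx // slots_per_chrom]
        base = (slot_idx % slots_per_chrom) * slot
        # keep a margin so adjacent regions never sit closer than ~600 bp and
        # stay separable at window-scan resolution
        jitter = int(rng.integers(0, max(1, slot - cfg.region_len_bp - 600)))
        start = base + jitter
        end = start + cfg.region_len_bp
        if rclass == "astrocyte_LMR":
            lv, cp = (cfg.lmr_low, cfg.lmr_high), astro_boundary
        elif rclass == "NSC_LMR":
            lv, cp = (cfg.lmr_high, cfg.lmr_low), astro_boundary
        elif rclass == "wave1":
            lv = cfg.level_pairs[int(rng.integers(len(cfg.level_pairs)))]
            cp = int(rng.integers(w1[0], w1[1] + 1))
        elif rclass == "wave2":
            lv, cp = (cfg.lmr_high, cfg.lmr_low), int(rng.integers(w2[0], w2[1] + 1))
        else:  # variable_other: bimodal across cells, no trajectory structure
            lv, cp = (cfg.lmr_low, cfg.lmr_high), None
        rows.append((f"region_{i:04d}", chrom, start, end, rclass,
                     np.nan if cp is None else cp, lv[0], lv[1]))
    regions_df = pd.DataFrame(rows, columns=[
        "region_id", "chrom", "start", "end", "region_class",
        "change_point_rank", "level_before", "level_after"])

    # --- per-cell x per-region true levels
    n_regions = len(regions_df)
    level = np.empty((cfg.n_cells, n_regions))
    for j, reg in enumerate(regions_df.itertuples()):
        if reg.region_class == "variable_other":
            pick = rng.random(cfg.n_cells) < 0.5
            level[:, j] = np.where(pick, reg.level_before, reg.level_after)
        else:
            before = cell_rank < reg.change_point_rank
            level[:, j] = np.where(before, reg.level_before, reg.level_after)

    # --- genes: coupled genes wrap their linked region; the rest sit in
    #     background with no region in the gene body
    linkable = regions_df.index[regions_df.region_class != "background"].tolist()
    n_coupled = min(len(linkable), cfg.n_genes)
    gene_rows = []
    for g in range(cfg.n_genes):
        gid = f"gene_{g:04d}"
        strand = "+" if g % 2 == 0 else "-"
        if g < n_coupled:
            reg = regions_df.iloc[linkable[g]]
            mid = (int(reg.start) + int(reg.end)) // 2
            if strand == "+":
                tss = mid - cfg.coupled_tss_offset_bp
                start, end = tss, int(reg.end) + 1000
            else:
                tss = mid + cfg.coupled_tss_offset_bp
                start, end = int(reg.start) - 1000, tss + 1
            start = max(0, start)
            gene_rows.append((gid, reg.chrom, start, end, strand, tss,
                              reg.region_id, cfg.coupling_sign))
        else:
            chrom = chroms[g % cfg.n_chroms]
            start = int(rng.integers(0, cfg.chrom_len_bp - 10_000))
            end = start + 8_000
            tss = start if strand == "+" else end - 1
            gene_rows.append((gid, chrom, start, end, strand, tss, "", 0))
    genes_df = pd.DataFrame(gene_rows, columns=[
        "gene_id", "chrom", "start", "end", "strand", "tss",
        "linked_region", "coupling_sign"])

    truth = SyntheticTruth(cells=cells_df, regions=regions_df,
                           genes=genes_df, level_matrix=level)
    return cpg_sites, gpc_sites, truth


# ---------------------------------------------------------------------------
# methylomes / accessibility
# ---------------------------------------------------------------------------

def _region_of_sites(sites: np.ndarray, chrom: str, truth: SyntheticTruth) -> np.ndarray:
    """Region index per site (-1 for background) for level lookups per cell."""
    region_of_site = np.full(len(sites), -1, dtype=int)
    sub = truth.regions[truth.regions.chrom == chrom]
    for j, reg in zip(sub.index, sub.itertuples()):
        lo, hi = np.searchsorted(sites, [reg.start, reg.end])
        region_of_site[lo:hi] = j
    return region_of_site


def _promoter_mask(sites: np.ndarray, chrom: str, truth: SyntheticTruth,
                   halfwidth: int) -> np.ndarray:
    mask = np.zeros(len(sites), dtype=bool)
    for g in truth.genes[truth.genes.chrom == chrom].itertuples():
        lo, hi = np.searchsorted(sites, [g.tss - halfwidth, g.tss + halfwidth + 1])
        mask[lo:hi] = True
    return mask


def simulate_methylomes(
    cpg_sites: dict, gpc_sites: dict, truth: SyntheticTruth, cfg: SimConfig,
) -> tuple[list[CpGCallSet], list[CpGCallSet]]:
    """Draw sparse binary calls for both contexts for every cell.

    Each cell observes each site independently with its own coverage fraction
    (uniform over ``coverage_fraction_range``); an observed site carries one
    read whose call is Bernoulli with the cell's true level there: the
    background level outside regions, the hypomethylated promoter level
    within +/-promoter_halfwidth_bp of a TSS, and inside a planted region the
    region's before/after level according to the cell's pseudotime rank
    (regions take precedence). GpC accessibility is generated on its own
    disjoint grid; promoters are accessible, and inside non-background
    regions the accessibility level is the complement of the methylation
    level (open where unmethylated), otherwise the accessibility background.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    cov = rng.uniform(*cfg.coverage_fraction_range, size=cfg.n_cells)
    meth_cells, acc_cells = [], []
    region_of = {c: _region_of_sites(cpg_sites[c], c, truth) for c in cpg_sites}
    region_of_g = {c: _region_of_sites(gpc_sites[c], c, truth) for c in gpc_sites}
    prom = {c: _promoter_mask(cpg_sites[c], c, truth, cfg.promoter_halfwidth_bp)
            for c in cpg_sites}
    prom_g = {c: _promoter_mask(gpc_sites[c], c, truth, cfg.promoter_halfwidth_bp)
              for c in gpc_sites}
    cell_ids = truth.cells.cell_id.to_numpy()
    for ci in range(cfg.n_cells):
        calls_m, calls_a = {}, {}
        for chrom, sites in cpg_sites.items():
            obs = rng.random(len(sites)) < cov[ci]
            if not obs.any():
                continue
            ridx = region_of[chrom][obs]
            p = np.where(prom[chrom][obs], cfg.promoter_level,
                         cfg.background_level)
            inside = ridx >= 0
            if inside.any():
                p[inside] = truth.level_matrix[ci, ridx[inside]]
            meth = (rng.random(obs.sum()) < p).astype(np.int64)
            calls_m[chrom] = (sites[obs], meth, np.ones_like(meth))
        for chrom, sites in gpc_sites.items():
            obs = rng.random(len(sites)) < cov[ci]
            if not obs.any():
                continue
            ridx = region_of_g[chrom][obs]
            p = np.where(prom_g[chrom][obs], cfg.promoter_acc_level,
                         cfg.accessibility_background)
            inside = ridx >= 0
            if inside.any():
                p[inside] = 1.0 - truth.level_matrix[ci, ridx[inside]]
            acc = (rng.random(obs.sum()) < p).astype(np.int64)
            calls_a[chrom] = (sites[obs], acc, np.ones_like(acc))
        meth_cells.append(CpGCallSet(cell_ids[ci], "CpG", calls_m))
        acc_cells.append(CpGCallSet(cell_ids[ci], "GpC", calls_a))
    return meth_cells, acc_cells


def simulate_step_series(
    n_regions: int = 500, n_cells: int = 500, level_gap: float = 0.6,
    base_level: float = 0.2, coverage_p: float = 0.7,
    sites_per_region: float = 8.0, cp_fraction_window: tuple = (0.1, 0.9),
    constant: bool = False, seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Region-level methylation series along pseudotime with Bernoulli noise.

    A light-weight generator for changepoint studies that skips the genome
    layer: per region, each cell is covered with probability ``coverage_p``;
    a covered cell's value is the mean of ~``sites_per_region`` Bernoulli
    site calls (Poisson-distributed site count, minimum 1) at the cell's true
    level. The level steps from ``base_level`` to ``base_level + level_gap``
    (direction randomized) at a change-point rank drawn uniformly inside
    ``cp_fraction_window`` of the rank range; with ``constant=True`` all
    regions stay at a constant mid level (the null for false-event rates).

    Returns (values [cells x regions, NaN where uncovered], ranks,
    true change-point ranks, true directions +1 methylation / -1
    demethylation; the last two are zero arrays when ``constant``).
    """
    rng = np.random.default_rng(seed)
    ranks = np.arange(1, n_cells + 1)
    values = np.full((n_cells, n_regions), np.nan)
    cps = np.zeros(n_regions)
    dirs = np.zeros(n_regions, dtype=int)
    lo = int(np.ceil(cp_fraction_window[0] * n_cells))
    hi = int(np.floor(cp_fraction_window[1] * n_cells))
    for j in range(n_regions):
        if constant:
            level = np.full(n_cells, base_level + level_gap / 2.0)
        else:
            cp = int(rng.integers(lo, hi + 1))
            up = bool(rng.integers(2))
            before = base_level if up else base_level + level_gap
            after = base_level + level_gap if up else base_level
            level = np.where(ranks < cp, before, after)
            cps[j] = cp
            dirs[j] = 1 if up else -1
        covered = rng.random(n_cells) < coverage_p
        k = np.maximum(rng.poisson(sites_per_region, size=n_cells), 1)
        vals = rng.binomial(k, level) / k
        values[covered, j] = vals[covered]
    return values, ranks, cps, dirs


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(truth: SyntheticTruth, cfg: SimConfig) -> pd.DataFrame:
    """Negative-binomial counts, genes x cells, coupled to region methylation.

    For a coupled gene the log-mean is shifted by
    ``coupling_effect * coupling_sign * (level - 1/2)`` where ``level`` is the
    cell's true methylation level of the linked gene-body region, so
    coupling_sign = -1 silences genes whose region gains methylation. For
    very large dispersion the counts are drawn Poisson (the NB limit).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    region_idx = {r.region_id: j for j, r in enumerate(truth.regions.itertuples())}
    n_cells = len(truth.cells)
    mat = np.empty((len(truth.genes), n_cells), dtype=np.int64)
    for gi, gene in enumerate(truth.genes.itertuples()):
        mu = np.full(n_cells, cfg.nb_mean)
        if gene.linked_region and gene.coupling_sign != 0:
            lev = truth.level_matrix[:, region_idx[gene.linked_region]]
            mu = cfg.nb_mean * np.exp(
                cfg.coupling_effect * gene.coupling_sign * (lev - 0.5))
        theta = cfg.nb_dispersion
        if theta > 1e6:
            mat[gi] = rng.poisson(mu)
        else:
            mat[gi] = rng.negative_binomial(theta, theta / (theta + mu))
    return pd.DataFrame(mat, index=truth.genes.gene_id.tolist(),
                        columns=truth.cells.cell_id.tolist())


def simulate_dataset(cfg: SimConfig) -> SyntheticDataset:
    """Full generator: genome + truth, methylomes, accessibility, expression."""
    cpg_sites, gpc_sites, truth = simulate_genome(cfg)
    meth_cells, acc_cells = simulate_methylomes(cpg_sites, gpc_sites, truth, cfg)
    counts = simulate_expression(truth, cfg)
    return SyntheticDataset(config=cfg, truth=truth, cpg_sites=cpg_sites,
                            gpc_sites=gpc_sites, meth_cells=meth_cells,
                            acc_cells=acc_cells, counts=counts)


# ---------------------------------------------------------------------------
# on-disk layout
# ---------------------------------------------------------------------------

def _config_hash(cfg: SimConfig) -> str:
    return hashlib.sha256(repr(asdict(cfg)).encode()).hexdigest()[:12]


def write_dataset(ds: SyntheticDataset, out_dir) -> None:
    """Write coverage files (one per cell per context), the count matrix,
    cell metadata and the ground-truth tables; round-trips losslessly through
    :func:`read_dataset`."""
    out_dir = str(out_dir)
    prov = f"methstem synthetic dataset config={_config_hash(ds.config)} seed={ds.config.seed}"
    for sub in ("meth", "acc"):
        os.makedirs(os.path.join(out_dir, sub), exist_ok=True)
    for cell in ds.meth_cells:
        write_cov_file(cell, os.path.join(out_dir, "meth", f"{cell.cell_id}.CpG.cov"),
                       provenance=prov)
    for cell in ds.acc_cells:
        write_cov_file(cell, os.path.join(out_dir, "acc", f"{cell.cell_id}.GpC.cov"),
                       provenance=prov)
    ds.counts.to_csv(os.path.join(out_dir, "expression_counts.tsv"),
                     sep="\t", index_label="gene_id")
    ds.truth.cells.to_csv(os.path.join(out_dir, "cell_metadata.tsv"),
                          sep="\t", index=False)
    ds.truth.regions.to_csv(os.path.join(out_dir, "truth_regions.tsv"),
                            sep="\t", index=False)
    ds.truth.genes.to_csv(os.path.join(out_dir, "truth_genes.tsv"),
                          sep="\t", index=False)
    np.savetxt(os.path.join(out_dir, "truth_level_matrix.tsv"),
               ds.truth.level_matrix, delimiter="\t", fmt="%.6g")


def read_dataset(out_dir) -> tuple[list[CpGCallSet], list[CpGCallSet],
                                   pd.DataFrame, pd.DataFrame]:
    """Read back methylation/accessibility call sets, counts and metadata."""
    out_dir = str(out_dir)
    meta = pd.read_csv(os.path.join(out_dir, "cell_metadata.tsv"), sep="\t")
    meth, acc = [], []
    for cell_id in meta.cell_id:
        meth.append(read_cov_file(
            os.path.join(out_dir, "meth", f"{cell_id}.CpG.cov"), "CpG"))
        p = os.path.join(out_dir, "acc", f"{cell_id}.GpC.cov")
        if os.path.exists(p):
            acc.append(read_cov_file(p, "GpC"))
    counts = pd.read_csv(os.path.join(out_dir, "expression_counts.tsv"),
                         sep="\t", index_col="gene_id")
    return meth, acc, counts, meta
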