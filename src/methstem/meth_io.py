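"""Per-cell methylation I/O, QC, ensemble smoothing and region quantification.

Single-cell bisulfite data arrives as one Bismark-style coverage file per cell
and context (CpG for endogenous methylation, GpC for NOMe-marked chromatin
accessibility). This module reads those files into sparse per-cell call sets,
filters low-quality cells, computes the tricube-smoothed ensemble methylation
track over all high-quality cells, and quantifies per-cell methylation in
genomic regions as the *shrunken mean of residuals*: the average deviation of
a cell's calls from the smoothed ensemble, shrunk toward zero when the region
is covered by few sites.

Coordinates are 0-based half-open internally; Bismark coverage files are
1-based inclusive on disk and converted on read/write.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._stats import tricube

__all__ = [
    "GenomicRegion",
    "CpGCallSet",
    "QCMetrics",
    "SmoothedTrack",
    "RegionMatrix",
    "read_cov_file",
    "write_cov_file",
    "cell_qc",
    "smooth_ensemble",
    "shrunken_residuals",
    "quantify_regions",
    "promoter_regions",
    "anchor_profile",
    "pseudobulk_smooth_track",
    "read_bed",
    "write_bed",
]


@dataclass(frozen=True)
class GenomicRegion:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str | None = None
    label: str | None = None

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid region {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class CpGCallSet:
    """One cell's sparse cytosine calls in a single context.

    ``calls`` maps chromosome -> (positions, n_methylated, n_total) arrays,
    positions strictly increasing, 0-based.
    """

    cell_id: str
    context: str  # "CpG" or "GpC"
    calls: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )

    def __post_init__(self):
        if self.context not in ("CpG", "GpC"):
            raise ValueError(f"context must be 'CpG' or 'GpC', got {self.context!r}")
        for chrom, (pos, meth, total) in self.calls.items():
            if not (len(pos) == len(meth) == len(total)):
                raise ValueError(f"{self.cell_id}/{chrom}: ragged call arrays")
            if len(pos) and np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"{self.cell_id}/{chrom}: positions not strictly increasing"
                )
            if np.any(meth > total) or np.any(total < 0):
                raise ValueError(f"{self.cell_id}/{chrom}: n_methylated > n_total")

    @property
    def n_sites(self) -> int:
        return sum(len(pos) for pos, _, _ in self.calls.values())

    def chroms(self) -> list[str]:
        return sorted(self.calls)

    def values(self, chrom: str) -> np.ndarray:
        """Per-site call value n_methylated / n_total (binary for 1x sites)."""
        _, meth, total = self.calls[chrom]
        return meth.astype(float) / np.maximum(total, 1)


@dataclass
class QCMetrics:
    cell_id: str
    n_cpg_sites: int
    n_genes_detected: int
    tss_profile_ok: bool
    passed: bool


@dataclass
class SmoothedTrack:
    """Smoothed ensemble methylation, defined at every pooled site position."""

    context: str
    bandwidth_bp: float
    track: dict[str, tuple[np.ndarray, np.ndarray]]  # chrom -> (pos, value)
    global_mean: float = np.nan

    def at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Track values at arbitrary positions (linear interpolation between
        pooled sites; the pooled global mean on chromosomes without data)."""
        positions = np.asarray(positions)
        if chrom not in self.track or len(self.track[chrom][0]) == 0:
            return np.full(positions.shape, self.global_mean)
        pos, val = self.track[chrom]
        return np.interp(positions, pos, val)


@dataclass
class RegionMatrix:
    """Cells x regions methylation measures with explicit missingness.

    ``values`` holds shrunken mean residuals (NaN where a region has no
    observed site in a cell); ``n_obs`` the observed-site counts; ``raw_mean``
    the plain methylated/total fraction per cell x region, for displays on the
    interpretable 0..1 scale.
    """

    regions: list[GenomicRegion]
    cells: list[str]
    values: np.ndarray
    n_obs: np.ndarray
    raw_mean: np.ndarray

    def __post_init__(self):
        expect = (len(self.cells), len(self.regions))
        for name in ("values", "n_obs", "raw_mean"):
            if getattr(self, name).shape != expect:
                raise ValueError(f"{name} has shape {getattr(self, name).shape}, "
                                 f"expected {expect}")

    @property
    def missing(self) -> np.ndarray:
        return self.n_obs == 0

    def obs_fraction(self) -> np.ndarray:
        """Per-region fraction of cells with at least one observed site."""
        return (self.n_obs > 0).mean(axis=0)

    def region_coverage(self) -> np.ndarray:
        """Per-region number of cells with at least one observed site."""
        return (self.n_obs > 0).sum(axis=0)


# ---------------------------------------------------------------------------
# Bismark coverage I/O
# ---------------------------------------------------------------------------

_COV_COLUMNS = ["chrom", "start", "end", "meth_pct", "n_meth", "n_unmeth"]


def read_cov_file(path, context: str = "CpG") -> CpGCallSet:
    """Read a Bismark coverage2cytosine-style coverage file for one cell.

    The 6 columns are chrom, position, position (1-based inclusive),
    methylation percentage, methylated count, unmethylated count. Positions
    are converted to 0-based. A ``# context:`` header written by this package
    is checked against the requested context; a mismatch is rejected so CpG
    and GpC calls can never be mixed silently.
    """
    cell_id = os.path.basename(str(path))
    for suffix in (".cov", ".tsv", ".txt"):
        if cell_id.endswith(suffix):
            cell_id = cell_id[: -len(suffix)]
    if cell_id.endswith(".CpG") or cell_id.endswith(".GpC"):
        cell_id = cell_id[:-4]

    header_lines = []
    with open(path) as fh:
        while True:
            offset = fh.tell()
            line = fh.readline()
            if line.startswith("#"):
                header_lines.append(line)
            else:
                fh.seek(offset)
                break
        body = fh.read()

    for line in header_lines:
        if "context:" in line:
            declared = line.split("context:")[1].strip()
            if declared != context:
                raise ValueError(
                    f"{path}: file declares context {declared!r} but "
                    f"{context!r} was requested"
                )

    n_header = len(header_lines)
    if not body.strip():
        return CpGCallSet(cell_id=cell_id, context=context, calls={})

    try:
        df = pd.read_csv(
            io.StringIO(body),
            sep="\t",
            names=_COV_COLUMNS,
            dtype={"chrom": str},
            header=None,
        )
        bad = df[["start", "end", "n_meth", "n_unmeth"]].isna().any(axis=1)
        if bad.any():
            raise ValueError(f"line {int(np.argmax(bad.values)) + 1 + n_header}")
        df = df.astype({"start": np.int64, "end": np.int64,
                        "n_meth": np.int64, "n_unmeth": np.int64})
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: malformed coverage file ({exc})") from exc

    calls = {}
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        pos = sub["start"].to_numpy() - 1  # 1-based -> 0-based
        meth = sub["n_meth"].to_numpy()
        total = meth + sub["n_unmeth"].to_numpy()
        if len(pos) and np.any(np.diff(pos) <= 0):
            raise ValueError(f"{path}: duplicate positions on {chrom}")
        calls[str(chrom)] = (pos, meth, total)
    return CpGCallSet(cell_id=cell_id, context=context, calls=calls)


def write_cov_file(cell: CpGCallSet, path, provenance: str | None = None) -> None:
    """Write a call set as a Bismark-style coverage file (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write(f"# context: {cell.context}\n")
        if provenance:
            fh.write(f"# {provenance}\n")
        for chrom in cell.chroms():
            pos, meth, total = cell.calls[chrom]
            unmeth = total - meth
            pct = np.where(total > 0, 100.0 * meth / np.maximum(total, 1), 0.0)
            for p, pc, m, u in zip(pos + 1, pct, meth, unmeth):
                fh.write(f"{chrom}\t{p}\t{p}\t{pc:g}\t{m}\t{u}\n")


def read_bed(path) -> list[GenomicRegion]:
    """Read BED (0-based half-open) intervals; BED6 strand honoured."""
    regions = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "track", "browser")) or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else None
            label = f[3] if len(f) > 3 else None
            regions.append(GenomicRegion(f[0], int(f[1]), int(f[2]),
                                         strand=strand, label=label))
    return regions


def write_bed(regions: Sequence[GenomicRegion], path, scores=None,
              provenance: str | None = None) -> None:
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        for i, r in enumerate(regions):
            name = r.label or f"region_{i}"
            score = 0 if scores is None else scores[i]
            strand = r.strand or "."
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t{score}\t{strand}\n")


# ---------------------------------------------------------------------------
# Cell QC
# ---------------------------------------------------------------------------

def _tss_window_mean(cell: CpGCallSet, tss_list, half_width: int) -> tuple[float, float]:
    """Mean call value within +/-half_width of TSSs, and in 1-3 kb flanks."""
    centre_m = centre_t = flank_m = flank_t = 0.0
    for chrom, grp in tss_list.groupby("chrom"):
        if chrom not in cell.calls:
            continue
        pos, meth, total = cell.calls[chrom]
        for tss in grp["tss"].to_numpy():
            lo, hi = np.searchsorted(pos, [tss - half_width, tss + half_width + 1])
            centre_m += meth[lo:hi].sum()
            centre_t += total[lo:hi].sum()
            for a, b in ((tss - 3000, tss - 1000), (tss + 1000, tss + 3000)):
                lo, hi = np.searchsorted(pos, [a, b])
                flank_m += meth[lo:hi].sum()
                flank_t += total[lo:hi].sum()
    centre = centre_m / centre_t if centre_t > 0 else np.nan
    flank = flank_m / flank_t if flank_t > 0 else np.nan
    return centre, flank


def cell_qc(
    cells: Sequence[CpGCallSet],
    expression: pd.DataFrame | None,
    tss_list: pd.DataFrame | None,
    min_cpg_sites: int = 50_000,
    min_genes: int = 1_500,
    tss_margin: float = 0.1,
    tss_half_width: int = 200,
) -> tuple[pd.DataFrame, list[CpGCallSet]]:
    """Filter cells on coverage, detected genes and the TSS methylation dip.

    A cell passes if it covers at least ``min_cpg_sites`` cytosines, detects
    at least ``min_genes`` genes (non-zero counts; skipped when no expression
    is supplied), and shows the expected hypomethylation around TSSs: mean
    methylation within +/-``tss_half_width`` bp of TSSs at least ``tss_margin``
    below the mean in the 1-3 kb flanks (skipped when no TSS list is given).

    Returns a per-cell QC table and the list of passing cells.
    """
    rows = []
    kept = []
    for cell in cells:
        n_sites = cell.n_sites
        if expression is not None and cell.cell_id in expression.columns:
            n_genes = int((expression[cell.cell_id] > 0).sum())
        elif expression is not None:
            n_genes = 0
        else:
            n_genes = -1
        if tss_list is not None:
            centre, flank = _tss_window_mean(cell, tss_list, tss_half_width)
            tss_ok = bool(
                np.isfinite(centre) and np.isfinite(flank)
                and centre < flank - tss_margin
            )
        else:
            tss_ok = True
        passed = (
            n_sites >= min_cpg_sites
            and (expression is None or n_genes >= min_genes)
            and tss_ok
        )
        rows.append(QCMetrics(cell.cell_id, n_sites, n_genes, tss_ok, passed))
        if passed:
            kept.append(cell)
    report = pd.DataFrame(
        [(m.cell_id, m.n_cpg_sites, m.n_genes_detected, m.tss_profile_ok, m.passed)
         for m in rows],
        columns=["cell_id", "n_cpg_sites", "n_genes_detected",
                 "tss_profile_ok", "pass"],
    )
    return report, kept


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------

def _pool_calls(cells: Iterable[CpGCallSet]) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Union of observed positions with summed counts across cells."""
    per_chrom: dict[str, list] = {}
    for cell in cells:
        for chrom, (pos, meth, total) in cell.calls.items():
            per_chrom.setdefault(chrom, []).append((pos, meth, total))
    pooled = {}
    for chrom, parts in per_chrom.items():
        pos = np.concatenate([p for p, _, _ in parts])
        meth = np.concatenate([m for _, m, _ in parts]).astype(float)
        total = np.concatenate([t for _, _, t in parts]).astype(float)
        upos, inv = np.unique(pos, return_inverse=True)
        pooled[chrom] = (
            upos,
            np.bincount(inv, weights=meth, minlength=len(upos)),
            np.bincount(inv, weights=total, minlength=len(upos)),
        )
    return pooled


def _tricube_smooth_arrays(
    pos: np.ndarray, num: np.ndarray, den: np.ndarray,
    bandwidth: float, fallback: float,
) -> np.ndarray:
    """Smoothed value sum(w*num)/sum(w*den) at each position, window +/-bandwidth."""
    n = len(pos)
    out = np.empty(n)
    lo = np.searchsorted(pos, pos - bandwidth, side="left")
    hi = np.searchsorted(pos, pos + bandwidth, side="right")
    for i in range(n):
        sl = slice(lo[i], hi[i])
        w = tricube(pos[sl] - pos[i], bandwidth)
        wd = float(w @ den[sl])
        out[i] = (w @ num[sl]) / wd if wd > 0 else fallback
    return out


def smooth_ensemble(
    cells: Sequence[CpGCallSet], context: str = "CpG",
    bandwidth_bp: float = 1000.0,
) -> SmoothedTrack:
    """Tricube-smoothed mean methylation of all cells over the genome.

    Calls from all cells are pooled per site; the smoothed value at a site is
    the tricube-weighted average of all pooled calls within ``bandwidth_bp``,
    so a constant signal is preserved exactly. Default bandwidth is 1,000 bp
    for CpG methylation; 500 bp is the convention for GpC accessibility.
    """
    if not cells:
        raise ValueError("smooth_ensemble requires at least one cell")
    for cell in cells:
        if cell.context != context:
            raise ValueError(
                f"cell {cell.cell_id} has context {cell.context}, expected {context}"
            )
    pooled = _pool_calls(cells)
    tot_m = sum(m.sum() for _, m, _ in pooled.values())
    tot_t = sum(t.sum() for _, _, t in pooled.values())
    global_mean = tot_m / tot_t if tot_t > 0 else np.nan
    track = {}
    for chrom, (pos, meth, total) in pooled.items():
        track[chrom] = (
            pos,
            _tricube_smooth_arrays(pos.astype(float), meth, total,
                                   bandwidth_bp, global_mean),
        )
    return SmoothedTrack(context=context, bandwidth_bp=bandwidth_bp,
                         track=track, global_mean=float(global_mean))


def pseudobulk_smooth_track(
    cell_group: Sequence[CpGCallSet], bandwidth_bp: float = 1000.0,
) -> SmoothedTrack:
    """Smoothed pseudobulk methylation curve for locus plots.

    Per-site mean methylation is pooled over the group, then smoothed with a
    tricube kernel (default 1,000 bp bandwidth), weighting each site equally.
    """
    if not cell_group:
        raise ValueError("pseudobulk_smooth_track requires at least one cell")
    pooled = _pool_calls(cell_group)
    tot_m = sum(m.sum() for _, m, _ in pooled.values())
    tot_t = sum(t.sum() for _, _, t in pooled.values())
    global_mean = tot_m / tot_t if tot_t > 0 else np.nan
    track = {}
    for chrom, (pos, meth, total) in pooled.items():
        means = meth / np.maximum(total, 1.0)
        track[chrom] = (
            pos,
            _tricube_smooth_arrays(pos.astype(float), means,
                                   np.ones_like(means), bandwidth_bp,
                                   global_mean),
        )
    return SmoothedTrack(context=cell_group[0].context,
                         bandwidth_bp=bandwidth_bp, track=track,
                         global_mean=float(global_mean))


# ---------------------------------------------------------------------------
# Region quantification (shrunken mean residuals)
# ---------------------------------------------------------------------------

def _region_arrays(regions: Sequence[GenomicRegion]):
    """Group region indices by chromosome with start/end arrays."""
    by_chrom: dict[str, list[int]] = {}
    for i, r in enumerate(regions):
        by_chrom.setdefault(r.chrom, []).append(i)
    out = {}
    for chrom, idx in by_chrom.items():
        idx = np.asarray(idx)
        starts = np.array([regions[i].start for i in idx])
        ends = np.array([regions[i].end for i in idx])
        out[chrom] = (idx, starts, ends)
    return out


def shrunken_residuals(
    cell: CpGCallSet, track: SmoothedTrack,
    regions: Sequence[GenomicRegion], shrinkage: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shrunken mean residual of one cell in each region.

    Per region the residual at each observed site is the cell's call value
    minus the smoothed ensemble value there; the region entry is
    sum(residuals) / (n_obs + shrinkage). Regions without observed sites are
    NaN (missing), never zero. Also returns the observed-site counts and the
    raw mean methylation fraction per region.
    """
    n = len(regions)
    values = np.full(n, np.nan)
    n_obs = np.zeros(n, dtype=np.int64)
    raw = np.full(n, np.nan)
    for chrom, (idx, starts, ends) in _region_arrays(regions).items():
        if chrom not in cell.calls:
            continue
        pos, meth, total = cell.calls[chrom]
        vals = meth.astype(float) / np.maximum(total, 1)
        resid = vals - track.at(chrom, pos)
        cs_resid = np.concatenate([[0.0], np.cumsum(resid)])
        cs_meth = np.concatenate([[0.0], np.cumsum(meth.astype(float))])
        cs_total = np.concatenate([[0.0], np.cumsum(total.astype(float))])
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="left")
        cnt = hi - lo
        with np.errstate(invalid="ignore", divide="ignore"):
            v = (cs_resid[hi] - cs_resid[lo]) / (cnt + shrinkage)
            tot = cs_total[hi] - cs_total[lo]
            rm = np.where(tot > 0, (cs_meth[hi] - cs_meth[lo]) / np.maximum(tot, 1), np.nan)
        covered = cnt > 0
        values[idx[covered]] = v[covered]
        raw[idx[covered]] = rm[covered]
        n_obs[idx] = cnt
    return values, n_obs, raw


def quantify_regions(
    cells: Sequence[CpGCallSet], regions: Sequence[GenomicRegion],
    track: SmoothedTrack | None = None, shrinkage: float = 1.0,
    bandwidth_bp: float = 1000.0,
) -> RegionMatrix:
    """Cells x regions shrunken-residual matrix (plus raw mean fractions).

    If no smoothed track is supplied the ensemble track is computed from the
    given cells first.
    """
    if track is None:
        track = smooth_ensemble(cells, context=cells[0].context,
                                bandwidth_bp=bandwidth_bp)
    values = np.full((len(cells), len(regions)), np.nan)
    n_obs = np.zeros((len(cells), len(regions)), dtype=np.int64)
    raw = np.full((len(cells), len(regions)), np.nan)
    for ci, cell in enumerate(cells):
        values[ci], n_obs[ci], raw[ci] = shrunken_residuals(
            cell, track, regions, shrinkage=shrinkage
        )
    return RegionMatrix(
        regions=list(regions), cells=[c.cell_id for c in cells],
        values=values, n_obs=n_obs, raw_mean=raw,
    )


def promoter_regions(tss_list: pd.DataFrame, half_width: int = 1000) -> list[GenomicRegion]:
    """Promoter intervals TSS +/- half_width (default 1,000 bp) per gene."""
    out = []
    for row in tss_list.itertuples():
        start = max(0, int(row.tss) - half_width)
        out.append(GenomicRegion(row.chrom, start, int(row.tss) + half_width,
                                 strand=getattr(row, "strand", None),
                                 label=getattr(row, "gene_id", None)))
    return out


# ---------------------------------------------------------------------------
# Anchor profiles (TSS / CTCF metaplots)
# ---------------------------------------------------------------------------

def anchor_profile(
    cells: CpGCallSet | Sequence[CpGCallSet],
    anchors: pd.DataFrame, window_bp: int = 2000, bin_bp: int = 50,
) -> pd.DataFrame:
    """Average methylation by distance bin around anchor points.

    ``anchors`` needs columns chrom, pos and optionally strand; sites around
    minus-strand anchors are mirrored so that positive distances are always
    downstream in the anchor's orientation. Distance bins are
    [k*bin_bp, (k+1)*bin_bp) covering [-window_bp, window_bp); bins with no
    observed call are NaN.
    """
    if isinstance(cells, CpGCallSet):
        cells = [cells]
    edges = np.arange(-window_bp, window_bp + bin_bp, bin_bp)
    n_bins = len(edges) - 1
    meth_sum = np.zeros(n_bins)
    total_sum = np.zeros(n_bins)
    pooled = _pool_calls(cells)
    has_strand = "strand" in anchors.columns
    for row in anchors.itertuples():
        chrom = row.chrom
        if chrom not in pooled:
            continue
        pos, meth, total = pooled[chrom]
        lo, hi = np.searchsorted(pos, [row.pos - window_bp, row.pos + window_bp])
        rel = (pos[lo:hi] - int(row.pos)).astype(float)
        if has_strand and row.strand == "-":
            rel = -rel
        which = np.digitize(rel, edges) - 1
        ok = (which >= 0) & (which < n_bins)
        np.add.at(meth_sum, which[ok], meth[lo:hi][ok])
        np.add.at(total_sum, which[ok], total[lo:hi][ok])
    with np.errstate(invalid="ignore"):
        value = np.where(total_sum > 0, meth_sum / np.maximum(total_sum, 1), np.nan)
    return pd.DataFrame({
        "bin_start": edges[:-1], "bin_end": edges[1:],
        "mean_methylation": value, "n_calls": total_sum.astype(int),
    })
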