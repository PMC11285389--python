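"""Per-bin (RD, MQ) profile construction.

This module turns a coordinate-sorted BAM plus its reference FASTA into the
two-dimensional per-bin profile the candidate detector consumes:

1. the chromosome is divided into contiguous, non-overlapping bins of fixed
   width ``Lb``; bins whose reference window contains an ``N`` are masked out;
2. read depth (RD) and mapping quality (MQ) are averaged per bin, with
   uncovered positions contributing zero;
3. the RD signal is corrected for GC bias against bins of similar GC fraction;
4. both signals are smoothed with an exact 1-D total-variation denoiser;
5. the smoothed RD is partitioned by permutation-tested recursive (circular)
   binary segmentation, and per-segment means of the standardized signals are
   recorded.

Coordinates are 0-based half-open throughout this module.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pysam

from .config import PipelineConfig

logger = logging.getLogger(__name__)

__all__ = [
    "BinGrid",
    "BinProfile",
    "Segment",
    "SegmentTable",
    "ProfileResult",
    "build_bins",
    "bin_gc",
    "compute_rd_mq",
    "correct_gc",
    "tv_denoise",
    "standardize",
    "segment_cbs",
    "build_profile",
]

# GC bins are "similar" when their GC fractions differ by at most this much.
GC_CLASS_TOL = 0.002
_EPS = 1e-12


@dataclass
class BinGrid:
    """Fixed-width binning of one chromosome.

    ``n_mask[i]`` is True when the reference window of bin ``i`` contains at
    least one ``N``; masked bins carry no signal downstream.
    """

    chromosome: str
    lb: int
    chrom_length: int
    n_mask: np.ndarray

    @property
    def n_bins(self) -> int:
        return int(self.n_mask.size)

    def bin_starts(self) -> np.ndarray:
        return np.arange(self.n_bins, dtype=np.int64) * self.lb

    def bin_ends(self) -> np.ndarray:
        return np.minimum(self.bin_starts() + self.lb, self.chrom_length)

    def bin_widths(self) -> np.ndarray:
        # the terminal bin may be truncated; denominators use the true width
        return self.bin_ends() - self.bin_starts()


@dataclass
class BinProfile:
    """Per-bin mean read depth, mean mapping quality and GC fraction.

    Masked bins hold NaN in every signal array.
    """

    grid: BinGrid
    rd: np.ndarray
    mq: np.ndarray
    gc: np.ndarray


@dataclass
class Segment:
    """Half-open bin-index range with mean standardized (RD, MQ) features."""

    start_bin: int
    end_bin: int
    mean_std_rd: float
    mean_std_mq: float

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin


@dataclass
class SegmentTable:
    """Ordered, non-overlapping segments partitioning the unmasked bins."""

    segments: list[Segment] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def features(self) -> np.ndarray:
        """(n_segments, 2) array of (mean_std_rd, mean_std_mq)."""
        return np.array(
            [[s.mean_std_rd, s.mean_std_mq] for s in self.segments], dtype=float
        ).reshape(len(self.segments), 2)


@dataclass
class ProfileResult:
    """Everything the profile stage computed, for one chromosome."""

    grid: BinGrid
    gc: np.ndarray
    rd_raw: np.ndarray
    rd_gc: np.ndarray
    rd_smooth: np.ndarray
    mq_raw: np.ndarray
    mq_smooth: np.ndarray
    z_rd: np.ndarray
    z_mq: np.ndarray
    segments: SegmentTable


def build_bins(reference_path: str, chromosome: str, lb: int = 1000) -> BinGrid:
    """Divide ``chromosome`` into ``ceil(length / lb)`` fixed-width bins.

    A bin is masked when its reference window contains one or more ``N``
    (case-insensitive); the final bin's window may be shorter than ``lb``.
    """
    if lb <= 0:
        raise ValueError(f"bin length must be positive, got {lb}")
    if lb < 100:
        raise ValueError(f"bin length must be >= 100, got {lb}")
    with pysam.FastaFile(reference_path) as fa:
        if chromosome not in fa.references:
            raise ValueError(
                f"chromosome {chromosome!r} not found in {reference_path}"
            )
        seq = fa.fetch(chromosome).upper()
    length = len(seq)
    n_bins = -(-length // lb)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_n = arr == ord("N")
    starts = np.arange(n_bins) * lb
    if is_n.any():
        mask = np.add.reduceat(is_n, starts) > 0
    else:
        mask = np.zeros(n_bins, dtype=bool)
    return BinGrid(chromosome=chromosome, lb=lb, chrom_length=length, n_mask=mask)


def bin_gc(reference_path: str, grid: BinGrid) -> np.ndarray:
    """GC fraction per bin (NaN for masked bins), over the true window width."""
    with pysam.FastaFile(reference_path) as fa:
        seq = fa.fetch(grid.chromosome).upper()
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    gc_counts = np.add.reduceat(is_gc.astype(np.int64), grid.bin_starts())
    gc = gc_counts / grid.bin_widths()
    gc[grid.n_mask] = np.nan
    return gc


def _counts_per_read(bam: pysam.AlignmentFile, chromosome: str):
    """Yield (start, end, mapq) for reads contributing to depth.

    Primary alignments only: secondary, supplementary, duplicate and QC-fail
    records are excluded so each sequenced base is counted at most once.
    Supplementary alignments still contribute split-read evidence downstream.
    """
    for read in bam.fetch(chromosome):
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        if read.is_duplicate or read.is_qcfail:
            continue
        end = read.reference_end
        if end is None:
            continue
        yield read.reference_start, end, read.mapping_quality


def compute_rd_mq(
    bam_path: str, grid: BinGrid, gc: np.ndarray | None = None
) -> BinProfile:
    """Average read depth and mapping quality per bin.

    Per-position depth is the pileup of aligned read bases; per-position
    mapping quality is the mean MAPQ of reads covering the position (zero when
    uncovered, mirroring the zero-fill of missing positions). Bin values are
    means over the bin's reference positions.
    """
    length = grid.chrom_length
    depth_diff = np.zeros(length + 1, dtype=np.float64)
    mq_diff = np.zeros(length + 1, dtype=np.float64)
    n_reads = 0
    with pysam.AlignmentFile(bam_path) as bam:
        if grid.chromosome not in bam.references:
            raise ValueError(
                f"chromosome {grid.chromosome!r} not found in {bam_path}"
            )
        if not bam.has_index():
            raise ValueError(f"{bam_path} has no index (.bai); sort and index it")
        starts, ends, mqs = [], [], []
        for start, end, mapq in _counts_per_read(bam, grid.chromosome):
            starts.append(start)
            ends.append(min(end, length))
            mqs.append(mapq)
        n_reads = len(starts)
        if n_reads:
            s = np.asarray(starts, dtype=np.int64)
            e = np.asarray(ends, dtype=np.int64)
            q = np.asarray(mqs, dtype=np.float64)
            np.add.at(depth_diff, s, 1.0)
            np.add.at(depth_diff, e, -1.0)
            np.add.at(mq_diff, s, q)
            np.add.at(mq_diff, e, -q)
    if n_reads == 0:
        warnings.warn(
            f"no mapped reads on {grid.chromosome}; profile is all zero",
            stacklevel=2,
        )
    depth = np.cumsum(depth_diff)[:length]
    mq_sum = np.cumsum(mq_diff)[:length]
    with np.errstate(invalid="ignore", divide="ignore"):
        mq_pos = np.where(depth > 0, mq_sum / np.maximum(depth, 1e-300), 0.0)
    bin_starts = grid.bin_starts()
    widths = grid.bin_widths().astype(float)
    rd = np.add.reduceat(depth, bin_starts) / widths
    mq = np.add.reduceat(mq_pos, bin_starts) / widths
    rd[grid.n_mask] = np.nan
    mq[grid.n_mask] = np.nan
    if gc is None:
        gc = np.full(grid.n_bins, np.nan)
    return BinProfile(grid=grid, rd=rd, mq=mq, gc=gc)


def correct_gc(profile: BinProfile) -> BinProfile:
    """GC-correct the RD signal: ``RD'_i = (RD_ref / RD_GC) * RD_i``.

    ``RD_GC`` is the typical RD of bins whose GC fraction differs from bin
    i's by at most 0.002, and ``RD_ref`` the typical RD of all unmasked bins.
    The typical value is the *median*: duplicated bins are strong RD
    outliers, and on a desk-scale genome they make up enough of a GC class
    to drag a class mean upward and spuriously depress the corrected RD of
    the ordinary bins sharing that class. The median coincides with the mean
    for homogeneous classes and is immune to that contamination. Bins whose
    GC class has zero typical RD are left unchanged (with a warning). MQ is
    untouched.
    """
    rd = profile.rd.copy()
    ok = ~profile.grid.n_mask & np.isfinite(profile.rd) & np.isfinite(profile.gc)
    if not ok.any():
        return BinProfile(profile.grid, rd, profile.mq.copy(), profile.gc)
    gc = profile.gc[ok]
    vals = profile.rd[ok]
    order = np.argsort(gc, kind="stable")
    gc_sorted = gc[order]
    rd_sorted = vals[order]
    lo = np.searchsorted(gc_sorted, gc - GC_CLASS_TOL - _EPS, side="left")
    hi = np.searchsorted(gc_sorted, gc + GC_CLASS_TOL + _EPS, side="right")
    class_typ = np.array(
        [np.median(rd_sorted[a:b]) for a, b in zip(lo, hi)], dtype=float
    )
    global_typ = float(np.median(vals))
    zero = class_typ <= 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} bins fall in GC classes with zero median RD; "
            "left uncorrected",
            stacklevel=2,
        )
    factor = np.where(zero, 1.0, global_typ / np.where(zero, 1.0, class_typ))
    rd[ok] = vals * factor
    return BinProfile(profile.grid, rd, profile.mq.copy(), profile.gc)


def tv_denoise(signal: np.ndarray, lam: float) -> np.ndarray:
    """Exact 1-D total-variation denoising (fused-lasso signal approximator).

    Returns the unique minimizer of

        0.5 * ||y - x||^2 + lam * sum_i |x[i+1] - x[i]|

    for the input ``y``, using a direct taut-string style sweep (Condat's
    algorithm); no iterative optimisation is involved, so the output is exact
    to floating-point precision.
    """
    if lam < 0:
        raise ValueError(f"TV penalty must be non-negative, got {lam}")
    y = np.asarray(signal, dtype=np.float64)
    if y.ndim != 1:
        raise ValueError("tv_denoise expects a 1-D signal")
    if not np.isfinite(y).all():
        raise ValueError("tv_denoise expects a finite signal")
    n = y.size
    if n == 0 or lam == 0 or n == 1:
        return y.copy()
    x = np.empty(n, dtype=np.float64)
    k = k0 = km = kp = 0
    vmin = y[0] - lam
    vmax = y[0] + lam
    umin = lam
    umax = -lam
    while True:
        while k < n - 1:
            if y[k + 1] + umin < vmin - lam:
                # negative jump: the running minorant cannot be continued
                x[k0 : km + 1] = vmin
                k = k0 = km = kp = km + 1
                vmin = y[k]
                vmax = y[k] + 2 * lam
                umin = lam
                umax = -lam
            elif y[k + 1] + umax > vmax + lam:
                # positive jump
                x[k0 : kp + 1] = vmax
                k = k0 = km = kp = kp + 1
                vmin = y[k] - 2 * lam
                vmax = y[k]
                umin = lam
                umax = -lam
            else:
                # no jump: extend the current segment
                k += 1
                umin += y[k] - vmin
                umax += y[k] - vmax
                if umin >= lam:
                    vmin += (umin - lam) / (k - k0 + 1)
                    umin = lam
                    km = k
                if umax <= -lam:
                    vmax += (umax + lam) / (k - k0 + 1)
                    umax = -lam
                    kp = k
        # boundary handling at the right end
        if umin < 0:
            x[k0 : km + 1] = vmin
            k = k0 = km = km + 1
            vmin = y[k]
            umin = lam
            umax = y[k] + lam - vmax
        elif umax > 0:
            x[k0 : kp + 1] = vmax
            k = k0 = kp = kp + 1
            vmax = y[k]
            umax = -lam
            umin = y[k] - lam - vmin
        else:
            x[k0:n] = vmin + umin / (k - k0 + 1)
            return x


def standardize(values: np.ndarray) -> np.ndarray:
    """Z-score with the population standard deviation: ``(r - mu) / sigma``.

    NaN entries (masked bins) are ignored for the statistics and preserved in
    the output. A constant input yields all zeros with a warning.
    """
    values = np.asarray(values, dtype=np.float64)
    finite = np.isfinite(values)
    if finite.sum() < 2:
        raise ValueError("standardize needs at least 2 finite values")
    mu = values[finite].mean()
    sigma = values[finite].std(ddof=0)
    out = np.full_like(values, np.nan)
    if sigma == 0:
        warnings.warn("constant signal: standardized values set to 0", stacklevel=2)
        out[finite] = 0.0
        return out
    out[finite] = (values[finite] - mu) / sigma
    return out


def _arc_lengths(n: int, dense_max: int = 64, ratio: float = 1.2) -> np.ndarray:
    """Arc lengths scanned by the CBS statistic: 1..dense_max densely, then a
    geometric grid up to n//2 (an arc and its complement have equal
    statistics, so longer arcs are redundant)."""
    half = max(1, n // 2)
    dense = np.arange(1, min(dense_max, half) + 1)
    if half <= dense_max:
        return dense
    geo = [float(dense_max)]
    while geo[-1] * ratio < half:
        geo.append(geo[-1] * ratio)
    geo.append(float(half))
    return np.unique(np.concatenate([dense, np.rint(geo).astype(int)]))


def _max_arc_stat(
    values: np.ndarray, lengths: np.ndarray
) -> tuple[float, int, int]:
    """Best circular-segmentation arc of one segment.

    For an arc [i, j) of length L, the statistic is
    |mean_in - mean_out| * sqrt(L * (n - L) / n); for fixed L the maximizing
    window is found by a sliding sum, so the scan is O(n) per arc length.
    Returns (stat, i, j).
    """
    n = values.size
    c = np.concatenate([[0.0], np.cumsum(values)])
    mu = c[n] / n
    best = (-1.0, 0, n)
    for L in lengths:
        if L >= n:
            continue
        s = c[L:] - c[:-L]
        dev = np.abs(s - L * mu) * np.sqrt(n / (L * (n - L)))
        i = int(np.argmax(dev))
        if dev[i] > best[0]:
            best = (float(dev[i]), i, i + int(L))
    return best


def _perm_max_arc_stats(
    perm: np.ndarray, lengths: np.ndarray
) -> np.ndarray:
    """Max arc statistic of each row of a permutation block (same L grid)."""
    n = perm.shape[1]
    c = np.concatenate([np.zeros((perm.shape[0], 1)), np.cumsum(perm, axis=1)], axis=1)
    mu = c[:, n] / n
    best = np.zeros(perm.shape[0])
    for L in lengths:
        if L >= n:
            continue
        s = c[:, L:] - c[:, :-L]
        dev = np.abs(s - (L * mu)[:, None]) * np.sqrt(n / (L * (n - L)))
        np.maximum(best, dev.max(axis=1), out=best)
    return best


def _refine_arc(
    values: np.ndarray, i: int, j: int, lengths: np.ndarray
) -> tuple[int, int]:
    """Exact local re-scan around a grid-selected arc (large arcs only)."""
    n = values.size
    L = j - i
    if L <= 1 or (lengths.size and L <= 64):
        return i, j
    lo_l = max(1, int(L / 1.25))
    hi_l = min(max(1, n // 2), int(L * 1.25) + 1)
    dense = np.arange(lo_l, hi_l + 1)
    _, ii, jj = _max_arc_stat(values, dense)
    return ii, jj


def _cbs_breakpoints(
    values: np.ndarray,
    alpha: float,
    n_permutations: int,
    rng: np.random.Generator,
    max_perm_block: int = 250,
    adjust_values: np.ndarray | None = None,
) -> list[int]:
    """Recursive permutation-tested circular binary segmentation.

    Each segment is scanned for its best arc (interior window vs the rest;
    arcs touching a segment end reduce to ordinary binary splits). The arc's
    significance is assessed against the permutation null of the same
    scan, sequentially: permutation stops early once the p-value estimate is
    clearly below or above ``alpha``. Accepted arcs contribute their interior
    boundaries and the three resulting pieces are scanned recursively.
    """
    n = values.size
    breakpoints: list[int] = []
    stack = [(0, n)]
    while stack:
        lo, hi = stack.pop()
        m = hi - lo
        if m < 4:
            continue
        seg = values[lo:hi]
        if np.ptp(seg) == 0:
            continue
        lengths = _arc_lengths(m)
        obs, i, j = _max_arc_stat(seg, lengths)
        exceed = 0
        total = 0
        remaining = n_permutations
        while remaining > 0:
            block = min(max_perm_block, remaining)
            perm = rng.permuted(np.broadcast_to(seg, (block, m)).copy(), axis=1)
            exceed += int((_perm_max_arc_stats(perm, lengths) >= obs - _EPS).sum())
            total += block
            remaining -= block
            p_hat = (exceed + 1) / (total + 1)
            if total >= 100 and p_hat > 4 * alpha:
                break  # clearly insignificant
            if total >= 250 and exceed == 0:
                break  # clearly significant
        p = (exceed + 1) / (total + 1)
        if p <= alpha:
            i, j = _refine_arc(seg, i, j, lengths)
            if i == 0 and j == m:
                continue
            for bp in (i, j):
                if 0 < bp < m:
                    breakpoints.append(lo + bp)
            pieces = sorted({0, i, j, m})
            for a, b in zip(pieces[:-1], pieces[1:]):
                stack.append((lo + a, lo + b))
    # boundary re-fit on the *unsmoothed* signal when provided: TV smears a
    # step across a few bins at low SNR, which biases the changepoint MLE
    fit_values = values if adjust_values is None else adjust_values
    return _adjust_breakpoints(fit_values, sorted(breakpoints))


def _refit_single(values: np.ndarray, lo: int, hi: int) -> int:
    """Exact single-changepoint MLE split of values[lo:hi); returns index."""
    seg = values[lo:hi]
    m = seg.size
    c = np.concatenate([[0.0], np.cumsum(seg)])
    k = np.arange(1, m)
    f = c[1:m] ** 2 / k + (c[m] - c[1:m]) ** 2 / (m - k)
    return lo + int(np.argmax(f)) + 1


def _refit_pair(
    values: np.ndarray, lo: int, hi: int, bp1: int, bp2: int, window: int = 25
) -> tuple[int, int]:
    """Joint re-fit of two adjacent breakpoints within values[lo:hi).

    Minimizes the three-piece (three free means) residual sum of squares
    over boundary positions (i, j) restricted to ``window`` bins around the
    current estimates; equivalent to maximizing sum of (piece sum)^2 / len.
    """
    seg = values[lo:hi]
    m = seg.size
    c = np.concatenate([[0.0], np.cumsum(seg)])
    i_lo = max(1, bp1 - lo - window)
    i_hi = min(m - 2, bp1 - lo + window)
    j_hi = min(m - 1, bp2 - lo + window)
    best = (-np.inf, bp1, bp2)
    for i in range(i_lo, i_hi + 1):
        j_lo = max(i + 1, bp2 - lo - window)
        if j_lo > j_hi:
            continue
        j = np.arange(j_lo, j_hi + 1)
        s1 = c[i]
        s2 = c[j] - c[i]
        s3 = c[m] - c[j]
        f = s1 * s1 / i + s2 * s2 / (j - i) + s3 * s3 / (m - j)
        kk = int(np.argmax(f))
        if f[kk] > best[0]:
            best = (float(f[kk]), lo + i, lo + int(j[kk]))
    return best[1], best[2]


def _adjust_breakpoints(
    values: np.ndarray, breakpoints: list[int], max_sweeps: int = 5
) -> list[int]:
    """Locally re-estimate breakpoint positions after the recursion.

    Greedy recursive segmentation fixes a boundary permanently once placed,
    even when it was chosen under a misspecified intermediate model (an arc
    spanning more than one true segment). This post-pass re-fits adjacent
    breakpoint *pairs* jointly (exact three-mean changepoint fit of the span
    between their outer neighbours) so that the two edges of a short
    elevated segment do not bias each other, sweeping until stable. A lone
    breakpoint is re-fit as a single exact changepoint.
    """
    bps = sorted(set(breakpoints))
    n = values.size
    if not bps:
        return bps
    for _ in range(max_sweeps):
        changed = False
        if len(bps) == 1:
            lo, hi = 0, n
            new_bp = _refit_single(values, lo, hi)
            if new_bp != bps[0] and 0 < new_bp < n:
                bps[0] = new_bp
                changed = True
        else:
            for k in range(len(bps) - 1):
                lo = bps[k - 1] if k > 0 else 0
                hi = bps[k + 2] if k + 2 < len(bps) else n
                if hi - lo < 4:
                    continue
                new1, new2 = _refit_pair(values, lo, hi, bps[k], bps[k + 1])
                if (new1, new2) != (bps[k], bps[k + 1]):
                    bps[k], bps[k + 1] = new1, new2
                    changed = True
        bps = sorted(set(bps))
        if not changed:
            break
    return bps


def segment_cbs(
    rd_smooth: np.ndarray,
    mq_smooth: np.ndarray,
    n_mask: np.ndarray,
    config: PipelineConfig | None = None,
    rng: np.random.Generator | None = None,
    rd_raw: np.ndarray | None = None,
) -> tuple[SegmentTable, np.ndarray, np.ndarray]:
    """Segment the smoothed RD signal and annotate standardized features.

    Each maximal run of unmasked bins is segmented independently (segments
    never bridge masked gaps). Returns the segment table together with the
    standardized per-bin RD and MQ signals used for the annotations.
    """
    config = config or PipelineConfig()
    rng = rng or np.random.default_rng(config.seed)
    n_mask = np.asarray(n_mask, dtype=bool)
    unmasked = np.flatnonzero(~n_mask)
    table = SegmentTable()
    if unmasked.size == 0:
        return table, np.full_like(rd_smooth, np.nan), np.full_like(mq_smooth, np.nan)
    z_rd = standardize(rd_smooth)
    z_mq = standardize(mq_smooth)
    # maximal contiguous runs of unmasked bins
    gaps = np.flatnonzero(np.diff(unmasked) > 1)
    run_bounds = np.concatenate([[0], gaps + 1, [unmasked.size]])
    for r in range(run_bounds.size - 1):
        run = unmasked[run_bounds[r] : run_bounds[r + 1]]
        lo, hi = int(run[0]), int(run[-1]) + 1
        seg_values = rd_smooth[lo:hi]
        if hi - lo < 3:
            bps: list[int] = []
        else:
            bps = _cbs_breakpoints(
                seg_values,
                config.cbs_alpha,
                config.cbs_permutations,
                rng,
                adjust_values=None if rd_raw is None else rd_raw[lo:hi],
            )
        edges = [0, *bps, hi - lo]
        for a, b in zip(edges[:-1], edges[1:]):
            table.segments.append(
                Segment(
                    start_bin=lo + a,
                    end_bin=lo + b,
                    mean_std_rd=float(np.nanmean(z_rd[lo + a : lo + b])),
                    mean_std_mq=float(np.nanmean(z_mq[lo + a : lo + b])),
                )
            )
    return table, z_rd, z_mq


def build_profile(
    bam_path: str,
    reference_path: str,
    chromosome: str,
    config: PipelineConfig | None = None,
    rng: np.random.Generator | None = None,
) -> ProfileResult:
    """Run the full profile stage for one chromosome.

    BAM + FASTA -> binned, GC-corrected, TV-smoothed, CBS-segmented,
    standardized (RD, MQ) profile.
    """
    config = config or PipelineConfig()
    grid = build_bins(reference_path, chromosome, config.lb)
    gc = bin_gc(reference_path, grid)
    raw = compute_rd_mq(bam_path, grid, gc=gc)
    corrected = correct_gc(raw)
    ok = ~grid.n_mask
    rd_smooth = np.full(grid.n_bins, np.nan)
    mq_smooth = np.full(grid.n_bins, np.nan)
    # smooth each unmasked run separately: TV coupling across a masked gap
    # would leak signal between unrelated regions
    unmasked = np.flatnonzero(ok)
    if unmasked.size:
        gaps = np.flatnonzero(np.diff(unmasked) > 1)
        run_bounds = np.concatenate([[0], gaps + 1, [unmasked.size]])
        for r in range(run_bounds.size - 1):
            run = unmasked[run_bounds[r] : run_bounds[r + 1]]
            lo, hi = int(run[0]), int(run[-1]) + 1
            rd_smooth[lo:hi] = tv_denoise(corrected.rd[lo:hi], config.tv_lambda)
            mq_smooth[lo:hi] = tv_denoise(corrected.mq[lo:hi], config.tv_lambda)
    segments, z_rd, z_mq = segment_cbs(
        rd_smooth,
        mq_smooth,
        grid.n_mask,
        config=config,
        rng=rng,
        rd_raw=corrected.rd,
    )
    logger.info(
        "%s: %d bins (%d masked), %d segments",
        chromosome,
        grid.n_bins,
        int(grid.n_mask.sum()),
        len(segments),
    )
    return ProfileResult(
        grid=grid,
        gc=gc,
        rd_raw=raw.rd,
        rd_gc=corrected.rd,
        rd_smooth=rd_smooth,
        mq_raw=raw.mq,
        mq_smooth=mq_smooth,
        z_rd=z_rd,
        z_mq=z_mq,
        segments=segments,
    )
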