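"""Per-cell copy-number profiling.

A cell's uniquely mapping reads are counted into the equipartition bins,
the systematic GC-content bias is removed with a Lowess fit in log
space, the residual log-ratio is segmented into a piecewise-constant
copy-number ratio c_b/c-bar, and finally a multiplier M is found such
that M * c_b/c-bar rounds to integers with minimal mean squared error.
The rounded values are the integer copy-number profile; the residual
rounding error at the optimal M doubles as a per-cell quality score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from statsmodels.nonparametric.smoothers_lowess import lowess

from .binning import GenomeBinning
from . import segmentation

DEFAULT_MAPQ_MIN = 30
DEFAULT_LOWESS_SPAN = 0.3
DEFAULT_LOWESS_ITER = 3
DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_ALPHA = 0.02
DEFAULT_MIN_WIDTH = 3
DEFAULT_SEG_PERM = 100
DEFAULT_CI_HALFWIDTH = 2
DEFAULT_M_LO = 1.0
DEFAULT_M_HI = 8.0
DEFAULT_M_STEP = 0.01
QUANTIZE_ERROR_FLAG = 0.10  # flag threshold for anomalous rounding error

_TIE_TOL = 1e-9


@dataclass
class CellBinCounts:
    cell_id: str
    counts: np.ndarray  # per non-excluded bin
    total_reads: int
    discarded: int = 0


@dataclass
class RatioProfile:
    cell_id: str
    log_ratio: np.ndarray     # log(n_b/n-bar) - LowessFit(g_b)
    lowess_curve: np.ndarray  # fitted B(g) per bin
    gc: np.ndarray
    chrom: np.ndarray


@dataclass
class Changepoint:
    """A segment boundary: first bin index of the right segment, CI, sign."""
    pos: int
    ci_lo: int
    ci_hi: int
    sign: int


@dataclass
class SegmentedProfile:
    cell_id: str
    seg_values: np.ndarray    # per-bin piecewise-constant c_b/c-bar estimate, mean 1
    segments: list            # (start_bin, end_bin, mean_ratio)
    changepoints: list        # Changepoint
    chrom: np.ndarray


@dataclass
class CNProfile:
    cell_id: str
    cn: np.ndarray            # integer CN per bin
    multiplier: float
    quantize_error: float     # mean of (M*seg - round(M*seg))^2 at the optimum
    segments: list            # merged (start_bin, end_bin, cn, mean_ratio)
    changepoints: list = field(default_factory=list)  # surviving Changepoints
    chrom: np.ndarray | None = None
    flagged: bool = False


def count_cell(reads, binning: GenomeBinning, cell_id: str = "cell",
               mapq_min: int = DEFAULT_MAPQ_MIN) -> CellBinCounts:
    """Count uniquely mapping reads into the non-excluded bins.

    ``reads`` is an iterable of (chrom, pos) or (chrom, pos, mapq)
    records, or a DataFrame with those columns; a read is assigned to the
    bin whose half-open [start, end) contains its leftmost position.
    Reads below ``mapq_min`` (when MAPQ is present), in excluded bins, or
    on contigs absent from the binning are discarded and tallied.
    """
    if isinstance(reads, pd.DataFrame):
        chroms = reads["chrom"].to_numpy()
        pos = reads["pos"].to_numpy(dtype=np.int64)
        mapq = reads["mapq"].to_numpy() if "mapq" in reads.columns else None
    else:
        rows = list(reads)
        chroms = np.array([r[0] for r in rows], dtype=object)
        pos = np.array([r[1] for r in rows], dtype=np.int64)
        mapq = np.array([r[2] for r in rows]) if rows and len(rows[0]) > 2 else None

    total = len(pos)
    if mapq is not None:
        ok = np.asarray(mapq, dtype=float) >= mapq_min
        chroms, pos = chroms[ok], pos[ok]

    bins = binning.bins
    counts_all = np.zeros(len(bins), dtype=np.int64)
    assigned = 0
    for chrom in pd.unique(pd.Series(chroms)):
        sel = chroms == chrom
        sub = bins.index[bins["chrom"] == chrom]
        if len(sub) == 0:
            continue
        starts = bins.loc[sub, "start"].to_numpy()
        ends = bins.loc[sub, "end"].to_numpy()
        p = pos[sel]
        inside = (p >= starts[0]) & (p < ends[-1])
        idx = np.searchsorted(starts, p[inside], side="right") - 1
        np.add.at(counts_all, sub.to_numpy()[idx], 1)
        assigned += int(inside.sum())
    usable_mask = ~bins["excluded"].to_numpy()
    counts = counts_all[usable_mask]
    discarded = total - int(counts.sum())
    return CellBinCounts(cell_id=cell_id, counts=counts, total_reads=total,
                         discarded=discarded)


def gc_correct(counts: CellBinCounts, binning: GenomeBinning,
               span: float = DEFAULT_LOWESS_SPAN, iters: int = DEFAULT_LOWESS_ITER,
               pseudocount: float = DEFAULT_PSEUDOCOUNT) -> RatioProfile:
    """Remove the GC bias B(g) from the per-bin log count ratios.

    y_b = log((n_b + pc) / mean(n_b + pc)) is fit against bin GC with a
    robust Lowess (span ``span``, ``iters`` robustifying iterations) and
    the fit is subtracted: the residual estimates log(c_b/c-bar) + noise.
    """
    return gc_correct_arrays(counts.counts, binning.usable_gc(),
                             binning.usable_chrom_labels(), counts.cell_id,
                             span=span, iters=iters, pseudocount=pseudocount)


def gc_correct_arrays(counts: np.ndarray, gc: np.ndarray, chrom: np.ndarray,
                      cell_id: str = "cell", span: float = DEFAULT_LOWESS_SPAN,
                      iters: int = DEFAULT_LOWESS_ITER,
                      pseudocount: float = DEFAULT_PSEUDOCOUNT) -> RatioProfile:
    counts = np.asarray(counts, dtype=float)
    gc = np.asarray(gc, dtype=float)
    if counts.size < 10:
        raise ValueError("need at least 10 non-excluded bins")
    if counts.sum() == 0:
        raise ValueError(f"empty cell {cell_id!r}: all bin counts are zero")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    n = counts + pseudocount
    y = np.log(n / n.mean())
    spread = float(np.nanmax(gc) - np.nanmin(gc))
    if spread < 1e-9:
        fit = np.full_like(y, y.mean())
    else:
        fit = lowess(y, gc, frac=span, it=iters, delta=0.01 * spread,
                     return_sorted=False)
    return RatioProfile(cell_id=cell_id, log_ratio=y - fit, lowess_curve=fit,
                        gc=gc, chrom=np.asarray(chrom))


def _chrom_slices(chrom: np.ndarray):
    """Contiguous (start, stop) runs of equal chromosome label."""
    boundaries = [0] + [i for i in range(1, len(chrom)) if chrom[i] != chrom[i - 1]]
    boundaries.append(len(chrom))
    return [(boundaries[i], boundaries[i + 1]) for i in range(len(boundaries) - 1)]


def segment_profile(ratio: RatioProfile, alpha: float = DEFAULT_ALPHA,
                    min_width: int = DEFAULT_MIN_WIDTH, n_perm: int = DEFAULT_SEG_PERM,
                    ci_halfwidth: int = DEFAULT_CI_HALFWIDTH,
                    rng=None) -> SegmentedProfile:
    """Piecewise-constant fit of the copy-number ratio, per chromosome.

    Breaks are found on the log-ratio; segment means are computed on the
    linear scale exp(log_ratio) and the profile is rescaled to mean 1, so
    segment values estimate c_b/c-bar.  Each change point carries a
    +-``ci_halfwidth``-bin confidence interval clipped to its chromosome.
    """
    if rng is None:
        rng = np.random.default_rng()
    x = ratio.log_ratio
    linear = np.exp(x)
    seg_values = np.empty_like(linear)
    segments = []
    changepoints = []
    for lo, hi in _chrom_slices(ratio.chrom):
        breaks = segmentation.segment(x[lo:hi], alpha=alpha, min_width=min_width,
                                      n_perm=n_perm, rng=rng)
        bounds = [lo] + [lo + b for b in breaks] + [hi]
        for i in range(len(bounds) - 1):
            s, e = bounds[i], bounds[i + 1]
            seg_values[s:e] = linear[s:e].mean()
            segments.append((s, e, float(linear[s:e].mean())))
            if i > 0:
                sign = 1 if seg_values[s] > seg_values[s - 1] else -1
                changepoints.append(Changepoint(
                    pos=s, ci_lo=max(lo, s - ci_halfwidth),
                    ci_hi=min(hi - 1, s + ci_halfwidth), sign=sign))
    scale = seg_values.mean()
    seg_values = seg_values / scale
    segments = [(s, e, m / scale) for s, e, m in segments]
    return SegmentedProfile(cell_id=ratio.cell_id, seg_values=seg_values,
                            segments=segments, changepoints=changepoints,
                            chrom=ratio.chrom)


def _rounding_error(m: float, values: np.ndarray, weights: np.ndarray) -> float:
    scaled = m * values
    err = (scaled - np.round(scaled)) ** 2
    return float(np.sum(err * weights) / np.sum(weights))


def quantize(segmented: SegmentedProfile, m_lo: float = DEFAULT_M_LO,
             m_hi: float = DEFAULT_M_HI, m_step: float = DEFAULT_M_STEP,
             flag_threshold: float = QUANTIZE_ERROR_FLAG) -> CNProfile:
    """Scale the segmented ratios onto integers with the best multiplier M.

    M is scanned on a grid (then refined locally) to minimize the mean
    squared rounding error of M * seg_b over bins; ties within 1e-9 are
    broken toward M nearest 2 (diploid prior), then toward smaller M.
    Adjacent segments with equal integer CN are merged and their change
    points dropped.
    """
    if m_lo < 0.5 or m_hi <= m_lo:
        raise ValueError("require m_lo >= 0.5 and m_hi > m_lo")
    values = np.array([m for _, _, m in segmented.segments])
    weights = np.array([e - s for s, e, _ in segmented.segments], dtype=float)

    grid = np.arange(m_lo, m_hi + 0.5 * m_step, m_step)
    scaled = grid[:, None] * values[None, :]
    errs = ((scaled - np.round(scaled)) ** 2 * weights).sum(axis=1) / weights.sum()
    best = errs.min()
    # candidate minima: the true optimum may sit between grid points, so every
    # grid region within the discretization slack is refined before tie-breaking
    slack = (m_step * float(np.max(np.abs(values)))) ** 2
    cand = np.flatnonzero(errs <= best + slack)
    candidates = []
    run_start = 0
    for k in range(1, cand.size + 1):  # one representative per consecutive run
        if k == cand.size or cand[k] != cand[k - 1] + 1:
            run = cand[run_start:k]
            candidates.append(int(run[np.argmin(errs[run])]))
            run_start = k
    refined = []
    for idx in candidates:
        lo = max(m_lo, grid[idx] - m_step)
        hi = min(m_hi, grid[idx] + m_step)
        res = minimize_scalar(_rounding_error, args=(values, weights),
                              method="bounded", bounds=(lo, hi),
                              options={"xatol": 1e-8})
        m_cand, e_cand = float(res.x), float(res.fun)
        e_grid = float(errs[idx])
        if e_grid <= e_cand:
            m_cand, e_cand = float(grid[idx]), e_grid
        refined.append((m_cand, e_cand))
    err_min = min(e for _, e in refined)
    ties = [m for m, e in refined if e <= err_min + _TIE_TOL]
    m_star = min(ties, key=lambda m: (abs(m - 2.0), m))
    err_star = _rounding_error(m_star, values, weights)

    cn = np.round(m_star * segmented.seg_values).astype(int)
    cn = np.maximum(cn, 0)

    merged, kept_cps = _merge_segments(segmented, cn)
    return CNProfile(cell_id=segmented.cell_id, cn=cn, multiplier=m_star,
                     quantize_error=err_star, segments=merged,
                     changepoints=kept_cps, chrom=segmented.chrom,
                     flagged=err_star > flag_threshold)


def _merge_segments(segmented: SegmentedProfile, cn: np.ndarray):
    """Merge adjacent equal-CN segments; keep change points whose flanking
    integer CN values differ (sign recomputed from the integers)."""
    cp_by_pos = {cp.pos: cp for cp in segmented.changepoints}
    chrom_starts = {lo for lo, _ in _chrom_slices(segmented.chrom)}
    merged = []
    kept = []
    for s, e, mean_ratio in segmented.segments:
        seg_cn = int(cn[s])
        if merged and merged[-1][2] == seg_cn and s == merged[-1][1] and s not in chrom_starts:
            ps, pe, pcn, pm = merged[-1]
            w1, w2 = pe - ps, e - s
            merged[-1] = (ps, e, pcn, (pm * w1 + mean_ratio * w2) / (w1 + w2))
        else:
            merged.append((s, e, seg_cn, mean_ratio))
    for i in range(1, len(merged)):
        s = merged[i][0]
        if s in cp_by_pos and merged[i][2] != merged[i - 1][2]:
            cp = cp_by_pos[s]
            sign = 1 if merged[i][2] > merged[i - 1][2] else -1
            kept.append(Changepoint(pos=cp.pos, ci_lo=cp.ci_lo, ci_hi=cp.ci_hi, sign=sign))
    return merged, kept


def profile_cell(counts: CellBinCounts, binning: GenomeBinning, rng=None,
                 span: float = DEFAULT_LOWESS_SPAN, iters: int = DEFAULT_LOWESS_ITER,
                 pseudocount: float = DEFAULT_PSEUDOCOUNT, alpha: float = DEFAULT_ALPHA,
                 min_width: int = DEFAULT_MIN_WIDTH, n_perm: int = DEFAULT_SEG_PERM,
                 ci_halfwidth: int = DEFAULT_CI_HALFWIDTH, m_lo: float = DEFAULT_M_LO,
                 m_hi: float = DEFAULT_M_HI, m_step: float = DEFAULT_M_STEP,
                 flag_threshold: float = QUANTIZE_ERROR_FLAG):
    """Counts -> GC-corrected ratios -> segments -> integer CN, in one call."""
    ratio = gc_correct(counts, binning, span=span, iters=iters, pseudocount=pseudocount)
    seg = segment_profile(ratio, alpha=alpha, min_width=min_width, n_perm=n_perm,
                          ci_halfwidth=ci_halfwidth, rng=rng)
    cnp = quantize(seg, m_lo=m_lo, m_hi=m_hi, m_step=m_step,
                   flag_threshold=flag_threshold)
    return ratio, seg, cnp
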