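"""Change-point segmentation of per-bin log-ratio signals.

A recursive splitting scheme with circular-binary-segmentation
semantics: every candidate segment is tested for homogeneity with a
statistic that maximizes the standardized mean difference over both
single splits (all positions) and interior arcs (windows over a
geometric length grid, the circular alternative that catches an event in
the middle of an otherwise flat segment).  Significance comes from a
within-segment permutation test at level ``alpha``; a segment that
rejects is split at the best single-split position and both halves are
re-examined.  Two shortcuts keep the test fast without changing
decisions in practice:

* a statistic beyond an analytic high-signal threshold (far outside any
  permutation maximum) is accepted without permuting;
* permutation replicates run in blocks with early stopping as soon as
  the p-value can no longer fall below ``alpha``.

A final prune merges adjacent segments with numerically equal means, so
on noiseless piecewise-constant input the returned breaks equal the true
breaks exactly.
"""

from __future__ import annotations

import numpy as np

_EQUAL_MEAN_TOL = 1e-10
_ARC_GRID_RATIO = 1.25


def _arc_lengths(n: int, min_width: int) -> np.ndarray:
    """Geometric grid of interior-arc lengths tested by the detection statistic."""
    out = []
    l = min_width
    while l <= n - min_width:
        out.append(l)
        l = max(l + 1, int(round(l * _ARC_GRID_RATIO)))
    return np.array(out, dtype=int)


def _split_stats(x: np.ndarray, min_width: int):
    """Standardized mean-difference statistic for every admissible single split.

    t = (mean_L - mean_R) / (sd * sqrt(1/l + 1/r)) with the
    whole-segment sd, which is invariant under permutation.
    """
    n = x.size
    if n < 2 * min_width:
        return np.empty(0, dtype=int), np.empty(0)
    sd = float(x.std())
    if sd < 1e-12:
        return np.empty(0, dtype=int), np.empty(0)
    cs = np.cumsum(x)
    lengths = np.arange(min_width, n - min_width + 1)
    left_sum = cs[lengths - 1]
    mean_l = left_sum / lengths
    mean_r = (cs[-1] - left_sum) / (n - lengths)
    t = np.abs(mean_l - mean_r) / (sd * np.sqrt(1.0 / lengths + 1.0 / (n - lengths)))
    return lengths, t


def _best_split(x: np.ndarray, min_width: int):
    lengths, t = _split_stats(x, min_width)
    if t.size == 0:
        return None, 0.0
    j = int(np.argmax(t))
    return int(lengths[j]), float(t[j])


def _detection_stat_batch(xs: np.ndarray, min_width: int) -> np.ndarray:
    """Detection statistic for each row of a (P, n) batch.

    Maximum over all single splits and over all interior arcs with
    lengths on the geometric grid, of the standardized arc-vs-complement
    mean difference.  Rows share one sd (they are permutations of the
    same segment).
    """
    p, n = xs.shape
    sd = float(xs[0].std())
    if sd < 1e-12 or n < 2 * min_width:
        return np.zeros(p)
    cs = np.cumsum(xs, axis=1)
    total = cs[:, -1:]
    lengths = np.arange(min_width, n - min_width + 1)
    left = cs[:, lengths - 1]
    t_split = np.abs(left / lengths - (total - left) / (n - lengths)) / np.sqrt(
        1.0 / lengths + 1.0 / (n - lengths))
    best = t_split.max(axis=1)
    cs0 = np.concatenate([np.zeros((p, 1)), cs], axis=1)
    for l in _arc_lengths(n, min_width):
        w = cs0[:, l:] - cs0[:, :-l]
        t_arc = np.abs(w / l - (total - w) / (n - l)) / np.sqrt(1.0 / l + 1.0 / (n - l))
        best = np.maximum(best, t_arc.max(axis=1))
    return best / sd


def _detection_stat(x: np.ndarray, min_width: int) -> float:
    return float(_detection_stat_batch(x[None, :], min_width)[0])


def _permutation_p(x, stat_obs, n_perm, alpha, min_width, rng, block=25):
    """Permutation p-value (1+exceed)/(1+P) with early stopping.

    Stops as soon as the exceedance count rules out p < alpha.
    """
    max_exceed = int(np.floor(alpha * (n_perm + 1) - 1.0))  # largest count still < alpha
    exceed = 0
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        perms = rng.permuted(np.tile(x, (b, 1)), axis=1)
        stats = _detection_stat_batch(perms, min_width)
        exceed += int((stats >= stat_obs - 1e-12).sum())
        done += b
        if exceed > max_exceed:
            return 1.0  # cannot reach significance; exact value not needed
    return (1.0 + exceed) / (1.0 + n_perm)


def high_signal_threshold(n: int) -> float:
    """Analytic bound above which no permutation maximum plausibly reaches.

    The permutation null of the max standardized statistic concentrates
    near sqrt(2 log n); a +3 margin puts the threshold far into its tail.
    """
    return float(np.sqrt(2.0 * np.log(max(n, 2))) + 3.0)


def segment(x: np.ndarray, alpha: float = 0.02, min_width: int = 3,
            n_perm: int = 100, rng=None) -> list[int]:
    """Return sorted interior break indices of the fitted piecewise-constant model.

    A break at ``b`` separates ``x[..:b]`` from ``x[b:..]``.  Input
    shorter than ``2*min_width`` yields no breaks (single segment).
    """
    x = np.asarray(x, dtype=float)
    if rng is None:
        rng = np.random.default_rng()
    breaks: list[int] = []
    stack = [(0, x.size)]
    while stack:
        lo, hi = stack.pop()
        seg = x[lo:hi]
        idx, split_stat = _best_split(seg, min_width)
        if idx is None or split_stat <= 0.0:
            continue
        stat = _detection_stat(seg, min_width)
        if stat > high_signal_threshold(hi - lo):
            accept = True
        else:
            p = _permutation_p(seg, stat, n_perm, alpha, min_width, rng)
            accept = p < alpha
        if accept:
            breaks.append(lo + idx)
            stack.append((lo, lo + idx))
            stack.append((lo + idx, hi))
    breaks.sort()
    return _prune_equal_means(x, breaks)


def _prune_equal_means(x: np.ndarray, breaks: list[int]) -> list[int]:
    """Drop breaks whose flanking segment means are numerically equal."""
    if not breaks:
        return breaks
    scale = max(1.0, float(np.max(np.abs(x))))
    while True:
        bounds = [0] + breaks + [x.size]
        means = [x[bounds[i]:bounds[i + 1]].mean() for i in range(len(bounds) - 1)]
        keep = [b for i, b in enumerate(breaks)
                if abs(means[i + 1] - means[i]) > _EQUAL_MEAN_TOL * scale]
        if keep == breaks:
            return breaks
        breaks = keep
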