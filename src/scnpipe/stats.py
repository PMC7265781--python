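"""Feature-sharing statistics: one-sided Fisher's exact test and p-value combination.

For a pair of cells the features of one change-point sign form a 2x2
contingency table (present in both / A only / B only / neither).  The
one-sided Fisher p-value is the upper tail of the hypergeometric
distribution: with ``F`` features total, ``nA`` present in cell A and
``nB`` in cell B, the number shared under the null of independent
feature sets is ``X ~ Hypergeom(F, nA, nB)`` and ``p = P(X >= both)``.
"""

from __future__ import annotations

import numpy as np
from scipy import special
from scipy.stats import hypergeom

P_FLOOR = 1e-300
P_CEIL = 1.0 - 1e-16
LOG_P_FLOOR = float(np.log(P_FLOOR))

COMBINE_RULES = ("fisher", "stouffer")


def fisher_exact_greater(both, a_only, b_only, neither):
    """One-sided Fisher's exact p-value, alternative: odds ratio > 1.

    Accepts scalars or broadcastable arrays; returns the upper
    hypergeometric tail ``P(X >= both)``.
    """
    both = np.asarray(both)
    a_only = np.asarray(a_only)
    b_only = np.asarray(b_only)
    neither = np.asarray(neither)
    if np.any(both < 0) or np.any(a_only < 0) or np.any(b_only < 0) or np.any(neither < 0):
        raise ValueError("contingency counts must be non-negative")
    n_a = both + a_only
    n_b = both + b_only
    total = n_a + b_only + neither
    with np.errstate(invalid="ignore"):
        p = hypergeom.sf(both - 1, total, n_a, n_b)
    p = np.where(both <= 0, 1.0, p)  # P(X >= 0) = 1, also covers empty tables
    return np.clip(p, 0.0, 1.0)[()]


class FisherTailTable:
    """Precomputed upper-tail table for all 2x2 tables with a fixed feature count.

    ``tail[nA, nB, k] = P(X >= k)`` for ``X ~ Hypergeom(F, nA, nB)``.
    Row-constrained permutations of an incidence table never change the
    feature count ``F``, so one table serves every permutation replicate.
    Memory is ``(F+1)^3`` doubles; intended for F up to a few hundred.
    """

    def __init__(self, n_features: int):
        if n_features < 0:
            raise ValueError("n_features must be >= 0")
        self.n_features = int(n_features)
        f = self.n_features
        idx = np.arange(f + 1)
        n_a = idx[:, None, None]
        n_b = idx[None, :, None]
        k = idx[None, None, :]
        with np.errstate(invalid="ignore"):
            logpmf = (
                _log_comb(n_a, k)
                + _log_comb(f - n_a, n_b - k)
                - _log_comb(f, n_b)
            )
        pmf = np.exp(logpmf)
        invalid = (k > n_a) | (k > n_b) | (k < n_a + n_b - f)
        pmf[invalid] = 0.0
        tail = np.cumsum(pmf[:, :, ::-1], axis=2)[:, :, ::-1]
        self.tail = np.clip(tail, 0.0, 1.0)

    def p_greater(self, both, n_a, n_b):
        """``P(X >= both)`` looked up elementwise; arguments broadcast."""
        both, n_a, n_b = np.broadcast_arrays(both, n_a, n_b)
        return self.tail[n_a, n_b, both]


def _log_comb(n, k):
    return special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1)


def clamp_p(p):
    """Clamp p-values into [1e-300, 1 - 1e-16] before log/probit transforms."""
    return np.clip(p, P_FLOOR, P_CEIL)


def combine_pvalues(p_pos, p_neg, rule: str = "fisher"):
    """Combine the two per-sign p-values into one.

    fisher:   p_c = upper chi^2_4 tail at -2(ln p+ + ln p-)
    stouffer: p_c = 1 - Phi((z+ + z-)/sqrt(2)),  z = Phi^{-1}(1 - p)
    """
    if rule not in COMBINE_RULES:
        raise ValueError(f"unknown combine rule {rule!r}; use one of {COMBINE_RULES}")
    p_pos = clamp_p(np.asarray(p_pos, dtype=float))
    p_neg = clamp_p(np.asarray(p_neg, dtype=float))
    if rule == "fisher":
        stat = -2.0 * (np.log(p_pos) + np.log(p_neg))
        p_c = special.chdtrc(4, stat)
    else:
        z = -special.ndtri(p_pos) - special.ndtri(p_neg)
        p_c = special.ndtr(-z / np.sqrt(2.0))
    return np.clip(p_c, 0.0, 1.0)[()]


def log_dissimilarity(p_pos, p_neg, rule: str = "fisher"):
    """Pairwise dissimilarity ln(p_c), clamped to [ln(1e-300), 0]."""
    p_c = combine_pvalues(p_pos, p_neg, rule)
    return np.clip(np.log(clamp_p(p_c)), LOG_P_FLOOR, 0.0)[()]
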