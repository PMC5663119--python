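"""One-sided Wilcoxon signed-rank testing with zero-dropping.

Zeros are dropped before ranking (so the effective sample size of a
feature depends on its number of nonzero differences); absolute
differences are ranked with mid-ranks under ties.  For small effective
sizes the full null distribution of W+ over all 2^n sign assignments is
computed exactly by convolution; above the cutoff a normal approximation
with tie-corrected variance and a 0.5 continuity correction is used.
Both tail p-values, P(W+ <= w) and P(W+ >= w), are always returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["SignedRankResult", "NotTestableError", "signed_rank", "test_subset"]

DEFAULT_EXACT_CUTOFF = 20


class NotTestableError(ValueError):
    """All supplied differences are zero: the test is undefined."""


@dataclass
class SignedRankResult:
    n_input: int
    n_effective: int
    w_plus: float
    p_less: float  # P(W+ <= w) under H0: one-sided "shifted below zero"
    p_greater: float  # P(W+ >= w)
    method: str  # {"exact", "approx"}


def _exact_tail_probs(ranks2: np.ndarray, w2: int) -> tuple[float, float]:
    """Exact tails of 2*W+ for doubled integer ranks via convolution."""
    total = int(ranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    upper = 0
    for r in ranks2:
        r = int(r)
        upper += r
        dist[r : upper + 1] += dist[0 : upper - r + 1].copy()  # 0/1 use of each rank
    dist /= dist.sum()
    p_less = float(dist[: w2 + 1].sum())
    p_greater = float(dist[w2:].sum())
    return p_less, p_greater


def signed_rank(
    diffs,
    exact_cutoff: int = DEFAULT_EXACT_CUTOFF,
    continuity_correction: bool = True,
) -> SignedRankResult:
    """Wilcoxon signed-rank test of a vector of paired differences.

    Raises
    ------
    NotTestableError
        If no nonzero differences remain after zero-dropping.
    """
    d = np.asarray(diffs, dtype=float).ravel()
    n_input = d.size
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise NotTestableError("all differences are zero after zero-dropping")
    ranks = stats.rankdata(np.abs(d))  # mid-ranks under ties
    w_plus = float(ranks[d > 0].sum())

    if n <= exact_cutoff:
        # doubled ranks are integers even with mid-ranks
        ranks2 = np.rint(2.0 * ranks).astype(np.int64)
        w2 = int(np.rint(2.0 * w_plus))
        p_less, p_greater = _exact_tail_probs(ranks2, w2)
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= float(((tie_counts**3 - tie_counts) / 48.0).sum())
        sd = np.sqrt(var)
        cc = 0.5 if continuity_correction else 0.0
        p_less = float(stats.norm.cdf((w_plus - mu + cc) / sd))
        p_greater = float(stats.norm.sf((w_plus - mu - cc) / sd))
        p_less = min(max(p_less, 0.0), 1.0)
        p_greater = min(max(p_greater, 0.0), 1.0)
        method = "approx"

    return SignedRankResult(
        n_input=n_input,
        n_effective=n,
        w_plus=w_plus,
        p_less=p_less,
        p_greater=p_greater,
        method=method,
    )


def test_subset(
    diffs,
    mask,
    exact_cutoff: int = DEFAULT_EXACT_CUTOFF,
    continuity_correction: bool = True,
) -> SignedRankResult:
    """signed_rank on the masked subset of ``diffs``.

    ``n_input`` of the result is the number of included subjects (before
    zero-dropping).  An empty selection is not testable.
    """
    d = np.asarray(diffs, dtype=float).ravel()
    m = np.asarray(mask, dtype=bool).ravel()
    if m.shape != d.shape:
        raise ValueError("mask length must equal the differences length")
    sub = d[m]
    if sub.size == 0:
        raise NotTestableError("empty subset selection")
    return signed_rank(sub, exact_cutoff=exact_cutoff,
                       continuity_correction=continuity_correction)
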