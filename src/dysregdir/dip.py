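"""Hartigan's dip statistic and the Hommel-controlled multimodality screen.

The dip statistic of a sample is the smallest sup-norm distance between its
empirical distribution function and any unimodal distribution function
(a CDF convex up to a mode and concave after it).  It is computed with the
classic iterative greatest-convex-minorant / least-concave-majorant
algorithm on the sorted sample.  The value reported is the sup-norm dip
itself (e.g. 0.25 for a two-point sample), not a doubled convention.

P-values are calibrated by Monte-Carlo simulation against the standard
uniform null; the null table for a given (n, B, seed) is cached because a
site's features share a common sample size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from dysregdir.multiplicity import hommel_adjust

__all__ = [
    "DipResult",
    "MultimodalScreen",
    "dip_statistic",
    "dip_pvalue",
    "null_dip_table",
    "screen_multimodal",
]


def _dip_sorted(x: np.ndarray, mn: np.ndarray, mj: np.ndarray,
                gcm: np.ndarray, lcm: np.ndarray) -> float:
    """Dip of a sorted sample ``x[1..n]`` (index 0 unused); work arrays are
    int64 of length n + 2.  Internal distances are in counts; the returned
    value is divided by 2n."""
    n = x.shape[0] - 1
    if n < 2:
        return 0.0
    if x[n] == x[1]:
        return 0.0
    low = 1
    high = n
    dip = 1.0
    while True:
        # Greatest-convex-minorant predecessor pointers on [low, high].
        mn[low] = low
        for j in range(low + 1, high + 1):
            mn[j] = j - 1
            while True:
                mnj = mn[j]
                if mnj == low:
                    break
                mnmnj = mn[mnj]
                if ((x[j] - x[mnj]) * (mnj - mnmnj)
                        < (x[mnj] - x[mnmnj]) * (j - mnj)):
                    break
                mn[j] = mnmnj
        # Least-concave-majorant successor pointers on [low, high].
        mj[high] = high
        for k in range(high - 1, low - 1, -1):
            mj[k] = k + 1
            while True:
                mjk = mj[k]
                if mjk == high:
                    break
                mjmjk = mj[mjk]
                if ((x[k] - x[mjk]) * (mjk - mjmjk)
                        < (x[mjk] - x[mjmjk]) * (k - mjk)):
                    break
                mj[k] = mjmjk

        # Collect GCM change points from high down to low.
        gcm[1] = high
        i = 1
        while gcm[i] > low:
            gcm[i + 1] = mn[gcm[i]]
            i += 1
        l_gcm = i
        ig = i
        ix = i - 1
        # Collect LCM change points from low up to high.
        lcm[1] = low
        i = 1
        while lcm[i] < high:
            lcm[i + 1] = mj[lcm[i]]
            i += 1
        l_lcm = i
        ih = i
        iv = 2

        # Largest distance between the GCM and the LCM on [low, high].
        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            while True:
                gcmix = gcm[ix]
                lcmiv = lcm[iv]
                if gcmix > lcmiv:
                    # next change point is on the LCM
                    gcmi1 = gcm[ix + 1]
                    denom = x[gcmix] - x[gcmi1]
                    frac = (x[lcmiv] - x[gcmi1]) / denom if denom > 0 else 1.0
                    dx = (lcmiv - gcmi1 + 1) - frac * (gcmix - gcmi1)
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    # next change point is on the GCM
                    lcmiv1 = lcm[iv - 1]
                    denom = x[lcmiv] - x[lcmiv1]
                    frac = (x[gcmix] - x[lcmiv1]) / denom if denom > 0 else 1.0
                    dx = frac * (lcmiv - lcmiv1) - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                if ix < 1:
                    ix = 1
                if iv > l_lcm:
                    iv = l_lcm
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0

        if d < dip:
            break

        # Max deviation of the ECDF above the GCM on [low, gcm[ig]] ...
        dip_l = 0.0
        for j in range(ig, l_gcm):
            max_t = 1.0
            j_ = gcm[j + 1]
            jb = gcm[j]
            if jb - j_ > 1 and x[jb] != x[j_]:
                c = (jb - j_) / (x[jb] - x[j_])
                for jj in range(j_, jb + 1):
                    t = (jj - j_ + 1) - (x[jj] - x[j_]) * c
                    if max_t < t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t
        # ... and below the LCM on [lcm[ih], high].
        dip_u = 0.0
        for j in range(ih, l_lcm):
            max_t = 1.0
            j_ = lcm[j]
            jb = lcm[j + 1]
            if jb - j_ > 1 and x[jb] != x[j_]:
                c = (jb - j_) / (x[jb] - x[j_])
                for jj in range(j_, jb + 1):
                    t = (x[jj] - x[j_]) * c - (jj - j_ - 1)
                    if max_t < t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t

        dipnew = dip_l if dip_l > dip_u else dip_u
        if dip < dipnew:
            dip = dipnew
        if low == gcm[ig] and high == lcm[ih]:
            break
        low = gcm[ig]
        high = lcm[ih]

    return dip / (2.0 * n)


try:  # optional acceleration; the pure-Python kernel is the reference path
    from numba import njit as _njit

    _dip_sorted_fast = _njit(cache=False)(_dip_sorted)
except ImportError:  # pragma: no cover
    _dip_sorted_fast = _dip_sorted


def dip_statistic(values) -> float:
    """Hartigan's dip statistic of a sample (n >= 2; ties permitted)."""
    x = np.asarray(values, dtype=float).ravel()
    n = x.size
    if n < 2:
        raise ValueError("dip statistic requires at least 2 observations")
    if not np.isfinite(x).all():
        raise ValueError("dip statistic requires finite values")
    xs = np.empty(n + 1)
    xs[1:] = np.sort(x)
    work = np.empty(n + 2, dtype=np.int64)
    return float(
        _dip_sorted_fast(xs, work.copy(), work.copy(), work.copy(), work.copy())
    )


@dataclass
class DipResult:
    """A dip statistic with its Monte-Carlo p-value."""

    n: int
    dip: float
    p_value: float
    mc_reps: int
    seed: int


@lru_cache(maxsize=8)
def null_dip_table(n: int, B: int, seed: int) -> np.ndarray:
    """B dip statistics of uniform(0, 1) samples of size n (sorted output).

    Cached: all features of a site share n, so the screen reuses one table.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    xs = np.empty(n + 1)
    out = np.empty(B)
    work = np.empty(n + 2, dtype=np.int64)
    w1, w2, w3, w4 = work.copy(), work.copy(), work.copy(), work.copy()
    for b in range(B):
        xs[1:] = np.sort(rng.random(n))
        out[b] = _dip_sorted_fast(xs, w1, w2, w3, w4)
    out.sort()
    out.flags.writeable = False
    return out


def dip_pvalue(dip: float, n: int, B: int = 10000, seed: int = 0) -> DipResult:
    """Add-one Monte-Carlo p-value of an observed dip against the uniform null.

    p = (1 + #{null replicates with dip >= observed}) / (B + 1).
    """
    table = null_dip_table(n, B, seed)
    n_ge = int(B - np.searchsorted(table, dip, side="left"))
    return DipResult(n=n, dip=float(dip), p_value=(1 + n_ge) / (B + 1),
                     mc_reps=B, seed=seed)


@dataclass
class MultimodalScreen:
    """Per-site multimodality screen with Hommel FWER control."""

    site: str
    features: list[str]
    dips: np.ndarray
    feature_pvalues: np.ndarray
    hommel_adjusted: np.ndarray
    alpha: float
    mc_reps: int
    seed: int
    n: int
    selected: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.selected = [
            f for f, p in zip(self.features, self.hommel_adjusted) if p < self.alpha
        ]

    def to_frame(self):
        import pandas as pd

        sel = set(self.selected)
        return pd.DataFrame(
            {
                "site": self.site,
                "feature": self.features,
                "dip": self.dips,
                "p": self.feature_pvalues,
                "p_hommel": self.hommel_adjusted,
                "selected": [f in sel for f in self.features],
            }
        )

    def write(self, path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)


def screen_multimodal(diffs, B: int = 10000, alpha: float = 0.05,
                      seed: int = 0) -> MultimodalScreen:
    """Screen a site's difference matrix for multimodal features.

    One dip p-value per feature (zeros included), Hommel adjustment across
    the site's features, selection at adjusted p strictly below ``alpha``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    mat = diffs.diffs
    n = mat.shape[1]
    table = null_dip_table(n, B, seed)
    dips = np.array([dip_statistic(row) for row in mat])
    n_ge = B - np.searchsorted(table, dips, side="left")
    pvals = (1 + n_ge) / (B + 1)
    adjusted = hommel_adjust(pvals)
    return MultimodalScreen(
        site=diffs.site,
        features=list(diffs.features),
        dips=dips,
        feature_pvalues=pvals,
        hommel_adjusted=adjusted,
        alpha=alpha,
        mc_reps=B,
        seed=seed,
        n=n,
    )
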