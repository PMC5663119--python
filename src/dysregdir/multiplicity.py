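"""Multiple-testing adjustments: Hommel FWER, Benjamini-Hochberg FDR, and
the fold/unfold construction of FDR-adjusted one-sided p-values.

The one-sided construction carries a (lower-tail, upper-tail) p-value pair
per test, folds it to a two-sided value p* = min(2 min(pl, pu), 1) with a
recorded direction, applies BH across the family, and unfolds the adjusted
value q back to a single number: q/2 for the lower tail, 1 - q/2 for the
upper tail, 0.5 on an exact tie.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = ["OneSidedAdjusted", "hommel_adjust", "bh_adjust", "adjust_one_sided"]


def _check_pvector(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a non-empty 1-d vector")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def hommel_adjust(p) -> np.ndarray:
    """Hommel adjusted p-values (closed testing with Simes local tests).

    The adjusted value for hypothesis i is the maximum over all subsets S
    containing i of the Simes p-value of S; this function computes the
    standard O(m^2) shortcut.
    """
    p = _check_pvector(p)
    m = p.size
    if m == 1:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ps = p[order]
    i = np.arange(1, m + 1)
    q = np.full(m, min(m * ps[0] / 1, *(m * ps / i)))
    pa = q.copy()
    for mm in range(m - 1, 1, -1):
        # indices 0 .. m-mm (i1) and m-mm+1 .. m-1 (i2), as in the classic
        # sequential shortcut
        i2 = np.arange(m - mm + 1, m)
        q1 = np.min(mm * ps[i2] / np.arange(2, mm + 1))
        i1 = np.arange(0, m - mm + 1)
        q[i1] = np.minimum(mm * ps[i1], q1)
        q[i2] = q[m - mm]
        pa = np.maximum(pa, q)
    pa = np.maximum(pa, ps)
    out = np.empty(m)
    out[order] = np.minimum(pa, 1.0)
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    q_(i) = min_{j >= i} m p_(j) / j, capped at 1, in the input order.
    """
    p = _check_pvector(p)
    m = p.size
    order = np.argsort(p, kind="stable")
    ps = p[order]
    scaled = m * ps / np.arange(1, m + 1)
    q = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def simes(p) -> float:
    """Simes combination p-value of a hypothesis subset: min_i m p_(i) / i."""
    p = _check_pvector(p)
    ps = np.sort(p)
    m = ps.size
    return float(np.min(m * ps / np.arange(1, m + 1)))


@dataclass
class OneSidedAdjusted:
    """A single FDR-adjusted one-sided value for a two-tailed test pair."""

    direction: str  # {"down", "up", "none"}
    q_two_sided: float  # BH-adjusted folded p*
    p_one_adj: float  # q/2 (down), 1 - q/2 (up), or 0.5 (none)


def fold_two_sided(p_less: float, p_greater: float) -> tuple[float, str]:
    """Fold a tail pair into p* = min(2 min(pl, pg), 1) and its direction."""
    if p_less < p_greater:
        return min(2.0 * p_less, 1.0), "down"
    if p_greater < p_less:
        return min(2.0 * p_greater, 1.0), "up"
    return min(2.0 * p_less, 1.0), "none"


def adjust_one_sided(
    results: Sequence[tuple[float, float]], family_id: str = ""
) -> list[OneSidedAdjusted]:
    """BH-adjust a family of (p_less, p_greater) pairs into one-sided values.

    The fold -> BH -> unfold construction makes classification thresholds
    alpha/2 and 1 - alpha/2 on the one-sided scale exactly equivalent to BH
    rejection at level alpha on the folded two-sided values.
    """
    if len(results) == 0:
        raise ValueError(f"empty family {family_id!r}")
    folds = np.empty(len(results))
    directions = []
    for i, (pl, pg) in enumerate(results):
        for v in (pl, pg):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"p-value {v} outside [0, 1] in family {family_id!r}")
        folds[i], d = fold_two_sided(pl, pg)
        directions.append(d)
    q = bh_adjust(folds)
    out = []
    for qi, d in zip(q, directions):
        if d == "down":
            p1 = qi / 2.0
        elif d == "up":
            p1 = 1.0 - qi / 2.0
        else:
            p1 = 0.5
        out.append(OneSidedAdjusted(direction=d, q_two_sided=float(qi), p_one_adj=float(p1)))
    return out
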