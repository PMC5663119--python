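"""Independent brute-force oracles used to validate the fast implementations.

These deliberately avoid the algorithms used by the package:

* ``dip_oracle`` minimizes the sup-norm distance to piecewise-linear
  unimodal distribution functions with knots at the data points, solving
  one linear program per candidate mode position.
* ``signed_rank_oracle`` enumerates all 2^n sign assignments.
* ``hommel_oracle`` evaluates the closed-testing definition over all
  subsets with Simes local tests.
* ``bh_oracle`` is the quadratic-time step-up definition.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog
from scipy.stats import rankdata


# ---------------------------------------------------------------------------
# Dip oracle


def _solve_mode_lp(F, z, mode_kind, pos, gap_branch=None):
    """Min sup-distance for one candidate mode position.

    F[j] = ECDF value at z[j] (right limits), z strictly increasing.
    mode_kind is "knot" (jump allowed at z[pos]) or "gap" (mode strictly
    between z[pos-1] and z[pos]; pos = 0 means before z[0], pos = m after
    z[m-1]).

    For an interior gap the segment containing the mode must admit a
    convex rise (slope >= preceding slope), a jump, and a concave rise
    (slope >= following slope) within its endpoint values: with the mode
    position free this reduces to min(s_before, s_after) * dz <= delta_g,
    a disjunction solved as two sub-LPs selected by ``gap_branch``
    ("before" / "after").
    """
    m = len(z)
    span = max(z[-1] - z[0], 1.0)
    big = 1e6 * span
    z0, z1 = z[0] - big, z[-1] + big  # virtual anchors where G = 0 and 1

    # variables: g_0..g_{m-1}, h (left value at knot mode; always present,
    # tied to its segment endpoint when unused), d
    nv = m + 2
    ih, idd = m, m + 1

    c = np.zeros(nv)
    c[idd] = 1.0
    A_ub, b_ub = [], []
    A_eq, b_eq = [], []

    def row():
        return np.zeros(nv)

    # left value at each knot j (index into variables): h at a knot mode,
    # else g_j itself
    def leftvar(j):
        return ih if (mode_kind == "knot" and j == pos) else j

    # band constraints: |F_j - g_j| <= d and |F_{j-1} - leftval_j| <= d
    for j in range(m):
        r = row(); r[j] = 1.0; r[idd] = -1.0
        A_ub.append(r); b_ub.append(F[j])          # g_j - d <= F_j
        r = row(); r[j] = -1.0; r[idd] = -1.0
        A_ub.append(r); b_ub.append(-F[j])         # -g_j - d <= -F_j
        prev = F[j - 1] if j > 0 else 0.0
        lv = leftvar(j)
        r = row(); r[lv] = 1.0; r[idd] = -1.0
        A_ub.append(r); b_ub.append(prev)
        r = row(); r[lv] = -1.0; r[idd] = -1.0
        A_ub.append(r); b_ub.append(-prev)
    # sup on [z_{m-1}, infinity): |1 - g_{m-1}| <= d
    r = row(); r[m - 1] = -1.0; r[idd] = -1.0
    A_ub.append(r); b_ub.append(-1.0)

    # monotonicity (g nondecreasing, h between its neighbours)
    for j in range(m - 1):
        r = row(); r[j] = 1.0; r[leftvar(j + 1)] = -1.0
        A_ub.append(r); b_ub.append(0.0)           # g_j <= leftval_{j+1}
    if mode_kind == "knot":
        r = row(); r[ih] = 1.0; r[pos] = -1.0
        A_ub.append(r); b_ub.append(0.0)           # h <= g_pos
        if pos == 0:
            r = row(); r[ih] = -1.0
            A_ub.append(r); b_ub.append(0.0)       # h >= 0
    else:
        # tie the unused jump variable down
        r = row(); r[ih] = 1.0
        A_eq.append(r); b_eq.append(0.0)

    # segment slopes, as affine expressions slope_i = (right_i - left_i)/dz.
    # Virtual segment "start": (z0, 0) -> (z[0], leftval_0);
    # virtual segment "end": (z[m-1], g_{m-1}) -> (z1, 1).
    def slope_expr(i):
        """(coeff vector, constant) of slope of segment i; i in [-1, m-1]."""
        r = row()
        if i == -1:
            r[leftvar(0)] = 1.0 / (z[0] - z0)
            return r, 0.0
        if i == m - 1:
            r[m - 1] = -1.0 / (z1 - z[-1])
            return r, 1.0 / (z1 - z[-1])
        dz = z[i + 1] - z[i]
        r[leftvar(i + 1)] = 1.0 / dz
        r[i] -= 1.0 / dz
        return r, 0.0

    # convex region: segments -1 .. conv_end; concave: conc_start .. m-1
    if mode_kind == "knot":
        conv_end = pos - 1    # last segment strictly below the mode knot
        conc_start = pos      # first segment at/after the mode knot
    else:
        conv_end = pos - 1    # segments fully below the gap
        conc_start = pos      # segments fully above the gap; segment pos-? ...
        # mode inside gap (z[pos-1], z[pos]): segment index pos-1 is free
        conv_end = pos - 2
        conc_start = pos

    convex = list(range(-1, conv_end + 1))
    concave = list(range(conc_start, m))
    for a, b in zip(convex, convex[1:]):   # slope_a <= slope_b
        ra, ca = slope_expr(a)
        rb, cb = slope_expr(b)
        A_ub.append(ra - rb); b_ub.append(cb - ca)
    for a, b in zip(concave, concave[1:]):  # slope_a >= slope_b
        ra, ca = slope_expr(a)
        rb, cb = slope_expr(b)
        A_ub.append(rb - ra); b_ub.append(ca - cb)

    if mode_kind == "gap" and 1 <= pos <= m - 1:
        # coupling across the mode-containing segment (z[pos-1], z[pos])
        dz = z[pos] - z[pos - 1]
        seg = -1 if pos == 1 else pos - 2
        rs, cs = slope_expr(seg if gap_branch == "before" else pos)
        r = rs * dz
        r[pos] -= 1.0
        r[pos - 1] += 1.0
        A_ub.append(r); b_ub.append(-cs * dz)  # s*dz - (g_pos - g_{pos-1}) <= 0

    bounds = [(0.0, 1.0)] * m + [(0.0, 1.0), (0.0, 1.0)]
    res = linprog(
        c, A_ub=np.array(A_ub), b_ub=np.array(b_ub),
        A_eq=np.array(A_eq) if A_eq else None,
        b_eq=np.array(b_eq) if b_eq else None,
        bounds=bounds, method="highs",
    )
    return res.fun if res.status == 0 else np.inf


def dip_oracle(values) -> float:
    """Exhaustive-mode LP minimization of sup|F_n - G| over unimodal G."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    z, counts = np.unique(x, return_counts=True)
    F = np.cumsum(counts) / n
    m = len(z)
    if m == 1:
        return 0.0
    best = np.inf
    for pos in range(m):
        best = min(best, _solve_mode_lp(F, z, "knot", pos))
    for pos in (0, m):
        best = min(best, _solve_mode_lp(F, z, "gap", pos))
    for pos in range(1, m):
        for branch in ("before", "after"):
            best = min(best, _solve_mode_lp(F, z, "gap", pos, gap_branch=branch))
    return best


# ---------------------------------------------------------------------------
# Signed-rank oracle


def signed_rank_oracle(diffs):
    """Exact (p_less, p_greater, w_plus) by enumerating all sign patterns."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("no nonzero differences")
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n_le = n_ge = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w <= w_obs + 1e-9:
            n_le += 1
        if w >= w_obs - 1e-9:
            n_ge += 1
    total = 2**n
    return n_le / total, n_ge / total, w_obs


# ---------------------------------------------------------------------------
# Multiplicity oracles


def simes_oracle(p):
    ps = np.sort(np.asarray(p, dtype=float))
    k = len(ps)
    return (k * ps / np.arange(1, k + 1)).min()


def hommel_oracle(p):
    """Closed-testing adjusted p-values with Simes local tests.

    adjusted_i = max over subsets S containing i of Simes(S).
    """
    p = np.asarray(p, dtype=float)
    m = len(p)
    adjusted = np.zeros(m)
    idx = list(range(m))
    for r in range(1, m + 1):
        for subset in itertools.combinations(idx, r):
            sp = simes_oracle(p[list(subset)])
            for i in subset:
                adjusted[i] = max(adjusted[i], sp)
    return np.minimum(adjusted, 1.0)


def bh_oracle(p):
    """Quadratic-time direct evaluation of the BH step-up definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    adjusted = np.empty(m)
    for i in range(m):
        rank_i = np.sum(p <= p[i])  # handles ties like average of sorted walk
        # direct definition: q_i = min over j with p_j >= p_i of m*p_j/rank_j
        candidates = []
        for j in range(m):
            if p[j] >= p[i]:
                rank_j = np.sum(p <= p[j])
                candidates.append(m * p[j] / rank_j)
        adjusted[i] = min(1.0, min(candidates))
    return adjusted
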