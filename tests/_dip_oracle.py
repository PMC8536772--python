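"""Brute-force dip oracle: direct minimization over unimodal CDFs.

For each candidate mode block the best unimodal CDF within sup-distance d
of the empirical CDF is sought by linear programming: G is piecewise
linear between the unique sample values with an optional atom (jump) at
the mode, convex before it (on pre-jump values) and concave after it,
nondecreasing, pinned inside the tube [F - d, F + d] at every step corner.
The dip is the smallest feasible d over all mode positions. Completely
independent of the hull-based production implementation.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


def dip_lp(values: np.ndarray) -> float:
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    xu, first = np.unique(v, return_index=True)
    counts = np.diff(np.append(first, n))
    lo = first / n                 # ECDF left limit at each unique value
    up = (first + counts) / n      # ECDF value at each unique value
    if len(xu) == 1:
        return 0.0
    best = np.inf
    for mode in range(len(xu)):
        d = _dip_lp_mode(xu, lo, up, mode)
        if d is not None:
            best = min(best, d)
    return best


def _dip_lp_mode(xu, lo, up, m):
    """Min d for a unimodal CDF with mode (and possible atom) at xu[m].

    Variables: G_0..G_{nb-1} (post-jump values), J (atom at the mode, so
    the pre-jump value there is G_m - J), d.
    """
    nb = len(xu)
    nv = nb + 2
    iJ, iD = nb, nb + 1
    A_ub, b_ub = [], []

    def row(pairs, rhs):
        r = np.zeros(nv)
        for idx, coef in pairs:
            r[idx] += coef
        A_ub.append(r)
        b_ub.append(rhs)

    def vc(k):  # pre-jump value coefficients
        return [(k, 1.0), (iJ, -1.0)] if k == m else [(k, 1.0)]

    for k in range(nb):
        if k == m:
            row([(k, -1.0), (iD, -1.0)], -up[k])              # G_m >= up - d
            row([(k, 1.0), (iD, -1.0)], up[k])                # G_m <= up + d
            row([(k, 1.0), (iJ, -1.0), (iD, -1.0)], lo[k])    # v_m <= lo + d
            row([(k, -1.0), (iJ, 1.0), (iD, -1.0)], -lo[k])   # v_m >= lo - d
        else:
            row([(k, -1.0), (iD, -1.0)], -up[k])
            row([(k, 1.0), (iD, -1.0)], lo[k])

    # monotonicity of pre-jump values up to the mode, post-jump beyond
    for k in range(nb - 1):
        if k + 1 <= m:
            row([(i, c) for i, c in vc(k)]
                + [(i, -c) for i, c in vc(k + 1)], 0.0)
        if k >= m:
            row([(k, 1.0), (k + 1, -1.0)], 0.0)

    # curvature: second difference >= 0 (convex, pre-jump values) before
    # the mode, <= 0 (concave, post-jump values) after it
    dx = np.diff(xu)
    for k in range(1, nb - 1):
        if k + 1 <= m:
            trip = []
            for i, c in vc(k - 1):
                trip.append((i, c * dx[k]))
            for i, c in vc(k):
                trip.append((i, -c * (dx[k] + dx[k - 1])))
            for i, c in vc(k + 1):
                trip.append((i, c * dx[k - 1]))
            row([(i, -c) for i, c in trip], 0.0)
        elif k - 1 >= m:
            row([(k - 1, dx[k]), (k, -(dx[k] + dx[k - 1])),
                 (k + 1, dx[k - 1])], 0.0)

    bounds = [(0.0, 1.0)] * nb + [(0.0, 1.0), (0.0, None)]
    row([(nb - 1, -1.0), (iD, -1.0)], -1.0)   # right tail reaches 1
    if m == 0:
        row([(iJ, 1.0), (0, -1.0)], 0.0)      # pre-jump value stays >= 0

    c = np.zeros(nv)
    c[iD] = 1.0
    res = linprog(c, A_ub=np.array(A_ub), b_ub=np.array(b_ub),
                  bounds=bounds, method="highs")
    return float(res.x[iD]) if res.success else None
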