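"""Definitional oracle for the dip statistic, for cross-checking tests.

Computes min over unimodal CDFs G of sup_x |F_n(x) - G(x)| by direct
enumeration: for every possible mode position (an atom at a data value, or
a mode strictly inside a gap between adjacent values) one linear program
over the knot values of a piecewise-linear unimodal CDF is solved, with no
pruning, no hull shortcuts and no shared code with the package's
implementation beyond the problem statement itself.  Exhaustive and slow:
use on small samples only.
"""

import numpy as np
from scipy.optimize import linprog


def dip_oracle(x) -> float:
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    v, counts = np.unique(x, return_counts=True)
    h = np.cumsum(counts) / n
    k = v.size
    if k == 1:
        return 1.0 / (2 * n)
    p = np.concatenate(([0.0], h[:-1]))  # ECDF left limits
    dv = np.diff(v)
    best = np.inf

    def solve(atom: bool, m: int) -> float:
        nv = k + (2 if atom else 1)
        ti = nv - 1
        li = k if atom else None
        c = np.zeros(nv)
        c[ti] = 1.0
        A, b = [], []

        def le(coefs, rhs):
            row = np.zeros(nv)
            for i, val in coefs:
                row[i] += val
            A.append(row)
            b.append(rhs)

        le([(0, -1.0)], 0.0)
        le([(k - 1, 1.0)], 1.0)
        for j in range(k - 1):
            le([(j, 1.0), (j + 1, -1.0)], 0.0)
        for j in range(k):
            le([(j, 1.0), (ti, -1.0)], h[j])
            le([(j, -1.0), (ti, -1.0)], -h[j])
            tgt = li if (atom and j == m) else j
            le([(tgt, 1.0), (ti, -1.0)], p[j])
            le([(tgt, -1.0), (ti, -1.0)], -p[j])
        if atom:
            le([(li, 1.0), (m, -1.0)], 0.0)
            if m > 0:
                le([(m - 1, 1.0), (li, -1.0)], 0.0)
        conv = list(range(0, m)) if atom else list(range(0, m - 1))
        conc = list(range(m, k - 1))

        def seg(j):
            hi = j + 1
            if atom and hi == m:
                hi = li
            return j, hi, dv[j]

        for segs, sign in ((conv, 1.0), (conc, -1.0)):
            for a, bseg in zip(segs[:-1], segs[1:]):
                lo1, hi1, d1 = seg(a)
                lo2, hi2, d2 = seg(bseg)
                le([(hi1, sign / d1), (lo1, -sign / d1),
                    (hi2, -sign / d2), (lo2, sign / d2)], 0.0)
        res = linprog(c, A_ub=np.array(A), b_ub=np.array(b),
                      bounds=[(None, None)] * nv, method="highs")
        return res.fun if res.status == 0 else np.inf

    for m in range(k):
        best = min(best, solve(True, m))
    for g in range(k + 1):
        best = min(best, solve(False, g))
    return max(best, 1.0 / (2 * n))
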