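"""Hartigan's dip statistic for unimodality.

The dip of a sample is the smallest sup-norm distance between its empirical
CDF and any unimodal CDF (a distribution function that is convex up to some
mode and concave after it, with at most one atom, located at the mode).
Large values indicate multimodality; the minimum attainable value for a
sample of size n is 1/(2n) and the maximum is 1/4.

Computation follows the greatest-convex-minorant / least-concave-majorant
construction on the sorted sample: for every candidate mode position (an
atom at a distinct data value, or a mode strictly between two adjacent
values) the best-fitting unimodal CDF splits into a convex branch fitted
from the left and a concave branch fitted from the right.  The GCM/LCM of
the appropriate ECDF envelopes give, for each candidate, a lower bound on
the achievable sup distance that is tight whenever the two branches join
monotonically without interacting.  Candidates are then resolved exactly,
in order of increasing bound, by a small linear program per candidate
(knot values of a piecewise-linear unimodal CDF), stopping as soon as the
running minimum drops below the next bound.  The result is exact, not an
approximation, and fully deterministic.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog

__all__ = ["dip_statistic"]


def _ecdf_distinct(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Distinct sorted values and ECDF heights (right-continuous)."""
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    v, counts = np.unique(x, return_counts=True)
    h = np.cumsum(counts) / n
    return v, h, n


def _prefix_gcm_devmax(v: np.ndarray, p: np.ndarray, h: np.ndarray):
    """Incremental greatest convex minorant of the points (v_j, p_j).

    Returns two arrays over j = 0..k-1:

    * ``incl[j]`` = max_{i <= j-1} h_i - GCM_{0..j}(v_i)   (hull includes j)
    * ``excl[j]`` = max_{i <= j-1} h_i - GCM_{0..j-1}(v_i) (hull stops at j-1)
    """
    k = v.size
    incl = np.zeros(k)
    excl = np.zeros(k)
    hull: list[int] = []
    prev_full = 0.0  # max_{i<=j-1}(h_i - GCM_{0..j-1}(v_i)) including i=j-1
    for j in range(k):
        excl[j] = prev_full
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            if (p[i2] - p[i1]) * (v[j] - v[i1]) >= (p[j] - p[i1]) * (v[i2] - v[i1]):
                hull.pop()
            else:
                break
        hull.append(j)
        if j == 0:
            incl[j] = 0.0
            prev_full = h[0] - p[0]
            continue
        hv = v[hull]
        hp = p[hull]
        fitted = np.interp(v[: j + 1], hv, hp)
        devs = h[: j + 1] - fitted
        incl[j] = devs[:j].max()
        prev_full = devs.max()
    return incl, excl


def _case_bounds(v: np.ndarray, h: np.ndarray, p: np.ndarray):
    """Lower bound on the sup distance for every candidate mode position.

    Candidate ``("atom", m)`` puts the mode (and the CDF's only jump) at
    knot m; ``("gap", g)`` puts it strictly inside (v_{g-1}, v_g), with
    g = 0 meaning a fully concave CDF and g = k fully convex.
    """
    k = v.size
    left_incl, left_excl = _prefix_gcm_devmax(v, p, h)
    # Mirror for the concave side: LCM of h over suffixes == reflected GCM.
    vr = -v[::-1]
    pr = 1.0 - h[::-1]          # reflected "left limits"
    hr = 1.0 - np.concatenate(([0.0], h[:-1]))[::-1]
    right_incl_r, right_excl_r = _prefix_gcm_devmax(vr, pr, hr)
    right_incl = right_incl_r[::-1]
    right_excl = right_excl_r[::-1]

    cases = []
    for m in range(k):
        cases.append((max(left_incl[m], right_incl[m]) / 2.0, "atom", m))
    for g in range(k + 1):
        if g < k:
            left = left_excl[g]
        else:
            # convex hull over all knots, deviations over all of them
            left = _full_side(v, p, h)
        right = right_excl[g - 1] if g > 0 else _full_side(vr, pr, hr)
        cases.append((max(left, right) / 2.0, "gap", g))
    return cases


def _full_side(v: np.ndarray, p: np.ndarray, h: np.ndarray) -> float:
    """max_i h_i - GCM_{all}(v_i): the fully convex (one-sided) deviation."""
    hull = [0]
    for j in range(1, v.size):
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            if (p[i2] - p[i1]) * (v[j] - v[i1]) >= (p[j] - p[i1]) * (v[i2] - v[i1]):
                hull.pop()
            else:
                break
        hull.append(j)
    fitted = np.interp(v, v[hull], p[hull])
    return float(np.max(h - fitted))


def _solve_case(v, h, p, case, m) -> float:
    """Exact minimal sup distance for one candidate mode position (an LP).

    Variables are the knot values G_0..G_{k-1} of a piecewise-linear
    unimodal CDF (plus a separate left-limit variable when the mode carries
    an atom at a knot) and the sup distance t.
    """
    k = v.size
    dv = np.diff(v)
    atom = case == "atom"
    nv = k + (2 if atom else 1)
    ti = nv - 1
    li = k if atom else None
    c = np.zeros(nv)
    c[ti] = 1.0
    rows: list[np.ndarray] = []
    rhs: list[float] = []

    def le(coefs, b):
        row = np.zeros(nv)
        for i, val in coefs:
            row[i] += val
        rows.append(row)
        rhs.append(b)

    le([(0, -1.0)], 0.0)          # G_0 >= 0
    le([(k - 1, 1.0)], 1.0)       # G_{k-1} <= 1
    for j in range(k - 1):
        le([(j, 1.0), (j + 1, -1.0)], 0.0)  # monotone
    for j in range(k):
        le([(j, 1.0), (ti, -1.0)], h[j])     # |h_j - G_j| <= t
        le([(j, -1.0), (ti, -1.0)], -h[j])
        tgt = li if (atom and j == m) else j  # left limit at v_j
        le([(tgt, 1.0), (ti, -1.0)], p[j])
        le([(tgt, -1.0), (ti, -1.0)], -p[j])
    if atom:
        le([(li, 1.0), (m, -1.0)], 0.0)       # L <= G_m (jump up at mode)
        if m > 0:
            le([(m - 1, 1.0), (li, -1.0)], 0.0)

    if atom:
        conv_segs = list(range(0, m))
        conc_segs = list(range(m, k - 1))
    else:
        conv_segs = list(range(0, m - 1))
        conc_segs = list(range(m, k - 1))

    def seg(j):
        hi = j + 1
        if atom and hi == m:
            hi = li
        return j, hi, dv[j]

    for segs, sign in ((conv_segs, 1.0), (conc_segs, -1.0)):
        for a, b in zip(segs[:-1], segs[1:]):
            lo1, hi1, d1 = seg(a)
            lo2, hi2, d2 = seg(b)
            le([(hi1, sign / d1), (lo1, -sign / d1),
                (hi2, -sign / d2), (lo2, sign / d2)], 0.0)

    res = linprog(c, A_ub=np.vstack(rows), b_ub=np.array(rhs),
                  bounds=[(None, None)] * nv, method="highs")
    if res.status != 0:  # pragma: no cover - LP is always feasible
        return np.inf
    return float(res.fun)


def dip_statistic(sample) -> float:
    """Hartigan's dip statistic D of a sample.

    Parameters
    ----------
    sample : array-like
        At least 4 finite values; ties allowed.

    Returns
    -------
    float
        D in [1/(2n), 1/4].  An all-equal sample returns the floor 1/(2n).
    """
    x = np.asarray(sample, dtype=float).ravel()
    if x.size < 4:
        raise ValueError("dip_statistic requires at least 4 observations")
    if not np.all(np.isfinite(x)):
        raise ValueError("dip_statistic requires finite values")
    v, h, n = _ecdf_distinct(x)
    floor = 1.0 / (2 * n)
    if v.size == 1:
        return floor
    p = np.concatenate(([0.0], h[:-1]))
    cases = sorted(_case_bounds(v, h, p))
    best = np.inf
    for lb, case, m in cases:
        if best <= lb + 1e-12:
            break
        best = min(best, _solve_case(v, h, p, case, m))
    return float(max(best, floor))
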