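"""Broken-line (segmented) regression with unknown breakpoints.

The core of threshold detection along a stressor gradient: a piecewise
linear mean with ``n_breakpoints`` unknown change points psi, estimated by
iterative linearization.  At each iteration the working model

    y ~ 1 + x + sum_j [ beta_j * U_j + gamma_j * V_j ]

is fitted by least squares, where ``U_j = (x - psi_j) * 1[x > psi_j]`` is
the slope-change basis and ``V_j = -1[x > psi_j]`` carries the gap
parameter gamma_j; the update ``psi_j <- psi_j + gamma_j / beta_j`` drives
the gap to zero.  At convergence the delta-method standard error of the
breakpoint is ``SE(gamma_j) / |beta_j|``.

A ``SegmentedModel`` / ``SegmentedResults`` pair exposes the fit the way
statsmodels models do; :func:`fit_segmented` is the functional shortcut.
:func:`brute_force_breakpoints` is an exhaustive-search estimator for small
problems, used as an independent check on the iterative fit.  The module
also houses the Davies test for the existence of a slope change (the
breakpoint is a nuisance parameter absent under the null) and Dixon's
Q-test for single-outlier screening in small samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

__all__ = [
    "SegmentedModel",
    "SegmentedResults",
    "DaviesResult",
    "DixonResult",
    "fit_segmented",
    "brute_force_breakpoints",
    "davies_test",
    "dixon_outlier_test",
]


# --------------------------------------------------------------------------
# least-squares helpers

def _design(x: np.ndarray, psi: np.ndarray, gaps: bool) -> np.ndarray:
    cols = [np.ones_like(x), x]
    for p in psi:
        cols.append(np.where(x > p, x - p, 0.0))
    if gaps:
        for p in psi:
            cols.append(np.where(x > p, -1.0, 0.0))
    return np.column_stack(cols)


def _ols(X: np.ndarray, y: np.ndarray):
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    return beta, rss, rank


@dataclass
class SegmentedResults:
    """Fit of a piecewise-linear mean with estimated breakpoints.

    Attributes
    ----------
    psi : ndarray
        Estimated breakpoint locations, strictly increasing.
    intercept, slope : float
        Intercept and slope of the leftmost segment.
    slope_changes : ndarray
        Per-breakpoint change in slope (beta_U terms).
    psi_se : ndarray
        Delta-method standard errors of the breakpoints.
    psi_ci : ndarray, shape (n_breakpoints, 2)
        95% confidence intervals for the breakpoints.
    rss : float
        Residual sum of squares of the final fit (breakpoints fixed).
    converged : bool
        False when the gap parameters had not vanished at ``max_iter``.
    """

    psi: np.ndarray
    intercept: float
    slope: float
    slope_changes: np.ndarray
    psi_se: np.ndarray
    psi_ci: np.ndarray
    rss: float
    fittedvalues: np.ndarray
    converged: bool
    n_iter: int
    nobs: int
    model: "SegmentedModel | None" = field(default=None, repr=False)

    @property
    def n_breakpoints(self) -> int:
        return len(self.psi)

    @property
    def n_params(self) -> int:
        # intercept + base slope + one slope change and one location per break
        return 2 + 2 * self.n_breakpoints

    def segment_slopes(self) -> np.ndarray:
        """Slope of each segment, left to right."""
        return self.slope + np.concatenate(([0.0], np.cumsum(self.slope_changes)))

    def bic(self) -> float:
        n = self.nobs
        rss = max(self.rss, np.finfo(float).tiny)
        return n * np.log(rss / n) + self.n_params * np.log(n)

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = self.intercept + self.slope * x
        for p, b in zip(self.psi, self.slope_changes):
            y = y + b * np.where(x > p, x - p, 0.0)
        return y

    def summary(self) -> str:
        lines = [
            "Segmented regression results",
            "============================",
            f"nobs: {self.nobs}   breakpoints: {self.n_breakpoints}   "
            f"converged: {self.converged} ({self.n_iter} iter)",
            f"RSS: {self.rss:.6g}   BIC: {self.bic():.6g}",
            f"intercept: {self.intercept:.6g}   base slope: {self.slope:.6g}",
        ]
        for j, (p, se, (lo, hi), b) in enumerate(
            zip(self.psi, self.psi_se, self.psi_ci, self.slope_changes)
        ):
            lines.append(
                f"psi_{j + 1}: {p:.4f}  SE {se:.4f}  95% CI [{lo:.4f}, {hi:.4f}]"
                f"  slope change {b:.6g}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "psi": list(map(float, self.psi)),
            "psi_se": list(map(float, self.psi_se)),
            "psi_ci": [[float(a), float(b)] for a, b in self.psi_ci],
            "intercept": float(self.intercept),
            "slope": float(self.slope),
            "slope_changes": list(map(float, self.slope_changes)),
            "rss": float(self.rss),
            "bic": float(self.bic()),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "nobs": int(self.nobs),
        }


class SegmentedModel:
    """Piecewise-linear regression of a response on one covariate.

    Parameters
    ----------
    x, y : array-like
        Gradient values and responses, same length.
    n_breakpoints : int
        Number of change points to estimate (0, 1 or 2).

    Examples
    --------
    >>> model = SegmentedModel(x, y, n_breakpoints=1)
    >>> res = model.fit()
    >>> res.psi
    """

    def __init__(self, x, y, n_breakpoints: int = 1):
        x = np.asarray(x, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.size != y.size:
            raise ValueError("x and y must have the same length")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("x and y must be finite")
        if n_breakpoints not in (0, 1, 2):
            raise ValueError("n_breakpoints must be 0, 1 or 2")
        n_distinct = np.unique(x).size
        if n_distinct < 3 * max(n_breakpoints, 1):
            raise ValueError(
                f"need at least {3 * max(n_breakpoints, 1)} distinct x values "
                f"for {n_breakpoints} breakpoint(s); got {n_distinct}"
            )
        order = np.argsort(x, kind="stable")
        self.x = x[order]
        self.y = y[order]
        self.n_breakpoints = n_breakpoints

    @classmethod
    def from_dataframe(cls, data, x: str, y: str, n_breakpoints: int = 1):
        return cls(data[x].to_numpy(), data[y].to_numpy(), n_breakpoints)

    # -- fitting -----------------------------------------------------------

    def _fit_zero(self) -> SegmentedResults:
        X = np.column_stack([np.ones_like(self.x), self.x])
        beta, rss, _ = _ols(X, self.y)
        e = np.empty(0)
        return SegmentedResults(
            psi=e, intercept=float(beta[0]), slope=float(beta[1]),
            slope_changes=e, psi_se=e, psi_ci=e.reshape(0, 2), rss=rss,
            fittedvalues=X @ beta, converged=True, n_iter=0,
            nobs=self.x.size, model=self,
        )

    def _candidate_starts(self, max_grid: int = 12) -> list[np.ndarray]:
        """Initial breakpoint placements from a coarse RSS grid scan.

        Candidate locations are midpoints between adjacent distinct x
        values (subsampled to at most ``max_grid`` by quantile position for
        large gradients); singles or ordered pairs are ranked by their
        fixed-psi least-squares RSS and the best few are returned as
        starting values, alongside the default quantile placement.
        """
        x, y, k = self.x, self.y, self.n_breakpoints
        xs = np.unique(x)
        mids = 0.5 * (xs[:-1] + xs[1:])
        if mids.size > max_grid:
            idx = np.unique(np.linspace(0, mids.size - 1, max_grid).astype(int))
            mids = mids[idx]
        if k == 1:
            cands = [np.array([m]) for m in mids]
        else:
            cands = [np.array(pair) for pair in combinations(mids, 2)]
        scored = []
        for psi in cands:
            _, rss, _ = _ols(_design(x, psi, gaps=False), y)
            scored.append((rss, tuple(psi)))
        scored.sort()
        starts = [np.array(s[1]) for s in scored[:3]]
        qs = np.linspace(0, 1, k + 2)[1:-1]
        starts.append(np.quantile(x, qs))
        return starts, np.array(scored[0][1])

    def fit(self, psi_init=None, max_iter: int = 50, tol: float = 1e-4
            ) -> SegmentedResults:
        """Iterative-linearization fit with data-driven multistart.

        When ``psi_init`` is given, a single run starts there; otherwise a
        coarse grid scan over candidate breakpoints supplies a few starting
        placements and the refinement with the lowest final RSS wins
        (single-start broken-line fitting is prone to local optima).
        Non-convergence is reported through ``SegmentedResults.converged``,
        never raised.  A breakpoint update that leaves the observed x-range
        is pulled back to the nearest interior grid midpoint and the step
        is damped.
        """
        if self.n_breakpoints == 0:
            return self._fit_zero()
        if psi_init is not None:
            psi = np.sort(np.asarray(psi_init, dtype=float))
            if psi.size != self.n_breakpoints:
                raise ValueError("psi_init length must equal n_breakpoints")
            if psi.min() <= self.x.min() or psi.max() >= self.x.max():
                raise ValueError("psi_init must lie strictly inside the x-range")
            starts = [psi]
            grid_best = None
        else:
            max_grid = 30 if (self.x.size <= 40 or self.n_breakpoints == 1) \
                else 16
            starts, grid_best = self._candidate_starts(max_grid=max_grid)
        best = None
        for start in starts:
            res = self._iterate(start, max_iter, tol)
            if best is None or (res.rss, not res.converged) < \
                    (best.rss, not best.converged):
                best = res
        if grid_best is not None:
            # refinement can stall; never return worse than the grid scan
            fallback = self._finalize(grid_best, converged=True, n_iter=0)
            if fallback.rss < best.rss:
                best = fallback
        return best

    def _iterate(self, psi0: np.ndarray, max_iter: int, tol: float
                 ) -> SegmentedResults:
        x, y = self.x, self.y
        k = self.n_breakpoints
        lo, hi = x.min(), x.max()
        xs = np.unique(x)
        mids = 0.5 * (xs[:-1] + xs[1:])
        psi = np.asarray(psi0, dtype=float).copy()

        restarted = False
        converged = False
        it = 0
        damp = np.ones(k)

        def fixed_rss(p):
            _, r, _ = _ols(_design(x, p, gaps=False), y)
            return r

        rss_cur = fixed_rss(psi)
        for it in range(1, max_iter + 1):
            X = _design(x, psi, gaps=True)
            beta, _, rank = _ols(X, y)
            if rank < X.shape[1] and not restarted:
                # collinear slope-change columns (e.g. psi_1 == psi_2):
                # restart once from perturbed initials
                restarted = True
                span = hi - lo
                psi = np.sort(psi + span * 0.05 * np.linspace(-1, 1, k))
                psi = np.clip(psi, mids[0], mids[-1])
                damp[:] = 1.0
                rss_cur = fixed_rss(psi)
                continue
            b_u = beta[2:2 + k]
            gam = beta[2 + k:2 + 2 * k]
            if np.max(np.abs(gam)) < tol:
                converged = True
                break
            with np.errstate(divide="ignore", invalid="ignore"):
                step = np.where(np.abs(b_u) > 1e-12, gam / b_u, 0.0)
            # accept only non-increasing RSS; halve the step otherwise
            accepted = False
            scale = damp.copy()
            for _ in range(8):
                new = psi + scale * step
                out = (new <= lo) | (new >= hi)
                if np.any(out):
                    # pull back to nearest interior midpoint, damp onwards
                    new[out] = mids[
                        np.argmin(np.abs(mids[:, None] - new[out]), axis=0)]
                    damp[out] *= 0.5
                new = np.sort(new)
                rss_new = fixed_rss(new)
                if rss_new <= rss_cur * (1 + 1e-12):
                    psi, rss_cur, accepted = new, rss_new, True
                    break
                scale *= 0.5
            if not accepted:
                break  # no improving damped step: local optimum reached
        return self._finalize(psi, converged=converged, n_iter=it)

    def _finalize(self, psi: np.ndarray, converged: bool, n_iter: int
                  ) -> SegmentedResults:
        """Refit with breakpoints fixed; delta-method SEs from the gap term."""
        x, y = self.x, self.y
        k = psi.size
        X = _design(x, psi, gaps=True)
        beta, _, _ = _ols(X, y)
        b_u = beta[2:2 + k]
        gam_se = self._gamma_se(X, y)
        with np.errstate(divide="ignore", invalid="ignore"):
            psi_se = np.where(np.abs(b_u) > 1e-12, gam_se / np.abs(b_u), np.inf)
        z = stats.norm.ppf(0.975)
        ci = np.column_stack([psi - z * psi_se, psi + z * psi_se])
        Xf = _design(x, psi, gaps=False)
        bf, rss, _ = _ols(Xf, y)
        return SegmentedResults(
            psi=psi, intercept=float(bf[0]), slope=float(bf[1]),
            slope_changes=bf[2:2 + k].copy(), psi_se=psi_se, psi_ci=ci,
            rss=rss, fittedvalues=Xf @ bf, converged=converged, n_iter=n_iter,
            nobs=x.size, model=self,
        )

    @staticmethod
    def _gamma_se(X: np.ndarray, y: np.ndarray) -> np.ndarray:
        n, p = X.shape
        beta, rss, rank = _ols(X, y)
        dof = max(n - p, 1)
        sigma2 = rss / dof
        XtX = X.T @ X
        try:
            cov = sigma2 * np.linalg.pinv(XtX)
        except np.linalg.LinAlgError:  # pragma: no cover
            return np.full((p - 2) // 2, np.inf)
        k = (p - 2) // 2
        return np.sqrt(np.clip(np.diag(cov)[2 + k:2 + 2 * k], 0.0, None))


def fit_segmented(x, y, n_breakpoints: int = 1, psi_init=None,
                  max_iter: int = 50, tol: float = 1e-4) -> SegmentedResults:
    """Fit a broken-line regression; see :class:`SegmentedModel`."""
    return SegmentedModel(x, y, n_breakpoints).fit(
        psi_init=psi_init, max_iter=max_iter, tol=tol)


def brute_force_breakpoints(x, y, n_breakpoints: int = 1) -> SegmentedResults:
    """Exhaustive-search breakpoint fit for small problems.

    Candidate breakpoints are the midpoints between adjacent distinct x
    values; every candidate (or ordered pair, for two breakpoints) is fitted
    exactly by least squares and the global RSS minimum is returned.  Ties
    are broken in favour of the smaller breakpoint(s).  Intended for data
    with at most a few dozen points as an independent oracle for
    :func:`fit_segmented`.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    if n_breakpoints not in (1, 2):
        raise ValueError("n_breakpoints must be 1 or 2")
    if x.size > 60:
        raise ValueError("brute_force_breakpoints is meant for small data")
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    xs = np.unique(x)
    mids = 0.5 * (xs[:-1] + xs[1:])
    if mids.size < n_breakpoints:
        raise ValueError("not enough distinct x values")
    if n_breakpoints == 1:
        candidates = [(m,) for m in mids]
    else:
        candidates = list(combinations(mids, 2))
    best = None
    for cand in candidates:
        psi = np.asarray(cand)
        X = _design(x, psi, gaps=False)
        beta, rss, _ = _ols(X, y)
        key = (rss, tuple(psi))
        if best is None or key < best[0]:
            best = (key, psi, beta, rss, X @ beta)
    _, psi, beta, rss, fitted = best
    k = n_breakpoints
    e = np.full(k, np.nan)
    return SegmentedResults(
        psi=psi, intercept=float(beta[0]), slope=float(beta[1]),
        slope_changes=beta[2:2 + k].copy(), psi_se=e,
        psi_ci=np.column_stack([e, e]), rss=rss, fittedvalues=fitted,
        converged=True, n_iter=0, nobs=x.size, model=None,
    )


# --------------------------------------------------------------------------
# Davies test

@dataclass
class DaviesResult:
    """Davies test for a slope change at an unknown location.

    ``statistic`` is the maximum over the candidate grid of the absolute
    t-statistic for adding a hinge term; ``pvalue`` is Davies' upper bound
    adjusted for the search over the grid, capped at 1.
    """

    statistic: float
    pvalue: float
    grid: np.ndarray
    k_grid: int

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"DaviesResult(statistic={self.statistic:.4f}, "
                f"pvalue={self.pvalue:.4g}, k_grid={self.k_grid})")


def davies_test(x, y, k_grid: int = 10) -> DaviesResult:
    """Test for the existence of a breakpoint in the x-y relationship.

    At each candidate location psi_k (evenly spaced interior quantiles of
    x) the t-statistic t_k for adding ``(x - psi_k)_+`` to the straight-line
    model is computed.  With M = max_k |t_k|, the adjusted p-value is
    Davies' upper bound for the maximum of a t-process with nu = n - 3
    degrees of freedom,

        p = P(|T_nu| > M) + V * (1 + M^2/nu)^(-(nu-1)/2) / sqrt(8 * pi),

    where V is the total variation of the signed statistics across the
    grid (the correction term reduces to the Gaussian form
    ``V * exp(-M^2/2) / sqrt(8*pi)`` as nu grows).  The bound is
    conservative; p is capped at 1.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    if x.size < 6:
        raise ValueError("davies_test requires at least 6 points")
    if np.unique(x).size < 3:
        raise ValueError("davies_test requires at least 3 distinct x values")
    if k_grid < 2:
        raise ValueError("k_grid must be at least 2")
    qs = np.linspace(0, 1, k_grid + 2)[1:-1]
    grid = np.quantile(x, qs)
    # keep candidates that split the data non-trivially
    grid = grid[(grid > x.min()) & (grid < x.max())]
    grid = np.unique(grid)
    if grid.size < 2:
        raise ValueError("degenerate x: candidate grid collapsed")
    ts = np.empty(grid.size)
    n = x.size
    tss = float(np.sum((y - y.mean()) ** 2))
    for i, psi in enumerate(grid):
        X = np.column_stack([np.ones_like(x), x, np.where(x > psi, x - psi, 0.0)])
        beta, rss, rank = _ols(X, y)
        dof = n - X.shape[1]
        if rank < X.shape[1] or dof <= 0:
            ts[i] = 0.0
            continue
        sigma2 = rss / dof
        if rss <= 1e-12 * max(tss, np.finfo(float).tiny):
            ts[i] = 0.0  # the line already fits perfectly: no evidence scale
            continue
        XtX_inv = np.linalg.pinv(X.T @ X)
        se = np.sqrt(sigma2 * XtX_inv[2, 2])
        ts[i] = beta[2] / se if se > 0 else 0.0
    M = float(np.max(np.abs(ts)))
    V = float(np.sum(np.abs(np.diff(ts))))
    nu = n - 3
    p = (2 * stats.t.sf(M, nu)
         + V * (1.0 + M * M / nu) ** (-(nu - 1) / 2.0) / np.sqrt(8 * np.pi))
    return DaviesResult(statistic=M, pvalue=float(min(p, 1.0)),
                        grid=grid, k_grid=int(grid.size))


# --------------------------------------------------------------------------
# Dixon's Q-test

# Two-tailed critical values for Dixon's ratios (Rorabacher 1991),
# alpha = 0.05 and 0.01, n = 3..30.  The ratio used depends on n:
# r10 for n <= 7, r11 for 8-10, r21 for 11-13, r22 for n >= 14.
_DIXON_CRIT = {
    0.05: {
        3: 0.970, 4: 0.829, 5: 0.710, 6: 0.625, 7: 0.568,
        8: 0.615, 9: 0.570, 10: 0.534,
        11: 0.625, 12: 0.592, 13: 0.565,
        14: 0.546, 15: 0.525, 16: 0.507, 17: 0.490, 18: 0.475,
        19: 0.462, 20: 0.450, 21: 0.440, 22: 0.430, 23: 0.421,
        24: 0.413, 25: 0.406, 26: 0.399, 27: 0.393, 28: 0.387,
        29: 0.381, 30: 0.376,
    },
    0.01: {
        3: 0.994, 4: 0.926, 5: 0.821, 6: 0.740, 7: 0.680,
        8: 0.717, 9: 0.672, 10: 0.635,
        11: 0.709, 12: 0.660, 13: 0.638,
        14: 0.641, 15: 0.616, 16: 0.595, 17: 0.577, 18: 0.561,
        19: 0.547, 20: 0.535, 21: 0.524, 22: 0.514, 23: 0.505,
        24: 0.497, 25: 0.489, 26: 0.486, 27: 0.475, 28: 0.469,
        29: 0.463, 30: 0.457,
    },
}


@dataclass
class DixonResult:
    """Single-outlier screen by Dixon's Q ratio."""

    is_outlier: bool
    q: float
    critical: float
    index: int | None
    alpha: float


def _dixon_ratio(s: np.ndarray, n: int, upper: bool) -> float:
    """Dixon ratio for the largest (upper) or smallest (lower) value."""
    if not upper:
        s = -s[::-1]
    if n <= 7:        # r10
        num = s[-1] - s[-2]
        den = s[-1] - s[0]
    elif n <= 10:     # r11
        num = s[-1] - s[-2]
        den = s[-1] - s[1]
    elif n <= 13:     # r21
        num = s[-1] - s[-3]
        den = s[-1] - s[1]
    else:             # r22
        num = s[-1] - s[-3]
        den = s[-1] - s[2]
    return num / den if den > 0 else 0.0


def dixon_outlier_test(values, alpha: float = 0.05) -> DixonResult:
    """Dixon's Q-test for a single outlier in a small sample (3 <= n <= 30).

    The ratio family follows standard practice by sample size; critical
    values are the published two-tailed tables.  At most one point (the more
    extreme end) is flagged per call; a zero-range sample flags nothing.
    """
    v = np.asarray(values, dtype=float).ravel()
    n = v.size
    if n < 3 or n > 30:
        raise ValueError("Dixon's test is tabulated for 3 <= n <= 30")
    if alpha not in _DIXON_CRIT:
        raise ValueError(f"alpha must be one of {sorted(_DIXON_CRIT)}")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    crit = _DIXON_CRIT[alpha][n]
    s = np.sort(v)
    if s[-1] == s[0]:
        return DixonResult(False, 0.0, crit, None, alpha)
    q_hi = _dixon_ratio(s, n, upper=True)
    q_lo = _dixon_ratio(s, n, upper=False)
    if q_hi >= q_lo:
        q, target = q_hi, s[-1]
    else:
        q, target = q_lo, s[0]
    is_out = q > crit
    idx = int(np.where(v == target)[0][0]) if is_out else None
    return DixonResult(bool(is_out), float(q), crit, idx, alpha)
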