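"""Stressor-interaction quantification along a gradient.

Works on the relative-survival scale: survival under a treatment divided by
control survival, ``w = W / W_0``.  Under Bliss independence the combined
relative survival of two stressors is the product ``w_X * w_Y``; the
deviation from additivity ``DA = w_XY - w_X * w_Y`` measures the
interaction, and its rescaled form maps interaction strength onto [-1, 2]:

*  -1 .. -0.5  synergy (combined effect stronger than independent action)
* -0.5 ..  0.5 additive
*  0.5 ..  1.3 antagonistic buffering (combined ~ strongest single stressor)
*  1.3 ..  2   suppression (one stressor reverses the other)

A multiplicative null model on the mortality scale,
``(N + SV) - N * SV``, expresses the same independence assumption —
individuals killed by one stressor cannot be killed again — and is carried
along as a cross-check: DA < 0 exactly when observed combined mortality
exceeds the null prediction.

The classical route, a two-way ANOVA-style interaction test with the water
bath as a random blocking factor, is provided for continuity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import INTRUSION, STABLE

__all__ = [
    "BINS",
    "InteractionTestResult",
    "to_survival",
    "deviation_from_additivity",
    "rescale_da",
    "classify_interaction",
    "multiplicative_null",
    "interaction_table",
    "two_way_interaction_test",
]

#: classification bins on the rescaled scale: left-closed, last bin closed
BINS = (
    (-1.0, -0.5, "synergy"),
    (-0.5, 0.5, "additive"),
    (0.5, 1.3, "buffering"),
    (1.3, 2.0, "suppression"),
)


def to_survival(mortality_pct):
    """Convert mortality percentage(s) to survival percentage(s)."""
    m = np.asarray(mortality_pct, dtype=float)
    if np.any((m < 0) | (m > 100) | ~np.isfinite(m)):
        raise ValueError("mortality_pct must lie in [0, 100]")
    out = 100.0 - m
    return out if out.ndim else float(out)


def deviation_from_additivity(w_x, w_y, w_xy):
    """DA = w_XY - w_X * w_Y on the relative-survival scale."""
    w_x, w_y, w_xy = (np.asarray(v, dtype=float) for v in (w_x, w_y, w_xy))
    if np.any(w_x < 0) or np.any(w_y < 0) or np.any(w_xy < 0):
        raise ValueError("relative responses must be >= 0")
    out = w_xy - w_x * w_y
    return out if out.ndim else float(out)


def rescale_da(w_x, w_y, w_xy, eps: float = 1e-9, return_degenerate=False):
    """Rescaled deviation from additivity, in [-1, 2].

    Negative DA (synergy) is scaled by the Bliss expectation E = w_X * w_Y,
    reaching -1 at total mortality (w_XY = 0).  Positive DA (antagonism) is
    scaled by ``min(w_X, w_Y) - E``, so the value is exactly 1 when the
    combined response equals the strongest single stressor (pure
    buffering); values up to 2 indicate suppression.  Results are clipped
    to [-1, 2].  Where the relevant denominator vanishes (< ``eps``), the
    clip boundary matching the sign of DA is returned and the point is
    flagged degenerate.
    """
    w_x, w_y, w_xy = np.broadcast_arrays(
        *(np.asarray(v, dtype=float) for v in (w_x, w_y, w_xy)))
    if np.any(w_x < 0) or np.any(w_y < 0) or np.any(w_xy < 0):
        raise ValueError("relative responses must be >= 0")
    if eps <= 0:
        raise ValueError("eps must be > 0")
    e = w_x * w_y
    w_min = np.minimum(w_x, w_y)
    da = w_xy - e
    out = np.zeros_like(da)
    degenerate = np.zeros(da.shape, dtype=bool)

    neg = da < -eps
    pos = da > eps
    with np.errstate(divide="ignore", invalid="ignore"):
        neg_ok = neg & (e >= eps)
        out[neg_ok] = da[neg_ok] / e[neg_ok]
        neg_bad = neg & (e < eps)
        out[neg_bad] = -1.0
        degenerate |= neg_bad
        den = w_min - e
        pos_ok = pos & (den >= eps)
        out[pos_ok] = da[pos_ok] / den[pos_ok]
        pos_bad = pos & (den < eps)
        out[pos_bad] = 2.0
        degenerate |= pos_bad
    out = np.clip(out, -1.0, 2.0)
    if out.ndim == 0:
        out = float(out)
        degenerate = bool(degenerate)
    if return_degenerate:
        return out, degenerate
    return out


def classify_interaction(rescaled_da):
    """Map a rescaled DA value in [-1, 2] to its interaction class."""
    v = np.asarray(rescaled_da, dtype=float)
    if np.any((v < -1.0) | (v > 2.0) | ~np.isfinite(v)):
        raise ValueError("rescaled DA must lie in [-1, 2]")
    labels = np.empty(v.shape, dtype=object)
    for lo, hi, name in BINS:
        mask = (v >= lo) & (v < hi)
        labels[mask] = name
    labels[v == 2.0] = BINS[-1][2]
    if labels.ndim == 0:
        return str(labels[()])
    return labels


def multiplicative_null(n_effect, sv_effect):
    """Independent-action prediction for the combined mortality proportion.

    ``(N + SV) - N * SV`` for effects N, SV in [0, 1]: individuals killed by
    one stressor cannot be killed by the other, so the combined mortality
    is capped at 1.  Symmetric and monotone in both arguments.
    """
    n, sv = (np.asarray(v, dtype=float) for v in (n_effect, sv_effect))
    if np.any((n < 0) | (n > 1)) or np.any((sv < 0) | (sv > 1)):
        raise ValueError("effects must be mortality proportions in [0, 1]")
    out = n + sv - n * sv
    return out if out.ndim else float(out)


def interaction_table(observations: pd.DataFrame,
                      eps: float = 1e-9) -> pd.DataFrame:
    """Per-level interaction records from a tidy factorial tank table.

    Required cells: the shared control (0 g, stable), the intrusion-only
    cell (0 g, intrusion) and, for every level > 0, the nutrient-only
    (level, stable) and combined (level, intrusion) cells.  Cell means of
    mortality are converted to survival, relative responses, DA, rescaled
    DA, class label and the multiplicative-null prediction.  A zero control
    survival flags the whole table undefined rather than dividing by zero.
    """
    means = (observations.groupby(["nutrient_g", "salinity"])["mortality_pct"]
             .mean())

    def cell(level, sal):
        try:
            return float(means.loc[(level, sal)])
        except KeyError:
            raise ValueError(
                f"missing required cell: nutrient_g={level}, salinity={sal!r}"
            ) from None

    levels = sorted(observations["nutrient_g"].unique())
    if 0.0 not in levels:
        raise ValueError("missing required cell: nutrient_g=0 (control)")
    m0 = cell(0.0, STABLE)
    my = cell(0.0, INTRUSION)
    w0 = to_survival(m0)
    wy_abs = to_survival(my)
    rows = []
    for lvl in levels:
        if lvl == 0.0:
            continue
        mx = cell(lvl, STABLE)
        mxy = cell(lvl, INTRUSION)
        wx_abs = to_survival(mx)
        wxy_abs = to_survival(mxy)
        rec = {
            "nutrient_g": lvl,
            "W_0": w0, "W_X": wx_abs, "W_Y": wy_abs, "W_XY": wxy_abs,
        }
        if w0 <= 0:
            rec.update({k: np.nan for k in
                        ("w_X", "w_Y", "w_XY", "DA", "rescaled_DA",
                         "null_mortality_pct", "observed_mortality_pct")})
            rec["label"] = "undefined"
            rec["degenerate"] = True
        else:
            wx, wy, wxy = wx_abs / w0, wy_abs / w0, wxy_abs / w0
            da = deviation_from_additivity(wx, wy, wxy)
            rda, degen = rescale_da(wx, wy, wxy, eps=eps,
                                    return_degenerate=True)
            null_mort = 100.0 - float(np.clip(wx * wy * w0, 0.0, 100.0))
            rec.update({
                "w_X": wx, "w_Y": wy, "w_XY": wxy, "DA": da,
                "rescaled_DA": rda, "label": classify_interaction(rda),
                "null_mortality_pct": null_mort,
                "observed_mortality_pct": mxy,
                "degenerate": degen,
            })
        rows.append(rec)
    return pd.DataFrame(rows)


@dataclass
class InteractionTestResult:
    """Two-way interaction F-test with a bath variance-component check."""

    f_statistic: float
    df_num: int
    df_den: int
    pvalue: float
    bath_lrt: float
    bath_pvalue: float
    weighted: bool

    def to_dict(self) -> dict:
        return {
            "f_statistic": float(self.f_statistic),
            "df_num": int(self.df_num),
            "df_den": int(self.df_den),
            "pvalue": float(self.pvalue),
            "bath_lrt": float(self.bath_lrt),
            "bath_pvalue": float(self.bath_pvalue),
            "weighted": bool(self.weighted),
        }


def two_way_interaction_test(observations: pd.DataFrame,
                             weighting: str = "binomial"
                             ) -> InteractionTestResult:
    """Gradient x salinity interaction F-test on tank mortality.

    A fixed-effects two-way linear model with interaction is fitted by
    one-step weighted least squares.  With ``weighting="binomial"`` (the
    default) the heterogeneous variance of percentage mortality is modeled
    through the binomial variance function: the additive (main-effects)
    model supplies fitted mortality fractions p-hat, and each tank is
    weighted by ``n_initial / (p_hat (1 - p_hat))`` (the count factor drops
    out when all tanks hold the same number of individuals).  Estimating
    the weights under the additive model keeps them nearly independent of
    the interaction contrast, which keeps the F-test close to its nominal
    size; raw per-cell variance estimates (4 df each) would not.
    ``weighting="none"`` gives ordinary least squares.

    The water-bath variance component is tested by a likelihood-ratio
    against the fixed-effects model, referred to the 50:50
    chi-square(0, 1) mixture null.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = observations.copy()
    cells = df.groupby(["nutrient_g", "salinity"])["mortality_pct"]
    sizes = cells.size()
    if (sizes < 2).any():
        raise ValueError("need >= 2 replicates per cell")
    n_levels = df["nutrient_g"].nunique()
    n_sal = df["salinity"].nunique()
    if n_levels < 2 or n_sal < 2:
        raise ValueError("need at least 2 levels of each factor")
    if weighting not in ("binomial", "none"):
        raise ValueError("weighting must be 'binomial' or 'none'")

    formula = "mortality_pct ~ C(nutrient_g) * C(salinity)"
    ols_fit = smf.ols(formula, data=df).fit()
    if weighting == "none":
        fit = ols_fit
    else:
        n0 = df["n_initial"].to_numpy(dtype=float) \
            if "n_initial" in df.columns else np.ones(len(df))
        additive = smf.ols("mortality_pct ~ C(nutrient_g) + C(salinity)",
                           data=df).fit()
        floor = 1.0 / (2.0 * max(np.max(n0), 2.0) * df.groupby(
            ["nutrient_g", "salinity"]).size().max())
        p_hat = np.clip(additive.fittedvalues.to_numpy() / 100.0,
                        floor, 1.0 - floor)
        w = n0 / (p_hat * (1.0 - p_hat))
        fit = smf.wls(formula, data=df, weights=w).fit()
    aov = anova_lm(fit, typ=2)
    inter = aov.loc["C(nutrient_g):C(salinity)"]
    f = float(inter["F"])
    df_num = int(inter["df"])
    df_den = int(aov.loc["Residual", "df"])
    p = float(inter["PR(>F)"])
    # exactly additive responses leave both the interaction and residual
    # sums of squares at rounding level; report that as no interaction
    # rather than a 0/0 ratio
    ss_scale = float(aov["sum_sq"].sum())
    if inter["sum_sq"] <= 1e-10 * max(ss_scale, np.finfo(float).tiny):
        f, p = 0.0, 1.0

    # bath variance component: ML likelihood-ratio, 0.5*chi2_0 + 0.5*chi2_1
    bath_lrt = np.nan
    bath_p = np.nan
    if "bath_id" in df.columns and df["bath_id"].nunique() > 1:
        try:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mm = smf.mixedlm(formula, data=df,
                                 groups=df["bath_id"]).fit(reml=False)
            bath_lrt = float(max(0.0, 2.0 * (mm.llf - ols_fit.llf)))
            bath_p = 1.0 if bath_lrt <= 0 else float(
                0.5 * stats.chi2.sf(bath_lrt, 1))
        except Exception:  # pragma: no cover - optimizer hiccups
            pass
    return InteractionTestResult(
        f_statistic=f, df_num=df_num, df_den=df_den, pvalue=p,
        bath_lrt=bath_lrt, bath_pvalue=bath_p,
        weighted=(weighting == "binomial"))
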