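"""Synthetic full-factorial multi-stressor experiments with known truth.

Emulates a two-month mesocosm experiment in which zebra-mussel mortality is
measured along a 13-level nutrient-enrichment gradient (0-120 g of
slow-release fertilizer), with and without a weekly saltwater-intrusion
pulse, five replicate tanks per treatment, 15 individuals per tank, and six
water baths as a blocking factor.  Tank-level death counts are binomial
around a piecewise-linear mean mortality, optionally with a normal
bath effect on the probability scale and logit-normal extra-binomial
noise that inflates variance near the true thresholds (the early-warning
signature of an approaching tipping point).

Every generated dataset carries its ground truth (breakpoints, slopes,
seed), so downstream estimators can be scored against it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "STABLE",
    "INTRUSION",
    "SCHEMA_COLUMNS",
    "GradientDesign",
    "PiecewiseMean",
    "MeanModel",
    "make_design",
    "preset_scenarios",
    "simulate_experiment",
    "write_experiment",
    "write_truth",
    "validate_observations",
]

logger = logging.getLogger(__name__)

STABLE = "stable"
INTRUSION = "intrusion"

#: tidy schema for one experimental unit (tank) per row
SCHEMA_COLUMNS = ("tank_id", "bath_id", "nutrient_g", "salinity",
                  "n_initial", "n_dead", "mortality_pct")

#: default gradient: an even 10-g grid over the experiment's 0-120 g range
DEFAULT_LEVELS = tuple(float(g) for g in range(0, 121, 10))

#: stated near-threshold variance inflation used when inflation is enabled:
#: logit-scale noise sd at the threshold and the window, in grams, over
#: which it decays linearly to zero.  The sd emulates flickering between
#: alternative states close to the tipping point and is large enough that
#: the extra-binomial variance there clearly dominates the binomial
#: background of the presets.
DEFAULT_INFLATION_SD = 2.5
DEFAULT_INFLATION_WINDOW = 20.0


@dataclass(frozen=True)
class GradientDesign:
    """Full-factorial layout of a gradient x salinity experiment."""

    nutrient_levels: tuple[float, ...]
    salinity_treatments: tuple[str, ...]
    replicates: int
    baths: int
    individuals_per_tank: int

    @property
    def n_treatments(self) -> int:
        return len(self.nutrient_levels) * len(self.salinity_treatments)

    @property
    def n_units(self) -> int:
        return self.n_treatments * self.replicates

    def units(self, randomize_baths: bool = False, seed: int | None = None
              ) -> pd.DataFrame:
        """One row per tank: tank_id, bath_id, nutrient_g, salinity.

        Bath assignment is round-robin over the unit list by default (a
        reproducible partition); with ``randomize_baths`` the assignment is
        a seeded random balanced permutation.
        """
        rows = []
        tank = 0
        for sal in self.salinity_treatments:
            for lvl in self.nutrient_levels:
                for _ in range(self.replicates):
                    rows.append((tank, lvl, sal))
                    tank += 1
        df = pd.DataFrame(rows, columns=["tank_id", "nutrient_g", "salinity"])
        bath = np.arange(len(df)) % self.baths
        if randomize_baths:
            rng = np.random.default_rng(seed)
            bath = rng.permutation(bath)
        df.insert(1, "bath_id", bath)
        return df


def make_design(nutrient_levels=DEFAULT_LEVELS, replicates: int = 5,
                baths: int = 6, individuals_per_tank: int = 15,
                salinity_treatments=(STABLE, INTRUSION)) -> GradientDesign:
    """Build a full-factorial gradient design.

    Defaults reproduce the reference layout: 13 levels x 2 salinity
    treatments x 5 replicates = 130 tanks in 6 water baths, 15 mussels per
    tank.
    """
    levels = tuple(float(g) for g in nutrient_levels)
    if len(levels) < 2:
        raise ValueError("need at least 2 nutrient levels")
    if len(set(levels)) != len(levels):
        raise ValueError("nutrient levels must be distinct")
    if replicates < 1 or baths < 1 or individuals_per_tank < 1:
        raise ValueError("replicates, baths and individuals_per_tank must be >= 1")
    sal = tuple(salinity_treatments)
    if len(sal) < 1 or len(set(sal)) != len(sal):
        raise ValueError("salinity treatments must be distinct and non-empty")
    return GradientDesign(levels, sal, int(replicates), int(baths),
                          int(individuals_per_tank))


@dataclass(frozen=True)
class PiecewiseMean:
    """Piecewise-linear mean mortality (fraction) along the gradient."""

    intercept: float
    breakpoints: tuple[float, ...] = ()
    slopes: tuple[float, ...] = (0.0,)

    def __post_init__(self):
        if len(self.slopes) != len(self.breakpoints) + 1:
            raise ValueError("need exactly one slope per segment")
        bp = self.breakpoints
        if any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])):
            raise ValueError("breakpoints must be strictly increasing")

    def mean(self, x) -> np.ndarray:
        """Clipped mean mortality fraction at gradient value(s) x."""
        x = np.asarray(x, dtype=float)
        y = self.intercept + self.slopes[0] * x
        for bp, (s_prev, s_next) in zip(self.breakpoints,
                                        zip(self.slopes, self.slopes[1:])):
            y = y + (s_next - s_prev) * np.where(x > bp, x - bp, 0.0)
        raw = y
        if np.any((raw < 0) | (raw > 1)):
            logger.info("piecewise mean outside [0, 1]; clipping")
        return np.clip(y, 0.0, 1.0)


@dataclass(frozen=True)
class MeanModel:
    """True mean structure per salinity treatment, plus variance inflation.

    ``inflation_sd`` is the maximum standard deviation of logit-normal
    extra-binomial noise applied to the tank-level mortality probability;
    it decays linearly to zero over ``inflation_window`` grams of distance
    from the nearest true breakpoint (no noise when 0 or when a treatment
    has no breakpoint).
    """

    treatments: dict[str, PiecewiseMean] = field(default_factory=dict)
    inflation_sd: float = 0.0
    inflation_window: float = 20.0

    def breakpoints(self, salinity: str) -> tuple[float, ...]:
        return self.treatments[salinity].breakpoints

    def inflation_profile(self, salinity: str, x) -> np.ndarray:
        """Logit-scale noise sd at gradient value(s) x: >= 0, peaks at psi."""
        x = np.asarray(x, dtype=float)
        bp = self.treatments[salinity].breakpoints
        if self.inflation_sd <= 0 or not bp:
            return np.zeros_like(x)
        dist = np.min(np.abs(x[..., None] - np.asarray(bp)), axis=-1)
        return self.inflation_sd * np.clip(1.0 - dist / self.inflation_window,
                                           0.0, None)


_PRESETS = {
    "stable_single_threshold",
    "intrusion_double_threshold",
    "null_flat",
}

# Shapes follow the reported gradient responses: a flat-then-rising line
# breaking at 70 g under stable salinity, and a rise-fall-rise line with
# breaks at 26.91 g and 84.13 g under the intrusion pulse.
_STABLE_SINGLE = PiecewiseMean(intercept=0.05, breakpoints=(70.0,),
                               slopes=(0.0, 0.011))
_INTRUSION_DOUBLE = PiecewiseMean(intercept=0.08,
                                  breakpoints=(26.91, 84.13),
                                  slopes=(0.012, -0.004, 0.010))
_FLAT = PiecewiseMean(intercept=0.15)


def preset_scenarios(name: str, inflation_sd: float = 0.0,
                     inflation_window: float = 20.0) -> MeanModel:
    """Named ground-truth scenarios.

    * ``stable_single_threshold`` - both arms share the single 70-g
      threshold shape (a press-stressor-only world).
    * ``intrusion_double_threshold`` - the full two-stressor scenario:
      single 70-g threshold under stable salinity, rise-fall-rise with
      breakpoints at 26.91 g and 84.13 g under the intrusion.
    * ``null_flat`` - no breakpoints anywhere (calibration null).
    """
    if name not in _PRESETS:
        raise ValueError(
            f"unknown scenario {name!r}; valid names: {sorted(_PRESETS)}")
    if name == "stable_single_threshold":
        treatments = {STABLE: _STABLE_SINGLE, INTRUSION: _STABLE_SINGLE}
    elif name == "intrusion_double_threshold":
        treatments = {STABLE: _STABLE_SINGLE, INTRUSION: _INTRUSION_DOUBLE}
    else:
        treatments = {STABLE: _FLAT, INTRUSION: _FLAT}
    return MeanModel(treatments=treatments, inflation_sd=inflation_sd,
                     inflation_window=inflation_window)


def _logit(p):
    return np.log(p / (1.0 - p))


def _expit(z):
    return 1.0 / (1.0 + np.exp(-z))


def simulate_experiment(design: GradientDesign, mean_model: MeanModel,
                        bath_sd: float = 0.02, seed: int | None = None,
                        randomize_baths: bool = False) -> pd.DataFrame:
    """Draw one experiment: binomial tank mortality around the true means.

    Per tank, ``n_dead ~ Binomial(n_initial, p)`` with
    ``p = clip(piecewise mean + bath effect, 0, 1)``; bath effects are
    N(0, bath_sd), drawn once per bath.  Where the mean model's variance
    inflation is active, p additionally receives logit-normal jitter with
    the stated sd profile.  Bit-reproducible for a fixed seed.
    """
    if bath_sd < 0:
        raise ValueError("bath_sd must be >= 0")
    missing = [s for s in design.salinity_treatments
               if s not in mean_model.treatments]
    if missing:
        raise ValueError(f"mean model lacks treatment(s): {missing}")
    rng = np.random.default_rng(seed)
    units = design.units(randomize_baths=randomize_baths,
                         seed=None if seed is None else seed + 1)
    bath_eff = rng.normal(0.0, bath_sd, size=design.baths) if bath_sd > 0 \
        else np.zeros(design.baths)
    p = np.empty(len(units))
    for sal in design.salinity_treatments:
        mask = (units["salinity"] == sal).to_numpy()
        xg = units.loc[mask, "nutrient_g"].to_numpy()
        base = mean_model.treatments[sal].mean(xg)
        sd_prof = mean_model.inflation_profile(sal, xg)
        pj = np.clip(base + bath_eff[units.loc[mask, "bath_id"].to_numpy()],
                     0.0, 1.0)
        active = sd_prof > 0
        if np.any(active):
            eps = rng.normal(0.0, 1.0, size=active.sum()) * sd_prof[active]
            safe = np.clip(pj[active], 1e-6, 1.0 - 1e-6)
            pj[active] = _expit(_logit(safe) + eps)
        p[mask] = pj
    n0 = design.individuals_per_tank
    n_dead = rng.binomial(n0, p)
    out = units.copy()
    out["n_initial"] = n0
    out["n_dead"] = n_dead
    out["mortality_pct"] = 100.0 * n_dead / n0
    return out


def write_experiment(observations: pd.DataFrame, path) -> None:
    """Write the tidy tank table as UTF-8 CSV with '.' decimals."""
    validate_observations(observations)
    observations.loc[:, list(SCHEMA_COLUMNS)].to_csv(path, index=False)


def write_truth(mean_model: MeanModel, seed, path) -> None:
    """JSON sidecar with the ground truth for recovery tests."""
    payload = {
        "seed": seed,
        "inflation_sd": mean_model.inflation_sd,
        "inflation_window": mean_model.inflation_window,
        "treatments": {
            sal: {
                "intercept": pm.intercept,
                "breakpoints": list(pm.breakpoints),
                "slopes": list(pm.slopes),
            }
            for sal, pm in mean_model.treatments.items()
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def validate_observations(df: pd.DataFrame, require_counts: bool = True
                          ) -> pd.DataFrame:
    """Check a tidy tank table against the schema; returns the frame.

    Raises ``ValueError`` naming the offending column or row.  When counts
    are present, ``mortality_pct`` must equal ``100 * n_dead / n_initial``.
    """
    missing = [c for c in ("tank_id", "bath_id", "nutrient_g", "salinity",
                           "mortality_pct") if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    has_counts = {"n_initial", "n_dead"}.issubset(df.columns)
    if require_counts and not has_counts:
        raise ValueError("missing count columns n_initial/n_dead")
    if has_counts:
        n0 = df["n_initial"].to_numpy()
        nd = df["n_dead"].to_numpy()
        bad = np.where((nd < 0) | (nd > n0) | (n0 <= 0))[0]
        if bad.size:
            raise ValueError(
                f"invalid counts at row(s) {bad[:5].tolist()}: "
                "need 0 <= n_dead <= n_initial, n_initial > 0")
        expect = 100.0 * nd / n0
        off = np.where(np.abs(expect - df["mortality_pct"].to_numpy()) > 1e-6)[0]
        if off.size:
            raise ValueError(
                f"mortality_pct inconsistent with counts at row(s) "
                f"{off[:5].tolist()}")
    m = df["mortality_pct"].to_numpy(dtype=float)
    bad = np.where((m < 0) | (m > 100) | ~np.isfinite(m))[0]
    if bad.size:
        raise ValueError(f"mortality_pct outside [0, 100] at row(s) "
                         f"{bad[:5].tolist()}")
    return df
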