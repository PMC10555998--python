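"""End-to-end analysis pipeline and machine-readable report.

Stage order mirrors the analysis workflow: Dixon outlier screening per
treatment cell, broken-line fits with a Davies existence test per salinity
treatment, variance/dip diagnostics, then interaction classification and
the two-way interaction test.  All randomness flows from one root seed,
split per stage through named ``numpy`` seed sequences so stage-level
reruns are reproducible, and the JSON report is byte-identical across runs
with the same configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diagnostics import dip_test, variance_profile
from .interactions import interaction_table, two_way_interaction_test
from .segmented import SegmentedModel, davies_test, dixon_outlier_test
from .synthetic import (SCHEMA_COLUMNS, make_design, preset_scenarios,
                        simulate_experiment, validate_observations,
                        write_experiment)

__all__ = ["PipelineConfig", "PipelineReport", "read_experiment",
           "run_pipeline"]

_STAGE_SEEDS = {"simulate": 0, "dip": 1, "interactions": 2}


def _stage_seed(root_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence(entropy=root_seed,
                                spawn_key=(_STAGE_SEEDS[stage],))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Exactly one of ``input_path`` (a tidy CSV) or ``scenario`` (a synthetic
    preset name) must be given.  Numeric settings must be positive; the
    classification bins are fixed.
    """

    input_path: str | None = None
    scenario: str | None = None
    seed: int = 0
    davies_k: int = 10
    breakpoint_candidates: tuple[int, ...] = (0, 1, 2)
    dip_boot: int = 999
    smoother_span: float = 0.75
    outlier_alpha: float = 0.05
    alpha: float = 0.05
    bath_sd: float = 0.02
    inflation_sd: float = 0.0
    output_dir: str | None = None

    def __post_init__(self):
        if (self.input_path is None) == (self.scenario is None):
            raise ValueError("give exactly one of input_path or scenario")
        for name in ("davies_k", "dip_boot", "smoother_span",
                     "outlier_alpha", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.bath_sd < 0 or self.inflation_sd < 0:
            raise ValueError("bath_sd and inflation_sd must be >= 0")
        self.breakpoint_candidates = tuple(
            sorted(set(int(k) for k in self.breakpoint_candidates)))
        if any(k not in (0, 1, 2) for k in self.breakpoint_candidates):
            raise ValueError("breakpoint_candidates must be within {0, 1, 2}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["breakpoint_candidates"] = list(self.breakpoint_candidates)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineReport:
    """Structured result bundle for one run."""

    config: dict
    provenance: dict
    exclusions: list
    treatments: dict
    interactions: dict | None
    errors: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "config": self.config,
            "provenance": self.provenance,
            "exclusions": self.exclusions,
            "treatments": self.treatments,
            "interactions": self.interactions,
            "errors": self.errors,
        }, sort_keys=True, indent=2, allow_nan=True)

    def summary(self) -> str:
        lines = ["tipstress pipeline report",
                 "=========================",
                 f"seed: {self.provenance['seed']}   "
                 f"config hash: {self.provenance['config_hash']}",
                 f"excluded tanks: {[e['tank_id'] for e in self.exclusions]}"]
        for sal, block in sorted(self.treatments.items()):
            sel = block["selected_fit"]
            lines.append(
                f"[{sal}] breakpoints: {sel['psi'] if sel else 'none'}  "
                f"Davies p = {block['davies']['pvalue']:.4g}  "
                f"dip p = {block['dip']['pvalue']:.4g}")
        if self.interactions:
            tw = self.interactions["two_way_test"]
            lines.append(
                f"interaction F({tw['df_num']},{tw['df_den']}) = "
                f"{tw['f_statistic']:.3f}, p = {tw['pvalue']:.4g}")
            labels = [r["label"] for r in self.interactions["table"]]
            lines.append(f"interaction labels along gradient: {labels}")
        for err in self.errors:
            lines.append(f"stage {err['stage']} failed: {err['error']}")
        return "\n".join(lines)


def read_experiment(path) -> pd.DataFrame:
    """Read and validate a tidy tank table.

    ``mortality_pct`` is recomputed from the counts when both count columns
    are present (a mismatch beyond 1e-6 is an error).  A file carrying only
    mortality is accepted; the frame is then flagged via
    ``df.attrs['counts_present'] = False``.
    """
    df = pd.read_csv(path)
    missing = [c for c in ("tank_id", "bath_id", "nutrient_g", "salinity",
                           "mortality_pct") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    counts = {"n_initial", "n_dead"}.issubset(df.columns)
    validate_observations(df, require_counts=False)
    if counts:
        validate_observations(df, require_counts=True)
        df["mortality_pct"] = 100.0 * df["n_dead"] / df["n_initial"]
    df.attrs["counts_present"] = counts
    return df


def _screen_outliers(df: pd.DataFrame, alpha: float):
    """Dixon screening within each treatment cell; one pass, <= 1 flag/cell."""
    excluded = []
    keep = np.ones(len(df), dtype=bool)
    for (lvl, sal), sub in df.groupby(["nutrient_g", "salinity"]):
        vals = sub["mortality_pct"].to_numpy()
        if vals.size < 3 or vals.size > 30:
            continue
        res = dixon_outlier_test(vals, alpha=alpha)
        if res.is_outlier:
            row = sub.iloc[res.index]
            keep[df.index.get_loc(row.name)] = False
            excluded.append({"tank_id": int(row["tank_id"]),
                             "nutrient_g": float(lvl), "salinity": str(sal),
                             "mortality_pct": float(row["mortality_pct"]),
                             "q": res.q, "critical": res.critical})
    return df[keep].reset_index(drop=True), excluded


def _analyze_treatment(sub: pd.DataFrame, config: PipelineConfig,
                       dip_seed: int) -> dict:
    x = sub["nutrient_g"].to_numpy(dtype=float)
    y = sub["mortality_pct"].to_numpy(dtype=float)
    dav = davies_test(x, y, k_grid=config.davies_k)
    fits = {}
    for k in config.breakpoint_candidates:
        try:
            fits[k] = SegmentedModel(x, y, n_breakpoints=k).fit()
        except ValueError:
            continue
    # existence gate: without Davies evidence keep the straight line;
    # with evidence, choose among breakpoint fits by BIC
    selected_k = 0
    if dav.pvalue < config.alpha:
        cands = {k: f for k, f in fits.items() if k > 0}
        if cands:
            selected_k = min(cands, key=lambda k: cands[k].bic())
    selected = fits.get(selected_k)
    vp = variance_profile(sub, span=config.smoother_span)
    dip = dip_test(y, n_boot=config.dip_boot, seed=dip_seed)
    return {
        "n_tanks": int(len(sub)),
        "davies": {"statistic": dav.statistic, "pvalue": dav.pvalue,
                   "k_grid": dav.k_grid},
        "fits": {str(k): f.to_dict() for k, f in fits.items()},
        "selected_n_breakpoints": int(selected_k),
        "selected_fit": selected.to_dict() if selected is not None else None,
        "variance_profile": vp.to_dict(),
        "dip": {"statistic": dip.statistic, "pvalue": dip.pvalue,
                "n": dip.n, "n_boot": dip.n_boot, "seed": dip.seed},
    }


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run the full analysis and return (and optionally write) the report."""
    if config.scenario is not None:
        design = make_design()
        model = preset_scenarios(config.scenario,
                                 inflation_sd=config.inflation_sd)
        obs = simulate_experiment(design, model, bath_sd=config.bath_sd,
                                  seed=_stage_seed(config.seed, "simulate"))
    else:
        obs = read_experiment(config.input_path)

    screened, excluded = _screen_outliers(obs, config.outlier_alpha)

    treatments: dict[str, dict] = {}
    errors: list[dict] = []
    dip_seed = _stage_seed(config.seed, "dip")
    for i, sal in enumerate(sorted(screened["salinity"].unique())):
        sub = screened[screened["salinity"] == sal]
        try:
            treatments[str(sal)] = _analyze_treatment(sub, config,
                                                      dip_seed + i)
        except Exception as exc:
            errors.append({"stage": f"treatment:{sal}", "error": str(exc)})

    interactions = None
    n_sal = screened["salinity"].nunique()
    if n_sal >= 2:
        try:
            table = interaction_table(screened)
            tw = two_way_interaction_test(screened)
            interactions = {
                "table": json.loads(
                    table.to_json(orient="records", double_precision=12)),
                "two_way_test": tw.to_dict(),
            }
        except Exception as exc:
            errors.append({"stage": "interactions", "error": str(exc)})
    else:
        errors.append({"stage": "interactions",
                       "error": "skipped: single salinity treatment"})

    report = PipelineReport(
        config=config.to_dict(),
        provenance={"seed": int(config.seed),
                    "config_hash": config.config_hash(),
                    "package_version": __version__},
        exclusions=excluded,
        treatments=treatments,
        interactions=interactions,
        errors=errors,
    )
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json(), encoding="utf-8")
        if config.scenario is not None:
            write_experiment(obs, out / "observations.csv")
        if interactions is not None:
            pd.DataFrame(interactions["table"]).to_csv(
                out / "interactions.csv", index=False)
    return report
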