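"""Generator: design cardinalities, reproducibility, binomial noise law."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tipstress as ts
from tipstress.synthetic import (INTRUSION, STABLE, MeanModel, PiecewiseMean,
                                 validate_observations, write_experiment,
                                 write_truth)


class TestDesign:
    @pytest.mark.parametrize("levels,sal,reps,units,treats", [
        (13, 2, 5, 130, 26),          # reference factorial layout
        (1 + 1, 1, 1, 2, 2),
        (3, 2, 4, 24, 6),
    ])
    def test_cardinalities(self, levels, sal, reps, units, treats):
        d = ts.make_design(nutrient_levels=np.arange(levels) * 10.0,
                           replicates=reps,
                           salinity_treatments=("stable", "intrusion")[:sal])
        assert d.n_units == units
        assert d.n_treatments == treats
        assert len(d.units()) == units

    def test_degenerate_single_cell(self):
        d = ts.make_design(nutrient_levels=[0.0, 10.0], replicates=1,
                           baths=1, salinity_treatments=("stable",))
        assert d.n_units == 2 and d.n_treatments == 2

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(levels=st.integers(2, 8), sal=st.integers(1, 2),
           reps=st.integers(1, 6), baths=st.integers(1, 7))
    def test_cardinality_products_hold_generally(self, levels, sal, reps,
                                                 baths):
        d = ts.make_design(nutrient_levels=np.arange(levels) * 5.0,
                           replicates=reps, baths=baths,
                           salinity_treatments=("a", "b")[:sal])
        u = d.units()
        assert len(u) == levels * sal * reps == d.n_units
        # bath assignment partitions the units
        assert u["bath_id"].between(0, baths - 1).all()
        assert u.groupby("bath_id").size().sum() == d.n_units

    def test_rejects_bad_counts(self):
        with pytest.raises(ValueError):
            ts.make_design(replicates=0)
        with pytest.raises(ValueError):
            ts.make_design(baths=0)
        with pytest.raises(ValueError):
            ts.make_design(nutrient_levels=[10.0])

    def test_randomized_baths_still_balanced(self):
        d = ts.make_design()
        u = d.units(randomize_baths=True, seed=3)
        sizes = u.groupby("bath_id").size()
        assert sizes.max() - sizes.min() <= 1


class TestPresets:
    def test_breakpoint_truths(self):
        m = ts.preset_scenarios("stable_single_threshold")
        assert m.breakpoints(STABLE) == (70.0,)
        m = ts.preset_scenarios("intrusion_double_threshold")
        assert m.breakpoints(INTRUSION) == (26.91, 84.13)
        assert m.breakpoints(STABLE) == (70.0,)
        m = ts.preset_scenarios("null_flat")
        assert m.breakpoints(STABLE) == () and m.breakpoints(INTRUSION) == ()

    def test_intrusion_shape_rises_falls_rises(self):
        pm = ts.preset_scenarios("intrusion_double_threshold").treatments[
            INTRUSION]
        assert pm.slopes[0] > 0 > pm.slopes[1] and pm.slopes[2] > 0

    def test_unknown_name_lists_valid(self):
        with pytest.raises(ValueError, match="null_flat"):
            ts.preset_scenarios("bogus")


class TestSimulate:
    def test_zero_truth_all_alive(self, default_design):
        flat0 = MeanModel(treatments={STABLE: PiecewiseMean(0.0),
                                      INTRUSION: PiecewiseMean(0.0)})
        obs = ts.simulate_experiment(default_design, flat0, bath_sd=0.0,
                                     seed=1)
        assert (obs.n_dead == 0).all() and (obs.mortality_pct == 0).all()

    def test_saturation_all_dead(self, default_design):
        flat1 = MeanModel(treatments={STABLE: PiecewiseMean(1.0),
                                      INTRUSION: PiecewiseMean(1.0)})
        obs = ts.simulate_experiment(default_design, flat1, bath_sd=0.0,
                                     seed=1)
        assert (obs.n_dead == obs.n_initial).all()

    def test_bit_reproducible(self, default_design):
        m = ts.preset_scenarios("intrusion_double_threshold",
                                inflation_sd=1.0)
        a = ts.simulate_experiment(default_design, m, seed=7)
        b = ts.simulate_experiment(default_design, m, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_treatment_rejected(self, default_design):
        partial = MeanModel(treatments={STABLE: PiecewiseMean(0.1)})
        with pytest.raises(ValueError, match="intrusion"):
            ts.simulate_experiment(default_design, partial, seed=1)

    def test_mean_tracks_piecewise_truth(self):
        # 200 replicate experiments: per-level average mortality follows
        # the analytic piecewise line within Monte-Carlo error
        d = ts.make_design(salinity_treatments=(STABLE,))
        m = ts.preset_scenarios("stable_single_threshold")
        acc = []
        for i in range(200):
            obs = ts.simulate_experiment(d, m, bath_sd=0.0, seed=900 + i)
            acc.append(obs.groupby("nutrient_g")["mortality_pct"].mean())
        got = pd.concat(acc, axis=1).mean(axis=1)
        levels = got.index.to_numpy()
        truth = m.treatments[STABLE].mean(levels) * 100
        p = truth / 100
        mc_se = 100 * np.sqrt(p * (1 - p) / (15 * 5 * 200))
        assert np.all(np.abs(got.to_numpy() - truth) < 4 * np.maximum(
            mc_se, 1e-3))

    def test_variance_matches_binomial_law(self):
        # bath_sd = 0, no inflation: per-level variance approaches
        # p(1-p)/n * 100^2 (percent scale) as replicates grow
        d = ts.make_design(nutrient_levels=[0.0, 60.0, 120.0],
                           replicates=10_000, baths=1,
                           salinity_treatments=(STABLE,))
        m = ts.preset_scenarios("stable_single_threshold")
        obs = ts.simulate_experiment(d, m, bath_sd=0.0, seed=5)
        var = obs.groupby("nutrient_g")["mortality_pct"].var(ddof=1)
        p = m.treatments[STABLE].mean(var.index.to_numpy())
        expected = p * (1 - p) / 15 * 100 ** 2
        rel = np.abs(var.to_numpy() - expected) / expected
        assert np.all(rel < 0.05)

    def test_inflation_profile_peaks_at_breakpoint(self):
        m = ts.preset_scenarios("stable_single_threshold", inflation_sd=2.0,
                                inflation_window=20.0)
        prof = m.inflation_profile(STABLE, np.array([0.0, 55.0, 70.0, 90.0]))
        assert prof[0] == 0.0 and prof[3] == 0.0
        assert prof[2] == pytest.approx(2.0)
        assert 0 < prof[1] < prof[2]


class TestIO:
    def test_writer_roundtrip(self, tmp_path, two_stressor_obs):
        path = tmp_path / "exp.csv"
        write_experiment(two_stressor_obs, path)
        back = pd.read_csv(path)
        validate_observations(back)
        pd.testing.assert_frame_equal(
            back, two_stressor_obs.loc[:, back.columns.tolist()],
            check_dtype=False)

    def test_truth_sidecar(self, tmp_path):
        m = ts.preset_scenarios("intrusion_double_threshold")
        write_truth(m, 42, tmp_path / "truth.json")
        truth = json.loads((tmp_path / "truth.json").read_text())
        assert truth["seed"] == 42
        assert truth["treatments"]["intrusion"]["breakpoints"] == [26.91,
                                                                   84.13]

    def test_validate_rejects_bad_counts(self, two_stressor_obs):
        bad = two_stressor_obs.copy()
        bad.loc[3, "n_dead"] = bad.loc[3, "n_initial"] + 1
        with pytest.raises(ValueError, match="row"):
            validate_observations(bad)
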