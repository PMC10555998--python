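"""Interaction metrics, classification and the two-way test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tipstress as ts
from tipstress.interactions import BINS
from tipstress.synthetic import INTRUSION, STABLE, MeanModel, PiecewiseMean


class TestScalarMetrics:
    @pytest.mark.parametrize("mort,surv", [(0.0, 100.0), (100.0, 0.0),
                                           (37.5, 62.5)])
    def test_survival_conversion(self, mort, surv):
        assert ts.to_survival(mort) == surv

    def test_survival_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            ts.to_survival(101.0)
        with pytest.raises(ValueError):
            ts.to_survival(-0.5)

    @pytest.mark.parametrize("wx,wy,wxy,da", [
        (1.0, 1.0, 1.0, 0.0),
        (0.8, 0.5, 0.4, 0.0),       # exactly multiplicative
        (0.8, 0.5, 0.2, -0.2),
    ])
    def test_deviation_from_additivity(self, wx, wy, wxy, da):
        assert ts.deviation_from_additivity(wx, wy, wxy) == pytest.approx(da)

    @pytest.mark.parametrize("wx,wy,wxy,expected", [
        (0.8, 0.8, 0.0, -1.0),      # total mortality: extreme synergy
        (0.8, 0.5, 0.5, 1.0),       # combined equals strongest stressor
        (1.0, 1.0, 1.0, 0.0),
    ])
    def test_rescale_anchor_points(self, wx, wy, wxy, expected):
        assert ts.rescale_da(wx, wy, wxy) == pytest.approx(expected)

    def test_rescale_degenerate_flagged(self):
        val, degen = ts.rescale_da(0.0, 0.5, 0.4, return_degenerate=True)
        assert degen and val in (-1.0, 2.0)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(wx=st.floats(0, 1.5), wy=st.floats(0, 1.5), wxy=st.floats(0, 1.5))
    def test_rescale_bounded(self, wx, wy, wxy):
        assert -1.0 <= ts.rescale_da(wx, wy, wxy) <= 2.0

    @pytest.mark.parametrize("value,label", [
        (-1.0, "synergy"), (-0.7, "synergy"), (-0.5, "additive"),
        (0.0, "additive"), (0.5, "buffering"), (1.2, "buffering"),
        (1.3, "suppression"), (1.5, "suppression"), (2.0, "suppression"),
    ])
    def test_classification_bins(self, value, label):
        assert ts.classify_interaction(value) == label

    def test_classification_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            ts.classify_interaction(2.1)

    def test_bins_partition_without_gaps(self):
        edges = [b[0] for b in BINS] + [BINS[-1][1]]
        assert edges == sorted(edges)
        assert edges[0] == -1.0 and edges[-1] == 2.0
        for lo, hi in zip(edges[:-1], edges[1:]):
            assert lo < hi

    @pytest.mark.parametrize("n,sv,out", [(0.0, 0.0, 0.0), (1.0, 0.3, 1.0),
                                          (0.4, 0.3, 0.58)])
    def test_multiplicative_null_values(self, n, sv, out):
        assert ts.multiplicative_null(n, sv) == pytest.approx(out)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(n=st.floats(0, 1), sv=st.floats(0, 1), d=st.floats(0, 1))
    def test_multiplicative_null_symmetric_monotone_capped(self, n, sv, d):
        a = ts.multiplicative_null(n, sv)
        assert a == pytest.approx(ts.multiplicative_null(sv, n))
        assert a <= 1.0 + 1e-12
        hi = min(1.0, n + d)
        assert ts.multiplicative_null(hi, sv) >= a - 1e-12

    def test_null_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            ts.multiplicative_null(1.2, 0.1)

    def test_da_sign_matches_null_model_comparison(self):
        # DA < 0 exactly when observed combined mortality exceeds the
        # multiplicative-null prediction, for any survivals with W_0 > 0
        rng = np.random.default_rng(8)
        for _ in range(300):
            w0 = rng.uniform(10, 100)
            wx, wy, wxy = rng.uniform(0, 100, 3)
            da = ts.deviation_from_additivity(wx / w0, wy / w0, wxy / w0)
            null_mort = 1.0 - (wx / w0) * (wy / w0)  # relative scale
            obs_mort = 1.0 - wxy / w0
            if abs(da) > 1e-12:
                assert (da < 0) == (obs_mort > null_mort)


class TestInteractionTable:
    def test_identical_cells_all_additive(self, default_design):
        flat = MeanModel(treatments={STABLE: PiecewiseMean(0.3),
                                     INTRUSION: PiecewiseMean(0.3)})
        obs = ts.simulate_experiment(default_design, flat, bath_sd=0.0,
                                     seed=1)
        obs["mortality_pct"] = 30.0  # force exact equality of all cells
        tab = ts.interaction_table(obs)
        assert np.allclose(tab["DA"], 0.0)
        assert (tab["label"] == "additive").all()

    def test_scale_invariance_of_labels(self, two_stressor_obs):
        tab = ts.interaction_table(two_stressor_obs)
        # halving every survival (W -> W/2) leaves w, DA and labels alone
        scaled = two_stressor_obs.copy()
        scaled["mortality_pct"] = 100.0 - (100.0 -
                                           scaled["mortality_pct"]) / 2.0
        scaled = scaled.drop(columns=["n_initial", "n_dead"])
        tab2 = ts.interaction_table(scaled)
        assert np.allclose(tab["DA"], tab2["DA"], atol=1e-12)
        assert (tab["label"] == tab2["label"]).all()

    def test_missing_cell_named(self, two_stressor_obs):
        broken = two_stressor_obs[~(
            (two_stressor_obs.nutrient_g == 40.0)
            & (two_stressor_obs.salinity == INTRUSION))]
        with pytest.raises(ValueError, match="40"):
            ts.interaction_table(broken)

    def test_zero_control_survival_flagged(self, default_design):
        m = MeanModel(treatments={STABLE: PiecewiseMean(1.0),
                                  INTRUSION: PiecewiseMean(0.5)})
        obs = ts.simulate_experiment(default_design, m, bath_sd=0.0, seed=2)
        tab = ts.interaction_table(obs)
        assert (tab["label"] == "undefined").all()
        assert tab["DA"].isna().all()

    def test_null_surface_recovered(self):
        # combined cell mean on the Bliss surface: per-level DA within two
        # delta-method SEs in most runs, at every level
        d = ts.make_design()
        s0, ratio = 0.90, 0.80  # control survival; s_Y / s_0
        slope = 0.003
        m = MeanModel(treatments={
            STABLE: PiecewiseMean(1 - s0, slopes=(slope,)),
            INTRUSION: PiecewiseMean(1 - s0 * ratio, slopes=(slope * ratio,)),
        })
        inside = np.zeros(12)
        reps = 120
        for i in range(reps):
            obs = ts.simulate_experiment(d, m, bath_sd=0.0, seed=10_000 + i)
            tab = ts.interaction_table(obs)
            lv = tab["nutrient_g"].to_numpy()
            sx = s0 - slope * lv
            sy = s0 * ratio
            sxy = sx * ratio
            var = {k: p * (1 - p) / (15 * 5) for k, p in
                   (("0", 1 - s0), ("x", 1 - sx), ("y", 1 - sy),
                    ("xy", 1 - sxy))}
            g0 = sx * sy / s0 ** 3
            se = np.sqrt(var["xy"] / s0 ** 2 + (sy / s0 ** 2) ** 2 * var["x"]
                         + (sx / s0 ** 2) ** 2 * var["y"]
                         + g0 ** 2 * var["0"])
            inside += (np.abs(tab["DA"].to_numpy()) < 2 * se)
        assert np.all(inside / reps >= 0.9)

    def test_synergy_labels_recovered_at_low_levels(self):
        # combined survival pulled to a third of the Bliss expectation for
        # every level > 0 (the level-0 intrusion cell must stay at the true
        # salinity-only survival, since it defines w_Y): clear synergy
        # should be labelled at the low end
        d = ts.make_design()
        s0, ratio = 0.95, 0.85
        slope = 0.004
        m_at_0 = 1.0 - s0 * ratio
        s2 = ratio * slope / 3.0                      # slope for levels >= 10
        m_at_10 = 1.0 - (ratio / 3.0) * (s0 - slope * 10.0)
        s1 = (m_at_10 - m_at_0 - 5.0 * s2) / 5.0      # steep drop onto surface
        m = MeanModel(treatments={
            STABLE: PiecewiseMean(1 - s0, slopes=(slope,)),
            INTRUSION: PiecewiseMean(m_at_0, breakpoints=(5.0,),
                                     slopes=(s1, s2)),
        })
        low = slice(0, 3)  # levels 10..30 g
        hits = 0
        reps = 100
        for i in range(reps):
            obs = ts.simulate_experiment(d, m, bath_sd=0.0, seed=20_000 + i)
            tab = ts.interaction_table(obs)
            hits += (tab["label"].to_numpy()[low] == "synergy").all()
        assert hits / reps >= 0.9


class TestTwoWayTest:
    def test_pure_main_effect_gives_zero_f(self, default_design):
        obs = default_design.units().assign(
            n_initial=15,
            mortality_pct=lambda df: np.where(df.salinity == STABLE, 20.0,
                                              40.0))
        obs["n_dead"] = (obs["mortality_pct"] / 100 * 15).astype(int)
        res = ts.two_way_interaction_test(obs)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-9)
        assert res.pvalue == pytest.approx(1.0)

    def test_df_structure_on_reference_design(self, two_stressor_obs):
        res = ts.two_way_interaction_test(two_stressor_obs)
        assert res.df_num == 12  # (13 - 1) x (2 - 1)
        assert res.df_den == 130 - 26

    def test_detects_strong_interaction(self, two_stressor_obs):
        res = ts.two_way_interaction_test(two_stressor_obs)
        assert res.pvalue < 0.01

    def test_requires_replication(self, default_design):
        obs = ts.simulate_experiment(
            ts.make_design(replicates=1), ts.preset_scenarios("null_flat"),
            seed=3)
        with pytest.raises(ValueError):
            ts.two_way_interaction_test(obs)

    def test_bath_component_reported(self, two_stressor_obs):
        res = ts.two_way_interaction_test(two_stressor_obs)
        assert res.bath_lrt >= 0.0
        assert 0.0 < res.bath_pvalue <= 1.0
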