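"""Deviation-from-control response variables and realized heritability."""

import numpy as np
import pandas as pd
import pytest

from allomsel import (
    HeritabilityEstimate,
    aggregate_h2,
    control_reference_fits,
    divergence_range,
    line_deviation_table,
    realized_h2,
    response_series,
    trend_test,
)
from allomsel.errors import AllomselError, MissingControlError, SingularRegressionError
from allomsel.response import ResponseSeries
from conftest import morph_from_logpoints


def _dev_table(rows):
    return pd.DataFrame(rows, columns=["replicate", "generation", "line",
                                       "dev_gono_pct"])


def _series(S_c, R, **kw):
    S_c, R = np.asarray(S_c, float), np.asarray(R, float)
    defaults = dict(replicate="A", line="up",
                    generations=np.arange(1, S_c.size + 1), R=R, S_c=S_c,
                    residual_mode="vertical", fit_method="OLS",
                    weighting="unweighted")
    defaults.update(kw)
    return ResponseSeries(**defaults)


class TestControlReferenceFits:
    def test_one_fit_per_cell(self, default_sim):
        fits = control_reference_fits(default_sim.morph)
        assert len(fits) == 27   # 3 replicates x 9 generations
        assert all(f.method == "RMA" for f in fits.values())
        ns = [f.n for f in fits.values()]
        assert all(n == default_sim.config.n_measured_control for n in ns)

    def test_missing_control_cell_named(self, small_sim):
        m = small_sim.morph
        broken = m[~((m.line == "control") & (m.generation == 2)
                     & (m.replicate == "A"))]
        with pytest.raises(MissingControlError, match="generation 2"):
            control_reference_fits(broken)

    def test_recovers_generating_slope(self, default_sim):
        cfg = default_sim.config
        fits = control_reference_fits(default_sim.morph, method="OLS")
        slopes = np.array([f.slope for f in fits.values()])
        ses = np.array([f.se_slope for f in fits.values()])
        z = (slopes - cfg.beta) / ses
        # each control fit should sit near the generating slope
        assert np.mean(np.abs(z) < 3) > 0.95


class TestLineDeviationTable:
    def test_control_vs_itself_is_zero(self, small_sim):
        dev = line_deviation_table(small_sim.morph)
        ctrl = dev[dev.line == "control"]
        assert np.allclose(ctrl.dev_gono_mm, 0)
        assert np.allclose(ctrl.dev_gono_pct, 0)
        assert np.allclose(ctrl.mean_sl_dev_mm, 0)
        assert np.allclose(ctrl.rma_slope_dev, 0)

    def test_no_selection_deviations_fluctuate_about_zero(self):
        from allomsel.simulate import SimConfig, simulate_experiment
        # all lines bred at random: deviations are pure sampling noise
        cfg = SimConfig(seed=21, n_generations=5)
        res = simulate_experiment(cfg)
        m = res.morph.copy()
        # relabel so the pipeline sees up/down labels but selection was on
        # the control template: instead, simulate with h2_d = 0 so selection
        # cannot produce genetic change
        cfg0 = SimConfig(seed=21, n_generations=5, h2_d=0.0)
        dev = line_deviation_table(simulate_experiment(cfg0).morph)
        sel = dev[dev.line != "control"]
        assert abs(sel.dev_gono_pct.mean()) < 0.5
        del m, res

    def test_sparse_cell_excluded_with_warning(self, small_sim, caplog):
        m = small_sim.morph
        cell = (m.line == "up") & (m.generation == 3) & (m.replicate == "A")
        thinned = pd.concat([m[~cell], m[cell].head(2)])
        with caplog.at_level("WARNING"):
            dev = line_deviation_table(thinned)
        assert not ((dev.line == "up") & (dev.generation == 3)
                    & (dev.replicate == "A")).any()
        assert any("excluded" in r.message for r in caplog.records)


class TestDivergenceRange:
    def test_all_zero(self):
        t = _dev_table([(r, 9, l, 0.0) for r in "ABC" for l in ("up", "down")])
        assert divergence_range(t) == (0.0, 0.0)

    def test_symmetric_five_percent(self):
        t = _dev_table([(r, 9, "up", 5.0) for r in "ABC"]
                       + [(r, 9, "down", -5.0) for r in "ABC"])
        assert divergence_range(t) == (10.0, 10.0)

    def test_missing_line_rejected(self):
        t = _dev_table([("A", 9, "up", 5.0), ("B", 9, "up", 4.0),
                        ("B", 9, "down", -3.0), ("C", 9, "up", 2.0),
                        ("C", 9, "down", -1.0), ("A", 9, "down", -2.0)])
        assert divergence_range(t) == (3.0, 7.0)
        with pytest.raises(AllomselError):
            divergence_range(t[t.line != "down"])

    def test_multiple_generations_rejected(self):
        t = _dev_table([("A", 8, "up", 5.0), ("A", 9, "down", -5.0)])
        with pytest.raises(ValueError):
            divergence_range(t)


class TestResponseSeries:
    def test_control_template_has_exactly_zero_response(self, small_sim):
        # a "focal" line that *is* the control: vertical-OLS residuals from
        # a fit to the very same males average to zero identically
        ctrl = small_sim.morph[small_sim.morph.line == "control"].copy()
        focal = ctrl.copy()
        focal["line"] = "up"
        focal["fish_id"] = focal["fish_id"] + "-twin"
        series = response_series(pd.concat([ctrl, focal]), rounds=[],
                                 residual_mode="vertical")
        for s in series.values():
            np.testing.assert_allclose(s.R, 0.0, atol=1e-12)
            np.testing.assert_allclose(s.S_c, 0.0)

    def test_first_generation_pairs_with_zero_cumulative(self, default_sim):
        series = response_series(default_sim.morph, default_sim.rounds)
        for s in series.values():
            assert s.generations[0] == 1
            assert s.S_c[0] == 0.0
            assert s.S_c.size == s.R.size == 9
        up = [s for (r, l), s in series.items() if l == "up"]
        down = [s for (r, l), s in series.items() if l == "down"]
        assert all(np.all(np.diff(s.S_c) > 0) for s in up)
        assert all(np.all(np.diff(s.S_c) < 0) for s in down)

    def test_simulator_truth_tracks_response(self, default_sim):
        # R_t should follow the true genetic divergence focal - control
        series = response_series(default_sim.morph, default_sim.rounds,
                                 residual_mode="vertical")
        truth = default_sim.truth.set_index(["replicate", "line", "generation"])
        for (rep, line), s in series.items():
            true_dev = np.array([
                truth.loc[(rep, line, g), "mean_g_d"]
                - truth.loc[(rep, "control", g), "mean_g_d"]
                for g in s.generations
            ])
            resid = s.R - true_dev
            # sampling noise of a cohort mean, a few x sigma_d / sqrt(n)
            assert np.all(np.abs(resid) < 0.006)

    def test_unknown_mode_rejected(self, small_sim):
        with pytest.raises(ValueError):
            response_series(small_sim.morph, [], residual_mode="diagonal")


class TestRealizedH2:
    def test_noiseless_slope_doubling(self):
        S_c = np.array([0.0, 0.5, 1.0, 1.5, 2.0])
        est = realized_h2(_series(S_c, 0.014 * S_c))
        assert est.h2 == pytest.approx(0.028)
        assert est.r_squared == pytest.approx(1.0)

    def test_h2_is_twice_slope_identity(self, default_sim):
        series = response_series(default_sim.morph, default_sim.rounds)
        for s in series.values():
            est = realized_h2(s)
            assert est.h2 == 2.0 * est.slope

    def test_through_origin_flag(self):
        S_c = np.array([0.0, 1.0, 2.0, 3.0])
        R = 0.02 * S_c + 0.005
        with_int = realized_h2(_series(S_c, R), include_intercept=True)
        origin = realized_h2(_series(S_c, R), include_intercept=False)
        assert with_int.slope == pytest.approx(0.02)
        assert origin.slope != pytest.approx(0.02, abs=1e-4)

    def test_constant_regressor_rejected(self):
        with pytest.raises(SingularRegressionError):
            realized_h2(_series([1.0, 1.0, 1.0], [0.0, 0.1, 0.2]))

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            realized_h2(_series([0.0, 1.0], [0.0, 0.1]))


class TestAggregateH2:
    def test_mean_and_se_across_replicates(self):
        ests = [HeritabilityEstimate(h / 2, h, 0.0, 1.0, 9, "vertical",
                                     "unweighted") for h in (0.02, 0.03, 0.04)]
        mean, se = aggregate_h2(ests)
        assert mean == pytest.approx(0.03)
        assert se == pytest.approx(np.std([0.02, 0.03, 0.04], ddof=1)
                                   / np.sqrt(3))


class TestTrendTest:
    def _table(self, fn, gens=9):
        rows = []
        for rep in "ABC":
            for g in range(1, gens + 1):
                rows.append({"replicate": rep, "generation": g, "line": "up",
                             "dev_gono_pct": fn(rep, g)})
        return pd.DataFrame(rows)

    def test_constant_deviations_give_zero_f(self):
        out = trend_test(self._table(lambda r, g: 1.7))
        assert out["generation"]["F"] == pytest.approx(0.0)

    def test_df_pattern_for_27_cells(self):
        rng = np.random.default_rng(3)
        out = trend_test(self._table(lambda r, g: 0.5 * g + rng.normal()))
        assert (out["generation"]["df_num"], out["generation"]["df_den"]) == (1, 21)
        assert (out["replicate"]["df_num"], out["replicate"]["df_den"]) == (2, 21)
        assert out["generation"]["p"] < 0.001

    def test_matches_statsmodels_type3(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(8)
        offs = {"A": 0.0, "B": 0.4, "C": -0.2}
        t = self._table(lambda r, g: 0.3 * g + offs[r] + rng.normal(0, 0.3))
        out = trend_test(t)
        fit = smf.ols("dev_gono_pct ~ generation * C(replicate, Sum)",
                      data=t).fit()
        a = sm.stats.anova_lm(fit, typ=3)
        assert out["generation"]["F"] == pytest.approx(
            a.loc["generation", "F"], rel=1e-8)
        assert out["replicate"]["F"] == pytest.approx(
            a.loc["C(replicate, Sum)", "F"], rel=1e-8)
        assert out["interaction"]["F"] == pytest.approx(
            a.loc["generation:C(replicate, Sum)", "F"], rel=1e-8)

    def test_rank_deficiency_reported(self):
        t = self._table(lambda r, g: 0.1 * g, gens=2)
        with pytest.raises((AllomselError, ValueError)):
            trend_test(t)
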