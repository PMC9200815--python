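import math

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

import hdxfda as h
from hdxfda.kinetics import InsufficientObservationsError
from hdxfda.testing import CannotModerateError, DegreesOfFreedom, NestedFitPair

from conftest import make_long_table


def make_pair(rss0, rss1, n_obs=24):
    """A NestedFitPair stub carrying only the quantities the statistics use."""
    return NestedFitPair(null_fit=None, alt_fits={}, rss0=rss0, rss1=rss1, n_obs=n_obs)


class TestDegreesOfFreedom:
    @pytest.mark.parametrize(
        "spec, C, expected",
        [
            (h.ModelSpec("exponential"), 2, (3, 6, 3)),
            (h.ModelSpec("weibull"), 2, (4, 8, 4)),
            (h.ModelSpec("weibull", fixed={"b": 0.5, "q": 1.0, "d": 0.0}), 2, (1, 2, 1)),
            (h.ModelSpec("weibull"), 3, (4, 12, 8)),
        ],
    )
    def test_parameter_counts(self, spec, C, expected):
        dof = h.testing.degrees_of_freedom(spec, C, n_obs=40)
        assert (dof.p1, dof.p2, dof.d1) == expected
        assert dof.d2 == 40 - dof.p2

    def test_insufficient_observations(self):
        with pytest.raises(InsufficientObservationsError):
            h.testing.degrees_of_freedom(h.ModelSpec("weibull"), 2, n_obs=8)


class TestFStatistic:
    def test_equal_rss_gives_zero(self):
        dof = DegreesOfFreedom(p1=4, p2=8, d1=4, d2=16)
        assert h.f_statistic(make_pair(1.0, 1.0), dof) == 0.0

    def test_direct_arithmetic(self):
        dof = DegreesOfFreedom(p1=3, p2=6, d1=3, d2=6)
        assert h.f_statistic(make_pair(2.0, 1.0), dof) == pytest.approx(2.0, rel=1e-14)

    def test_perfect_alternative_flags_infinity(self):
        dof = DegreesOfFreedom(p1=3, p2=6, d1=3, d2=6)
        assert math.isinf(h.f_statistic(make_pair(1.0, 0.0), dof))

    def test_matches_brute_force_from_residuals(self, two_condition_dataset):
        """F recomputed from raw residuals must agree to 1e-10 relative."""
        ds = two_condition_dataset
        spec = h.ModelSpec("weibull")
        pair = h.nested_fit(ds, ds.analyte_ids[0], spec)
        dof = h.testing.degrees_of_freedom(spec, 2, pair.n_obs)
        f_fast = h.f_statistic(pair, dof)

        sub = ds.analyte_table(ds.analyte_ids[0])
        t = sub["exposure_s"].to_numpy(float)
        y = sub["value"].to_numpy(float)
        rss0 = float(np.sum((y - pair.null_fit.predict(t)) ** 2))
        rss1 = 0.0
        for cond, fit in pair.alt_fits.items():
            m = (sub["condition"] == cond).to_numpy()
            rss1 += float(np.sum((y[m] - fit.predict(t[m])) ** 2))
        f_brute = (dof.d2 / dof.d1) * (rss0 - rss1) / rss1
        assert f_fast == pytest.approx(f_brute, rel=1e-10)


class TestModeration:
    def test_zero_prior_df_returns_sample_variance(self):
        # d0 = 0 in the shrinkage formula leaves s_i^2 untouched
        s = (0.0 * 1.0 + 16 * 3.0) / (0.0 + 16)
        assert s == 3.0

    def test_equal_weights_average(self):
        hyper = h.EBHyperparams(d0=16.0, s0_sq=1.0)
        assert h.moderate_variance(3.0, 16, hyper) == pytest.approx(2.0)

    def test_infinite_prior_df_fully_shrinks(self):
        hyper = h.EBHyperparams(d0=math.inf, s0_sq=0.42)
        assert h.moderate_variance(123.0, 16, hyper) == 0.42

    def test_shrinkage_stays_between_sample_and_prior(self, rng):
        hyper = h.EBHyperparams(d0=4.0, s0_sq=0.01)
        for s2 in rng.uniform(0.001, 0.1, size=50):
            s_tilde = h.moderate_variance(float(s2), 16, hyper)
            assert min(s2, 0.01) - 1e-15 <= s_tilde <= max(s2, 0.01) + 1e-15

    def test_moderated_f_reduces_to_ordinary_f_at_sample_variance(self):
        # with s~^2 = rss1/d2 the moderated statistic equals Eq.-7 F exactly
        pair = make_pair(2.0, 1.0)
        dof = DegreesOfFreedom(p1=4, p2=8, d1=4, d2=16)
        s2 = pair.rss1 / dof.d2
        assert h.moderated_f(pair, dof, s2) == pytest.approx(
            h.f_statistic(pair, dof), rel=1e-14
        )

    def test_moderated_f_arithmetic(self):
        pair = make_pair(2.0, 1.0)
        dof = DegreesOfFreedom(p1=3, p2=6, d1=3, d2=6)
        assert h.moderated_f(pair, dof, 0.2) == pytest.approx(5.0 / 3.0, rel=1e-14)
        assert h.moderated_f(make_pair(1.0, 1.0), dof, 0.2) == 0.0


class TestEBHyperparams:
    def test_identical_variances_give_infinite_prior_df(self):
        hyper = h.estimate_eb_hyperparams([0.02] * 10, [16] * 10)
        assert math.isinf(hyper.d0)
        assert hyper.s0_sq == pytest.approx(0.02, rel=1e-9)

    def test_monte_carlo_recovery(self):
        """5000 draws from s0^2 F(d2=8, d0=4) recover the hyperparameters."""
        rng = np.random.default_rng(42)
        s0_sq, d0, d2 = 0.01, 4.0, 8
        draws = s0_sq * stats.f.rvs(d2, d0, size=5000, random_state=rng)
        hyper = h.estimate_eb_hyperparams(draws, np.full(5000, d2))
        assert abs(hyper.d0 - d0) / d0 <= 0.25
        assert abs(hyper.s0_sq - s0_sq) / s0_sq <= 0.10

    def test_single_variance_cannot_moderate(self):
        with pytest.raises(CannotModerateError):
            h.estimate_eb_hyperparams([0.02], [16])

    def test_trigamma_inversion_is_exact(self):
        from hdxfda.testing import _trigamma_inverse

        for x in (0.1, 0.5, 2.0, 10.0, 100.0):
            y = float(special.polygamma(1, x))
            assert _trigamma_inverse(y) == pytest.approx(x, rel=1e-6)


class TestFPvalue:
    def test_zero_statistic_gives_one(self):
        assert h.f_pvalue(0.0, 3, 16) == 1.0

    def test_symmetric_f_at_one_gives_half(self):
        # F(k, k) is symmetric about 1 under reciprocal; P(F > 1) = 1/2,
        # checked against the regularised incomplete beta directly.
        for k in (2, 5, 9):
            p = h.f_pvalue(1.0, k, k)
            beta_tail = float(special.betainc(k / 2, k / 2, 0.5))
            assert p == pytest.approx(0.5, abs=1e-12)
            assert p == pytest.approx(beta_tail, abs=1e-12)

    def test_tail_monotone_in_statistic(self):
        ps = [h.f_pvalue(f, 4, 20) for f in (0.5, 1.0, 2.0, 5.0, 50.0)]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        assert ps[-1] < 1e-6

    def test_infinite_statistic_gives_zero(self):
        assert h.f_pvalue(math.inf, 4, 20) == 0.0

    def test_infinite_denominator_uses_chi2_limit(self):
        p = h.f_pvalue(2.0, 4, math.inf)
        assert p == pytest.approx(float(stats.chi2.sf(8.0, 4)), rel=1e-12)


class TestBenjaminiHochberg:
    def test_hand_computed_example(self):
        out = h.adjust_bh([0.01, 0.02, 0.03])
        assert np.allclose(out, [0.03, 0.03, 0.03])

    def test_all_ones_unchanged(self):
        assert np.allclose(h.adjust_bh([1.0, 1.0, 1.0]), 1.0)

    def test_single_value_unchanged(self):
        assert h.adjust_bh([0.2])[0] == pytest.approx(0.2)

    def test_nan_propagates_outside_family(self):
        out = h.adjust_bh([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        # family size is 2, not 3
        assert out[0] == pytest.approx(0.02)

    def test_monotone_in_rank_and_capped(self, rng):
        p = rng.uniform(size=50)
        out = h.adjust_bh(p)
        order = np.argsort(p)
        assert np.all(np.diff(out[order]) >= -1e-12)
        assert out.max() <= 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            h.adjust_bh([0.5, 1.5])


class TestNestedFit:
    def test_identical_conditions_give_near_zero_f(self):
        times = np.array([0.0, 30.0, 240.0, 1800.0])
        params = h.KineticParams(a=6.0, b=0.01, q=1.0, d=500.0)
        rows = []
        for cond in "AB":
            for rep in "12":
                for t in times:
                    rows.append(("PEPK", 1, 4, 1, cond, rep, t, h.evaluate_model(params, t)))
        ds = h.HDXDataset(make_long_table(rows))
        pair = h.nested_fit(ds, ds.analyte_ids[0])
        dof = h.testing.degrees_of_freedom(h.ModelSpec(), 2, pair.n_obs)
        # identical data: both models fit (near) perfectly -> F ~ 0 or inf-flag
        assert pair.rss0 == pytest.approx(pair.rss1, abs=1e-6)

    def test_distinct_curves_separate_cleanly(self, two_condition_dataset):
        ds = two_condition_dataset
        pair = h.nested_fit(ds, ds.analyte_ids[0])
        assert pair.rss1 <= 1e-4
        assert pair.rss0 > 100 * max(pair.rss1, 1e-12)

    def test_condition_entirely_missing(self):
        times = np.array([0.0, 30.0, 240.0, 1800.0])
        rows = [
            ("PEPK", 1, 4, 1, "A", rep, t, 1.0 + t / 1000)
            for rep in "12"
            for t in times
        ]
        rows += [("PEPK", 1, 4, 1, "B", "1", t, np.nan) for t in times]
        ds = h.HDXDataset(make_long_table(rows))
        with pytest.raises(InsufficientObservationsError):
            h.nested_fit(ds, ds.analyte_ids[0])

    def test_nesting_holds_after_fallback(self, small_simulated):
        dataset, _ = small_simulated
        for analyte_id in dataset.analyte_ids[:10]:
            pair = h.nested_fit(dataset, analyte_id)
            assert pair.rss1 <= pair.rss0 + 1e-6


class TestRunFunctionalTest:
    def test_single_condition_errors(self):
        rows = [("PEPK", 1, 4, 1, "A", "1", t, v) for t, v in [(0.0, 1.0), (30.0, 2.0)]]
        ds = h.HDXDataset(make_long_table(rows))
        with pytest.raises(ValueError, match="single condition"):
            h.run_functional_test(ds)

    def test_spiked_analyte_ranks_first(self, small_simulated):
        """An analyte given a large condition shift attains the smallest p."""
        dataset, _ = small_simulated
        table = dataset.table.drop(columns=["analyte_id"]).copy()
        target = dataset.analyte_ids[0]
        seq = dataset.annotations().set_index("analyte_id").loc[target]
        mask = (
            (table["analyte_sequence"] == seq["analyte_sequence"])
            & (table["charge"] == seq["charge"])
            & (table["condition"] == "B")
            & (table["exposure_s"] > 0)
        )
        table.loc[mask, "value"] += 40.0
        res = h.run_functional_test(h.HDXDataset(table))
        best = res.loc[res["p_adjusted"].idxmin(), "analyte_id"]
        assert best == target

    def test_status_and_pvalue_contracts(self, small_results):
        res = small_results
        ok = res["status"] == "ok"
        assert ok.any()
        assert (res.loc[ok, "F"] >= 0).all()
        assert res.loc[ok, "p_value"].between(0, 1).all()
        assert (res.loc[ok, "p_adjusted"] >= res.loc[ok, "p_value"] - 1e-12).all()

    def test_moderation_shrinkage_invariant(self, small_simulated):
        dataset, _ = small_simulated
        tester = h.FunctionalHdxTest().fit(dataset)
        res = tester.results_
        ok = res["status"] == "ok"
        s0 = tester.eb_.s0_sq
        lo = np.minimum(res.loc[ok, "s2"], s0)
        hi = np.maximum(res.loc[ok, "s2"], s0)
        s_tilde = res.loc[ok, "s2_moderated"]
        assert ((s_tilde >= lo - 1e-15) & (s_tilde <= hi + 1e-15)).all()

    def test_unmoderated_equals_plain_f_test(self, small_simulated):
        dataset, _ = small_simulated
        res = h.run_functional_test(dataset, moderation=False)
        ok = res["status"] == "ok"
        expected = [
            h.f_pvalue(f, d1, d2)
            for f, d1, d2 in zip(res.loc[ok, "F"], res.loc[ok, "d1"], res.loc[ok, "d2"])
        ]
        assert np.allclose(res.loc[ok, "p_value"], expected, rtol=0, atol=0)

    def test_three_condition_anova(self):
        """With C = 3 the alternative has 3k parameters and the test runs."""
        times = np.array([0.0, 30.0, 240.0, 1800.0, 14400.0])
        rng = np.random.default_rng(5)
        rows = []
        for cond, b in [("A", 0.01), ("B", 0.01), ("C", 0.0005)]:
            params = h.KineticParams(a=8.0, b=b, q=1.0, d=700.0)
            for rep in "123":
                for t in times:
                    rows.append(
                        ("PEPK", 1, 4, 1, cond, rep, t,
                         h.evaluate_model(params, t) + rng.normal(0, 0.05))
                    )
        ds = h.HDXDataset(make_long_table(rows))
        res = h.run_functional_test(ds, moderation=False)
        row = res.iloc[0]
        assert row["d1"] == 8  # p2 - p1 = 12 - 4
        assert row["d2"] == len(times) * 9 - 12
        assert row["p_value"] < 1e-4

    def test_sklearn_estimator_contract(self):
        from sklearn.base import clone

        tester = h.FunctionalHdxTest(form="exponential", fdr=0.01)
        assert tester.get_params()["form"] == "exponential"
        assert clone(tester).get_params() == tester.get_params()
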