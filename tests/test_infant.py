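"""Looking-time statistics: t-tests, Bayes factors, sign tests, generator."""

import math

import numpy as np
import pytest
from scipy import stats

from skelshape.infant import (DegenerateDataError, MAX_HABITUATION_TRIALS,
                              infant_habituation_met, jzs_bayes_factor,
                              paired_t, run_infant_analysis,
                              sign_binomial_test, subsample_effect_ci,
                              synth_looking_times)


class TestInfantCriterion:
    def test_decaying_sequence_met(self):
        assert infant_habituation_met([20, 18, 16, 14, 8, 7, 6, 5])

    def test_constant_sequence_not_met(self):
        assert not infant_habituation_met([12.0] * 10)


class TestPairedT:
    def test_closed_form_small_sample(self):
        res = paired_t([2, 4, 6], [1, 2, 3], d_ci_iterations=10)
        assert res.t == pytest.approx(2 * np.sqrt(3))
        assert res.df == 2
        assert res.d == pytest.approx(2.0)
        assert res.p == pytest.approx(2 * stats.t.sf(2 * np.sqrt(3), 2))

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_d_is_t_over_sqrt_n(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(1, 1, 20), rng.normal(0, 1, 20)
        res = paired_t(x, y, d_ci_iterations=10)
        assert res.d == pytest.approx(res.t / np.sqrt(20))

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(1, 1, 15), rng.normal(0, 1, 15)
        ref = stats.ttest_rel(x, y)
        res = paired_t(x, y, d_ci_iterations=10)
        assert res.t == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)


def jzs_oracle(t, n, r=0.707):
    """Independent fixed-grid (trapezoid) integration of the same marginal
    likelihood ratio, for cross-validation of the adaptive quadrature."""
    nu = n - 1
    delta = np.linspace(-12, 12, 200_001)
    alt = np.trapezoid(stats.nct.pdf(t, nu, delta * np.sqrt(n))
                       * stats.cauchy.pdf(delta, 0, r), delta)
    return alt / stats.t.pdf(t, nu)


class TestJZSBayesFactor:
    def test_matches_fixed_grid_oracle_at_null_t(self):
        bf = jzs_bayes_factor(0.0, 34)
        assert bf < 1.0
        assert bf == pytest.approx(jzs_oracle(0.0, 34), rel=1e-4)

    @pytest.mark.parametrize("t,n", [(1.3, 12), (2.5, 40), (-2.0, 25)])
    def test_matches_fixed_grid_oracle(self, t, n):
        assert jzs_bayes_factor(t, n) == pytest.approx(jzs_oracle(t, n), rel=1e-4)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        for t, n in ((3.04, 34), (1.0, 34), (2.6, 48)):
            ref = float(pingouin.bayesfactor_ttest(t, n, paired=True))
            assert jzs_bayes_factor(t, n) == pytest.approx(ref, rel=1e-6)

    def test_strictly_increasing_in_abs_t(self):
        ts = np.linspace(0.0, 5.0, 11)
        bfs = [jzs_bayes_factor(t, 30) for t in ts]
        assert np.all(np.diff(bfs) > 0)

    def test_never_exactly_one(self):
        for t in np.linspace(0.0, 4.0, 9):
            for n in (10, 34, 48):
                assert jzs_bayes_factor(t, n) != 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            jzs_bayes_factor(np.inf, 34)
        with pytest.raises(ValueError):
            jzs_bayes_factor(1.0, 1)


class TestSignTest:
    def test_even_split_capped_at_one(self):
        assert sign_binomial_test(8, 16).p == 1.0

    def test_fourteen_of_sixteen_exact_fraction(self):
        res = sign_binomial_test(14, 16)
        assert res.p == pytest.approx(274 / 65536)
        assert round(res.p, 3) == 0.004

    def test_full_enumeration_oracle_25_of_34(self):
        # exact tail by integer arithmetic
        tail = sum(math.comb(34, k) for k in range(25, 35))
        assert tail == 77663192
        assert sign_binomial_test(25, 34).p == pytest.approx(2 * tail / 2 ** 34)

    def test_symmetry(self):
        for n in (10, 16, 34):
            for k in range(n + 1):
                assert sign_binomial_test(k, n).p == \
                    pytest.approx(sign_binomial_test(n - k, n).p)

    def test_minlike_agrees_under_fair_coin(self):
        # the null is symmetric, so doubled-tail and min-likelihood coincide
        for k, n in ((14, 16), (25, 34), (3, 10)):
            assert sign_binomial_test(k, n, "double").p == \
                pytest.approx(sign_binomial_test(k, n, "minlike").p)


class TestSubsampleEffectCI:
    def test_full_sample_zero_width(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(1, 1, 20), rng.normal(0, 1, 20)
        lo, hi, skipped = subsample_effect_ci(x, y, 20, iterations=10, seed=0)
        d = paired_t(x, y, d_ci_iterations=10).d
        assert lo == hi == pytest.approx(d)
        assert skipped == 0

    def test_constant_differences_degenerate(self):
        x = np.arange(10.0)
        with pytest.raises(DegenerateDataError):
            subsample_effect_ci(x + 1.0, x, 10, iterations=10, seed=0)
        # smaller target: every draw has zero variance too -> all skipped
        with pytest.raises(DegenerateDataError):
            subsample_effect_ci(x + 1.0, x, 5, iterations=20, seed=0)

    def test_target_larger_than_sample_rejected(self):
        with pytest.raises(ValueError):
            subsample_effect_ci([1, 2], [0, 1], 3)

    def test_interval_brackets_the_full_sample_effect(self):
        """Subsampling without replacement spreads estimates around the
        full-sample d (its actual guarantee — the subsample distribution is
        centred on the observed sample, not the population), so the interval
        brackets the full-sample d in essentially every replication and
        carries the true d = 0.5 well inside its typical range."""
        hits_sample_d, lows, highs = 0, [], []
        n_rep = 100
        for k in range(n_rep):
            rng = np.random.default_rng(10_000 + k)
            diff = rng.normal(0.5, 1.0, 48)
            d_full = paired_t(diff, np.zeros(48), d_ci_iterations=1).d
            lo, hi, _ = subsample_effect_ci(diff, np.zeros(48), 34,
                                            iterations=400, seed=k)
            hits_sample_d += lo <= d_full <= hi
            lows.append(lo)
            highs.append(hi)
        assert hits_sample_d / n_rep >= 0.95
        assert np.mean(lows) < 0.5 < np.mean(highs)


class TestSynthLookingTimes:
    def test_schema_and_caps(self):
        df = synth_looking_times(10, seed=0)
        assert set(df.columns) == {"infant_id", "age_months", "phase",
                                   "trial_index", "trial_type", "looking_time",
                                   "valid"}
        hab = df[df["phase"] == "habituation"]
        assert hab["trial_index"].max() <= MAX_HABITUATION_TRIALS
        test = df[df["phase"] == "test"]
        assert (test.groupby("infant_id").size() == 6).all()
        # alternating types, 3 per type
        per_type = test.groupby(["infant_id", "trial_type"]).size()
        assert (per_type == 3).all()

    def test_deterministic_given_seed(self):
        a = synth_looking_times(8, seed=5)
        b = synth_looking_times(8, seed=5)
        assert a.equals(b)

    def test_habituation_criterion_respected(self):
        df = synth_looking_times(20, seed=1, invalid_rate=0.0)
        for _, g in df[df["phase"] == "habituation"].groupby("infant_id"):
            lt = g.sort_values("trial_index")["looking_time"].tolist()
            if len(lt) < MAX_HABITUATION_TRIALS:
                assert infant_habituation_met(lt)      # stopped because met
                # and not met at any earlier trial
                for k in range(8, len(lt)):
                    assert not infant_habituation_met(lt[:k])

    def test_null_effect_recovers_near_zero_d(self):
        """novelty_effect_d = 0, n = 200: |recovered d| < 0.15 in >= 90% of
        runs (the sampling SD of d at this n is ~0.07, so the band holds with
        margin; at smaller n the same band is not statistically attainable)."""
        hits = 0
        n_rep = 100
        for k in range(n_rep):
            df = synth_looking_times(200, novelty_effect_d=0.0, seed=20_000 + k,
                                     invalid_rate=0.0)
            test = df[df["phase"] == "test"]
            per = test.pivot_table(index="infant_id", columns="trial_type",
                                   values="looking_time")
            res = paired_t(per["different-skeleton"], per["same-skeleton"],
                           d_ci_iterations=1)
            hits += abs(res.d) < 0.15
        assert hits / n_rep >= 0.90

    def test_recovery_of_moderate_effect(self):
        """novelty_effect_d = 0.5, n = 200: recovered d in [0.3, 0.7] in
        >= 90% of seeded runs."""
        hits = 0
        n_rep = 100
        for k in range(n_rep):
            df = synth_looking_times(200, novelty_effect_d=0.5, seed=30_000 + k,
                                     invalid_rate=0.0)
            test = df[df["phase"] == "test"]
            per = test.pivot_table(index="infant_id", columns="trial_type",
                                   values="looking_time")
            res = paired_t(per["different-skeleton"], per["same-skeleton"],
                           d_ci_iterations=1)
            hits += 0.3 <= res.d <= 0.7
        assert hits / n_rep >= 0.90


class TestRunInfantAnalysis:
    def test_strong_effect_detected_with_power(self):
        """novelty d = 0.8, n = 48: the different-skeleton dishabituation
        contrast is significant at alpha = .05 in >= 90% of runs."""
        hits = 0
        n_rep = 50
        for k in range(n_rep):
            df = synth_looking_times(48, novelty_effect_d=0.8, seed=40_000 + k)
            rep = run_infant_analysis(df, bootstrap_iterations=100, seed=k)
            hits += rep["contrasts"]["test_diff_vs_same"].p < 0.05
        assert hits / n_rep >= 0.90

    def test_null_effect_sign_test_near_even(self):
        df = synth_looking_times(100, novelty_effect_d=0.0, seed=7)
        rep = run_infant_analysis(df, bootstrap_iterations=100, seed=0)
        st_res = rep["sign_tests"]["test_diff_vs_same"]
        assert abs(st_res.k - st_res.n / 2) <= 0.15 * st_res.n

    def test_report_structure_complete(self):
        df = synth_looking_times(24, seed=3)
        rep = run_infant_analysis(df, bootstrap_iterations=200, seed=0)
        for name in ("test_diff_vs_same", "dishabituation_diff",
                     "dishabituation_same", "first_trial_same",
                     "first_trial_diff", "first_trial_between_groups"):
            assert name in rep["contrasts"]
        res = rep["contrasts"]["test_diff_vs_same"]
        assert res.bf10 > 0 and 0 <= res.p <= 1
        assert rep["classification"] is not None
        assert 0 <= rep["classification"].score <= 1

    def test_empty_input_rejected(self):
        import pandas as pd
        with pytest.raises(ValueError):
            run_infant_analysis(pd.DataFrame())
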