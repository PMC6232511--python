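"""Multistep-regression estimator tests: slopes, fits, invariance, CIs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import reverbkit as rk
from reverbkit.process import ProcessParams, SubsampleSpec


class TestLagSlopes:
    def test_iid_trace_has_no_significant_slopes(self, iid_trace):
        tab = rk.lag_slopes(iid_trace, 5)
        assert np.all(np.abs(tab["slope"]) < 3 * tab["se"])

    def test_full_sampling_slopes_decay_as_m_to_k(self, trace_m09):
        tab = rk.lag_slopes(trace_m09, 3)
        for lag, slope, se in tab.itertuples(index=False):
            # nominal OLS SE understates under serial dependence; allow
            # a dependence inflation factor ~sqrt((1+m)/(1-m))
            infl = np.sqrt(1.9 / 0.1)
            assert abs(slope - 0.9 ** lag) < 3 * se * infl

    def test_thinning_preserves_slope_ratio(self, trace_m09):
        thin = rk.subsample(trace_m09, SubsampleSpec(fraction=0.05, seed=7))
        tab = rk.lag_slopes(thin, 2)
        r1, r2 = tab["slope"].to_numpy()
        assert r1 < 0.5          # heavily attenuated relative to m=0.9
        assert abs(r2 / r1 - 0.9) < 0.05

    def test_constant_trace_errors(self):
        trace = rk.ActivityTrace(np.full(1_000, 7), dt=4.0)
        with pytest.raises(ValueError, match="zero variance"):
            rk.lag_slopes(trace, 5)

    def test_k_max_too_large_errors(self, iid_trace):
        with pytest.raises(ValueError, match="too short"):
            rk.lag_slopes(iid_trace, iid_trace.n_bins // 10 + 1)


class TestFitExponential:
    @given(b=st.floats(0.01, 1.0), m=st.floats(0.05, 0.99))
    @settings(max_examples=100, deadline=None)
    def test_noiseless_round_trip_recovers_b_and_m(self, b, m):
        k = np.arange(1, 21)
        tab = pd.DataFrame({"lag": k, "slope": b * m ** k})
        res = rk.fit_exponential(tab, dt=4.0)
        assert res.converged
        assert res.m_hat == pytest.approx(m, rel=1e-6)
        assert res.b_hat == pytest.approx(b, rel=1e-6)

    def test_worked_example_tau(self):
        k = np.arange(1, 41)
        tab = pd.DataFrame({"lag": k, "slope": 0.5 * 0.98 ** k})
        res = rk.fit_exponential(tab, dt=4.0)
        assert res.m_hat == pytest.approx(0.98, abs=1e-9)
        assert res.b_hat == pytest.approx(0.5, abs=1e-9)
        assert res.tau_hat == pytest.approx(-4.0 / np.log(0.98), rel=1e-9)
        assert res.tau_hat == pytest.approx(198.0, abs=0.1)

    def test_tau_consistency_with_m(self, trace_m098):
        res = rk.estimate_m(trace_m098, n_boot=0)
        assert res.converged
        assert np.exp(-res.dt / res.tau_hat) == pytest.approx(res.m_hat, rel=1e-12)

    def test_zero_slopes_flagged_not_fit(self, iid_trace):
        res = rk.estimate_m(iid_trace, k_max=5, n_boot=0)
        assert (not res.converged) or abs(res.m_hat) < 0.05

    def test_fewer_than_three_lags_errors(self):
        tab = pd.DataFrame({"lag": [1, 2], "slope": [0.5, 0.25]})
        with pytest.raises(ValueError, match="at least 3"):
            rk.fit_exponential(tab, dt=4.0)

    def test_summary_mentions_key_quantities(self, trace_m098):
        text = rk.MultistepRegression(trace_m098).fit(n_boot=20, seed=0).summary()
        for token in ("m_hat", "tau", "CI", "converged"):
            assert token in text


class TestEstimatorRecovery:
    def test_midrange_m_recovered(self):
        tr = rk.simulate_branching(ProcessParams(m=0.5, h=5.0, n_bins=100_000, seed=71))
        res = rk.estimate_m(tr, n_boot=0)
        assert res.m_hat == pytest.approx(0.5, abs=0.05)

    def test_subsampling_invariance_median_under_0p01(self):
        diffs = {m: [] for m in (0.9, 0.95, 0.98)}
        for m in diffs:
            h = 2.0
            for seed in range(50):
                tr = rk.simulate_branching(ProcessParams(m=m, h=h, n_bins=50_000,
                                                         seed=1_000 + seed))
                thin = rk.subsample(tr, SubsampleSpec(fraction=0.05, seed=2_000 + seed))
                m_full = rk.estimate_m(tr, k_max=40, n_boot=0).m_hat
                m_thin = rk.estimate_m(thin, k_max=40, n_boot=0).m_hat
                diffs[m].append(abs(m_thin - m_full))
        for m, d in diffs.items():
            assert np.median(d) < 0.01, f"invariance failed at m={m}"

    def test_naive_estimator_biased_low_under_thinning(self):
        n_biased = 0
        seeds = range(30)
        for seed in seeds:
            tr = rk.simulate_branching(ProcessParams(m=0.9, h=2.0, n_bins=50_000,
                                                     seed=3_000 + seed))
            thin = rk.subsample(tr, SubsampleSpec(fraction=0.05, seed=4_000 + seed))
            n_biased += rk.estimate_m_naive(thin) < 0.9 - 0.05
        assert n_biased >= int(0.95 * len(list(seeds)))

    def test_naive_equals_full_lag1_without_thinning(self, trace_m09):
        identical = rk.subsample(trace_m09, SubsampleSpec(fraction=1.0, seed=0))
        assert rk.estimate_m_naive(identical) == pytest.approx(
            rk.estimate_m_naive(trace_m09), rel=1e-12)
        assert rk.estimate_m_naive(trace_m09) == pytest.approx(0.9, abs=0.02)

    def test_bootstrap_ci_covers_truth(self):
        # scaled-down calibration: 95% CI should cover m_true in >= 85/100 runs
        m_true, covered = 0.9, 0
        for seed in range(100):
            tr = rk.simulate_branching(ProcessParams(m=m_true, h=2.0, n_bins=10_000,
                                                     seed=5_000 + seed))
            res = rk.estimate_m(tr, n_boot=100, seed=seed)
            if res.ci is not None and res.ci[0] <= m_true <= res.ci[1]:
                covered += 1
        assert covered >= 85


class TestTimeResolved:
    @staticmethod
    def _ensemble(n_trials, schedule, h=3.0, n_bins=1_000, seed0=9_000):
        traces = [rk.simulate_branching(ProcessParams(m=schedule[0][1], h=h,
                                                      n_bins=n_bins, seed=seed0 + j,
                                                      m_schedule=schedule))
                  for j in range(n_trials)]
        return rk.TrialEnsemble(traces)

    def test_recovers_efficacy_step(self):
        ens = self._ensemble(100, [(0, 0.7), (500, 0.95)])
        tab = rk.estimate_m_timeresolved(ens, window=5, k_max=5)
        pre = tab[(tab.bin >= 50) & (tab.bin < 480)]["m_hat"]
        post = tab[(tab.bin >= 620) & (tab.bin < 990)]["m_hat"]
        assert pre.mean() == pytest.approx(0.7, abs=0.05)
        assert post.mean() == pytest.approx(0.95, abs=0.05)

    def test_stationary_ensemble_shows_no_trend(self):
        ens = self._ensemble(100, [(0, 0.9)], h=1.0, n_bins=400, seed0=11_000)
        tab = rk.estimate_m_timeresolved(ens, window=5, k_max=5)
        t = tab["bin"].to_numpy(dtype=float)
        y = tab["m_hat"].to_numpy()
        from scipy import stats
        res = stats.linregress(t, y)
        assert res.pvalue > 0.05
        assert y.mean() == pytest.approx(0.9, abs=0.05)

    def test_too_few_trials_errors(self):
        traces = [rk.simulate_branching(ProcessParams(m=0.5, h=2.0, n_bins=200, seed=s))
                  for s in range(3)]
        with pytest.raises(ValueError, match="too few trials"):
            rk.estimate_m_timeresolved(rk.TrialEnsemble(traces))

    def test_constant_trials_error(self):
        traces = [rk.ActivityTrace(np.full(200, 5), dt=4.0) for _ in range(10)]
        with pytest.raises(ValueError, match="zero variance across trials"):
            rk.estimate_m_timeresolved(rk.TrialEnsemble(traces))

    def test_mismatched_trials_rejected(self):
        a = rk.ActivityTrace(np.arange(100) % 3, dt=4.0)
        b = rk.ActivityTrace(np.arange(50) % 3, dt=4.0)
        with pytest.raises(ValueError):
            rk.TrialEnsemble([a, b])
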