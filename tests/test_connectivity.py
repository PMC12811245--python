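"""Stationarity screening and Granger-causal EC estimation."""

import numpy as np
import pytest
from statsmodels.tsa.stattools import adfuller

from dmnec import (RoiTimeSeries, StationarityError, adf_test, ec_matrix,
                   ensure_stationary, pairwise_ec, pairwise_gc,
                   simulate_var_timeseries, VarModel)


class TestAdf:
    def test_unit_root_null_retained_for_random_walks(self):
        hits = 0
        for seed in range(100):
            rw = np.random.default_rng(seed).standard_normal(500).cumsum()
            _, p = adf_test(rw)
            hits += p > 0.05
        assert hits >= 90

    def test_white_noise_rejected_as_nonstationary_rarely(self):
        hits = 0
        for seed in range(100):
            s = np.random.default_rng(1000 + seed).standard_normal(500)
            _, p = adf_test(s)
            hits += p < 0.05
        assert hits >= 90

    def test_agreement_with_reference_implementation(self):
        """Cross-implementation oracle: statsmodels adfuller."""
        rng = np.random.default_rng(7)
        for i in range(20):
            s = rng.standard_normal(300)
            if i % 2:
                s = s.cumsum()
            stat, p = adf_test(s, max_lag=8)
            ref_stat, ref_p, *_ = adfuller(s, maxlag=8, regression="c",
                                           autolag="AIC")
            assert abs(p - ref_p) < 0.02
            assert abs(stat - ref_stat) < 1e-6

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            adf_test(np.ones(100))

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="T ≥ 20"):
            adf_test(np.arange(10.0))


class TestEnsureStationary:
    def test_stationary_input_is_noop(self, rng):
        ts = RoiTimeSeries(rng.standard_normal((200, 3)), ("a", "b", "c"))
        out = ensure_stationary(ts)
        assert np.array_equal(out.values, ts.values)
        assert np.all(out.diff_order_applied == 0)

    def test_random_walk_roi_differenced_once(self):
        rng = np.random.default_rng(0)
        vals = rng.standard_normal((300, 3))
        vals[:, 1] = vals[:, 1].cumsum()
        ts = RoiTimeSeries(vals, ("a", "b", "c"))
        out = ensure_stationary(ts)
        assert list(out.diff_order_applied) == [0, 1, 0]
        assert out.n_timepoints == 299
        # untouched ROIs keep their (truncated) values
        assert np.allclose(out.values[:, 0], vals[-299:, 0])

    def test_drift_plus_walk_resolved_within_two_differences(self):
        ok = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            walk = r.standard_normal(300).cumsum() + 0.2 * np.arange(300)
            ts = RoiTimeSeries(
                np.column_stack([r.standard_normal(300), walk]), ("a", "b"))
            try:
                out = ensure_stationary(ts)
                ok += out.diff_order_applied[1] <= 2
            except StationarityError:
                pass
        assert ok >= 90

    def test_unresolvable_series_flagged_for_exclusion(self, rng):
        # a random walk with differencing disabled stays non-stationary
        vals = np.column_stack([rng.standard_normal(300),
                                rng.standard_normal(300).cumsum()])
        ts = RoiTimeSeries(vals, ("a", "b"), subject_id="sub-01")
        with pytest.raises(StationarityError, match="sub-01"):
            ensure_stationary(ts, max_diff=0)


class TestPairwiseEc:
    def test_recovers_injected_lag_coupling(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(5001)
        y = np.empty(5001)
        y[0] = rng.standard_normal()
        for t in range(1, 5001):
            y[t] = 0.5 * x[t - 1] + rng.standard_normal()
        assert pairwise_ec(x, y) == pytest.approx(0.5, abs=0.05)

    def test_null_coefficient_scales_as_root_t(self):
        t_len, hits = 200, 0
        for seed in range(200):
            r = np.random.default_rng(seed)
            b = pairwise_ec(r.standard_normal(t_len), r.standard_normal(t_len))
            hits += abs(b) < 3 / np.sqrt(t_len)
        assert hits >= 190

    def test_directionality(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(5001)
        y = np.empty(5001)
        y[0] = 0.0
        for t in range(1, 5001):
            y[t] = 0.6 * x[t - 1] + rng.standard_normal()
        assert abs(pairwise_ec(y, x)) < abs(pairwise_ec(x, y))

    def test_matches_bruteforce_normal_equations(self):
        """Independent oracle: solve the normal equations directly."""
        rng = np.random.default_rng(11)
        for _ in range(10):
            m = VarModel(rng.uniform(-0.3, 0.3, (4, 4)) * 0.5,
                         n_timepoints=200)
            ts = simulate_var_timeseries(m, int(rng.integers(1 << 30)))
            x, y = ts.values[:, 0], ts.values[:, 1]
            xc, yc = x - x.mean(), y - y.mean()
            design = np.column_stack([np.ones(199), yc[:-1], xc[:-1]])
            beta = np.linalg.solve(design.T @ design, design.T @ yc[1:])
            assert pairwise_ec(x, y) == pytest.approx(beta[2], abs=1e-10)

    def test_collinear_regressors_rejected(self, rng):
        x = rng.standard_normal(100)
        with pytest.raises(ValueError, match="collinear"):
            pairwise_ec(x, 2.0 * x + 1.0)

    def test_constant_series_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            pairwise_ec(np.ones(100), rng.standard_normal(100))

    def test_log_ratio_variant_positive_and_consistent(self, rng):
        x = rng.standard_normal(400)
        y = rng.standard_normal(400)
        res = pairwise_gc(x, y)
        assert res["log_ratio"] >= 0
        assert 0 <= res["p"] <= 1
        assert res["coef"] == pytest.approx(pairwise_ec(x, y), abs=1e-12)


class TestEcMatrix:
    def test_full_matrix_structure(self, partition):
        m = VarModel(np.diag(np.full(33, 0.3)), n_timepoints=120)
        ts = simulate_var_timeseries(m, 5)
        res = ec_matrix(ts, partition)
        assert res.ec.shape == (33, 33)
        assert np.all(np.isnan(np.diag(res.ec)))
        assert np.isfinite(res.ec).sum() == 33 * 32
        assert res.mpfc_to_pcc_block.shape == (12, 11)
        assert res.block_vector().size == 132

    def test_block_mean_is_exact_block_average(self, partition):
        m = VarModel(np.diag(np.full(33, 0.2)), n_timepoints=100)
        res = ec_matrix(simulate_var_timeseries(m, 9), partition)
        mpfc = partition.indices("mPFC")
        pcc = partition.indices("PCC")
        block = res.ec[np.ix_(mpfc, pcc)]
        assert res.mean_mpfc_to_pcc == pytest.approx(block.mean(), abs=1e-12)

    def test_constant_roi_rejected_before_estimation(self, partition, rng):
        vals = rng.standard_normal((100, 33))
        vals[:, 5] = 1.0
        ts = RoiTimeSeries(vals, partition.roi_labels)
        with pytest.raises(ValueError, match="constant"):
            ec_matrix(ts, partition)

    def test_mean_block_ec_monotone_in_injected_coupling(self, partition):
        """Stronger mPFC→PCC coupling must raise the estimated block mean."""
        mpfc, pcc = partition.indices("mPFC"), partition.indices("PCC")
        means = []
        for coupling in (0.05, 0.15, 0.25):
            a = np.diag(np.full(33, 0.3))
            a[np.ix_(mpfc, pcc)] = coupling
            ts = simulate_var_timeseries(VarModel(a, n_timepoints=2000), 21)
            means.append(ec_matrix(ts, partition).mean_mpfc_to_pcc)
        assert means[0] < means[1] < means[2]
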