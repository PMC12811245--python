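"""Mixed-model contrasts, effect sizes, paired tests, responder rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dmnec import (SubjectRecord, cohens_d_from_t, duration_terciles,
                   fit_group_lmm, paired_pre_post_test, pearson_with_p,
                   responder_delta_ec_test, responder_label,
                   simulate_meanec_records)


class TestCohensD:
    def test_hand_evaluated_example(self):
        # 2·(10+10)/(√18·√100) = 40/(4.2426·10)
        assert cohens_d_from_t(2, 10, 10, 18) == pytest.approx(0.9428, abs=1e-4)

    def test_zero_t_gives_zero_d(self):
        assert cohens_d_from_t(0, 5, 7, 10) == 0.0

    @given(t=st.floats(-50, 50), n1=st.integers(1, 500),
           n2=st.integers(1, 500), df=st.floats(0.5, 1000))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetric_in_t(self, t, n1, n2, df):
        assert cohens_d_from_t(-t, n1, n2, df) == pytest.approx(
            -cohens_d_from_t(t, n1, n2, df), rel=1e-12, abs=1e-12)

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError, match="df"):
            cohens_d_from_t(1, 5, 5, 0)


class TestLmm:
    def test_single_site_matches_ols_oracle(self):
        """With one site the model collapses to OLS; t must agree."""
        import statsmodels.formula.api as smf
        from dmnec.io import records_to_frame

        recs = simulate_meanec_records(1, 60, -0.4, seed=2,
                                       site_intercept_sd=0, site_slope_sd=0)
        res = fit_group_lmm(recs, "diagnosis")
        assert res.single_site_ols
        df = records_to_frame(recs)
        df["y"] = df["mean_ec_mpfc_pcc"]
        df["grp"] = (df["diagnosis"] == "MDD").astype(float)
        ols = smf.ols("y ~ grp + age + sex + education + motion", df).fit()
        assert res.t_value == pytest.approx(ols.tvalues["grp"], abs=1e-6)

    def test_injected_effect_detected(self):
        recs = simulate_meanec_records(8, 60, -0.5, seed=3)
        res = fit_group_lmm(recs, "diagnosis")
        assert res.p_value < 0.01
        assert res.cohens_d < 0
        assert np.sign(res.cohens_d) == np.sign(res.t_value)
        assert res.n_sites == 8

    def test_p_consistent_with_t_and_df(self):
        from scipy import stats

        recs = simulate_meanec_records(5, 30, -0.3, seed=4)
        res = fit_group_lmm(recs, "diagnosis")
        assert res.p_value == pytest.approx(
            2 * stats.t.sf(abs(res.t_value), res.df), abs=1e-12)

    def test_d_estimate_converges_with_n(self):
        """The mixed-model d approaches the generating value as n grows.

        Estimation error shrinks with n until the small Wald-SE attenuation
        floor (boundary-truncated slope variance) is reached, so the check
        is: error drops sharply from the smallest n, and the large-n mean is
        within 10 % of the generating d.
        """
        true_d = -0.5
        rmses, means = [], []
        for n_per in (10, 40, 160):
            # slope heterogeneity off: the cohort-level effect then equals
            # the generating d exactly, so the error is pure estimation error
            ds = [fit_group_lmm(
                simulate_meanec_records(6, n_per, true_d, seed=500 + r,
                                        site_slope_sd=0.0),
                "diagnosis", min_site_n=min(9, n_per - 1)).cohens_d
                for r in range(25)]
            rmses.append(np.sqrt(np.mean((np.array(ds) - true_d) ** 2)))
            means.append(np.mean(ds))
        assert rmses[0] > rmses[1] and rmses[0] > rmses[2]
        assert abs(means[2] - true_d) <= 0.1 * abs(true_d) + 0.02

    def test_constant_contrast_rejected(self):
        recs = simulate_meanec_records(3, 15, 0.0, seed=5)
        for r in recs:
            r.diagnosis = "MDD"
            r.episode = "recurrent"
        with pytest.raises(ValueError):
            fit_group_lmm(recs, "diagnosis")

    def test_small_sites_filtered_out(self):
        recs = simulate_meanec_records(4, 30, -0.5, seed=6)
        tiny = simulate_meanec_records(1, 4, 0.0, seed=7)
        for r in tiny:
            r.site = "tiny_site"
        res = fit_group_lmm(recs + tiny, "diagnosis", min_site_n=10)
        assert res.n_sites == 4
        assert res.n_excluded_site_filter == 8

    def test_unknown_contrast_rejected(self):
        recs = simulate_meanec_records(2, 12, 0.0, seed=8)
        with pytest.raises(ValueError, match="unknown contrast"):
            fit_group_lmm(recs, "handedness")


class TestDurationTerciles:
    def test_paper_cutpoints(self):
        recs = [SubjectRecord(subject_id=f"s{i}", site="x",
                              illness_duration_months=d)
                for i, d in enumerate([1, 2, 12, 30, 40])]
        assert duration_terciles(recs) == ["short", "short", "middle",
                                           "long", "long"]

    def test_boundaries_inclusive(self):
        recs = [SubjectRecord(subject_id=f"s{i}", site="x",
                              illness_duration_months=d)
                for i, d in enumerate([3.0, 24.0])]
        assert duration_terciles(recs) == ["short", "long"]

    def test_all_missing_rejected(self):
        recs = [SubjectRecord(subject_id="s", site="x")]
        with pytest.raises(ValueError, match="missing"):
            duration_terciles(recs)

    def test_empty_long_tercile_skips_contrast(self):
        recs = simulate_meanec_records(2, 15, 0.0, seed=9)
        for r in recs:
            if r.diagnosis == "MDD":
                r.illness_duration_months = 1.0  # everyone short
        with pytest.raises(ValueError):
            fit_group_lmm(recs, "duration_tercile", min_site_n=1)


class TestPairedTest:
    def test_identical_pairs(self):
        t, p, d = paired_pre_post_test(np.arange(5.0), np.arange(5.0))
        assert (t, p, d) == (0.0, 1.0, 0.0)

    def test_constant_nonzero_shift_rejected(self):
        pre = np.arange(5.0) + 1
        with pytest.raises(ValueError, match="zero-variance"):
            paired_pre_post_test(pre, pre - 1.0)

    def test_one_sd_shift_power(self):
        """Mean |t| for a 1·SD paired shift at n=20 sits near √n."""
        ts = []
        for seed in range(500):
            r = np.random.default_rng(seed)
            post = r.standard_normal(20)
            pre = post + 1.0 + r.standard_normal(20)  # diff ~ N(1, 1)
            t, _, _ = paired_pre_post_test(pre, post)
            ts.append(abs(t))
        assert 3.5 <= np.mean(ts) <= 5.5


class TestResponder:
    def test_strong_reduction_is_responder(self):
        assert responder_label(27.69, 5.92)  # 78.6 % reduction

    def test_exact_half_is_responder(self):
        assert responder_label(20.0, 10.0)

    def test_just_under_half_is_not(self):
        assert not responder_label(20.0, 10.1)

    @given(pre=st.floats(1.0, 60.0), post=st.floats(0.0, 60.0),
           k=st.floats(0.1, 10.0))
    @settings(max_examples=100, deadline=None)
    def test_scale_invariant(self, pre, post, k):
        assert responder_label(pre, post) == responder_label(k * pre, k * post)

    def test_nonpositive_pre_rejected(self):
        with pytest.raises(ValueError):
            responder_label(0.0, 0.0)


class TestPearson:
    def test_perfect_correlations(self, rng):
        x = rng.standard_normal(30)
        assert pearson_with_p(x, x)[0] == pytest.approx(1.0)
        assert pearson_with_p(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        for _ in range(10):
            x, y = rng.standard_normal((2, 25))
            r, _ = pearson_with_p(x, y)
            manual = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
                np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
            assert r == pytest.approx(manual, abs=1e-12)

    def test_zero_variance_rejected(self, rng):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_with_p(np.ones(10), rng.standard_normal(10))


class TestDeltaEcTest:
    def test_null_calibrated(self):
        rej = 0
        for seed in range(500):
            r = np.random.default_rng(seed)
            _, p = responder_delta_ec_test(r.standard_normal(30),
                                           r.standard_normal(30))
            rej += p < 0.05
        assert 0.03 <= rej / 500 <= 0.07

    def test_two_sd_shift_detected(self):
        hits = 0
        for seed in range(40):
            r = np.random.default_rng(1000 + seed)
            _, p = responder_delta_ec_test(r.standard_normal(30) + 2.0,
                                           r.standard_normal(30))
            hits += p < 0.01
        assert hits >= 38

    def test_single_subject_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            responder_delta_ec_test(np.array([1.0]), np.array([0.0, 1.0]))
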