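"""The synthetic multi-site cohort generator."""

import numpy as np
import pytest

from dmnec import (CohortConfig, GroupSpec, SiteSpec, SubjectRecord,
                   TreatmentConfig, VarModel, adf_test, coupling_delta_for_d,
                   default_partition, ec_matrix, responder_label,
                   simulate_cohort, simulate_treatment_outcomes,
                   simulate_var_timeseries, site_r_squared, write_cohort)
from dmnec.io import read_phenotypes, read_timeseries


class TestVarSimulation:
    def test_zero_coupling_gives_uncorrelated_lags(self):
        t_len = 500
        ts = simulate_var_timeseries(
            VarModel(np.zeros((3, 3)), n_timepoints=t_len), seed=0)
        v = ts.values - ts.values.mean(axis=0)
        for i in range(3):
            for j in range(3):
                c = np.mean(v[1:, j] * v[:-1, i]) / (v[:, i].std() * v[:, j].std())
                assert abs(c) < 4 / np.sqrt(t_len)

    def test_ols_recovers_directed_coupling(self):
        a = np.array([[0.0, 0.5], [0.0, 0.0]])  # ROI1 -> ROI2
        ts = simulate_var_timeseries(VarModel(a, n_timepoints=5000), seed=1)
        x1, x2 = ts.values[:, 0], ts.values[:, 1]
        design = np.column_stack([x2[:-1], x1[:-1]])
        beta, *_ = np.linalg.lstsq(design, x2[1:], rcond=None)
        assert beta[1] == pytest.approx(0.5, abs=0.05)

    def test_drift_flagged_nonstationary(self):
        flagged = 0
        for seed in range(100):
            ts = simulate_var_timeseries(
                VarModel(np.zeros((1, 1)), n_timepoints=200,
                         drift_slope=0.05), seed=seed)
            _, p = adf_test(ts.values[:, 0])
            flagged += p > 0.05  # unit-root null retained => non-stationary
        assert flagged >= 95

    def test_reproducible(self):
        m = VarModel(np.diag([0.4, 0.2]), n_timepoints=80)
        a = simulate_var_timeseries(m, seed=42)
        b = simulate_var_timeseries(m, seed=42)
        assert np.array_equal(a.values, b.values)

    def test_explosive_coupling_rejected(self):
        with pytest.raises(ValueError, match="spectral radius"):
            simulate_var_timeseries(
                VarModel(np.diag([1.05, 0.2]), n_timepoints=100), seed=0)

    def test_invalid_model_parameters(self):
        with pytest.raises(ValueError, match="n_timepoints"):
            VarModel(np.zeros((2, 2)), n_timepoints=10)
        with pytest.raises(ValueError, match="noise_sd"):
            VarModel(np.zeros((2, 2)), noise_sd=0.0)


def _mean_ecs(config):
    part = default_partition()
    series, records = simulate_cohort(config, part)
    means = np.array([ec_matrix(ts, part).mean_mpfc_to_pcc for ts in series])
    return means, records


class TestCohort:
    def test_validation(self):
        with pytest.raises(ValueError, match="at least one site"):
            CohortConfig(sites=[])
        with pytest.raises(ValueError, match="at least one group"):
            CohortConfig(groups=[])
        with pytest.raises(ValueError, match="n_per_group"):
            SiteSpec("s", 0)

    def test_reproducible_bit_identical(self):
        cfg = CohortConfig(sites=[SiteSpec("s", 3)], n_timepoints=60, seed=5)
        s1, r1 = simulate_cohort(cfg)
        s2, r2 = simulate_cohort(cfg)
        assert all(np.array_equal(a.values, b.values) for a, b in zip(s1, s2))
        assert [r.age for r in r1] == [r.age for r in r2]

    def test_injected_group_effect_recovered(self):
        """Coupling delta targeting d = −0.5 yields an estimated effect of
        that order on mean EC."""
        delta = coupling_delta_for_d(-0.5, CohortConfig())
        cfg = CohortConfig(
            sites=[SiteSpec("s1", 200)],
            groups=[GroupSpec("NC", 0.0), GroupSpec("MDD", delta)],
            n_timepoints=150, seed=11)
        means, records = _mean_ecs(cfg)
        grp = np.array([r.diagnosis for r in records])
        a, b = means[grp == "MDD"], means[grp == "NC"]
        sd = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
        d_hat = (a.mean() - b.mean()) / sd
        assert -0.7 <= d_hat <= -0.3

    def test_null_config_groups_indistinguishable(self):
        ok = 0
        for seed in range(5):
            cfg = CohortConfig(
                sites=[SiteSpec("s1", 40)],
                groups=[GroupSpec("NC", 0.0), GroupSpec("MDD", 0.0)],
                n_timepoints=100, seed=100 + seed)
            means, records = _mean_ecs(cfg)
            grp = np.array([r.diagnosis for r in records])
            a, b = means[grp == "MDD"], means[grp == "NC"]
            se = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
            ok += abs(a.mean() - b.mean()) < 2 * se
        assert ok >= 4

    def test_site_shifts_visible_before_harmonization(self):
        cfg = CohortConfig(
            sites=[SiteSpec("s1", 20, -0.2), SiteSpec("s2", 20, 0.0),
                   SiteSpec("s3", 20, 0.2)],
            groups=[GroupSpec("MDD", 0.0)],
            n_timepoints=100, seed=3)
        means, records = _mean_ecs(cfg)
        sites = np.array([r.site for r in records])
        assert site_r_squared(means, sites) > 0.05

    def test_effect_injection_monotone(self):
        """Larger |coupling delta| must produce larger |estimated d|."""
        d_hats = []
        for delta in (-0.02, -0.06, -0.12):
            cfg = CohortConfig(
                sites=[SiteSpec("s1", 120)],
                groups=[GroupSpec("NC", 0.0), GroupSpec("MDD", delta)],
                n_timepoints=100, seed=17)
            means, records = _mean_ecs(cfg)
            grp = np.array([r.diagnosis for r in records])
            a, b = means[grp == "MDD"], means[grp == "NC"]
            sd = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
            d_hats.append(abs((a.mean() - b.mean()) / sd))
        assert d_hats[0] < d_hats[1] < d_hats[2]

    def test_write_cohort_roundtrip(self, tmp_path):
        cfg = CohortConfig(sites=[SiteSpec("s", 2)], n_timepoints=60, seed=1)
        series, records = simulate_cohort(cfg)
        out = write_cohort(series, records, cfg, tmp_path)
        back = read_phenotypes(out / "phenotypes.csv")
        assert len(back) == len(records)
        ts = read_timeseries(out / "timeseries" / f"{records[0].subject_id}.tsv")
        assert np.max(np.abs(ts.values - series[0].values)) < 1e-12


def _treated(rng, n):
    return [SubjectRecord(subject_id=f"s{i}", site="x",
                          hamd_pre=float(np.clip(rng.normal(22, 5), 5, 52)))
            for i in range(n)]


class TestTreatmentOutcomes:
    def test_configured_correlation_realized(self, rng):
        cfg = CohortConfig(treatment=TreatmentConfig(
            ec_to_hamd_change_correlation=0.6))
        ec = rng.normal(0.1, 0.1, 300)
        recs = _treated(rng, 300)
        simulate_treatment_outcomes(recs, cfg, seed=0, baseline_ec=ec)
        delta = np.array([r.hamd_pre - r.hamd_post for r in recs])
        assert 0.45 <= np.corrcoef(ec, delta)[0, 1] <= 0.72

    def test_zero_correlation_gives_independence(self):
        cfg = CohortConfig(treatment=TreatmentConfig(
            ec_to_hamd_change_correlation=0.0))
        ok = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            ec = r.normal(0.1, 0.1, 300)
            recs = _treated(r, 300)
            simulate_treatment_outcomes(recs, cfg, seed=seed, baseline_ec=ec)
            delta = np.array([x.hamd_pre - x.hamd_post for x in recs])
            ok += abs(np.corrcoef(ec, delta)[0, 1]) < 0.15
        assert ok >= 9

    def test_responder_fraction_calibrated(self):
        """Default fraction 213/315 ⇒ count within the binomial 99% interval."""
        cfg = CohortConfig()
        counts = []
        for seed in range(5):
            r = np.random.default_rng(50 + seed)
            recs = _treated(r, 315)
            simulate_treatment_outcomes(recs, cfg, seed=seed,
                                        baseline_ec=r.normal(0.1, 0.1, 315))
            counts.append(sum(responder_label(x.hamd_pre, x.hamd_post)
                              for x in recs))
        assert all(190 <= c <= 236 for c in counts)

    def test_nonpositive_hamd_pre_rejected(self, rng):
        rec = SubjectRecord(subject_id="s", site="x", hamd_pre=0.0)
        with pytest.raises(ValueError, match="hamd_pre"):
            simulate_treatment_outcomes([rec], CohortConfig(), seed=0,
                                        baseline_ec=np.array([0.1]))

    def test_invalid_treatment_config(self):
        with pytest.raises(ValueError, match="fraction_responders"):
            TreatmentConfig(fraction_responders=1.2)
        with pytest.raises(ValueError, match="correlation"):
            TreatmentConfig(ec_to_hamd_change_correlation=1.5)
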