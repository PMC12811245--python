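"""Shared synthetic constructions used across the test suite."""

from __future__ import annotations

import subprocess
import tempfile
from pathlib import Path

import numpy as np

from dmnec import CohortConfig, SubjectRecord, TreatmentConfig, \
    simulate_treatment_outcomes


def classification_cohort(seed: int, n_pos: int = 213, n_neg: int = 102,
                          effect_d: float = 1.5, k: int = 10,
                          n_features: int = 132):
    """EC-like feature matrix with ``k`` informative connections separated by
    ``effect_d`` between responders (1) and non-responders (0)."""
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    x = rng.standard_normal((n, n_features))
    y = np.r_[np.ones(n_pos), np.zeros(n_neg)].astype(int)
    x[y == 1, :k] += effect_d
    perm = rng.permutation(n)
    return x[perm], y[perm]


def prognostic_cohort(seed: int, n: int = 138, rho: float = 0.6, k: int = 10,
                      n_features: int = 132):
    """Treated cohort whose HAMD-17 change correlates with the mean of ``k``
    prognostic connections at level ``rho`` (Gaussian copula).

    Returns (features, delta_hamd, latent signal).
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(0.1, 0.1, (n, n_features))
    signal = x[:, :k].mean(axis=1)
    records = [
        SubjectRecord(subject_id=f"s{i}", site="x",
                      hamd_pre=float(np.clip(rng.normal(22, 5), 5, 52)))
        for i in range(n)
    ]
    cfg = CohortConfig(
        treatment=TreatmentConfig(ec_to_hamd_change_correlation=rho))
    simulate_treatment_outcomes(records, cfg, seed=seed, baseline_ec=signal)
    delta = np.array([r.hamd_pre - r.hamd_post for r in records])
    return x, delta, signal


def site_shifted_values(seed: int, n_per_site: int = 500,
                        shifts=(-0.3, 0.3), scales=(1.0, 2.0),
                        base_sd: float = 0.2, n_features: int = 1,
                        beta_age: float = 0.002):
    """Scalar (or multi-feature) values with constructed additive site shifts
    and multiplicative site noise scales (relative to ``base_sd``, the
    within-site dispersion typical of mean-EC values) plus an age covariate
    effect.

    Returns (values, site labels, covariates (age, sex, motion)).
    """
    rng = np.random.default_rng(seed)
    n = n_per_site * len(shifts)
    sites = np.repeat([f"site_{i}" for i in range(len(shifts))], n_per_site)
    cov = np.column_stack([
        rng.normal(35, 10, n),
        rng.integers(0, 2, n).astype(float),
        np.abs(rng.normal(0.12, 0.04, n)),
    ])
    y = np.empty((n, n_features))
    for i in range(n):
        s = int(i // n_per_site)
        y[i] = (0.1 + beta_age * (cov[i, 0] - 35) + shifts[s]
                + rng.normal(0.0, scales[s] * base_sd, n_features))
    return (y.ravel() if n_features == 1 else y), sites, cov


def sva_combat_reference(values: np.ndarray, sites: np.ndarray,
                         covariates: np.ndarray) -> np.ndarray:
    """Harmonize with the independent Bioconductor sva::ComBat implementation
    (parametric priors) via Rscript; the cross-implementation oracle."""
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    with tempfile.TemporaryDirectory() as td:
        td = Path(td)
        np.savetxt(td / "y.csv", values, delimiter=",")
        np.savetxt(td / "cov.csv", covariates, delimiter=",")
        (td / "site.txt").write_text("\n".join(sites))
        script = f"""
suppressMessages(library(sva))
y <- as.matrix(read.csv("{td}/y.csv", header=FALSE))
cov <- as.matrix(read.csv("{td}/cov.csv", header=FALSE))
site <- readLines("{td}/site.txt")
out <- ComBat(dat=t(y), batch=site, mod=cov, par.prior=TRUE)
write.table(t(out), "{td}/out.csv", sep=",", row.names=FALSE, col.names=FALSE)
"""
        subprocess.run(["Rscript", "-e", script], check=True,
                       capture_output=True)
        return np.loadtxt(td / "out.csv", delimiter=",")
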