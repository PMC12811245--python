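"""Synthetic multi-site cohort generator.

Generates everything the downstream analysis consumes — ROI time series,
phenotypes, and treatment outcomes — with the statistical structure the
pipeline assumes:

* stationary VAR(1) ROI dynamics with a directed mPFC→PCC coupling block
  (optionally drifting, for exercising the stationarity screen);
* group differences injected as shifts of the mPFC→PCC coupling;
* additive and multiplicative site effects applied to the subject-level
  coupling (hence inherited by the estimated EC values);
* linear covariate effects (age, sex, head motion) on coupling;
* HAMD-17 treatment outcomes whose pre–post change correlates with baseline
  connectivity at a configured level through a Gaussian-copula link, with a
  calibrated responder fraction.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import stats

from .io import DmnPartition, RoiTimeSeries, SubjectRecord, default_partition, \
    write_timeseries, write_phenotypes

__all__ = [
    "VarModel",
    "SiteSpec",
    "GroupSpec",
    "TreatmentConfig",
    "CohortConfig",
    "simulate_var_timeseries",
    "simulate_cohort",
    "simulate_treatment_outcomes",
    "simulate_meanec_records",
    "coupling_delta_for_d",
    "write_cohort",
]


@dataclass
class VarModel:
    """A first-order vector-autoregression x_t = Aᵀ·x_{t−1} + drift·t + ε.

    ``coupling_matrix[i, j]`` is the lag-1 effect of ROI i on ROI j, matching
    the source→target orientation of the EC matrix. With all drift slopes
    zero the process is stationary iff the spectral radius of A is < 1.
    """

    coupling_matrix: np.ndarray
    noise_sd: float | np.ndarray = 1.0
    n_timepoints: int = 200
    drift_slope: float | np.ndarray = 0.0

    def __post_init__(self) -> None:
        self.coupling_matrix = np.asarray(self.coupling_matrix, dtype=float)
        n = self.coupling_matrix.shape[0]
        if self.coupling_matrix.shape != (n, n):
            raise ValueError("coupling_matrix must be square")
        if self.n_timepoints < 50:
            raise ValueError(f"n_timepoints must be ≥ 50, got {self.n_timepoints}")
        self.noise_sd = np.broadcast_to(np.asarray(self.noise_sd, float), (n,)).copy()
        if np.any(self.noise_sd <= 0):
            raise ValueError("noise_sd must be positive")
        self.drift_slope = np.broadcast_to(np.asarray(self.drift_slope, float), (n,)).copy()

    @property
    def n_rois(self) -> int:
        return self.coupling_matrix.shape[0]

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.coupling_matrix))))


BURN_IN = 100  # discarded initial steps; any stationary initialization suffices


def simulate_var_timeseries(model: VarModel, seed: int,
                            subject_id: str | None = None) -> RoiTimeSeries:
    """Simulate one subject's T×N ROI matrix from a VAR(1) model.

    A burn-in of 100 steps is discarded. Reproducible: the same
    (model, seed) pair yields the identical matrix.
    """
    if np.all(model.drift_slope == 0):
        sr = model.spectral_radius()
        if sr >= 1:
            raise ValueError(
                f"non-stationary coupling: spectral radius {sr:.3f} ≥ 1 with "
                "zero drift; the VAR(1) process would diverge"
            )
    rng = np.random.default_rng(seed)
    n, t = model.n_rois, model.n_timepoints
    at = model.coupling_matrix.T
    x = np.zeros(n)
    out = np.empty((t, n))
    for step in range(BURN_IN + t):
        x = at @ x + rng.normal(0.0, model.noise_sd)
        if step >= BURN_IN:
            k = step - BURN_IN
            out[k] = x + model.drift_slope * k
    return RoiTimeSeries(out, _default_labels(n), subject_id=subject_id)


def _default_labels(n: int) -> tuple[str, ...]:
    part = default_partition()
    if n == part.n_rois:
        return part.roi_labels
    return tuple(f"ROI_{i + 1:02d}" for i in range(n))


@dataclass
class SiteSpec:
    """One acquisition site: sample size per group and its EC distortions."""

    id: str
    n_per_group: int
    additive_site_shift: float = 0.0
    multiplicative_site_scale: float = 1.0

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("site id must be nonempty")
        if self.n_per_group < 1:
            raise ValueError(f"site {self.id!r}: n_per_group must be ≥ 1")
        if self.multiplicative_site_scale <= 0:
            raise ValueError(f"site {self.id!r}: multiplicative scale must be > 0")


@dataclass
class GroupSpec:
    """A diagnostic group and its shift of the mPFC→PCC coupling."""

    label: str
    coupling_delta_mpfc_to_pcc: float = 0.0


@dataclass
class TreatmentConfig:
    """Treatment-outcome generation parameters.

    ``fraction_responders`` and the EC↔ΔHAMD correlation default to the
    responder split (213/315) and a moderate brain–outcome coupling; HAMD-17
    baseline moments are typical of moderately-to-severely depressed
    samples.
    """

    fraction_responders: float = 213 / 315
    ec_to_hamd_change_correlation: float = 0.4
    hamd_pre_mean: float = 22.0
    hamd_pre_sd: float = 5.0
    hamd_change_sd: float = 6.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_responders <= 1.0:
            raise ValueError("fraction_responders must be in [0, 1]")
        if abs(self.ec_to_hamd_change_correlation) > 1.0:
            raise ValueError("|ec_to_hamd_change_correlation| must be ≤ 1")


@dataclass
class CovariateEffects:
    """Linear slopes of coupling on (centred) covariates."""

    age: float = -0.001      # per year, centred at 35
    sex: float = 0.01        # male (1) minus female (0)
    motion: float = -0.1     # per mm mean framewise displacement, centred at 0.12


@dataclass
class CohortConfig:
    """Full recipe for a synthetic multi-site cohort.

    Defaults give a four-site cohort totalling 315 subjects per group,
    mirroring the treated-cohort size used for response prediction
    (responder fraction 213/315), with mild site distortions and a weak
    MDD coupling deficit.
    """

    sites: list[SiteSpec] = field(default_factory=lambda: [
        SiteSpec("site_A", 161, -0.02, 1.0),
        SiteSpec("site_B", 26, 0.03, 1.2),
        SiteSpec("site_C", 72, 0.01, 0.9),
        SiteSpec("site_D", 56, -0.01, 1.1),
    ])
    groups: list[GroupSpec] = field(default_factory=lambda: [
        GroupSpec("NC", 0.0),
        GroupSpec("MDD", -0.015),
    ])
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    treatment: TreatmentConfig = field(default_factory=TreatmentConfig)
    seed: int = 0
    n_timepoints: int = 200
    base_coupling: float = 0.15
    self_coupling: float = 0.3
    subject_coupling_sd: float = 0.1
    connection_jitter_sd: float = 0.02

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("cohort needs at least one site")
        if not self.groups:
            raise ValueError("cohort needs at least one group")


def coupling_delta_for_d(d: float, config: CohortConfig) -> float:
    """Coupling shift that injects approximately a Cohen's d group difference
    on mean mPFC→PCC EC (subject-level coupling dispersion dominates the
    mean-EC variance, so delta ≈ d·subject_coupling_sd)."""
    return d * config.subject_coupling_sd


def simulate_cohort(
    config: CohortConfig, partition: DmnPartition | None = None,
) -> tuple[list[RoiTimeSeries], list[SubjectRecord]]:
    """Generate per-subject VAR(1) time series and phenotype records.

    Each subject's mPFC→PCC coupling block is

        base + group delta + covariate terms + γ_site + δ_site·η_subject

    (η ~ N(0, subject_coupling_sd), plus small per-connection jitter), so the
    estimated EC inherits the configured additive/multiplicative site
    distortions. Covariates, site and group are recorded per subject.
    """
    part = partition or default_partition()
    mpfc = part.indices("mPFC")
    pcc = part.indices("PCC")
    n_rois = part.n_rois
    root = np.random.default_rng(np.random.SeedSequence([config.seed, 2025]))
    series: list[RoiTimeSeries] = []
    records: list[SubjectRecord] = []
    ce = config.covariate_effects
    idx = 0
    for site in config.sites:
        for group in config.groups:
            for _ in range(site.n_per_group):
                rng = np.random.default_rng(
                    np.random.SeedSequence([config.seed, idx]))
                age = float(np.clip(rng.normal(35.0, 12.0), 18.0, 65.0))
                sex = int(rng.random() < 0.4)
                education = float(np.clip(rng.normal(12.5, 3.5), 6.0, 22.0))
                motion = float(np.clip(abs(rng.normal(0.12, 0.05)), 0.03, 0.5))
                is_mdd = group.label != "NC"
                if is_mdd:
                    duration = float(rng.lognormal(np.log(12.0), 1.2))
                    episode = "FEDN" if rng.random() < 0.5 else "recurrent"
                    medication = bool(rng.random() < 0.7) if episode == "recurrent" else False
                    arm = "medication" if rng.random() < 229 / 315 else "rTMS"
                    hamd_pre = float(np.clip(
                        rng.normal(config.treatment.hamd_pre_mean,
                                   config.treatment.hamd_pre_sd), 5.0, 52.0))
                else:
                    duration, episode, medication, arm, hamd_pre = (
                        None, "unknown", None, "none", None)
                eta = rng.normal()
                block_mean = (
                    config.base_coupling
                    + group.coupling_delta_mpfc_to_pcc
                    + ce.age * (age - 35.0)
                    + ce.sex * sex
                    + ce.motion * (motion - 0.12)
                    + site.additive_site_shift
                    + site.multiplicative_site_scale * config.subject_coupling_sd * eta
                )
                a = np.zeros((n_rois, n_rois))
                np.fill_diagonal(a, config.self_coupling)
                jitter = rng.normal(0.0, config.connection_jitter_sd,
                                    size=(mpfc.size, pcc.size))
                a[np.ix_(mpfc, pcc)] = block_mean + jitter
                model = VarModel(a, noise_sd=1.0, n_timepoints=config.n_timepoints)
                sid = f"{site.id}_{group.label}_{idx:04d}"
                ts_seed = int(rng.integers(0, 2**31 - 1))
                ts = simulate_var_timeseries(model, ts_seed, subject_id=sid)
                ts.roi_labels = part.roi_labels
                series.append(ts)
                records.append(SubjectRecord(
                    subject_id=sid,
                    site=site.id,
                    diagnosis="MDD" if is_mdd else "NC",
                    episode=episode,
                    medication_on=medication,
                    illness_duration_months=duration,
                    age=age, sex=sex, education=education, motion=motion,
                    hamd_pre=hamd_pre, hamd_post=None,
                    treatment_arm=arm,
                ))
                idx += 1
    return series, records


def simulate_treatment_outcomes(
    records: list[SubjectRecord], config: CohortConfig, seed: int,
    baseline_ec: np.ndarray | None = None,
) -> list[SubjectRecord]:
    """Fill ``hamd_post`` so that the pre−post HAMD-17 change correlates with
    baseline mean EC at the configured level.

    Gaussian-copula construction: baseline EC values are rank-transformed to
    normal scores z_e; the change is Δ = μ_Δ + σ_Δ·(ρ·z_e + √(1−ρ²)·ζ) with
    μ_Δ calibrated so the responder fraction (Δ/pre ≥ 50%) matches the
    configured fraction in expectation. Only subjects with hamd_pre present
    are filled; hamd_pre ≤ 0 is an error (percent reduction undefined).
    """
    tr = config.treatment
    treated = [i for i, r in enumerate(records) if r.hamd_pre is not None]
    for i in treated:
        if records[i].hamd_pre <= 0:
            raise ValueError(
                f"subject {records[i].subject_id!r}: hamd_pre must be > 0"
            )
    if not treated:
        return records
    if baseline_ec is None:
        ec = np.array([records[i].mean_ec_mpfc_pcc for i in treated], dtype=float)
        if np.any(np.isnan(ec)):
            raise ValueError(
                "baseline mean EC missing: pass baseline_ec or fill "
                "mean_ec_mpfc_pcc on the records first"
            )
    else:
        baseline_ec = np.asarray(baseline_ec, dtype=float)
        if baseline_ec.size != len(treated):
            raise ValueError(
                f"baseline_ec has {baseline_ec.size} values for {len(treated)} "
                "treated subjects"
            )
        ec = baseline_ec
    rng = np.random.default_rng(np.random.SeedSequence([seed, 777]))
    n = len(treated)
    ranks = stats.rankdata(ec, method="average")
    z_e = stats.norm.ppf((ranks - 0.5) / n)
    rho = tr.ec_to_hamd_change_correlation
    z = rho * z_e + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    pre = np.array([records[i].hamd_pre for i in treated])
    # μ_Δ such that P(Δ ≥ pre/2) = fraction_responders under the generating moments
    spread = np.sqrt(0.25 * tr.hamd_pre_sd**2 + tr.hamd_change_sd**2)
    mu_delta = 0.5 * tr.hamd_pre_mean + spread * stats.norm.ppf(tr.fraction_responders)
    delta = mu_delta + tr.hamd_change_sd * z
    post = np.clip(pre - delta, 0.0, 52.0)
    for k, i in enumerate(treated):
        records[i].hamd_post = float(post[k])
    return records


def simulate_meanec_records(
    n_sites: int, n_per_site_per_group: int, effect_d: float, seed: int,
    resid_sd: float = 1.0, site_intercept_sd: float = 0.2,
    site_slope_sd: float = 0.05, covariate_slopes: tuple = (-0.005, 0.1, 0.01, -0.5),
) -> list[SubjectRecord]:
    """Directly generate subject records with a filled ``mean_ec_mpfc_pcc``
    under a site-random-effects model — the design the group-level mixed
    model assumes — without simulating any time series.

    y = d·σ·1[MDD] + β·(age, sex, education, motion) + u_site
        + v_site·1[MDD] + ε,   ε ~ N(0, resid_sd²).

    Used for calibration and power studies of the group-inference stage.
    """
    rng = np.random.default_rng(seed)
    b_age, b_sex, b_edu, b_mot = covariate_slopes
    records = []
    for s in range(n_sites):
        u = rng.normal(0.0, site_intercept_sd)
        v = rng.normal(0.0, site_slope_sd)
        for g, label in enumerate(["NC", "MDD"]):
            for k in range(n_per_site_per_group):
                age = float(np.clip(rng.normal(35, 12), 18, 65))
                sex = int(rng.random() < 0.4)
                edu = float(np.clip(rng.normal(12.5, 3.5), 6, 22))
                mot = float(np.clip(abs(rng.normal(0.12, 0.05)), 0.03, 0.5))
                is_mdd = label == "MDD"
                y = (effect_d * resid_sd * is_mdd
                     + b_age * (age - 35) + b_sex * sex
                     + b_edu * (edu - 12.5) + b_mot * (mot - 0.12)
                     + u + v * is_mdd + rng.normal(0.0, resid_sd))
                records.append(SubjectRecord(
                    subject_id=f"s{s}_{label}_{k}",
                    site=f"site_{s}",
                    diagnosis="MDD" if is_mdd else "NC",
                    episode="recurrent" if is_mdd else "unknown",
                    age=age, sex=sex, education=edu, motion=mot,
                    mean_ec_mpfc_pcc=float(y),
                ))
    return records


def write_cohort(series: list[RoiTimeSeries], records: list[SubjectRecord],
                 config: CohortConfig, out_dir: str | Path) -> Path:
    """Write per-subject TSV time series, the phenotype CSV, and the
    generating config as a JSON sidecar."""
    out = Path(out_dir)
    ts_dir = out / "timeseries"
    ts_dir.mkdir(parents=True, exist_ok=True)
    for ts in series:
        write_timeseries(ts, ts_dir / f"{ts.subject_id}.tsv")
    write_phenotypes(records, out / "phenotypes.csv")
    with open(out / "cohort_config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=2)
    return out
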