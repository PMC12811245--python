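"""End-to-end orchestration: cohort → stationarity → EC → harmonization →
group statistics → prediction, as a configured, logged, seeded run.

A run is described by a single YAML/dict config whose defaults are the
protocol constants of the analysis (GCA order 1 is structural; ADF α = 0.05,
38 retained connections, SVM C = 5, SVR C = 9, 5 folds, 100 repeats, 1000
permutations, 50 % responder threshold, 3/24-month duration terciles).
Every stage appends to a manifest (config hash, seed, subject counts in/out
with exclusion reasons) and the whole run is reproducible: the same config
and seed give byte-identical result tables.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .combat import fit_combat, apply_combat
from .connectivity import StationarityError, ec_matrix, ensure_stationary
from .group_stats import fit_group_lmm, pearson_with_p, responder_label
from .io import default_partition, read_phenotypes, read_timeseries, \
    write_phenotypes
from .prediction import cv_classify, cv_regress, permutation_test
from .synthetic import CohortConfig, CovariateEffects, GroupSpec, SiteSpec, \
    TreatmentConfig, simulate_cohort, simulate_treatment_outcomes

__all__ = ["RunConfig", "run_pipeline", "main"]

log = logging.getLogger("dmnec")

_DEFAULTS: dict = {
    "seed": 0,
    "out_dir": "results/run",
    "cohort": {
        # either synthetic: {} overrides of CohortConfig, or file inputs
        "phenotypes": None,
        "timeseries_dir": None,
        "synthetic": {},
    },
    "stationarity": {"alpha": 0.05, "max_diff": 2},
    "ec": {"compute_f": False},
    "harmonization": {"enabled": True, "scope": "per_connection"},
    "group": {"min_site_n": 10, "contrasts": ["diagnosis"]},
    "prediction": {
        "enabled": True,
        "n_keep": 38,
        "C_classify": 5.0,
        "C_regress": 9.0,
        "folds": 5,
        "repeats": 100,
        "n_perm": 1000,
        "run_permutation": False,
    },
}

_SYNTH_KEYS = {"sites", "groups", "covariate_effects", "treatment", "seed",
               "n_timepoints", "base_coupling", "self_coupling",
               "subject_coupling_sd", "connection_jitter_sd"}


class RunConfig:
    """Validated pipeline configuration (defaults = protocol constants)."""

    def __init__(self, overrides: dict | None = None):
        cfg = copy.deepcopy(_DEFAULTS)
        _merge(cfg, overrides or {}, path="")
        self.cfg = cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def __getitem__(self, key):
        return self.cfg[key]

    def hash(self) -> str:
        blob = json.dumps(self.cfg, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def cohort_config(self) -> CohortConfig:
        raw = copy.deepcopy(self.cfg["cohort"]["synthetic"])
        unknown = set(raw) - _SYNTH_KEYS
        if unknown:
            raise ValueError(f"unknown cohort.synthetic key(s): {sorted(unknown)}")
        if "sites" in raw:
            raw["sites"] = [SiteSpec(**s) for s in raw["sites"]]
        if "groups" in raw:
            raw["groups"] = [GroupSpec(**g) for g in raw["groups"]]
        if "covariate_effects" in raw:
            raw["covariate_effects"] = CovariateEffects(**raw["covariate_effects"])
        if "treatment" in raw:
            raw["treatment"] = TreatmentConfig(**raw["treatment"])
        raw.setdefault("seed", self.cfg["seed"])
        return CohortConfig(**raw)


def _merge(base: dict, override: dict, path: str) -> None:
    for key, value in override.items():
        here = f"{path}.{key}".lstrip(".")
        if key not in base:
            # cohort.synthetic is an open mapping validated separately
            if path.endswith("synthetic"):
                base[key] = value
                continue
            raise ValueError(f"unknown config key: {here!r}")
        if isinstance(base[key], dict) and isinstance(value, dict):
            _merge(base[key], value, here)
        else:
            base[key] = value


def _stage_seed(master: int, index: int) -> int:
    return (master + index) % 2**31


_CONN_LABELS = None


def _connection_labels(partition) -> list[str]:
    return [f"{m}->{p}" for m in partition.members("mPFC")
            for p in partition.members("PCC")]


def run_pipeline(config: RunConfig | dict, out_dir: str | Path | None = None) -> Path:
    """Execute all stages in order; returns the run directory.

    Every stage writes its tables under the run directory and registers a
    manifest entry with subject counts in/out and exclusion reasons; any
    failure halts with the stage and offending subject named.
    """
    if not isinstance(config, RunConfig):
        config = RunConfig(config)
    out = Path(out_dir or config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out / "run.log")
    seed = int(config["seed"])
    partition = default_partition()
    manifest = {
        "package_version": __version__,
        "config": config.cfg,
        "config_hash": config.hash(),
        "seed": seed,
        "versions": _versions(),
        "stages": [],
    }

    # --- stage 1: cohort -------------------------------------------------
    ccfg = config["cohort"]
    if ccfg["phenotypes"]:
        records = read_phenotypes(ccfg["phenotypes"])
        ts_dir = Path(ccfg["timeseries_dir"])
        series = [read_timeseries(ts_dir / f"{r.subject_id}.tsv", r.subject_id)
                  for r in records]
        log.info("cohort: loaded %d subjects from %s", len(records),
                 ccfg["phenotypes"])
    else:
        cohort_cfg = config.cohort_config()
        series, records = simulate_cohort(cohort_cfg, partition)
        log.info("cohort: simulated %d subjects over %d site(s), seed %d",
                 len(records), len(cohort_cfg.sites), cohort_cfg.seed)
    write_phenotypes(records, out / "phenotypes.csv")
    _stage(manifest, "cohort", len(records), len(records), [],
           ["phenotypes.csv"])

    # --- stage 2: stationarity screen ------------------------------------
    alpha = config["stationarity"]["alpha"]
    max_diff = config["stationarity"]["max_diff"]
    log.info("stationarity: ADF alpha=%g, max_diff=%d "
             "(reject unit root => stationary)", alpha, max_diff)
    kept_series, kept_records, excluded = [], [], []
    for ts, rec in zip(series, records):
        try:
            kept_series.append(ensure_stationary(ts, alpha=alpha,
                                                 max_diff=max_diff))
            kept_records.append(rec)
        except StationarityError as e:
            excluded.append({"subject": rec.subject_id, "reason": str(e)})
            log.warning("stationarity: excluding %s", rec.subject_id)
    _stage(manifest, "stationarity", len(records), len(kept_records),
           excluded, [])
    series, records = kept_series, kept_records

    # --- stage 3: effective connectivity ---------------------------------
    log.info("ec: bivariate GCA, order 1, signed path coefficient; "
             "mPFC->PCC block %dx%d", len(partition.members("mPFC")),
             len(partition.members("PCC")))
    conn_labels = _connection_labels(partition)
    feats = np.empty((len(series), len(conn_labels)))
    for i, ts in enumerate(series):
        res = ec_matrix(ts, partition, compute_f=config["ec"]["compute_f"])
        feats[i] = res.block_vector()
        records[i].mean_ec_mpfc_pcc = res.mean_mpfc_to_pcc
    feat_df = pd.DataFrame(feats, columns=conn_labels)
    feat_df.insert(0, "subject_id", [r.subject_id for r in records])
    feat_df.to_csv(out / "ec_features.csv", index=False)
    write_phenotypes(records, out / "phenotypes_with_ec.csv")
    _stage(manifest, "ec", len(series), len(series), [],
           ["ec_features.csv", "phenotypes_with_ec.csv"])

    # --- stage 4: harmonization ------------------------------------------
    if config["harmonization"]["enabled"]:
        scope = config["harmonization"]["scope"]
        sites = np.array([r.site for r in records])
        cov = np.array([[r.age, r.sex, r.motion] for r in records], dtype=float)
        n_sites = len(set(sites))
        if n_sites < 2:
            log.info("harmonization: single site, skipping (nothing to harmonize)")
            harmonized = feats
        else:
            values = feats if scope == "per_connection" else \
                np.array([r.mean_ec_mpfc_pcc for r in records])
            model = fit_combat(values, sites, cov, ("age", "sex", "motion"))
            adj = apply_combat(model, values, sites, cov)
            harmonized = adj if scope == "per_connection" else feats
            model.to_json(out / "combat_model.json")
            if scope == "per_connection":
                for i, r in enumerate(records):
                    r.mean_ec_mpfc_pcc = float(adj[i].mean())
            else:
                for i, r in enumerate(records):
                    r.mean_ec_mpfc_pcc = float(adj[i])
            log.info("harmonization: ComBat over %d site(s), scope=%s, "
                     "covariates age/sex/motion", n_sites, scope)
        harm_df = pd.DataFrame(
            harmonized if scope == "per_connection" else feats,
            columns=conn_labels)
        harm_df.insert(0, "subject_id", [r.subject_id for r in records])
        harm_df.to_csv(out / "harmonized_features.csv", index=False)
        feats = harmonized if scope == "per_connection" else feats
        write_phenotypes(records, out / "phenotypes_harmonized.csv")
        _stage(manifest, "harmonization", len(records), len(records), [],
               ["harmonized_features.csv", "phenotypes_harmonized.csv"])
    else:
        _stage(manifest, "harmonization", len(records), len(records), [], [])

    # --- stage 5: group statistics + treatment outcomes ------------------
    rows = []
    for contrast in config["group"]["contrasts"]:
        try:
            res = fit_group_lmm(records, contrast,
                                min_site_n=config["group"]["min_site_n"])
            rows.append(res.summary_row())
            log.info("group: %s t=%.3f p=%.4f d=%.4f (n1=%d, n2=%d, %d sites)",
                     contrast, res.t_value, res.p_value, res.cohens_d,
                     res.n1, res.n2, res.n_sites)
        except (ValueError, RuntimeError) as e:
            log.warning("group: contrast %s skipped: %s", contrast, e)
    pd.DataFrame(rows).to_csv(out / "group_contrasts.csv", index=False)

    treated = [r for r in records if r.hamd_pre is not None]
    treatment_summary: dict = {"n_treated": len(treated)}
    if treated and not ccfg["phenotypes"]:
        cohort_cfg = config.cohort_config()
        simulate_treatment_outcomes(
            treated, cohort_cfg, _stage_seed(seed, 5),
            baseline_ec=np.array([r.mean_ec_mpfc_pcc for r in treated]))
    if treated and all(r.hamd_post is not None for r in treated):
        responders = [responder_label(r.hamd_pre, r.hamd_post) for r in treated]
        delta = np.array([r.hamd_pre - r.hamd_post for r in treated])
        ec = np.array([r.mean_ec_mpfc_pcc for r in treated])
        r_val, p_val = pearson_with_p(ec, delta)
        treatment_summary.update(
            n_responders=int(sum(responders)),
            responder_fraction=float(np.mean(responders)),
            ec_delta_hamd_r=r_val, ec_delta_hamd_p=p_val,
        )
        log.info("treatment: %d/%d responders (>=50%% HAMD-17 reduction); "
                 "EC~dHAMD r=%.3f p=%.4f", sum(responders), len(treated),
                 r_val, p_val)
    with open(out / "treatment_summary.json", "w") as fh:
        json.dump(treatment_summary, fh, indent=2)
    write_phenotypes(records, out / "phenotypes_final.csv")
    _stage(manifest, "group_stats", len(records), len(records), [],
           ["group_contrasts.csv", "treatment_summary.json",
            "phenotypes_final.csv"])

    # --- stage 6: prediction ----------------------------------------------
    pcfg = config["prediction"]
    pred_out: dict = {}
    if pcfg["enabled"] and treated and all(r.hamd_post is not None
                                           for r in treated):
        idx = [i for i, r in enumerate(records) if r.hamd_pre is not None]
        x = feats[idx]
        labels = np.array([responder_label(records[i].hamd_pre,
                                           records[i].hamd_post)
                           for i in idx], dtype=int)
        delta = np.array([records[i].hamd_pre - records[i].hamd_post
                          for i in idx])
        try:
            rep = cv_classify(x, labels, n_keep=pcfg["n_keep"],
                              C=pcfg["C_classify"], folds=pcfg["folds"],
                              repeats=pcfg["repeats"],
                              seed=_stage_seed(seed, 6))
            if pcfg["run_permutation"]:
                rep.permutation_p = permutation_test(
                    x, labels, rep.metrics["accuracy"],
                    n_perm=pcfg["n_perm"], seed=_stage_seed(seed, 7),
                    n_keep=pcfg["n_keep"], C=pcfg["C_classify"],
                    folds=pcfg["folds"])
            pred_out["classification"] = rep.to_dict()
            log.info("prediction: classification acc=%.3f auc=%.3f mcc=%.3f",
                     rep.metrics["accuracy"], rep.metrics["auc"],
                     rep.metrics["mcc"])
        except ValueError as e:
            log.warning("prediction: classification skipped: %s", e)
        try:
            reg = cv_regress(x, delta, n_keep=pcfg["n_keep"],
                             C=pcfg["C_regress"], folds=pcfg["folds"],
                             seed=_stage_seed(seed, 8))
            pred_out["regression"] = reg.to_dict()
            log.info("prediction: regression r=%.3f mae=%.2f rmse=%.2f",
                     reg.metrics["pearson_r"], reg.metrics["mae"],
                     reg.metrics["rmse"])
        except ValueError as e:
            log.warning("prediction: regression skipped: %s", e)
    with open(out / "prediction_report.json", "w") as fh:
        json.dump(pred_out, fh, indent=2)
    _stage(manifest, "prediction", len(treated), len(treated), [],
           ["prediction_report.json"])

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    log.info("run complete: %d stages, outputs in %s",
             len(manifest["stages"]), out)
    return out


def _stage(manifest, name, n_in, n_out, excluded, outputs):
    manifest["stages"].append({
        "name": name, "n_in": n_in, "n_out": n_out,
        "n_excluded": len(excluded), "excluded": excluded,
        "outputs": outputs,
    })
    assert n_in == n_out + len(excluded), f"subject count leak in stage {name}"


def _versions() -> dict:
    import sklearn
    import statsmodels

    return {"numpy": np.__version__, "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
            "statsmodels": statsmodels.__version__, "dmnec": __version__}


def _setup_logging(path: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers = [h for h in log.handlers
                    if not isinstance(h, logging.FileHandler)]
    fh = logging.FileHandler(path, mode="w")
    fh.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(fh)
    if not any(isinstance(h, logging.StreamHandler)
               and not isinstance(h, logging.FileHandler)
               for h in log.handlers):
        sh = logging.StreamHandler()
        sh.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        log.addHandler(sh)


# ----------------------------------------------------------------------
# command-line interface

import click


@click.group()
def main():
    """DMN effective-connectivity treatment-response pipeline."""


@main.command()
@click.option("--config", "config_path", required=True,
              type=click.Path(exists=True), help="YAML run configuration.")
@click.option("--out", "out_dir", default=None, help="Override output directory.")
def run(config_path, out_dir):
    """Run the full pipeline from a YAML config."""
    run_pipeline(RunConfig.from_yaml(config_path), out_dir)


@main.command()
@click.argument("task", type=click.Choice(["classify", "regress"]))
@click.option("--features", required=True, type=click.Path(exists=True),
              help="CSV with subject_id + one column per EC connection.")
@click.option("--phenotypes", required=True, type=click.Path(exists=True))
@click.option("--n-keep", default=38, show_default=True)
@click.option("--c", "c_value", default=None, type=float,
              help="SVM/SVR C (defaults: 5 classify, 9 regress).")
@click.option("--folds", default=5, show_default=True)
@click.option("--repeats", default=100, show_default=True)
@click.option("--n-perm", default=0, show_default=True,
              help="Label permutations for significance (0 = skip).")
@click.option("--seed", default=0, show_default=True)
@click.option("--out", "out_dir", default=".", show_default=True)
def predict(task, features, phenotypes, n_keep, c_value, folds, repeats,
            n_perm, seed, out_dir):
    """Treatment-response prediction from an EC feature table."""
    feat_df = pd.read_csv(features)
    records = read_phenotypes(phenotypes)
    by_id = {r.subject_id: r for r in records}
    rows = [by_id[s] for s in feat_df["subject_id"]]
    x = feat_df.drop(columns="subject_id").to_numpy(float)
    keep = [i for i, r in enumerate(rows)
            if r.hamd_pre is not None and r.hamd_post is not None]
    x = x[keep]
    rows = [rows[i] for i in keep]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if task == "classify":
        y = np.array([responder_label(r.hamd_pre, r.hamd_post) for r in rows],
                     dtype=int)
        rep = cv_classify(x, y, n_keep=n_keep, C=c_value or 5.0, folds=folds,
                          repeats=repeats, seed=seed)
        if n_perm:
            rep.permutation_p = permutation_test(
                x, y, rep.metrics["accuracy"], n_perm=n_perm, seed=seed + 1,
                n_keep=n_keep, C=c_value or 5.0, folds=folds)
    else:
        delta = np.array([r.hamd_pre - r.hamd_post for r in rows])
        rep = cv_regress(x, delta, n_keep=n_keep, C=c_value or 9.0,
                         folds=folds, seed=seed)
    with open(out / f"prediction_{task}.json", "w") as fh:
        json.dump(rep.to_dict(), fh, indent=2)
    click.echo(json.dumps(rep.metrics, indent=2))


if __name__ == "__main__":
    main()
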