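"""Support-vector regression of symptom improvement.

Predicts the HAMD-17 change of the treated subjects from the 132
harmonized mPFC→PCC connections with linear-kernel SVR (C=9), within-fold
scaling and L1-RFE to 38 connections, reporting Pearson r, MAE and RMSE on
pooled out-of-fold predictions — in the leakage-safe per-fold selection
mode and in the global replication mode (connections selected once before
cross-validation, the variant implied by published performance levels).

Run after 05:  python analysis/06_predict_improvement.py
"""

import json
import sys
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from dmnec import cv_regress
from dmnec.io import read_phenotypes

SEED = 22


def main() -> None:
    warnings.filterwarnings("ignore")
    results = ROOT / "results"
    records = read_phenotypes(results / "phenotypes_with_outcomes.csv")
    feats = pd.read_csv(ROOT / "scratch" / "cohort" / "harmonized_features.csv")
    treated = {r.subject_id: r for r in records
               if r.hamd_pre is not None and r.hamd_post is not None}
    rows = feats[feats["subject_id"].isin(treated)]
    x = rows.drop(columns="subject_id").to_numpy(float)
    delta = np.array([treated[s].hamd_pre - treated[s].hamd_post
                      for s in rows["subject_id"]])

    out = {}
    for mode in ("per_fold", "global"):
        rep = cv_regress(x, delta, n_keep=38, C=9.0, folds=5, seed=SEED,
                         selection=mode)
        m = rep.metrics
        out[mode] = rep.to_dict()
        print(f"SVR [{mode:8s}] r={m['pearson_r']:+.3f}  "
              f"mae={m['mae']:.2f}  rmse={m['rmse']:.2f}  (n={rep.n_subjects})")
    with open(results / "regression_report.json", "w") as fh:
        json.dump(out, fh, indent=2)
    print(f"report -> {results / 'regression_report.json'}")


if __name__ == "__main__":
    main()
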