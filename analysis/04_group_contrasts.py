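"""Mixed-model group contrasts on harmonized mean mPFC→PCC EC.

Fits y ~ 1 + Group + Age + Sex + Education + Motion + (1|Site) +
(Group|Site) by maximum likelihood for the diagnosis, episode, medication
and illness-duration-tercile contrasts, converting each t to a Cohen's d.
Sites contribute only with more than the minimum per-group count.

Run after 03:  python analysis/04_group_contrasts.py
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from dmnec import fit_group_lmm
from dmnec.io import read_phenotypes

CONTRASTS = ["diagnosis", "episode", "medication_on", "duration_tercile"]


def main() -> None:
    results = ROOT / "results"
    records = read_phenotypes(results / "phenotypes_harmonized.csv")
    rows = []
    for contrast in CONTRASTS:
        try:
            res = fit_group_lmm(records, contrast, min_site_n=10)
        except (ValueError, RuntimeError) as e:
            print(f"{contrast:18s} skipped: {e}")
            continue
        rows.append(res.summary_row())
        print(f"{contrast:18s} t={res.t_value:+.3f}  p={res.p_value:.4f}  "
              f"d={res.cohens_d:+.4f}  (n1={res.n1}, n2={res.n2}, "
              f"{res.n_sites} sites)")
    pd.DataFrame(rows).to_csv(results / "group_contrasts.csv", index=False)
    print(f"contrast table -> {results / 'group_contrasts.csv'}")


if __name__ == "__main__":
    main()
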