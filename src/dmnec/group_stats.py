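"""Group-level inference on mean mPFC→PCC effective connectivity.

The primary contrast is a linear mixed-effects model

    y ~ 1 + Group + Age + Sex + Education + Motion + (1 | Site) + (Group | Site)

fitted by maximum likelihood, with the t statistic of the Group fixed effect
referenced against a residual-df t distribution and converted to a Cohen's d
effect size via d = T·(n₁+n₂) / (√df·√(n₁·n₂)). Subgroup contrasts swap the
Group variable (diagnosis, episode status, medication status, illness-
duration tercile) in both the fixed and the random part. Sites contribute to
a two-group contrast only when they have more than a minimum number of
subjects in each group (default 10).

Also provided: paired pre/post t tests, Pearson correlation with its t-based
p, the ≥50 % HAMD-17 reduction responder rule, and the responder vs
non-responder ΔEC comparison (Welch).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

from .io import SubjectRecord, records_to_frame

__all__ = [
    "LmmResult",
    "fit_group_lmm",
    "cohens_d_from_t",
    "duration_terciles",
    "paired_pre_post_test",
    "responder_label",
    "pearson_with_p",
    "responder_delta_ec_test",
]

#: contrast field → (reference level, test level); coded 0/1 in the model
_CONTRAST_LEVELS = {
    "diagnosis": ("NC", "MDD"),
    "episode": ("FEDN", "recurrent"),
    "medication_on": (False, True),
    "duration_tercile": ("short", "long"),
}

_COVARIATES = ["age", "sex", "education", "motion"]


@dataclass
class LmmResult:
    """Outcome of one mixed-model group contrast."""

    contrast: str
    t_value: float
    p_value: float
    df: float
    cohens_d: float
    n1: int
    n2: int
    n_sites: int
    fixed_effects: pd.DataFrame
    converged: bool
    random_slope_dropped: bool = False
    single_site_ols: bool = False
    n_excluded_missing: int = 0
    n_excluded_site_filter: int = 0

    def summary_row(self) -> dict:
        return {
            "contrast": self.contrast, "n1": self.n1, "n2": self.n2,
            "t": self.t_value, "df": self.df, "p": self.p_value,
            "d": self.cohens_d, "n_sites": self.n_sites,
            "converged": self.converged,
        }


def cohens_d_from_t(t: float, n1: int, n2: int, df: float) -> float:
    """Effect size from a group-contrast t statistic:
    d = T·(n₁+n₂)/(√df·√(n₁·n₂))."""
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be ≥ 1")
    if df <= 0:
        raise ValueError(f"df must be > 0, got {df}")
    return float(t * (n1 + n2) / (np.sqrt(df) * np.sqrt(n1 * n2)))


def duration_terciles(
    records: Sequence[SubjectRecord],
    short_max: float = 3.0, long_min: float = 24.0,
) -> list[str | None]:
    """Label subjects by illness duration: ≤ short_max months → "short",
    ≥ long_min → "long", otherwise "middle" (None when missing).

    Defaults are the fixed 3- and 24-month bounds separating the shortest
    and longest duration terciles; boundary values are included in the outer
    groups.
    """
    durations = [r.illness_duration_months for r in records]
    if all(d is None for d in durations):
        raise ValueError("illness duration missing for every subject")
    labels: list[str | None] = []
    for d in durations:
        if d is None:
            labels.append(None)
        elif d <= short_max:
            labels.append("short")
        elif d >= long_min:
            labels.append("long")
        else:
            labels.append("middle")
    return labels


def fit_group_lmm(
    records: Sequence[SubjectRecord],
    contrast_field: str,
    value_field: str = "mean_ec_mpfc_pcc",
    min_site_n: int = 10,
) -> LmmResult:
    """Mixed-model contrast on mean EC (see module docstring).

    Subjects missing the outcome, the contrast field or any covariate are
    dropped (count reported); sites then need more than ``min_site_n``
    subjects in each group. Non-convergence with the random slope falls
    back to a random-intercept-only fit (flagged); all-one-site data fall
    back to OLS (flagged).
    """
    if contrast_field not in _CONTRAST_LEVELS:
        raise ValueError(
            f"unknown contrast {contrast_field!r}; expected one of "
            f"{sorted(_CONTRAST_LEVELS)}"
        )
    df = records_to_frame(records)
    df["y"] = df[value_field]
    if contrast_field == "duration_tercile":
        df["duration_tercile"] = duration_terciles(records)
        df = df[df["duration_tercile"].isin(["short", "long"])]
    ref, test = _CONTRAST_LEVELS[contrast_field]
    keep = df[contrast_field].isin([ref, test])
    df = df[keep]
    n_before = len(df)
    df = df.dropna(subset=["y", contrast_field, *_COVARIATES, "site"])
    n_missing = n_before - len(df)
    df = df.copy()
    df["grp"] = (df[contrast_field] == test).astype(float)
    if df["grp"].nunique() < 2:
        raise ValueError(
            f"contrast field {contrast_field!r} has fewer than 2 levels present"
        )

    counts = df.groupby(["site", "grp"]).size().unstack(fill_value=0)
    ok_sites = counts.index[(counts > min_site_n).all(axis=1)] if counts.shape[1] == 2 \
        else counts.index[:0]
    n_site_filtered = int(len(df) - df["site"].isin(ok_sites).sum())
    df = df[df["site"].isin(ok_sites)]
    if df.empty or df["grp"].nunique() < 2:
        raise ValueError(
            f"no site has more than {min_site_n} subjects in both groups "
            f"for contrast {contrast_field!r}"
        )

    n1 = int((df["grp"] == 0).sum())
    n2 = int((df["grp"] == 1).sum())
    n_sites = df["site"].nunique()
    formula = "y ~ grp + age + sex + education + motion"
    n = len(df)
    dof = float(n - 6)  # residual df: n − rank of the fixed-effects design

    converged, slope_dropped, single_site = True, False, False
    if n_sites == 1:
        res = smf.ols(formula, data=df).fit()
        fe = _fe_table(res.params, res.bse)
        tval = float(res.tvalues["grp"])
        single_site = True
    else:
        res = _fit_mixed(formula, df, "~grp")
        if res is None or not res.converged:
            res = _fit_mixed(formula, df, None)
            slope_dropped = True
        if res is None:
            raise RuntimeError("mixed model failed to converge even without "
                               "the random slope")
        converged = bool(res.converged)
        fe = _fe_table(res.fe_params, res.bse_fe)
        tval = float(res.fe_params["grp"] / res.bse_fe["grp"])

    p = float(2 * stats.t.sf(abs(tval), dof))
    d = cohens_d_from_t(tval, n1, n2, dof)
    return LmmResult(
        contrast=contrast_field, t_value=tval, p_value=p, df=dof,
        cohens_d=d, n1=n1, n2=n2, n_sites=n_sites, fixed_effects=fe,
        converged=converged, random_slope_dropped=slope_dropped,
        single_site_ols=single_site,
        n_excluded_missing=n_missing, n_excluded_site_filter=n_site_filtered,
    )


def _fit_mixed(formula: str, df: pd.DataFrame, re_formula: str | None):
    """ML fit with a small multi-start over optimizers, keeping the best
    log-likelihood among converged solutions (variance-component surfaces
    with few sites are flat enough that single-optimizer fits stall)."""
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(formula, df, groups=df["site"],
                                re_formula=re_formula)
        except (np.linalg.LinAlgError, ValueError):
            return None
        for method in (None, "lbfgs", "powell"):
            try:
                res = model.fit(reml=False) if method is None else \
                    model.fit(reml=False, method=method)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if res.converged and (best is None or res.llf > best.llf + 1e-8):
                best = res
            if best is not None and method is None:
                break  # default fit converged; accept it
    return best


def _fe_table(params, bse) -> pd.DataFrame:
    return pd.DataFrame({"coef": params, "se": bse})


def paired_pre_post_test(pre: np.ndarray, post: np.ndarray) -> tuple[float, float, float]:
    """Classical paired t test (df = n−1) with d = mean(diff)/sd(diff),
    diff = pre − post.

    Identical pairs give (0, 1, 0); a nonzero constant difference has zero
    variance and is an error.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be matched vectors")
    n = pre.size
    if n < 3:
        raise ValueError(f"need n ≥ 3 matched pairs, got {n}")
    diff = pre - post
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.all(diff == 0):
            return 0.0, 1.0, 0.0
        raise ValueError("zero-variance nonzero differences: paired t undefined")
    t = diff.mean() / (sd / np.sqrt(n))
    p = float(2 * stats.t.sf(abs(t), n - 1))
    return float(t), p, float(diff.mean() / sd)


def responder_label(hamd_pre: float, hamd_post: float) -> bool:
    """Treatment responder: HAMD-17 reduction of 50 % or greater."""
    if hamd_pre <= 0:
        raise ValueError(f"hamd_pre must be > 0, got {hamd_pre}")
    return (hamd_pre - hamd_post) / hamd_pre >= 0.5


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation with the two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched vectors with n ≥ 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def responder_delta_ec_test(
    delta_ec_responders: np.ndarray, delta_ec_nonresponders: np.ndarray,
) -> tuple[float, float]:
    """Welch two-sample t comparing the post−pre EC change between
    responders and non-responders."""
    a = np.asarray(delta_ec_responders, dtype=float)
    b = np.asarray(delta_ec_nonresponders, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 subjects")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
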