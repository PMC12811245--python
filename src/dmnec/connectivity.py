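"""Stationarity screening and order-1 Granger-causality effective connectivity.

The effective-connectivity (EC) measure is the signed lag-1 path coefficient
of bivariate Granger causality: for an ordered ROI pair (x → y), fit

    y_t = c + a·y_{t-1} + b·x_{t-1} + e_t

by OLS and report b. A positive b means past activity in x drives y up; the
sign is retained (connectivity reductions in patients are signed effects).
A log-ratio variant, ln(RSS_restricted / RSS_full) with its F test, is
available for significance-style analyses.

Before estimation every ROI series is screened for a unit root with the
augmented Dickey-Fuller (ADF) test (constant term, AIC lag selection);
series for which the unit-root null is not rejected are first-differenced
iteratively (standard convention: rejecting the unit root supports
stationarity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.tsa.adfvalues import mackinnonp

from .io import DmnPartition, RoiTimeSeries

__all__ = [
    "EcResult",
    "StationarityError",
    "adf_test",
    "ensure_stationary",
    "pairwise_ec",
    "pairwise_gc",
    "ec_matrix",
]


class StationarityError(ValueError):
    """A series could not be made stationary within the allowed differencing."""


def default_adf_maxlag(t: int) -> int:
    """Schwert's rule ⌊12·(T/100)^{1/4}⌋."""
    return int(np.floor(12.0 * (t / 100.0) ** 0.25))


def adf_test(series: np.ndarray, max_lag: int | None = None) -> tuple[float, float]:
    """Augmented Dickey-Fuller unit-root test with a constant term.

    The test regression is Δy_t = c + ρ·y_{t-1} + Σ φ_i·Δy_{t-i} + e_t with
    the augmentation order chosen by AIC up to ``max_lag`` (default
    ⌊12(T/100)^¼⌋); candidate orders are compared on a common sample, then
    the chosen order is refit on all usable observations. The p-value comes
    from MacKinnon's response surface for the constant-only case.

    Returns
    -------
    (statistic, p) : the t-ratio on ρ and its unit-root p-value. Small p
    rejects the unit root, i.e. supports stationarity.
    """
    y = np.asarray(series, dtype=float).ravel()
    t = y.size
    if t < 20:
        raise ValueError(f"ADF test needs T ≥ 20, got {t}")
    if np.ptp(y) == 0 or np.std(y) == 0:
        raise ValueError("ADF test undefined for a constant series")
    if max_lag is None:
        max_lag = default_adf_maxlag(t)
    max_lag = int(min(max_lag, (t - 1) // 2 - 2))
    max_lag = max(max_lag, 0)

    dy = np.diff(y)
    # Common estimation sample across candidate lags for AIC comparability.
    best_lag, best_aic = 0, np.inf
    n_common = t - 1 - max_lag
    for k in range(max_lag + 1):
        _, ssr, nobs, nparam = _adf_ols(y, dy, k, start=max_lag)
        aic = n_common * np.log(ssr / nobs) + 2 * nparam
        if aic < best_aic - 1e-12:
            best_aic, best_lag = aic, k
    stat, _, _, _ = _adf_ols(y, dy, best_lag, start=best_lag)
    p = float(mackinnonp(stat, regression="c", N=1))
    return float(stat), p


def _adf_ols(y: np.ndarray, dy: np.ndarray, k: int, start: int):
    """Fit the ADF regression with k augmentation lags, dropping the first
    ``start`` usable rows; return (t-ratio on the level term, SSR, nobs, nparams)."""
    t = y.size
    # rows of dy usable: indices start..t-2 (dy[i] = y[i+1]-y[i])
    resp = dy[start:]
    n = resp.size
    cols = [np.ones(n), y[start : t - 1]]
    for j in range(1, k + 1):
        cols.append(dy[start - j : t - 1 - j])
    x = np.column_stack(cols)
    beta, _, rank, _ = np.linalg.lstsq(x, resp, rcond=None)
    resid = resp - x @ beta
    ssr = float(resid @ resid)
    dof = n - x.shape[1]
    sigma2 = ssr / dof
    xtx_inv = np.linalg.pinv(x.T @ x)
    se_rho = np.sqrt(sigma2 * xtx_inv[1, 1])
    return beta[1] / se_rho, ssr, n, x.shape[1]


def ensure_stationary(
    ts: RoiTimeSeries, alpha: float = 0.05, max_diff: int = 2,
    max_lag: int | None = None,
) -> RoiTimeSeries:
    """Difference each non-stationary ROI series until the ADF test rejects
    the unit root at ``alpha``, up to ``max_diff`` times.

    All series are then truncated (from the front) to the common shortest
    length so the matrix stays rectangular; per-ROI differencing orders are
    recorded in ``diff_order_applied``.

    Raises
    ------
    StationarityError
        If any ROI still fails the screen after ``max_diff`` differences;
        the caller should exclude the subject and log the reason.
    """
    orders = np.zeros(ts.n_rois, dtype=int)
    worked: list[np.ndarray] = []
    for j in range(ts.n_rois):
        x = ts.values[:, j]
        d = 0
        _, p = adf_test(x, max_lag)
        while p > alpha and d < max_diff:
            x = np.diff(x)
            d += 1
            _, p = adf_test(x, max_lag)
        if p > alpha:
            raise StationarityError(
                f"ROI {ts.roi_labels[j]!r} of subject {ts.subject_id!r} remains "
                f"non-stationary after {max_diff} differences (ADF p = {p:.3f})"
            )
        orders[j] = d
        worked.append(x)
    length = min(x.size for x in worked)
    values = np.column_stack([x[-length:] for x in worked])
    return RoiTimeSeries(values, ts.roi_labels, diff_order_applied=orders,
                         subject_id=ts.subject_id)


def _gc_design(x: np.ndarray, y: np.ndarray):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("series must have equal length")
    t = x.size
    if t < 20:
        raise ValueError(f"need T ≥ 20, got {t}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant series: effective connectivity undefined")
    x = x - x.mean()
    y = y - y.mean()
    ylag, xlag, resp = y[:-1], x[:-1], y[1:]
    # collinear lagged regressors make the path coefficient unidentifiable
    r = np.corrcoef(xlag, ylag)[0, 1]
    if abs(r) > 1 - 1e-10:
        raise ValueError("x_{t-1} and y_{t-1} are collinear; coefficient unidentifiable")
    full = np.column_stack([np.ones(t - 1), ylag, xlag])
    return full, resp, ylag


def pairwise_ec(x: np.ndarray, y: np.ndarray) -> float:
    """Signed lag-1 Granger path coefficient of x → y (see module docstring)."""
    full, resp, _ = _gc_design(x, y)
    beta, *_ = np.linalg.lstsq(full, resp, rcond=None)
    return float(beta[2])


def pairwise_gc(x: np.ndarray, y: np.ndarray) -> dict:
    """Full order-1 bivariate GC decomposition of x → y.

    Returns the signed path coefficient plus the restricted/full residual
    sum-of-squares comparison: the log-ratio statistic ln(RSS_r/RSS_f),
    the equivalent F statistic with (1, T−4) df and its p-value.
    """
    full, resp, ylag = _gc_design(x, y)
    n = resp.size
    beta, *_ = np.linalg.lstsq(full, resp, rcond=None)
    resid_f = resp - full @ beta
    rss_f = float(resid_f @ resid_f)
    restricted = full[:, :2]
    beta_r, *_ = np.linalg.lstsq(restricted, resp, rcond=None)
    resid_r = resp - restricted @ beta_r
    rss_r = float(resid_r @ resid_r)
    df_resid = n - 3
    f_stat = (rss_r - rss_f) / (rss_f / df_resid)
    from scipy import stats

    p = float(stats.f.sf(f_stat, 1, df_resid))
    return {
        "coef": float(beta[2]),
        "log_ratio": float(np.log(rss_r / rss_f)),
        "f_stat": float(f_stat),
        "p": p,
    }


@dataclass
class EcResult:
    """Directed EC of one subject.

    ``ec[i, j]`` is the signed lag-1 influence of ROI i on ROI j (NaN on the
    diagonal). The mPFC→PCC block is the (mPFC rows × PCC columns) submatrix
    — 12×11 = 132 directed connections under the default partition — and
    ``mean_mpfc_to_pcc`` is the arithmetic mean of its entries.
    """

    ec: np.ndarray
    mpfc_to_pcc_block: np.ndarray
    mean_mpfc_to_pcc: float
    roi_labels: tuple[str, ...]
    f_stats: np.ndarray | None = None
    subject_id: str | None = None

    def block_vector(self) -> np.ndarray:
        """The 132 mPFC→PCC connections flattened row-major (mPFC-major)."""
        return self.mpfc_to_pcc_block.ravel()


def ec_matrix(ts: RoiTimeSeries, partition: DmnPartition,
              compute_f: bool = False) -> EcResult:
    """All-pairs order-1 Granger EC over the ROI set of ``ts``.

    Every ordered pair (i, j), i ≠ j, gets the signed path coefficient of
    ROI_i → ROI_j; optionally the per-connection F statistic as well.
    """
    ts.check_labels(partition)
    v = ts.values
    n = ts.n_rois
    for j in range(n):
        if np.std(v[:, j]) == 0:
            raise ValueError(
                f"ROI {ts.roi_labels[j]!r} is constant; run the stationarity "
                "screen / exclude before EC estimation"
            )
    ec = np.full((n, n), np.nan)
    fmat = np.full((n, n), np.nan) if compute_f else None
    vc = v - v.mean(axis=0)
    t = v.shape[0]
    ones = np.ones(t - 1)
    for j in range(n):  # target
        resp = vc[1:, j]
        ylag = vc[:-1, j]
        base = np.column_stack([ones, ylag])
        for i in range(n):  # source
            if i == j:
                continue
            xlag = vc[:-1, i]
            r = np.corrcoef(xlag, ylag)[0, 1]
            if abs(r) > 1 - 1e-10:
                raise ValueError(
                    f"collinear lagged series for pair "
                    f"({ts.roi_labels[i]!r} → {ts.roi_labels[j]!r})"
                )
            design = np.column_stack([base, xlag])
            beta, *_ = np.linalg.lstsq(design, resp, rcond=None)
            ec[i, j] = beta[2]
            if compute_f:
                resid_f = resp - design @ beta
                rss_f = resid_f @ resid_f
                beta_r, *_ = np.linalg.lstsq(base, resp, rcond=None)
                resid_r = resp - base @ beta_r
                rss_r = resid_r @ resid_r
                fmat[i, j] = (rss_r - rss_f) / (rss_f / (resp.size - 3))
    mpfc_idx = partition.indices("mPFC")
    pcc_idx = partition.indices("PCC")
    block = ec[np.ix_(mpfc_idx, pcc_idx)]
    return EcResult(
        ec=ec,
        mpfc_to_pcc_block=block,
        mean_mpfc_to_pcc=float(block.mean()),
        roi_labels=ts.roi_labels,
        f_stats=fmat,
        subject_id=ts.subject_id,
    )
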