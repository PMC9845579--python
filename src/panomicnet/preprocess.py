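"""Low-level normalization and testing for proteomic/metabolomic feature matrices.

Covers the stated upstream formulas: per-feature regression normalization of
log-intensities against sample-processing covariates (linear or natural cubic
spline), run-day median scaling to 1.0, observed-minimum imputation, paired
t-tests per feature, and Storey q-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "IntensityMatrix",
    "normalize_intensity",
    "runday_median_normalize",
    "impute_min",
    "paired_feature_test",
    "covariate_feature_test",
    "storey_qvalues",
]


@dataclass
class IntensityMatrix:
    """Features x samples log-intensity matrix with per-sample run covariates.

    ``run_covariates`` has one row per sample (matching the matrix columns)
    and numeric columns such as processing order; a ``run_day`` label column
    may also be present.
    """

    log_intensities: pd.DataFrame
    run_covariates: pd.DataFrame

    def __post_init__(self) -> None:
        if self.run_covariates.shape[0] != self.log_intensities.shape[1]:
            raise ValueError("one covariate row per sample is required")


def _natural_cubic_basis(x: np.ndarray, n_knots: int = 4) -> np.ndarray:
    """Natural cubic spline basis (no intercept column) with interior knots
    at equally spaced quantiles of x.

    Standard truncated-power construction with linearity constraints beyond
    the boundary knots; yields n_knots columns for n_knots + 2 knots total.
    """
    qs = np.linspace(0, 1, n_knots + 2)
    knots = np.quantile(x, qs)
    knots = np.unique(knots)
    if knots.size < 3:
        # not enough distinct values to support a spline; linear fallback
        return x[:, None].astype(float)
    k = knots
    kmax = k[-1]

    def d(j):
        num = np.maximum(x - k[j], 0.0) ** 3 - np.maximum(x - kmax, 0.0) ** 3
        return num / (kmax - k[j])

    cols = [x.astype(float)]
    last = d(len(k) - 2)
    for j in range(len(k) - 2):
        cols.append(d(j) - last)
    return np.column_stack(cols)


def normalize_intensity(
    m: IntensityMatrix,
    mode: str = "linear",
    covariate_columns: list[str] | None = None,
    n_knots: int = 4,
) -> IntensityMatrix:
    """Remove processing drift per feature while preserving each feature's mean.

    For every feature: compute the mean raw log-intensity, regress the
    log-intensities on the processing covariates (linear, or natural cubic
    spline with ``n_knots`` interior knots), and output
    ``raw - predicted + mean``.  A degenerate design (constant covariate)
    falls back to the identity with a warning.
    """
    if mode not in ("linear", "spline"):
        raise ValueError("mode must be 'linear' or 'spline'")
    X_raw = m.log_intensities.to_numpy(dtype=float)
    if X_raw.shape[1] < 3:
        raise ValueError("need at least 3 samples per feature")

    cov = m.run_covariates
    if covariate_columns is None:
        covariate_columns = [c for c in cov.columns if pd.api.types.is_numeric_dtype(cov[c])]
    if not covariate_columns:
        raise ValueError("no numeric processing covariates available")

    bases = []
    degenerate = False
    for c in covariate_columns:
        x = cov[c].to_numpy(dtype=float)
        if np.ptp(x) == 0.0:
            degenerate = True
            continue
        bases.append(x[:, None] if mode == "linear" else _natural_cubic_basis(x, n_knots))
    if degenerate and not bases:
        logger.warning("all processing covariates constant; normalization is identity")
        return IntensityMatrix(m.log_intensities.copy(), m.run_covariates.copy())
    if degenerate:
        logger.warning("constant processing covariate dropped from normalization design")

    D = np.column_stack([np.ones(X_raw.shape[1])] + bases)
    # hat projection shared across features
    pinv = np.linalg.pinv(D)
    out = np.empty_like(X_raw)
    obs = ~np.isnan(X_raw)
    for i in range(X_raw.shape[0]):
        row = X_raw[i]
        mask = obs[i]
        mean_raw = row[mask].mean()
        if mask.all():
            predicted = D @ (pinv @ row)
        else:
            Dm = D[mask]
            beta, *_ = np.linalg.lstsq(Dm, row[mask], rcond=None)
            predicted = D @ beta
        out[i] = row - predicted + mean_raw
    result = pd.DataFrame(out, index=m.log_intensities.index, columns=m.log_intensities.columns)
    return IntensityMatrix(result, m.run_covariates.copy())


def runday_median_normalize(
    m: pd.DataFrame, runday: pd.Series | list[str]
) -> tuple[pd.DataFrame, list[str]]:
    """Divide each feature by its within-run-day median, setting medians to 1.0.

    Returns the scaled matrix and the list of features flagged for a zero
    within-day median (left unscaled on that day).
    """
    runday = pd.Series(list(runday), index=m.columns)
    out = m.astype(float).copy()
    flagged: set[str] = set()
    for day in runday.unique():
        cols = runday.index[runday == day]
        block = out[cols]
        med = block.median(axis=1, skipna=True)
        zero = med == 0.0
        if zero.any():
            flagged.update(m.index[zero.to_numpy()])
            med = med.where(~zero, 1.0)
        out[cols] = block.div(med, axis=0)
    if flagged:
        logger.warning("zero within-day median; features left unscaled: %s", sorted(flagged))
    return out, sorted(flagged)


def impute_min(m: pd.DataFrame) -> pd.DataFrame:
    """Replace each feature's missing cells with that feature's observed minimum."""
    out = m.astype(float).copy()
    for feat in out.index:
        row = out.loc[feat]
        if row.isna().all():
            raise ValueError(f"feature {feat!r} has no observed values; cannot impute")
        out.loc[feat] = row.fillna(row.min())
    return out


def paired_feature_test(
    case_matrix: pd.DataFrame,
    control_matrix: pd.DataFrame,
    pairing: dict | None = None,
) -> pd.DataFrame:
    """Two-sided paired t-test per feature between matched case/control samples.

    ``pairing`` maps case column -> control column; identity (positional)
    pairing is used when omitted.  Features with zero-variance differences
    get t = 0, p = 1 and a flag.
    """
    if pairing is not None:
        case_cols = list(pairing.keys())
        ctrl_cols = [pairing[c] for c in case_cols]
        case_matrix = case_matrix[case_cols]
        control_matrix = control_matrix[ctrl_cols]
    if case_matrix.shape[1] != control_matrix.shape[1]:
        raise ValueError("case and control matrices must have equal pair counts")
    if case_matrix.shape[1] < 2:
        raise ValueError("need at least 2 pairs")
    if not case_matrix.index.equals(control_matrix.index):
        control_matrix = control_matrix.loc[case_matrix.index]

    diffs = case_matrix.to_numpy(dtype=float) - control_matrix.to_numpy(dtype=float)
    n = diffs.shape[1]
    rows = []
    for i, feat in enumerate(case_matrix.index):
        d = diffs[i]
        sd = d.std(ddof=1)
        if sd == 0.0:
            rows.append((feat, 0.0, 1.0, True))
            continue
        t = d.mean() * np.sqrt(n) / sd
        p = 2.0 * stats.t.sf(abs(t), df=n - 1)
        rows.append((feat, t, p, False))
    return pd.DataFrame(rows, columns=["feature", "t", "p", "zero_variance"]).set_index(
        "feature"
    )


def covariate_feature_test(
    matrix: pd.DataFrame, group: pd.Series, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Per-feature linear model of intensity on group plus clinical covariates.

    The group contrast's F-test (equivalently the squared t-test for one
    contrast) is reported — the covariate-adjusted companion to the paired
    test, sharing one code path per feature.
    """
    y_design = np.column_stack(
        [np.ones(len(group)), group.to_numpy(dtype=float), covariates.to_numpy(dtype=float)]
    )
    rows = []
    for feat in matrix.index:
        y = matrix.loc[feat].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(y_design, y, rcond=None)
        resid = y - y_design @ beta
        dof = len(y) - y_design.shape[1]
        sigma2 = resid @ resid / dof
        cov_beta = sigma2 * np.linalg.pinv(y_design.T @ y_design)
        se = np.sqrt(cov_beta[1, 1])
        f = (beta[1] / se) ** 2 if se > 0 else 0.0
        p = stats.f.sf(f, 1, dof) if se > 0 else 1.0
        rows.append((feat, beta[1], f, p))
    return pd.DataFrame(rows, columns=["feature", "group_effect", "F", "p"]).set_index(
        "feature"
    )


def storey_qvalues(pvalues, lambda_: float = 0.5, return_pi0: bool = False):
    """Storey q-values with pi0 estimated at a single lambda (default 0.5).

    pi0 = #(p > lambda) / (m * (1 - lambda)), clipped to (0, 1]; q for the
    i-th order statistic is min over j >= i of pi0 * m * p_(j) / j, so
    q-values are monotone in p and bounded by 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise ValueError("need a 1-D array of at least one p-value")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    pi0 = np.sum(p > lambda_) / (m * (1.0 - lambda_))
    pi0 = min(max(pi0, 1.0 / m), 1.0)  # clip into (0, 1]

    order = np.argsort(p, kind="mergesort")
    p_sorted = p[order]
    ranks = np.arange(1, m + 1)
    raw = pi0 * m * p_sorted / ranks
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return (q, pi0) if return_pi0 else q
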