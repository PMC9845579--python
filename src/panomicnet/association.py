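"""Conventional association statistics surrounding the network analysis.

Univariate Kendall tau-b screening of biomarkers against outcome measures,
average-linkage hierarchical clustering for heatmap ordering, quartile
logistic odds-ratio models with covariate adjustment and a trend test,
additive per-allele SNP association (linear for continuous outcomes,
logistic for binary), and cumulative incidence curves against biomarker
level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "kendall_screen",
    "cluster_heatmap_order",
    "quartile_logistic",
    "snp_association",
    "cumulative_incidence_curve",
]

_Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class AssociationResult:
    """One exposure-outcome association: estimate, uncertainty, p-value."""

    exposure: str
    outcome: str
    kind: str  # "tau" | "beta" | "OR"
    estimate: float
    se: float  # ln SE for OR
    ci_lower: float
    ci_upper: float
    p: float
    q: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "OR" and self.estimate <= 0:
            raise ValueError("odds ratio must be positive")
        if self.kind == "tau" and not -1.0 <= self.estimate <= 1.0:
            raise ValueError("tau must lie in [-1, 1]")


def kendall_screen(
    biomarkers: pd.DataFrame, outcomes: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Kendall tau-b of every biomarker against every outcome.

    Returns (tau matrix, p matrix, kept biomarkers).  A biomarker is kept
    when any outcome association reaches raw p < alpha — a deliberately
    uncorrected nominal screen.  Constant columns have undefined tau; they
    are flagged, excluded from the kept list, and their cells set to NaN.
    """
    if biomarkers.shape[0] != outcomes.shape[0]:
        raise ValueError("biomarkers and outcomes must cover the same patients")
    taus = pd.DataFrame(index=biomarkers.columns, columns=outcomes.columns, dtype=float)
    ps = pd.DataFrame(index=biomarkers.columns, columns=outcomes.columns, dtype=float)
    constant = [c for c in biomarkers.columns if biomarkers[c].nunique() <= 1]
    constant += [c for c in outcomes.columns if outcomes[c].nunique() <= 1]
    if constant:
        logger.warning("constant columns excluded from Kendall screen: %s", constant)
    for b in biomarkers.columns:
        for o in outcomes.columns:
            if b in constant or o in constant:
                taus.loc[b, o] = np.nan
                ps.loc[b, o] = np.nan
                continue
            res = stats.kendalltau(biomarkers[b], outcomes[o])
            taus.loc[b, o] = res.statistic
            ps.loc[b, o] = res.pvalue
    kept = [
        b
        for b in biomarkers.columns
        if b not in constant and (ps.loc[b] < alpha).any()
    ]
    return taus, ps, kept


def cluster_heatmap_order(tau: pd.DataFrame):
    """Average-linkage hierarchical clustering of a correlation matrix.

    Rows and columns are clustered independently with distance 1 - tau
    between observation vectors' correlation profiles; returns
    (row order, column order, row linkage, column linkage).
    """
    arr = tau.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("tau matrix must be finite for clustering")

    def _order(mat: np.ndarray):
        if mat.shape[0] < 2:
            return list(range(mat.shape[0])), None
        # pairwise distance between profile vectors: 1 - Kendall tau of rows
        m = mat.shape[0]
        d = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                if np.array_equal(mat[i], mat[j]):
                    t = 1.0
                else:
                    t = stats.kendalltau(mat[i], mat[j]).statistic
                    if not np.isfinite(t):
                        t = 0.0
                d[i, j] = d[j, i] = 1.0 - t
        link = hierarchy.linkage(squareform(d, checks=False), method="average")
        return list(hierarchy.leaves_list(link)), link

    row_idx, row_link = _order(arr)
    col_idx, col_link = _order(arr.T)
    row_order = [tau.index[i] for i in row_idx]
    col_order = [tau.columns[i] for i in col_idx]
    return row_order, col_order, row_link, col_link


def _bin_by_quantiles(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Quantile bins 0..n_bins-1; interior edges by linear interpolation,
    ties on an edge assigned to the lower bin ([low, high) convention,
    last bin closed)."""
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, x, side="left")


class _RidgeLogitResult:
    """Minimal params/bse holder for the ridge-stabilized fallback fit."""

    def __init__(self, params: np.ndarray, bse: np.ndarray):
        self.params = params
        self.bse = bse


def _fit_logit(X: np.ndarray, y: np.ndarray):
    """Newton-fit logistic; ridge-stabilized refit on separation, flagged."""
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(disp=0, maxiter=200, tol=1e-10)
        if not res.mle_retvals.get("converged", True) or np.abs(res.params).max() > 25:
            raise np.linalg.LinAlgError("separation suspected")
        return res, False
    except Exception:
        from .scoring import _logistic_fit

        beta, _, _ = _logistic_fit(X, y, ridge=1e-2)
        p = 1.0 / (1.0 + np.exp(-np.clip(X @ beta, -35, 35)))
        w = p * (1.0 - p)
        H = (X * w[:, None]).T @ X + 1e-2 * np.eye(X.shape[1])
        bse = np.sqrt(np.diag(np.linalg.inv(H)))
        logger.warning("separation in logistic fit; ridge-stabilized estimates")
        return _RidgeLogitResult(beta, bse), True


def quartile_logistic(
    biomarker,
    case_status,
    covariates: pd.DataFrame | None = None,
    n_bins: int = 4,
) -> pd.DataFrame:
    """Per-quantile-bin odds ratios against the lowest bin, plus a trend test.

    The biomarker is cut at sample quantiles into ``n_bins`` groups; the
    lowest is the reference.  A logistic model with indicator coding (and
    any supplied covariate columns) yields per-bin OR with Wald 95% CI and
    p-values; a separate fit replacing the indicators with the ordinal bin
    score 1..n_bins gives the Wald trend p.  Output rows: one per non-
    reference bin, plus a ``trend`` row.
    """
    x = np.asarray(biomarker, dtype=float)
    y = np.asarray(case_status, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("biomarker and case status lengths differ")
    if x.shape[0] < 8 * n_bins:
        raise ValueError(f"need n >= {8 * n_bins} for {n_bins} bins")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("case status must be binary 0/1")

    bins = _bin_by_quantiles(x, n_bins)
    counts = np.bincount(bins, minlength=n_bins)
    if (counts == 0).any():
        raise ValueError(f"empty quantile bin (counts {counts.tolist()})")

    indicators = np.column_stack([(bins == b).astype(float) for b in range(1, n_bins)])
    cov = (
        covariates.to_numpy(dtype=float)
        if covariates is not None and covariates.shape[1] > 0
        else np.empty((x.shape[0], 0))
    )
    X = np.column_stack([np.ones_like(x), indicators, cov])
    res, flagged = _fit_logit(X, y)
    params, bse = np.asarray(res.params), np.asarray(res.bse)

    rows = []
    for b in range(1, n_bins):
        coef, se = params[b], bse[b]
        rows.append(
            {
                "bin": f"Q{b + 1}",
                "n": int(counts[b]),
                "or_": float(np.exp(coef)),
                "ci_lower": float(np.exp(coef - _Z95 * se)),
                "ci_upper": float(np.exp(coef + _Z95 * se)),
                "p": float(2 * stats.norm.sf(abs(coef / se))) if se > 0 else np.nan,
                "flagged": flagged,
            }
        )
    rows.insert(
        0,
        {
            "bin": "Q1",
            "n": int(counts[0]),
            "or_": 1.0,
            "ci_lower": np.nan,
            "ci_upper": np.nan,
            "p": np.nan,
            "flagged": flagged,
        },
    )

    score = (bins + 1).astype(float)  # ordinal 1..n_bins
    X_tr = np.column_stack([np.ones_like(x), score, cov])
    res_tr, fl_tr = _fit_logit(X_tr, y)
    coef_t, se_t = np.asarray(res_tr.params)[1], np.asarray(res_tr.bse)[1]
    rows.append(
        {
            "bin": "trend",
            "n": int(x.shape[0]),
            "or_": float(np.exp(coef_t)),
            "ci_lower": float(np.exp(coef_t - _Z95 * se_t)),
            "ci_upper": float(np.exp(coef_t + _Z95 * se_t)),
            "p": float(2 * stats.norm.sf(abs(coef_t / se_t))) if se_t > 0 else np.nan,
            "flagged": flagged or fl_tr,
        }
    )
    out = pd.DataFrame(rows).rename(columns={"or_": "OR"})
    return out.set_index("bin")


def snp_association(
    genotype,
    outcome,
    covariates: pd.DataFrame | None = None,
    snp_name: str = "snp",
    outcome_name: str = "outcome",
) -> AssociationResult:
    """Additive per-allele association of a 0/1/2 genotype with an outcome.

    Continuous outcomes: linear regression beta per allele copy with SE and
    Wald 95% CI.  Binary outcomes: logistic regression reported as OR with
    the SE of the log-odds coefficient (ln SE) and the exponentiated CI.
    """
    g = np.asarray(genotype, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if not np.isin(g, (0.0, 1.0, 2.0)).all():
        raise ValueError("genotype must be additive-coded 0/1/2")
    if np.unique(g).size < 2:
        raise ValueError("monomorphic genotype; association undefined")
    cov = (
        covariates.to_numpy(dtype=float)
        if covariates is not None and covariates.shape[1] > 0
        else np.empty((g.shape[0], 0))
    )
    X = np.column_stack([np.ones_like(g), g, cov])

    binary = np.isin(y, (0.0, 1.0)).all() and np.unique(y).size == 2
    if binary:
        res, _ = _fit_logit(X, y)
        coef, se = float(np.asarray(res.params)[1]), float(np.asarray(res.bse)[1])
        return AssociationResult(
            exposure=snp_name,
            outcome=outcome_name,
            kind="OR",
            estimate=float(np.exp(coef)),
            se=se,
            ci_lower=float(np.exp(coef - _Z95 * se)),
            ci_upper=float(np.exp(coef + _Z95 * se)),
            p=float(2 * stats.norm.sf(abs(coef / se))),
        )
    res = sm.OLS(y, X).fit()
    coef, se = float(res.params[1]), float(res.bse[1])
    return AssociationResult(
        exposure=snp_name,
        outcome=outcome_name,
        kind="beta",
        estimate=coef,
        se=se,
        ci_lower=coef - _Z95 * se,
        ci_upper=coef + _Z95 * se,
        p=float(res.pvalues[1]),
    )


def cumulative_incidence_curve(
    biomarker, case_status, subset_filter=None
) -> pd.DataFrame:
    """Cumulative case fraction among patients at or below each biomarker value.

    Patients are sorted ascending by biomarker; at each observed value v the
    curve reports the fraction of cases among patients with value <= v.
    ``subset_filter`` (boolean mask) restricts the cohort first, e.g. to
    exclude statin-treated patients.
    """
    x = np.asarray(biomarker, dtype=float)
    y = np.asarray(case_status, dtype=float)
    if subset_filter is not None:
        mask = np.asarray(subset_filter, dtype=bool)
        x, y = x[mask], y[mask]
    if x.size == 0:
        raise ValueError("no patients after filtering")
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    cum_cases = np.cumsum(ys)
    counts = np.arange(1, xs.size + 1)
    frac = cum_cases / counts
    # one row per unique value: the last (largest-index) entry at each value
    keep = np.r_[xs[1:] != xs[:-1], True]
    return pd.DataFrame(
        {"value": xs[keep], "cumulative_incidence": frac[keep]}
    ).reset_index(drop=True)
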