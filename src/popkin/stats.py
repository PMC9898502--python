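"""Group statistics: ANCOVA with eta-squared and BH-FDR, Mann-Whitney with
rank-biserial effect size, a pooled two-sample proportion z-test, and partial
Spearman correlations with Student-t significance.

The ANCOVA is a least-squares linear model of the feature on an intercept,
the continuous covariates (age; age+IQ), and the dummy-coded diagnostic
group; the group term is tested added last (Type-II, which for a single
categorical predictor with no interactions is order-invariant).  Eta-squared
is classical, SS_group / SS_total.  With no covariates the procedure reduces
exactly to one-way ANOVA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonResult",
    "RankTestResult",
    "PartialCorrResult",
    "ancova_compare",
    "bh_adjust",
    "compare_all",
    "mannwhitney_rb",
    "proportions_ztest",
    "spearman_partial",
    "DegenerateModelError",
]


class DegenerateModelError(ValueError):
    """The linear model cannot be tested (zero residual variance, etc.)."""


@dataclass
class ComparisonResult:
    feature: str
    F: float
    df_effect: int
    df_error: int
    p_raw: float
    eta_squared: float
    n_used: int
    p_adjusted: float = math.nan
    skipped_reason: Optional[str] = None


@dataclass(frozen=True)
class RankTestResult:
    U: float
    p_two_sided: float
    r_rank_biserial: float
    method: str  # "exact" | "normal_approx"


@dataclass(frozen=True)
class PartialCorrResult:
    x_name: str
    y_name: str
    covariates: tuple[str, ...]
    rho: float
    p: float
    n: int


def _as_2d(covariates) -> np.ndarray:
    if covariates is None:
        return np.empty((0, 0))
    arr = np.asarray(covariates, dtype=float)
    if arr.size == 0:
        return np.empty((len(arr), 0)) if arr.ndim == 1 else arr
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr


def ancova_compare(
    y: Sequence[float],
    group: Sequence,
    covariates=None,
    feature: str = "y",
) -> ComparisonResult:
    """One-way ANCOVA of ``y`` on ``group`` adjusting for ``covariates``.

    Rows with any missing value are dropped listwise.  Requires at least two
    groups with >= 2 non-missing observations each.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(group, dtype=object)
    X = _as_2d(covariates)
    if X.shape[0] not in (0, len(y)):
        raise ValueError("covariates length mismatch")
    if X.shape[0] == 0:
        X = np.empty((len(y), 0))
    mask = ~np.isnan(y)
    if X.shape[1]:
        mask &= ~np.isnan(X).any(axis=1)
    y, g, X = y[mask], g[mask], X[mask]
    n = len(y)

    levels, g_idx = np.unique(g.astype(str), return_inverse=True)
    if len(levels) < 2:
        raise ValueError("ANCOVA requires >= 2 groups")
    counts = np.bincount(g_idx)
    if counts.min() < 2:
        raise ValueError("each group needs >= 2 non-missing observations")

    k = X.shape[1]
    n_groups = len(levels)
    df_effect = n_groups - 1
    df_error = n - df_effect - k - 1
    if df_error <= 0:
        raise ValueError("insufficient degrees of freedom")

    intercept = np.ones((n, 1))
    dummies = np.zeros((n, df_effect))
    for j in range(1, n_groups):
        dummies[g_idx == j, j - 1] = 1.0
    X_red = np.hstack([intercept, X])
    X_full = np.hstack([X_red, dummies])

    sse_red = _sse(X_red, y)
    sse_full = _sse(X_full, y)
    ss_total = float(((y - y.mean()) ** 2).sum())
    if ss_total <= 0 or sse_full <= 1e-12 * max(ss_total, 1.0):
        raise DegenerateModelError(f"zero residual variance for {feature!r}")
    ss_group = max(sse_red - sse_full, 0.0)
    F = (ss_group / df_effect) / (sse_full / df_error)
    p = float(sps.f.sf(F, df_effect, df_error))
    return ComparisonResult(
        feature=feature, F=float(F), df_effect=df_effect, df_error=df_error,
        p_raw=p, eta_squared=ss_group / ss_total, n_used=n,
    )


def _sse(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_all(
    feature_table: pd.DataFrame,
    group: str | Sequence = "group",
    covariates: Sequence[str] | None = None,
    feature_columns: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> list[ComparisonResult]:
    """ANCOVA for every feature column, BH-adjusted across the family.

    Features whose preconditions fail (all-missing, degenerate model, too few
    observations per group) are reported with ``skipped_reason`` set and are
    excluded from the BH family.
    """
    if isinstance(group, str):
        g = feature_table[group].to_numpy()
    else:
        g = np.asarray(group)
    cov_names = list(covariates or [])
    X = feature_table[cov_names].to_numpy(dtype=float) if cov_names else None
    if feature_columns is None:
        from .features import FEATURE_COLUMNS
        feature_columns = [c for c in FEATURE_COLUMNS if c in feature_table.columns]
    results: list[ComparisonResult] = []
    for col in feature_columns:
        y = feature_table[col].to_numpy(dtype=float)
        try:
            results.append(ancova_compare(y, g, X, feature=col))
        except (ValueError, DegenerateModelError) as exc:
            results.append(ComparisonResult(
                feature=col, F=math.nan, df_effect=0, df_error=0,
                p_raw=math.nan, eta_squared=math.nan, n_used=0,
                skipped_reason=str(exc),
            ))
    tested = [r for r in results if r.skipped_reason is None]
    if tested:
        adj = bh_adjust([r.p_raw for r in tested])
        for r, a in zip(tested, adj):
            r.p_adjusted = float(a)
    return results


def mannwhitney_rb(x: Sequence[float], y: Sequence[float]) -> RankTestResult:
    """Two-sided Mann-Whitney U with rank-biserial effect size.

    U is the statistic for sample ``x`` (midranks for ties).  The exact null
    distribution is enumerated when n1+n2 <= 20 and there are no ties;
    otherwise the normal approximation with tie and continuity corrections is
    used.  r = 1 - 2U/(n1*n2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < len(pooled)
    exact = (len(x) + len(y) <= 20) and not ties
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    U = float(res.statistic)
    r = 1.0 - 2.0 * U / (len(x) * len(y))
    return RankTestResult(
        U=U, p_two_sided=float(res.pvalue), r_rank_biserial=r,
        method="exact" if exact else "normal_approx",
    )


def proportions_ztest(
    successes: tuple[int, int], totals: tuple[int, int]
) -> tuple[float, float]:
    """Pooled two-sample proportion z-test; returns (Z, two-sided p)."""
    s1, s2 = successes
    n1, n2 = totals
    if n1 <= 0 or n2 <= 0:
        raise ValueError("totals must be positive")
    if not (0 <= s1 <= n1 and 0 <= s2 <= n2):
        raise ValueError("successes must lie in [0, total]")
    p1, p2 = s1 / n1, s2 / n2
    pooled = (s1 + s2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise DegenerateModelError("pooled proportion is 0 or 1")
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    p = 2.0 * float(sps.norm.sf(abs(z)))
    return z, min(p, 1.0)


def spearman_partial(
    x: Sequence[float],
    y: Sequence[float],
    covariates=None,
    x_name: str = "x",
    y_name: str = "y",
    covariate_names: Sequence[str] | None = None,
) -> PartialCorrResult:
    """Partial Spearman correlation of x and y controlling for covariates.

    Rank-then-partial: all variables are rank-transformed (midranks), the
    ranked x and y are residualised on the ranked covariates plus an
    intercept, and rho is the Pearson correlation of the residuals.
    Significance uses t = rho*sqrt((n-2-k)/(1-rho^2)) on n-2-k degrees of
    freedom.  Constant covariates are dropped; rows with missing values are
    dropped listwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    Z = _as_2d(covariates)
    if Z.shape[0] == 0:
        Z = np.empty((len(x), 0))
    if len(x) != len(y) or Z.shape[0] != len(x):
        raise ValueError("length mismatch")
    mask = ~(np.isnan(x) | np.isnan(y))
    if Z.shape[1]:
        mask &= ~np.isnan(Z).any(axis=1)
    x, y, Z = x[mask], y[mask], Z[mask]
    # drop constant covariates
    if Z.shape[1]:
        keep = Z.std(axis=0) > 0
        Z = Z[:, keep]
    n, k = len(x), Z.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > covariates + 2 (n={n}, k={k})")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")

    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if k:
        RZ = np.column_stack([sps.rankdata(Z[:, j]) for j in range(k)])
        D = np.hstack([np.ones((n, 1)), RZ])
        rx = rx - D @ np.linalg.lstsq(D, rx, rcond=None)[0]
        ry = ry - D @ np.linalg.lstsq(D, ry, rcond=None)[0]
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(min(rho, 1.0), -1.0)
    df = n - 2 - k
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt(df / (1.0 - rho * rho))
        p = 2.0 * float(sps.t.sf(abs(t), df))
    return PartialCorrResult(
        x_name=x_name, y_name=y_name,
        covariates=tuple(covariate_names or ()),
        rho=rho, p=min(p, 1.0), n=n,
    )
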