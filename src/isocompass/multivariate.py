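"""Canonical correlation, Wilks' Lambda tests, ANOVA attribution,
p-value adjustment, and marginal-means contrasts.

The canonical correlation analysis relates the delta13C feature block to
the delta2H block of the same samples: correlations and raw canonical
coefficients come from the singular value decomposition of the whitened
cross-covariance, with scores scaled to unit variance. Sequential
dimension tests use Rao's F approximation of Wilks' Lambda,
Lambda_k = prod_{i>=k} (1 - r_i^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
import statsmodels.formula.api as smf
from patsy import build_design_matrices
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CCAResult",
    "canonical_correlation",
    "wilks_lambda_test",
    "AnovaAttribution",
    "anova_type2",
    "holm_adjust",
    "sidak_adjust",
    "emmeans_contrast",
]


@dataclass
class CCAResult:
    correlations: np.ndarray          # descending, in [0, 1]
    x_coefficients: np.ndarray        # p x d raw coefficients (unit-variance variates)
    y_coefficients: np.ndarray        # q x d
    x_scores: pd.DataFrame | np.ndarray
    y_scores: pd.DataFrame | np.ndarray
    n: int
    p: int
    q: int
    x_columns: list = field(default_factory=list)
    y_columns: list = field(default_factory=list)
    dimension_tests: pd.DataFrame | None = None


def _whiten(block: np.ndarray, tol: float = 1e-10):
    """SVD whitening with rank truncation; returns (U_r, map to coefs)."""
    U, s, Vt = np.linalg.svd(block, full_matrices=False)
    rank = int(np.sum(s > tol * s[0])) if s.size and s[0] > 0 else 0
    if rank == 0:
        raise ValueError("feature block has zero variance")
    return U[:, :rank], Vt[:rank].T / s[:rank], rank


def canonical_correlation(X, Y) -> CCAResult:
    """Classical CCA between two feature blocks of the same samples.

    Rows with any missing value in either block are dropped (complete
    case); columns are centered internally. Rank-deficient blocks are
    truncated to their numerical rank with a warning.
    """
    x_cols = list(X.columns) if isinstance(X, pd.DataFrame) else []
    y_cols = list(Y.columns) if isinstance(Y, pd.DataFrame) else []
    Xa = np.asarray(X, dtype=float)
    Ya = np.asarray(Y, dtype=float)
    if Xa.shape[0] != Ya.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    keep = ~(np.isnan(Xa).any(axis=1) | np.isnan(Ya).any(axis=1))
    Xa, Ya = Xa[keep], Ya[keep]
    n, p = Xa.shape
    q = Ya.shape[1]
    if n <= p + q:
        warnings.warn(f"n = {n} <= p + q = {p + q}; canonical correlations "
                      "will be inflated")
    Xc = Xa - Xa.mean(0)
    Yc = Ya - Ya.mean(0)
    Ux, x_map, rx = _whiten(Xc)
    Uy, y_map, ry = _whiten(Yc)
    if rx < p or ry < q:
        warnings.warn(f"rank-deficient block(s): rank(X) = {rx}, rank(Y) = {ry}; "
                      "dimensions truncated")
    U, s, Vt = np.linalg.svd(Ux.T @ Uy)
    d = min(rx, ry)
    corr = np.clip(s[:d], 0.0, 1.0)
    scale = np.sqrt(n - 1)
    A = x_map @ U[:, :d] * scale   # p x d
    B = y_map @ Vt.T[:, :d] * scale
    xs, ys = Xc @ A, Yc @ B
    if x_cols:
        index = X.index[keep]
        names = [f"CC{i+1}" for i in range(d)]
        xs = pd.DataFrame(xs, index=index, columns=names)
        ys = pd.DataFrame(ys, index=index, columns=names)
    return CCAResult(correlations=corr, x_coefficients=A, y_coefficients=B,
                     x_scores=xs, y_scores=ys, n=n, p=p, q=q,
                     x_columns=x_cols, y_columns=y_cols)


def wilks_lambda_test(result: CCAResult, n: int | None = None,
                      p: int | None = None, q: int | None = None) -> pd.DataFrame:
    """Sequential Rao F approximations for the canonical dimensions.

    For dimension k the statistic Lambda_k = prod_{i>=k}(1 - r_i^2) tests
    whether dimensions k..d are jointly null given 1..k-1.
    """
    n = n or result.n
    p = p or result.p
    q = q or result.q
    r = np.asarray(result.correlations, dtype=float)
    d = len(r)
    rows = []
    for k in range(1, d + 1):
        pk, qk = p - k + 1, q - k + 1
        lam = float(np.prod(1.0 - r[k - 1:] ** 2))
        denom = pk ** 2 + qk ** 2 - 5
        t = np.sqrt((pk ** 2 * qk ** 2 - 4) / denom) if denom > 0 else 1.0
        w = n - 1.5 - (pk + qk) / 2.0
        df1 = pk * qk
        df2 = w * t - df1 / 2.0 + 1.0
        if df2 <= 0:
            raise ValueError(
                f"n = {n} too small for the F approximation at dimension {k}")
        lam_t = lam ** (1.0 / t) if lam > 0 else 0.0
        F = ((1.0 - lam_t) / lam_t) * df2 / df1 if lam_t > 0 else np.inf
        pval = float(st.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
        rows.append((k, lam, F, df1, df2, pval))
    out = pd.DataFrame(rows, columns=["dimension", "wilks_lambda", "F",
                                      "df1", "df2", "p"])
    result.dimension_tests = out
    return out


@dataclass
class AnovaAttribution:
    term: str
    F: float
    df: float
    p: float
    p_adj: float = np.nan
    sum_sq: float = np.nan


def anova_type2(y: pd.Series, design: pd.DataFrame,
                typ: int = 2) -> list[AnovaAttribution]:
    """Per-factor variance attribution by Type II (default) sums of squares.

    Each term's SS is the residual-SS increase from dropping it while
    keeping all other main effects. p values are Holm-adjusted across
    the table's terms. ``typ=3`` switches to Type III with sum-to-zero
    contrasts for designs with interactions.
    """
    df = design.copy()
    df["_y"] = np.asarray(y, dtype=float)
    factors = list(design.columns)
    coding = "Sum" if typ == 3 else "Treatment"
    terms = " + ".join(f"C({f}, {coding})" for f in factors)
    fit = smf.ols(f"_y ~ {terms}", data=df).fit()
    if fit.model.exog.shape[1] > np.linalg.matrix_rank(fit.model.exog):
        aliased = _aliased_factors(df, factors)
        raise ValueError(f"aliased factor levels in design: {aliased}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = sm.stats.anova_lm(fit, typ=typ)
    table = table[~table.index.str.contains("Residual")]
    raw_p = table["PR(>F)"].to_numpy(float)
    adj = holm_adjust(raw_p)
    out = []
    for (term, row), padj in zip(table.iterrows(), adj):
        name = term.replace("C(", "").replace(f", {coding})", "")
        out.append(AnovaAttribution(term=name, F=float(row["F"]),
                                    df=float(row["df"]), p=float(row["PR(>F)"]),
                                    p_adj=float(padj),
                                    sum_sq=float(row["sum_sq"])))
    return out


def _aliased_factors(df: pd.DataFrame, factors) -> list[tuple[str, str]]:
    pairs = []
    for a, b in combinations(factors, 2):
        tab = df.groupby(a, observed=True)[b].nunique()
        rev = df.groupby(b, observed=True)[a].nunique()
        if (tab == 1).all() and (rev == 1).all():
            pairs.append((a, b))
    return pairs


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjustment (monotone, never below the raw p)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 1:
        return p.copy()
    return multipletests(p, method="holm")[1]


def sidak_adjust(pvalues, m: int | None = None) -> np.ndarray:
    """Sidak adjustment 1 - (1 - p)^m; m defaults to len(pvalues)."""
    p = np.asarray(pvalues, dtype=float)
    m = m or p.size
    return 1.0 - (1.0 - p) ** m


def emmeans_contrast(y: pd.Series, design: pd.DataFrame, focal_factor: str,
                     alpha: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Estimated marginal means of *focal_factor* and all pairwise contrasts.

    Means are model-based predictions from the additive OLS fit averaged
    over a balanced reference grid of the other factors, reported with
    95% CIs; contrast p values are Sidak-adjusted for the number of
    pairs.
    """
    if focal_factor not in design.columns:
        raise ValueError(f"{focal_factor!r} not in design")
    df = design.copy()
    df["_y"] = np.asarray(y, dtype=float)
    counts = df.groupby(focal_factor, observed=False).size()
    empty = counts[counts == 0]
    if len(empty):
        raise ValueError(f"empty group(s) for {focal_factor!r}: {list(empty.index)}")
    factors = list(design.columns)
    terms = " + ".join(f"C({f})" for f in factors)
    fit = smf.ols(f"_y ~ {terms}", data=df).fit()
    design_info = fit.model.data.design_info

    other = [f for f in factors if f != focal_factor]
    level_sets = {f: sorted(df[f].astype(str).unique()) for f in factors}
    focal_levels = level_sets[focal_factor]

    def lvec(level: str) -> np.ndarray:
        grid = [{focal_factor: level, **dict(zip(other, combo))}
                for combo in _grid([level_sets[f] for f in other])]
        gm = build_design_matrices([design_info], pd.DataFrame(grid))[0]
        return np.asarray(gm).mean(axis=0)

    dfres = fit.df_resid
    cov = fit.cov_params().to_numpy()
    beta = fit.params.to_numpy()
    tcrit = st.t.ppf(1 - alpha / 2, dfres)
    mean_rows = []
    L = {}
    for lev in focal_levels:
        l = lvec(lev)
        L[lev] = l
        est = float(l @ beta)
        se = float(np.sqrt(l @ cov @ l))
        mean_rows.append((lev, est, se, est - tcrit * se, est + tcrit * se))
    means = pd.DataFrame(mean_rows, columns=[focal_factor, "emmean", "se",
                                             "ci_low", "ci_high"])
    pairs = list(combinations(focal_levels, 2))
    con_rows = []
    for a, b in pairs:
        ld = L[a] - L[b]
        est = float(ld @ beta)
        se = float(np.sqrt(ld @ cov @ ld))
        tval = est / se if se > 0 else np.inf
        p = 2 * float(st.t.sf(abs(tval), dfres))
        con_rows.append((f"{a} - {b}", est, se, tval, p))
    contrasts = pd.DataFrame(con_rows, columns=["contrast", "estimate", "se",
                                                "t", "p"])
    contrasts["p_adj"] = sidak_adjust(contrasts["p"].to_numpy(),
                                      m=len(pairs)) if len(pairs) else []
    return means, contrasts


def _grid(level_lists):
    if not level_lists:
        return [()]
    out = [()]
    for levels in level_lists:
        out = [c + (l,) for c in out for l in levels]
    return out
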