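"""Least-squares engine and the derived quantities the reports need.

A deliberately small OLS implementation (QR with column pivoting, Wald t
tests, extra-sum-of-squares F tests) plus the two report-specific
derivations:

* adjusted (least-squares) means per factor level at a covariate reference
  point, back-transformed to geometric means for ln-scale traits;
* the partial correlation of a quantitative term with the response,
  r = sign(b) * sqrt(t^2 / (t^2 + df)), the standard conversion from the
  term's Wald t statistic.

Everything is plain numpy/scipy so the Monte-Carlo calibration suites can
run thousands of fits in seconds; a statsmodels cross-check lives in the
test suite, not here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import linalg, stats

__all__ = [
    "OLSFit",
    "AdjustedMeans",
    "fit_ols",
    "nested_f_test",
    "ls_means",
    "partial_r",
    "build_design",
]

_RANK_TOL = 1e-10
_Z95 = 1.959963984540054  # normal 97.5% point; see docs/methods.md on CI choice


@dataclass
class OLSFit:
    """An ordinary-least-squares fit with everything reports derive from."""

    terms: List[str]
    params: np.ndarray
    se: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    df_resid: int
    rss: float
    r_squared: float
    n: int
    cov_params: np.ndarray
    y: np.ndarray = field(repr=False)

    def __getitem__(self, term: str) -> Dict[str, float]:
        i = self.terms.index(term)
        return {
            "beta": float(self.params[i]),
            "se": float(self.se[i]),
            "t": float(self.tvalues[i]),
            "p": float(self.pvalues[i]),
        }

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.params,
                "se": self.se,
                "t": self.tvalues,
                "p": self.pvalues,
            },
            index=self.terms,
        )


def _lstsq_qr(X: np.ndarray, y: np.ndarray, names: Sequence[str]):
    """Pivoted-QR least squares; raises on rank deficiency, naming the
    dependent columns."""
    n, p = X.shape
    Q, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    scale = diag[0] if diag.size and diag[0] > 0 else 1.0
    rank = int((diag > _RANK_TOL * scale).sum())
    if rank < p:
        bad = [names[j] for j in piv[rank:]]
        raise ValueError(f"rank-deficient design: collinear term(s) {bad}")
    coef_piv = linalg.solve_triangular(R, Q.T @ y)
    beta = np.empty(p)
    beta[piv] = coef_piv
    # (X'X)^-1 = P R^-1 R^-T P'
    Rinv = linalg.solve_triangular(R, np.eye(p))
    xtx_inv_piv = Rinv @ Rinv.T
    inv = np.empty_like(xtx_inv_piv)
    inv[np.ix_(piv, piv)] = xtx_inv_piv
    return beta, inv


def fit_ols(X, y, terms: Optional[Sequence[str]] = None) -> OLSFit:
    """Fit y = X b + e by least squares.

    X may be a DataFrame (column names become term names) or a 2-D array
    with `terms` supplied.  The caller is responsible for including an
    intercept column and for complete cases: missing values are an error,
    not silently dropped.
    """
    if isinstance(X, pd.DataFrame):
        terms = list(X.columns)
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        terms = list(terms) if terms is not None else [f"x{j}" for j in range(Xm.shape[1])]
    yv = np.asarray(y, dtype=float)
    n, p = Xm.shape
    if yv.shape != (n,):
        raise ValueError("response length does not match design rows")
    if np.isnan(Xm).any() or np.isnan(yv).any():
        raise ValueError("missing values in design or response; "
                         "complete-case filter first")
    if n <= p:
        raise ValueError(f"n={n} too small for {p} terms")

    beta, xtx_inv = _lstsq_qr(Xm, yv, terms)
    resid = yv - Xm @ beta
    rss = float(resid @ resid)
    df = n - p
    sigma2 = rss / df
    cov = sigma2 * xtx_inv
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    tss = float(((yv - yv.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return OLSFit(
        terms=terms,
        params=beta,
        se=se,
        tvalues=tvals,
        pvalues=np.clip(pvals, 0.0, 1.0),
        df_resid=df,
        rss=rss,
        r_squared=r2,
        n=n,
        cov_params=cov,
        y=yv,
    )


def nested_f_test(full: OLSFit, reduced: OLSFit) -> Tuple[float, float]:
    """Extra-sum-of-squares F test of a reduced model against a full model.

    The reduced model's terms must be a subset of the full model's and both
    must be fit to the same response.  Returns (F, p) with
    (p_full - p_reduced, df_full) degrees of freedom.
    """
    if not set(reduced.terms) <= set(full.terms):
        raise ValueError("models are not nested (reduced terms not a subset)")
    if reduced.n != full.n or not np.array_equal(reduced.y, full.y):
        raise ValueError("models were fit to different responses")
    df_num = len(full.terms) - len(reduced.terms)
    if df_num == 0:
        return 0.0, 1.0
    num = max(reduced.rss - full.rss, 0.0) / df_num
    den = full.rss / full.df_resid
    if den == 0:
        return np.inf, 0.0
    f = num / den
    return float(f), float(stats.f.sf(f, df_num, full.df_resid))


def partial_r(fit: OLSFit, term: str) -> float:
    """Signed partial correlation of a quantitative term with the response,
    derived from its Wald t: r = sign(b) sqrt(t^2/(t^2+df))."""
    if fit.df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    t = fit[term]["t"]
    return float(np.sign(t) * np.sqrt(t * t / (t * t + fit.df_resid)))


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

_DEFAULT_REFS = {"sex": "F", "arm": "placebo"}


def factor_reference(data: pd.DataFrame, col: str) -> str:
    """Reference level for a factor: fixed conventions for sex (female) and
    arm (placebo); otherwise the most frequent level (e.g. the largest
    ethnic group)."""
    if col in _DEFAULT_REFS and _DEFAULT_REFS[col] in set(data[col]):
        return _DEFAULT_REFS[col]
    return data[col].value_counts().idxmax()


def build_design(
    data: pd.DataFrame,
    numeric: Sequence[str] = (),
    factors: Sequence[str] = (),
    interactions: Sequence[Tuple[str, str]] = (),
) -> pd.DataFrame:
    """Intercept + numeric columns + reference-coded factor indicators +
    (numeric x factor-level) interaction columns.

    Factor columns are expanded to 0/1 indicators for every non-reference
    level, named ``col[level]``.  An interaction (num, factor) adds
    ``num:col[level]`` product columns.  Column order is deterministic.
    """
    out = pd.DataFrame(index=data.index)
    out["intercept"] = 1.0
    for col in numeric:
        out[col] = pd.to_numeric(data[col]).astype(float)
    dummies: Dict[str, pd.DataFrame] = {}
    for col in factors:
        ref = factor_reference(data, col)
        levels = [l for l in sorted(data[col].unique()) if l != ref]
        block = pd.DataFrame(index=data.index)
        for level in levels:
            block[f"{col}[{level}]"] = (data[col] == level).astype(float)
        dummies[col] = block
        for name in block.columns:
            out[name] = block[name]
    for num, fac in interactions:
        if fac not in dummies:
            raise ValueError(f"interaction references absent factor {fac!r}")
        base = pd.to_numeric(data[num]).astype(float)
        for name in dummies[fac].columns:
            out[f"{num}:{name}"] = base * dummies[fac][name]
    return out


# ---------------------------------------------------------------------------
# Adjusted means
# ---------------------------------------------------------------------------

@dataclass
class AdjustedMeans:
    """Model-adjusted means per level of a factor.

    For ln-scale traits means and CI bounds are back-transformed with exp,
    giving covariate-adjusted geometric means.  `reference_point` records
    the covariate values the predictions were made at.
    """

    factor: str
    scale: str  # "raw" or "ln"
    table: pd.DataFrame  # index level; columns mean, ci_low, ci_high, n
    reference_point: Dict[str, float]

    def mean(self, level) -> float:
        return float(self.table.loc[level, "mean"])


def ls_means(
    data: pd.DataFrame,
    response: str,
    factor: str,
    covariates: Sequence[str] = (),
    other_factors: Sequence[str] = (),
    scale: str = "raw",
) -> AdjustedMeans:
    """Least-squares means of `response` per level of `factor`.

    Fits response ~ factor + covariates (+ other factors) by OLS and
    predicts each level's mean at the covariate reference point: continuous
    covariates at their sample means, other factors at their observed level
    proportions.  CIs are estimate +/- 1.96 SE, computed before any
    back-transform; with scale="ln" the response is assumed already on the
    ln scale and means/bounds are exponentiated (geometric means).
    """
    if scale not in ("raw", "ln"):
        raise ValueError("scale must be 'raw' or 'ln'")
    df = data.dropna(subset=[response, factor, *covariates, *other_factors])
    X = build_design(df, numeric=covariates, factors=[factor, *other_factors])
    fit = fit_ols(X, df[response])

    ref = factor_reference(df, factor)
    levels = sorted(df[factor].unique())
    point: Dict[str, float] = {}
    x0 = pd.Series(0.0, index=X.columns)
    x0["intercept"] = 1.0
    for cov in covariates:
        point[cov] = float(pd.to_numeric(df[cov]).mean())
        x0[cov] = point[cov]
    for of in other_factors:
        props = df[of].value_counts(normalize=True)
        for name in X.columns:
            if name.startswith(f"{of}["):
                level = name[len(of) + 1 : -1]
                x0[name] = float(props.get(level, 0.0))
                point[name] = x0[name]

    rows = []
    for level in levels:
        x = x0.copy()
        for name in X.columns:
            if name.startswith(f"{factor}["):
                x[name] = 1.0 if name == f"{factor}[{level}]" else 0.0
        xv = x.to_numpy(dtype=float)
        est = float(xv @ fit.params)
        se = float(np.sqrt(xv @ fit.cov_params @ xv))
        lo, hi = est - _Z95 * se, est + _Z95 * se
        if scale == "ln":
            est, lo, hi = np.exp(est), np.exp(lo), np.exp(hi)
        rows.append(
            {
                "level": level,
                "mean": est,
                "ci_low": lo,
                "ci_high": hi,
                "n": int((df[factor] == level).sum()),
            }
        )
    table = pd.DataFrame(rows).set_index("level")
    return AdjustedMeans(
        factor=factor, scale=scale, table=table, reference_point=point
    )
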