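"""Full quadratic response-surface models with per-term ANOVA.

Each lineage score Y is regressed on the coded factor levels with the
ten-parameter full quadratic model

    Y = b0 + b1*X1 + b11*X1^2 + b2*X2 + b22*X2^2 + b3*X3 + b33*X3^2
        + b12*X1*X2 + b13*X1*X3 + b23*X2*X3 + e

by ordinary least squares (QR-based solve; normal equations are never
formed).  Term significance uses single-degree-of-freedom partial
(Type III) F-tests: the full model's residual sum of squares against
that of the model with the term removed, referred to F(1, df_residual).
Models are never refined by dropping non-significant terms.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QuadraticModelFit",
    "fit_quadratic",
    "anova",
    "predict_surface",
    "coded_grid",
    "RankDeficientError",
]

ALPHA = 0.05


class RankDeficientError(np.linalg.LinAlgError):
    """Raised when the model matrix does not have full column rank."""


@dataclass
class QuadraticModelFit:
    """OLS fit of the full quadratic model for one response."""

    response: str
    coefficients: pd.Series  # indexed by model term, intercept first
    residuals: np.ndarray
    fitted: np.ndarray
    sigma2_hat: float
    df_total: int
    df_model: int
    df_residual: int
    r2: float
    r2_adj: float
    X: pd.DataFrame  # model matrix retained for partial F-tests
    y: np.ndarray

    @property
    def terms(self) -> list[str]:
        return list(self.coefficients.index)

    def standard_errors(self) -> pd.Series:
        """Closed-form OLS coefficient standard errors."""
        XtX_inv = np.linalg.inv(self.X.T @ self.X)
        se = np.sqrt(np.maximum(np.diag(XtX_inv), 0.0) * self.sigma2_hat)
        return pd.Series(se, index=self.terms)

    def predict(self, X_new: pd.DataFrame) -> np.ndarray:
        X_new = X_new[self.terms]
        return X_new.to_numpy() @ self.coefficients.to_numpy()

    def summary(self) -> dict:
        return {
            "response": self.response,
            "n": len(self.y),
            "df_total": self.df_total,
            "df_model": self.df_model,
            "df_residual": self.df_residual,
            "r2": self.r2,
            "r2_adj": self.r2_adj,
            "sigma2_hat": self.sigma2_hat,
            "coefficients": self.coefficients.to_dict(),
        }


def _qr_lstsq(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least squares via thin QR; returns (beta, residuals)."""
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    if diag.min() <= np.finfo(float).eps * max(X.shape) * diag.max():
        raise RankDeficientError("model matrix is rank deficient")
    beta = np.linalg.solve(R, Q.T @ y)
    resid = y - X @ beta
    return beta, resid


def fit_quadratic(
    X: pd.DataFrame, y: pd.Series | np.ndarray, response: str = "response"
) -> QuadraticModelFit:
    """Ordinary least squares fit of the full quadratic model.

    Parameters
    ----------
    X : DataFrame
        Coded model matrix (from :func:`stemfactor.design.code_levels`),
        one row per observation, intercept column included.
    y : array-like
        Per-observation response values aligned with the rows of X.
    """
    if isinstance(y, pd.Series):
        y = y.reindex(X.index).to_numpy(dtype=float)
    else:
        y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more than {p} observations, got {n}")
    if not np.isfinite(y).all():
        raise ValueError("response contains non-finite values")

    Xv = X.to_numpy(dtype=float)
    try:
        beta, resid = _qr_lstsq(Xv, y)
    except RankDeficientError:
        # identify the offending columns for the error message
        rank = np.linalg.matrix_rank(Xv)
        bad = []
        for j, col in enumerate(X.columns):
            if np.linalg.matrix_rank(np.delete(Xv, j, axis=1)) == rank:
                bad.append(col)
        raise RankDeficientError(
            f"model matrix rank {rank} < {p}; collinear columns: {bad}"
        ) from None

    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    df_residual = n - p
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / df_residual
    return QuadraticModelFit(
        response=response,
        coefficients=pd.Series(beta, index=list(X.columns)),
        residuals=resid,
        fitted=y - resid,
        sigma2_hat=ss_res / df_residual,
        df_total=n - 1,
        df_model=p - 1,
        df_residual=df_residual,
        r2=r2,
        r2_adj=r2_adj,
        X=X,
        y=y,
    )


def anova(fit: QuadraticModelFit, alpha: float = ALPHA) -> pd.DataFrame:
    """Per-term partial F-tests of the fitted quadratic model.

    For each non-intercept term, SS is the increase in residual sum of
    squares when that term alone is removed from the full model; F =
    SS / sigma2_hat on (1, df_residual) degrees of freedom.  The
    intercept is never tested.
    """
    if fit.df_residual < 1:
        raise ValueError("ANOVA requires at least 1 residual degree of freedom")
    ss_res_full = float(fit.residuals @ fit.residuals)
    scale = float(fit.y @ fit.y)
    perfect = ss_res_full <= 1e-12 * max(scale, 1.0)
    if perfect:
        warnings.warn("perfect fit: residual variance ~ 0; p-values degenerate")
    Xv = fit.X.to_numpy(dtype=float)
    y = fit.y
    rows = []
    for j, term in enumerate(fit.terms):
        if term == "intercept":
            continue
        _, resid_j = _qr_lstsq(np.delete(Xv, j, axis=1), y)
        ss = float(resid_j @ resid_j) - ss_res_full
        ss = max(ss, 0.0)
        if perfect:
            f_stat = np.inf if ss > 1e-12 * max(scale, 1.0) else 0.0
            p = 0.0 if np.isinf(f_stat) else 1.0
        else:
            f_stat = ss / fit.sigma2_hat
            p = float(stats.f.sf(f_stat, 1, fit.df_residual))
        rows.append(
            {
                "term": term,
                "ss": ss,
                "df": 1,
                "F": f_stat,
                "p": p,
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(rows).set_index("term")


def coded_grid(
    factor_names: list[str],
    resolution: int = 21,
    fixed: dict[str, float] | None = None,
    lo: float = -1.0,
    hi: float = 1.0,
) -> pd.DataFrame:
    """Cartesian grid of coded levels; factors in *fixed* are held constant."""
    fixed = fixed or {}
    axes = []
    for name in factor_names:
        if name in fixed:
            axes.append(np.array([float(fixed[name])]))
        else:
            axes.append(np.linspace(lo, hi, resolution))
    mesh = np.meshgrid(*axes, indexing="ij")
    return pd.DataFrame({n: m.ravel() for n, m in zip(factor_names, mesh)})


def predict_surface(
    fit: QuadraticModelFit,
    coded_points: pd.DataFrame,
) -> pd.DataFrame:
    """Evaluate the fitted surface at coded factor settings.

    ``coded_points`` has one column per factor with coded levels; a
    warning is emitted for points outside [-1, +1] (extrapolation), but
    prediction proceeds.  Returns the points with a ``predicted`` column.
    """
    factor_names = [t for t in fit.terms if ":" not in t and "^" not in t and t != "intercept"]
    missing = [n for n in factor_names if n not in coded_points.columns]
    if missing:
        raise ValueError(f"coded_points missing factor column(s): {missing}")
    vals = coded_points[factor_names].to_numpy(dtype=float)
    if (np.abs(vals) > 1.0 + 1e-9).any():
        warnings.warn("predicting beyond the coded design range [-1, +1]")
    cols = {"intercept": np.ones(len(coded_points))}
    for n in factor_names:
        cols[n] = coded_points[n].to_numpy(dtype=float)
        cols[f"{n}^2"] = cols[n] ** 2
    for a, b in itertools.combinations(factor_names, 2):
        cols[f"{a}:{b}"] = cols[a] * cols[b]
    X_new = pd.DataFrame(cols)[fit.terms]
    out = coded_points.copy()
    out["predicted"] = X_new.to_numpy() @ fit.coefficients.to_numpy()
    return out
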