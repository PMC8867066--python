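"""Year adjustment via a linear mixed model.

For each variable the model is ``y = mu + year (fixed) + genotype (random)
+ e``.  The single variance ratio ``lambda = sigma2_g / sigma2_e`` is
estimated by restricted maximum likelihood through one-dimensional
optimization of the profiled likelihood — exact for one random effect and
dependency-light.  The per-genotype expected value is ``mu + BLUP``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = ["BlupResult", "fit_blup", "adjust_all"]


@dataclass
class BlupResult:
    """Fitted genotype values for one variable."""

    table: pd.DataFrame            # genotype, blup, expected
    mu: float
    sigma2_genotype: float
    sigma2_residual: float
    year_effects: dict             # year -> fixed effect (sum-to-zero coding)
    reml_loglik: float

    def expected(self) -> pd.Series:
        return self.table.set_index("genotype")["expected"]


def _design(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list, list]:
    genotypes = sorted(records["genotype"].unique())
    years = sorted(records["year"].unique())
    g_idx = records["genotype"].map({g: i for i, g in enumerate(genotypes)}).to_numpy()
    Z = np.zeros((len(records), len(genotypes)))
    Z[np.arange(len(records)), g_idx] = 1.0
    # intercept + sum-to-zero year contrasts, so the intercept is the
    # across-year mean and BLUP + mu is directly comparable between years
    X = [np.ones(len(records))]
    y_idx = records["year"].map({y: i for i, y in enumerate(years)}).to_numpy()
    for j in range(len(years) - 1):
        col = np.zeros(len(records))
        col[y_idx == j] = 1.0
        col[y_idx == len(years) - 1] = -1.0
        X.append(col)
    return np.column_stack(X), Z, genotypes, years


def _reml_pieces(lam: float, y: np.ndarray, X: np.ndarray, Z: np.ndarray):
    n, p = X.shape
    V = np.eye(n) + lam * (Z @ Z.T)
    cho = np.linalg.cholesky(V)
    logdet_v = 2.0 * np.log(np.diag(cho)).sum()
    Vi_y = np.linalg.solve(V, y)
    Vi_X = np.linalg.solve(V, X)
    XtViX = X.T @ Vi_X
    sign, logdet_x = np.linalg.slogdet(XtViX)
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    r = y - X @ beta
    Vi_r = np.linalg.solve(V, r)
    quad = float(r @ Vi_r)
    ll = -0.5 * (logdet_v + logdet_x + (n - p) * np.log(max(quad, 1e-300)))
    return ll, beta, Vi_r, quad


def fit_blup(
    records: pd.DataFrame,
    value_col: str = "value",
    variance_ratio: float | None = None,
) -> BlupResult:
    """Fit the mixed model for one variable and return shrunken genotype values.

    ``records`` needs columns genotype, year and ``value_col``.  Pass
    ``variance_ratio`` to skip REML and use a known ``sigma2_g/sigma2_e``.
    """
    records = records.dropna(subset=["genotype", "year", value_col])
    if records["genotype"].nunique() < 2:
        raise ValueError("need >= 2 genotypes to separate genotype variance")
    y = records[value_col].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in records")
    X, Z, genotypes, years = _design(records)
    if len(years) == 1:
        warnings.warn("single year: year effect dropped", stacklevel=2)

    if variance_ratio is None:
        res = minimize_scalar(
            lambda loglam: -_reml_pieces(np.exp(loglam), y, X, Z)[0],
            bounds=(-12.0, 12.0),
            method="bounded",
            options={"xatol": 1e-10},
        )
        lam = float(np.exp(res.x))
        # probe the boundary: full shrinkage may beat an interior optimum
        if _reml_pieces(0.0, y, X, Z)[0] >= -res.fun:
            lam = 0.0
            warnings.warn(
                "genotype variance pinned at 0 (boundary REML solution)",
                stacklevel=2,
            )
    else:
        lam = float(variance_ratio)
        if lam < 0:
            raise ValueError("variance_ratio must be >= 0")

    ll, beta, Vi_r, quad = _reml_pieces(lam, y, X, Z)
    n, p = X.shape
    sigma2_e = quad / (n - p)
    sigma2_g = lam * sigma2_e
    blup = lam * (Z.T @ Vi_r)
    mu = float(beta[0])

    year_eff = {}
    if len(years) > 1:
        eff = list(beta[1:])
        eff.append(-float(np.sum(eff)))
        year_eff = dict(zip(years, (float(e) for e in eff)))

    table = pd.DataFrame(
        {"genotype": genotypes, "blup": blup, "expected": mu + blup}
    )
    return BlupResult(
        table=table,
        mu=mu,
        sigma2_genotype=float(sigma2_g),
        sigma2_residual=float(sigma2_e),
        year_effects=year_eff,
        reml_loglik=float(ll),
    )


def adjust_all(long: pd.DataFrame, value_col: str = "value",
               variable_col: str = "variable") -> pd.DataFrame:
    """Fit every variable in a long table; returns a genotype x variable
    matrix of expected values."""
    pieces = {}
    for var, sub in long.groupby(variable_col):
        pieces[var] = fit_blup(sub, value_col=value_col).expected()
    wide = pd.DataFrame(pieces)
    wide.index.name = "genotype"
    return wide
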