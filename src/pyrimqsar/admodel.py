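"""Applicability-domain analysis: leverages, critical leverage and
standardized residuals (Williams plot).

The leverage of a query x against a training descriptor matrix X (with
intercept column) is h = x' (X'X)^-1 x; a prediction is flagged as
extrapolative when h exceeds the critical leverage h* = 3 (k + 1) / N.
Residuals are standardized by the regression standard error s (e/s by
default; the internally studentized e / (s sqrt(1 - h)) variant is
selectable) and flagged at the 2-sigma / 3-sigma bands.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AdReport",
    "leverages",
    "critical_leverage",
    "standardized_residuals",
    "ad_report",
    "williams_plot",
]


def _with_intercept(X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.hstack([np.ones((X.shape[0], 1)), X])


def leverages(X_train: np.ndarray, X_query: np.ndarray | None = None) -> np.ndarray:
    """Leverage h = x'(X'X)^-1 x per query row (intercept appended).

    With ``X_query=None`` the training rows are their own queries, i.e.
    the hat-matrix diagonal.
    """
    Xt = _with_intercept(X_train)
    xtx = Xt.T @ Xt
    if np.linalg.matrix_rank(xtx) < xtx.shape[0]:
        raise np.linalg.LinAlgError("training descriptor matrix is rank deficient")
    Xq = Xt if X_query is None else _with_intercept(X_query)
    # h_i = x_i' (X'X)^-1 x_i via a solve, no explicit inverse
    return np.einsum("ij,ji->i", Xq, np.linalg.solve(xtx, Xq.T))


def critical_leverage(k: int, N: int) -> float:
    """Critical leverage h* = 3 (k + 1) / N, reported to 3 decimals."""
    if N <= k + 1:
        raise ValueError("need N > k + 1 training compounds")
    return round(3.0 * (k + 1) / N, 3)


def standardized_residuals(residuals: np.ndarray, s: float,
                           leverage: np.ndarray | None = None,
                           studentized: bool = False) -> np.ndarray:
    """Residuals standardized by the regression standard error s.

    ``studentized=True`` divides additionally by sqrt(1 - h) (requires
    ``leverage``).
    """
    if s <= 0:
        raise ValueError("regression standard error must be positive")
    r = np.asarray(residuals, dtype=float) / s
    if studentized:
        if leverage is None:
            raise ValueError("studentized residuals require leverages")
        r = r / np.sqrt(1.0 - np.asarray(leverage))
    return r


@dataclass
class AdReport:
    """Per-compound applicability-domain report (Williams-plot data)."""

    names: list[str]
    leverage: np.ndarray
    std_residual: np.ndarray
    h_star: float

    @property
    def leverage_outlier(self) -> np.ndarray:
        return self.leverage > self.h_star

    @property
    def moderate_outlier(self) -> np.ndarray:
        return np.abs(self.std_residual) > 2.0

    @property
    def strong_outlier(self) -> np.ndarray:
        return np.abs(self.std_residual) > 3.0

    @property
    def in_domain(self) -> np.ndarray:
        return ~self.leverage_outlier & ~self.strong_outlier

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": self.names,
                "leverage": self.leverage,
                "std_residual": self.std_residual,
                "h_star": self.h_star,
                "in_domain": self.in_domain,
                "leverage_outlier": self.leverage_outlier,
                "moderate_outlier": self.moderate_outlier,
                "strong_outlier": self.strong_outlier,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def ad_report(
    X_train: np.ndarray,
    residuals: np.ndarray,
    s: float,
    names: list[str] | None = None,
    X_query: np.ndarray | None = None,
    query_residuals: np.ndarray | None = None,
    studentized: bool = False,
) -> AdReport:
    """Assemble an :class:`AdReport` for training (and optionally query) rows."""
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    k, N = X_train.shape[1], X_train.shape[0]
    if X_query is None:
        h = leverages(X_train)
        e = np.asarray(residuals, dtype=float)
    else:
        h = leverages(X_train, X_query)
        if query_residuals is None:
            raise ValueError("query residuals required with X_query")
        e = np.asarray(query_residuals, dtype=float)
    r = standardized_residuals(e, s, leverage=h, studentized=studentized)
    if names is None:
        names = [str(i) for i in range(len(r))]
    return AdReport(list(names), h, r, critical_leverage(k, N))


def williams_plot(report: AdReport, ax=None):
    """Leverage vs standardized-residual scatter with h* and sigma bands."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(report.leverage, report.std_residual, s=24)
    ax.axvline(report.h_star, ls="--", color="crimson", label=f"h* = {report.h_star}")
    for band in (2, 3):
        ax.axhline(band, ls=":", color="gray")
        ax.axhline(-band, ls=":", color="gray")
    ax.set_xlabel("leverage h")
    ax.set_ylabel("standardized residual")
    ax.legend()
    return ax
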