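"""Best Multi-Linear Regression (BMLR): stepwise forward descriptor
selection under noncollinearity and coefficient-significance constraints,
with internal (R2, leave-one-out q2, F, s2) and external (R2_test)
validation statistics.

The algorithm:

1. prune the descriptor pool (drop columns with missing values or zero
   variance);
2. fit every noncollinear descriptor pair (pairwise squared Pearson
   correlation below the threshold, default 0.6) and keep the top
   ``beam`` pairs by R2;
3. extend each seed greedily, at each step adding the descriptor that
   maximises R2 subject to noncollinearity with the current subset and
   to every coefficient satisfying |t| >= t_min, until ``max_k``
   descriptors or no admissible addition remains;
4. report the best model found, refit in natural scale (the search runs
   on centered/normalized descriptors; both give identical fitted
   values).

The public surface follows the Model/Results idiom: build a
:class:`BMLR` from a descriptor DataFrame and activities, call
``fit()``, and read estimates, t-values, diagnostics and ``summary()``
off the returned :class:`BMLRResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .admodel import AdReport, ad_report
from .model import LinearQsarModel

__all__ = [
    "FitStatistics",
    "prune_pool",
    "fit_ols",
    "q2_loo",
    "r2_external",
    "BMLR",
    "BMLRResults",
]


@dataclass
class FitStatistics:
    """Internal/external validation statistics of one multilinear fit."""

    R2: float
    q2_loo: float | None
    F: float
    s2: float
    t_values: np.ndarray
    N: int
    k: int
    R2_test: float | None = None
    r2_test_convention: str | None = None


def prune_pool(X: pd.DataFrame, verbose: bool = False) -> tuple[pd.DataFrame, list[str]]:
    """Drop descriptor columns with any missing value or zero variance."""
    removed = []
    for col in X.columns:
        v = X[col]
        if v.isna().any():
            removed.append(col)
        elif float(v.max() - v.min()) == 0.0:
            removed.append(col)
    kept = X.drop(columns=removed)
    if kept.shape[1] == 0:
        raise ValueError("descriptor pool is empty after pruning")
    if verbose and removed:
        print(f"pruned {len(removed)} descriptor(s): {removed}")
    return kept, removed


def _ols_core(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, float, np.ndarray]:
    """OLS with intercept: (beta incl. intercept, R2, s2, t-values)."""
    N = len(y)
    Xc = np.hstack([np.ones((N, 1)), X])
    k = X.shape[1]
    xtx = Xc.T @ Xc
    beta, rss_arr, rank, _ = np.linalg.lstsq(Xc, y, rcond=None)
    if rank < Xc.shape[1]:
        raise np.linalg.LinAlgError("descriptor matrix is rank deficient")
    resid = y - Xc @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    dof = N - k - 1
    if dof <= 0:
        raise ValueError("need N > k + 1 observations")
    s2 = rss / dof
    se = np.sqrt(np.clip(s2 * np.diag(np.linalg.inv(xtx)), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf)
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return beta, r2, s2, t


def fit_ols(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    names: list[str] | None = None,
) -> tuple[LinearQsarModel, FitStatistics]:
    """Ordinary least squares of y on the given descriptor columns.

    Runs through statsmodels; reports R2 = 1 - RSS/TSS,
    s2 = RSS/(N - k - 1), F = (R2/k) / ((1 - R2)/(N - k - 1)) and
    per-coefficient t-values.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.atleast_2d(np.asarray(X, dtype=float))
        if names is None:
            names = [f"x{i}" for i in range(Xa.shape[1])]
    y = np.asarray(y, dtype=float)
    N, k = Xa.shape
    res = sm.OLS(y, sm.add_constant(Xa, has_constant="add")).fit()
    if res.df_model < k or np.linalg.matrix_rank(Xa) < k:
        raise np.linalg.LinAlgError("descriptor matrix is rank deficient")
    r2 = float(res.rsquared)
    s2 = float(res.mse_resid)
    F = (r2 / k) / ((1.0 - r2) / (N - k - 1)) if r2 < 1.0 else np.inf
    model = LinearQsarModel(
        descriptor_names=names,
        coefficients=res.params[1:],
        intercept=float(res.params[0]),
        t_values=res.tvalues[1:],
        training_meta={"N": N, "k": k, "R2": r2, "F": F, "s2": s2},
    )
    stats = FitStatistics(R2=r2, q2_loo=None, F=F, s2=s2, t_values=res.tvalues, N=N, k=k)
    return model, stats


def q2_loo(X: pd.DataFrame | np.ndarray, y: np.ndarray, explicit: bool = False) -> float:
    """Leave-one-out cross-validated q2 = 1 - PRESS/TSS.

    Default uses the hat-matrix shortcut PRESS = sum (e_i / (1-h_i))^2;
    ``explicit=True`` runs the N refits instead (the two agree to
    numerical precision and are cross-checked in the test suite).
    """
    Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, dtype=float)
    N = len(y)
    if N < Xa.shape[1] + 3:
        raise ValueError("need N >= k + 3 for leave-one-out validation")
    tss = float(((y - y.mean()) ** 2).sum())
    if explicit:
        press = 0.0
        for i in range(N):
            mask = np.arange(N) != i
            Xc = np.hstack([np.ones((N - 1, 1)), Xa[mask]])
            beta, *_ = np.linalg.lstsq(Xc, y[mask], rcond=None)
            pred = beta[0] + Xa[i] @ beta[1:]
            press += (y[i] - pred) ** 2
    else:
        Xc = np.hstack([np.ones((N, 1)), Xa])
        beta, _, rank, _ = np.linalg.lstsq(Xc, y, rcond=None)
        if rank < Xc.shape[1]:
            raise np.linalg.LinAlgError("descriptor matrix is rank deficient")
        e = y - Xc @ beta
        h = np.einsum("ij,ji->i", Xc, np.linalg.solve(Xc.T @ Xc, Xc.T))
        press = float(((e / (1.0 - h)) ** 2).sum())
    return 1.0 - press / tss


def r2_external(
    model: LinearQsarModel,
    X_test: pd.DataFrame | np.ndarray,
    y_test: np.ndarray,
    convention: str = "correlation",
) -> float:
    """External-validation R2 on a held-out test set.

    ``convention='correlation'`` (default) is the squared Pearson
    correlation between predicted and observed activities;
    ``'predictive'`` is 1 - RSS_test/TSS_test.  Reports should carry the
    convention label since the two differ off the identity line.
    """
    if isinstance(X_test, pd.DataFrame):
        X_test = X_test[model.descriptor_names].to_numpy(dtype=float)
    y_test = np.asarray(y_test, dtype=float)
    if len(y_test) < 3:
        raise ValueError("external validation needs at least 3 test compounds")
    pred = model.predict_matrix(X_test)
    if convention == "correlation":
        if np.std(pred) == 0 or np.std(y_test) == 0:
            raise ValueError("zero variance in predictions or observations")
        return float(np.corrcoef(pred, y_test)[0, 1] ** 2)
    if convention == "predictive":
        tss = float(((y_test - y_test.mean()) ** 2).sum())
        return 1.0 - float(((y_test - pred) ** 2).sum()) / tss
    raise ValueError(f"unknown convention {convention!r}")


class BMLR:
    """Forward-selection multilinear QSAR model over a descriptor pool.

    Parameters
    ----------
    X : DataFrame
        Descriptor pool, one row per training compound.
    y : array-like
        Training activities (pIC50).
    max_k : int
        Largest descriptor count to grow to (>= 2).
    collinearity_r2 : float
        Pairwise squared-correlation threshold; descriptor pairs at or
        above it never co-occur in a model.
    beam : int
        Number of top two-descriptor seed models carried forward.
    t_min : float
        Significance gate: every coefficient of an accepted extension
        must have |t| >= t_min.
    """

    def __init__(
        self,
        X: pd.DataFrame,
        y,
        max_k: int = 5,
        collinearity_r2: float = 0.6,
        beam: int = 20,
        t_min: float = 2.0,
    ) -> None:
        if max_k < 2:
            raise ValueError("max_k must be >= 2")
        self.X, self.removed_columns = prune_pool(X)
        self.y = np.asarray(y, dtype=float)
        if len(self.y) != len(self.X):
            raise ValueError("X and y length mismatch")
        if len(self.y) <= max_k + 2:
            raise ValueError("need N > max_k + 2 training compounds")
        self.max_k = max_k
        self.collinearity_r2 = collinearity_r2
        self.beam = beam
        self.t_min = t_min

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, activity_col: str = "pic50", **kwargs
    ) -> "BMLR":
        y = df[activity_col].to_numpy(dtype=float)
        return cls(df.drop(columns=[activity_col]), y, **kwargs)

    # -- selection ----------------------------------------------------
    def _search_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Z-scored descriptors, the t-gate search runs on, plus corr^2."""
        Xa = self.X.to_numpy(dtype=float)
        Z = (Xa - Xa.mean(axis=0)) / Xa.std(axis=0, ddof=1)
        corr2 = np.corrcoef(Z, rowvar=False) ** 2
        return Xa, Z, corr2

    def _extend(self, subset: tuple[int, ...], Z: np.ndarray, corr2: np.ndarray,
                names: list[str]) -> tuple[tuple[int, ...], float, float]:
        """Greedy growth of one seed; returns (subset, R2, min|t|)."""
        cur = subset
        _, cur_r2, _, cur_t = _ols_core(Z[:, cur], self.y)
        while len(cur) < self.max_k:
            best = None
            for j in range(Z.shape[1]):
                if j in cur or any(corr2[j, c] >= self.collinearity_r2 for c in cur):
                    continue
                cand = cur + (j,)
                try:
                    _, r2, _, t = _ols_core(Z[:, cand], self.y)
                except np.linalg.LinAlgError:
                    continue
                if np.min(np.abs(t[1:])) < self.t_min:
                    continue
                key = (r2, float(np.min(np.abs(t[1:]))),
                       tuple(sorted(names[i] for i in cand)))
                # maximize R2; ties by larger min |t|, then lexicographic names
                if best is None or (key[0], key[1]) > (best[0][0], best[0][1]) or (
                    (key[0], key[1]) == (best[0][0], best[0][1]) and key[2] < best[0][2]
                ):
                    best = (key, cand)
            if best is None:
                break
            cur = best[1]
            _, cur_r2, _, cur_t = _ols_core(Z[:, cur], self.y)
        return cur, cur_r2, float(np.min(np.abs(cur_t[1:])))

    def fit(self) -> "BMLRResults":
        """Run the BMLR selection and return the fitted results object."""
        names = list(self.X.columns)
        Xa, Z, corr2 = self._search_arrays()
        p = Z.shape[1]

        # stage 1: all noncollinear pairs, ranked by R2
        seeds = []
        for i in range(p):
            for j in range(i + 1, p):
                if corr2[i, j] >= self.collinearity_r2:
                    continue
                try:
                    _, r2, _, t = _ols_core(Z[:, (i, j)], self.y)
                except np.linalg.LinAlgError:
                    continue
                seeds.append((r2, float(np.min(np.abs(t[1:]))), (i, j)))
        if not seeds:
            raise ValueError("no noncollinear descriptor pair available")
        seeds.sort(key=lambda s: (-s[0], -s[1], tuple(sorted(names[i] for i in s[2]))))

        # stage 2: greedy extension of the top seeds
        best = None
        for r2, tmin, pair in seeds[: self.beam]:
            subset, r2f, tminf = self._extend(pair, Z, corr2, names)
            key = (r2f, tminf, tuple(sorted(names[i] for i in subset)))
            if best is None or (key[0], key[1]) > (best[0][0], best[0][1]) or (
                (key[0], key[1]) == (best[0][0], best[0][1]) and key[2] < best[0][2]
            ):
                best = (key, subset)
        subset = list(best[1])

        # final model in natural scale (search ran normalized; fitted
        # values are identical, asserted in the test suite)
        sel_names = [names[i] for i in subset]
        Xsel = self.X[sel_names]
        model, stats = fit_ols(Xsel, self.y)
        stats.q2_loo = q2_loo(Xsel, self.y)
        model.training_meta["q2_loo"] = stats.q2_loo
        return BMLRResults(model=model, stats=stats, X=Xsel, y=self.y, bmlr=self)


@dataclass
class BMLRResults:
    """Fitted BMLR model with its validation statistics and diagnostics."""

    model: LinearQsarModel
    stats: FitStatistics
    X: pd.DataFrame
    y: np.ndarray
    bmlr: BMLR | None = field(default=None, repr=False)

    # statsmodels-flavoured accessors
    @property
    def params(self) -> pd.Series:
        return pd.Series(
            np.concatenate([[self.model.intercept], self.model.coefficients]),
            index=["intercept"] + list(self.model.descriptor_names),
        )

    @property
    def tvalues(self) -> pd.Series:
        return pd.Series(
            self.stats.t_values, index=["intercept"] + list(self.model.descriptor_names)
        )

    @property
    def rsquared(self) -> float:
        return self.stats.R2

    @property
    def q2(self) -> float:
        return self.stats.q2_loo

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.model.predict_matrix(self.X.to_numpy(dtype=float))

    @property
    def resid(self) -> np.ndarray:
        return self.y - self.fittedvalues

    def validate_external(
        self, X_test: pd.DataFrame, y_test, convention: str = "correlation"
    ) -> float:
        r2t = r2_external(self.model, X_test, np.asarray(y_test, float), convention)
        self.stats.R2_test = r2t
        self.stats.r2_test_convention = convention
        return r2t

    def ad_report(self, X_query: pd.DataFrame | None = None,
                  query_residuals=None, names=None) -> AdReport:
        """Applicability-domain report for the training set (or queries)."""
        Xq = None if X_query is None else X_query[self.model.descriptor_names].to_numpy(float)
        return ad_report(
            self.X.to_numpy(dtype=float),
            self.resid,
            np.sqrt(self.stats.s2),
            names=names if names is not None else list(self.X.index.astype(str)),
            X_query=Xq,
            query_residuals=query_residuals,
        )

    def williams_plot(self, ax=None):
        from .admodel import williams_plot

        return williams_plot(self.ad_report(), ax=ax)

    def summary(self) -> str:
        s = self.stats
        lines = [
            "BMLR multilinear QSAR fit",
            f"  N = {s.N}, k = {s.k}",
            f"  R2 = {s.R2:.4f}  q2(LOO) = {s.q2_loo:.4f}  F = {s.F:.2f}  s2 = {s.s2:.4f}",
        ]
        if s.R2_test is not None:
            lines.append(f"  R2_test = {s.R2_test:.4f} ({s.r2_test_convention})")
        lines.append(f"  {'descriptor':<12s} {'coef':>12s} {'t':>10s}")
        lines.append(f"  {'intercept':<12s} {self.model.intercept:>12.5f} {s.t_values[0]:>10.3f}")
        for name, c, t in zip(self.model.descriptor_names, self.model.coefficients,
                              s.t_values[1:]):
            lines.append(f"  {name:<12s} {c:>12.5f} {t:>10.3f}")
        return "\n".join(lines)
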