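"""Inverse-variance-weighted multivariable and univariable regression of
outcome SNP effects on disorder SNP effects.

The model regresses per-variant outcome estimates on one or two exposures'
per-variant estimates with an intercept, weighting each variant by the inverse
variance of its *outcome* estimate (w_k = se_out_k^-2). This is the
multivariable Egger-type design used for polygenic association profiling:
slopes are aggregate associations in outcome units per log-odds of disorder
liability, and the intercept absorbs directional pleiotropy not captured by
the exposures.

Inference uses the multiplicative dispersion estimator (weighted residual mean
square on n - p degrees of freedom) with two-sided P-values from the t
distribution, matching standard weighted-least-squares / MR-Egger practice.
The reported log-likelihood is the profiled Gaussian likelihood with
per-variant variances sigma^2 / w_k, so nested models compare validly in a
likelihood-ratio test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y


class InsufficientDataError(ValueError):
    """Fewer variants than the design requires."""


class SingularDesignError(ValueError):
    """Exactly (or numerically) collinear design columns."""


class BonferroniThreshold(NamedTuple):
    """Family-wise significance threshold alpha / n_tests."""
    exact: float
    rounded: float


def bonferroni_threshold(alpha: float, n_tests: int) -> BonferroniThreshold:
    """Bonferroni-adjusted threshold, exact and rounded to 4 decimals
    (the display convention for reported thresholds)."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if not (isinstance(n_tests, (int, np.integer)) and n_tests >= 1):
        raise ValueError("n_tests must be a positive integer")
    exact = alpha / n_tests
    return BonferroniThreshold(exact=exact, rounded=round(exact, 4))


class WeightedEffectRegression(RegressorMixin, BaseEstimator):
    """Weighted least squares with t-inference and model diagnostics.

    scikit-learn-style estimator: ``fit(X, y, sample_weight)`` where rows are
    variants, columns are exposure effect estimates and ``sample_weight`` the
    inverse outcome variances. Estimates are invariant to a positive rescaling
    of the weights.

    Parameters
    ----------
    fit_intercept:
        include an intercept column (default True; the Egger-type design).
    rcond_min:
        reciprocal condition number of the weighted normal matrix below which
        the design is declared singular.

    Attributes
    ----------
    intercept_, coef_ : point estimates
    se_, tvalues_, pvalues_ : per-parameter inference (intercept first)
    df_resid_ : residual degrees of freedom, n - p
    scale_ : multiplicative dispersion (weighted residual mean square)
    loglik_ : profiled Gaussian log-likelihood
    r2_weighted_, r2_unweighted_ : coefficients of determination
    vif_ : variance inflation factor per exposure (np.inf when collinear)
    """

    def __init__(self, fit_intercept: bool = True, rcond_min: float = 1e-12):
        self.fit_intercept = fit_intercept
        self.rcond_min = rcond_min

    def fit(self, X, y, sample_weight=None):
        X, y = check_X_y(X, y, y_numeric=True)
        n, k = X.shape
        w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=float)
        if w.shape != (n,) or np.any(w <= 0) or not np.all(np.isfinite(w)):
            raise ValueError("sample_weight must be positive, finite, one per row")
        D = np.column_stack([np.ones(n), X]) if self.fit_intercept else X
        p = D.shape[1]
        if n <= p:
            raise InsufficientDataError(
                f"need more rows ({n}) than parameters ({p})")

        A = D.T @ (w[:, None] * D)
        # scale-invariant conditioning check on the correlation-like matrix
        d = np.sqrt(np.diag(A))
        with np.errstate(divide="ignore", invalid="ignore"):
            C = A / np.outer(d, d)
        rcond = 1.0 / np.linalg.cond(C) if np.all(d > 0) else 0.0
        if not np.isfinite(rcond) or rcond < self.rcond_min:
            names = self._offending_columns(D, w)
            raise SingularDesignError(
                f"design is singular (rcond={rcond:.2e}); "
                f"collinear columns: {names}")

        b = np.linalg.solve(A, D.T @ (w * y))
        resid = y - D @ b
        rss_w = float(np.sum(w * resid ** 2))
        df = n - p
        scale = rss_w / df
        cov = scale * np.linalg.inv(A)
        se = np.sqrt(np.diag(cov))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, b / se, np.where(b == 0, 0.0, np.inf * np.sign(b)))
        pvals = 2.0 * sps.t.sf(np.abs(t), df) if df >= 1 else np.full(p, np.nan)

        ybar_w = float(np.sum(w * y) / np.sum(w))
        tss_w = float(np.sum(w * (y - ybar_w) ** 2))
        tss = float(np.sum((y - np.mean(y)) ** 2))
        sigma2_mle = rss_w / n
        if sigma2_mle > 0:
            loglik = (-0.5 * n * (np.log(2 * np.pi * sigma2_mle) + 1)
                      + 0.5 * float(np.sum(np.log(w))))
        else:
            loglik = np.inf  # perfect fit; degenerate Gaussian limit

        if self.fit_intercept:
            self.intercept_ = float(b[0])
            self.coef_ = b[1:]
        else:
            self.intercept_ = 0.0
            self.coef_ = b
        self.params_ = b
        self.se_ = se
        self.tvalues_ = t
        self.pvalues_ = pvals
        self.df_resid_ = df
        self.scale_ = scale
        self.loglik_ = float(loglik)
        self.r2_weighted_ = 1.0 - rss_w / tss_w if tss_w > 0 else 0.0
        self.r2_unweighted_ = (1.0 - float(np.sum(resid ** 2)) / tss) if tss > 0 else 0.0
        self.vif_ = variance_inflation_from_arrays(X, w) if k >= 2 else np.ones(k)
        self.n_features_in_ = k
        self.n_obs_ = n
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X)
        return self.intercept_ + X @ self.coef_

    @staticmethod
    def _offending_columns(D, w) -> str:
        sw = np.sqrt(w)
        Z = D * sw[:, None]
        names = []
        for i in range(Z.shape[1]):
            for j in range(i + 1, Z.shape[1]):
                zi, zj = Z[:, i], Z[:, j]
                denom = np.linalg.norm(zi) * np.linalg.norm(zj)
                if denom > 0 and abs(zi @ zj) / denom > 1 - 1e-10:
                    names.append(f"({i}, {j})")
        return ", ".join(names) if names else "undetermined"


def variance_inflation_from_arrays(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """VIF_j = 1 / (1 - R2_j), R2_j the weighted R2 of column j on the
    remaining columns plus intercept. Perfect collinearity yields np.inf."""
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if n < 3:
        raise ValueError("VIF needs at least 3 rows")
    out = np.empty(k)
    for j in range(k):
        yj = X[:, j]
        others = np.delete(X, j, axis=1)
        D = np.column_stack([np.ones(n), others])
        A = D.T @ (w[:, None] * D)
        try:
            b = np.linalg.solve(A, D.T @ (w * yj))
        except np.linalg.LinAlgError:
            out[j] = np.inf
            continue
        resid = yj - D @ b
        ybar = float(np.sum(w * yj) / np.sum(w))
        tss = float(np.sum(w * (yj - ybar) ** 2))
        rss = float(np.sum(w * resid ** 2))
        if tss <= 0:
            out[j] = np.inf
        else:
            r2 = 1.0 - rss / tss
            out[j] = np.inf if r2 > 1 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def variance_inflation(table: pd.DataFrame, exposures: Sequence[str],
                       weights: np.ndarray) -> dict[str, float]:
    """Per-exposure VIF on an aligned table (columns ``beta_<exposure>``)."""
    X = np.column_stack([table[f"beta_{e}"].to_numpy(dtype=float) for e in exposures])
    v = variance_inflation_from_arrays(X, np.asarray(weights, dtype=float))
    return dict(zip(exposures, (float(x) for x in v)))


@dataclass
class MvrResult:
    """Fitted multivariable (or univariable) weighted regression.

    ``estimates`` has one row per term ('intercept' first, then each
    exposure) with columns estimate, se, t, p.
    """

    outcome_trait: str
    exposures: tuple[str, ...]
    n_snps: int
    df_resid: int
    estimates: pd.DataFrame
    loglik: float
    r2_weighted: float
    r2_unweighted: float
    vif: dict[str, float] = field(default_factory=dict)
    orientation_trait: str | None = None

    @property
    def model(self) -> str:
        return "mvr" if len(self.exposures) > 1 else "uvr"

    def slope(self, exposure: str) -> pd.Series:
        return self.estimates.loc[exposure]

    @property
    def intercept(self) -> pd.Series:
        return self.estimates.loc["intercept"]

    def to_json_dict(self) -> dict:
        return {
            "outcome": self.outcome_trait,
            "exposures": list(self.exposures),
            "orientation": self.orientation_trait,
            "n_snps": self.n_snps,
            "df_resid": self.df_resid,
            "loglik": self.loglik,
            "r2_weighted": self.r2_weighted,
            "r2_unweighted": self.r2_unweighted,
            "vif": self.vif,
            "terms": {
                term: {k: (None if pd.isna(v) else float(v))
                       for k, v in row.items()}
                for term, row in self.estimates.iterrows()
            },
        }

    def to_frame(self) -> pd.DataFrame:
        """One row per term, suitable for TSV serialization."""
        df = self.estimates.reset_index(names="term")
        df.insert(0, "model", self.model)
        df.insert(1, "outcome", self.outcome_trait)
        df["n_snps"] = self.n_snps
        df["df_resid"] = self.df_resid
        df["loglik"] = self.loglik
        df["r2_weighted"] = self.r2_weighted
        df["vif"] = [self.vif.get(t, np.nan) for t in df["term"]]
        return df


def _fit(table: pd.DataFrame, exposures: Sequence[str], outcome: str,
         min_rows: int, orientation_trait: str | None) -> MvrResult:
    for trait in (*exposures, outcome):
        if f"beta_{trait}" not in table.columns:
            raise KeyError(f"aligned table has no beta_{trait} column")
    n = len(table)
    if n < min_rows:
        raise InsufficientDataError(
            f"{len(exposures)}-exposure fit needs >= {min_rows} variants, got {n}")
    se_out = table[f"se_{outcome}"].to_numpy(dtype=float)
    if np.any(se_out <= 0):
        raise ValueError("all outcome standard errors must be positive")
    w = se_out ** -2.0
    X = np.column_stack([table[f"beta_{e}"].to_numpy(dtype=float) for e in exposures])
    y = table[f"beta_{outcome}"].to_numpy(dtype=float)

    est = WeightedEffectRegression().fit(X, y, sample_weight=w)
    terms = ["intercept", *exposures]
    frame = pd.DataFrame(
        {"estimate": est.params_, "se": est.se_, "t": est.tvalues_, "p": est.pvalues_},
        index=pd.Index(terms, name="term"))
    vif = (dict(zip(exposures, (float(v) for v in est.vif_)))
           if len(exposures) >= 2 else {exposures[0]: 1.0})
    return MvrResult(
        outcome_trait=outcome, exposures=tuple(exposures), n_snps=n,
        df_resid=est.df_resid_, estimates=frame, loglik=est.loglik_,
        r2_weighted=est.r2_weighted_, r2_unweighted=est.r2_unweighted_,
        vif=vif, orientation_trait=orientation_trait)


def fit_weighted_mvr(table: pd.DataFrame, exposures: Sequence[str],
                     outcome: str, orientation_trait: str | None = None) -> MvrResult:
    """Fit the two-exposure weighted multivariable regression.

    ``table`` is an aligned table with ``beta_<trait>`` / ``se_<trait>``
    columns; weights are the inverse squared outcome standard errors.
    Requires at least 4 variants (df_resid = n - 3).
    """
    if len(exposures) != 2:
        raise ValueError("fit_weighted_mvr expects exactly two exposures")
    return _fit(table, exposures, outcome, min_rows=4,
                orientation_trait=orientation_trait)


def fit_weighted_uvr(table: pd.DataFrame, exposure: str, outcome: str,
                     orientation_trait: str | None = None) -> MvrResult:
    """Single-exposure analogue of :func:`fit_weighted_mvr` (df_resid = n - 2)."""
    return _fit(table, [exposure], outcome, min_rows=3,
                orientation_trait=orientation_trait)


def likelihood_ratio_test(reduced: MvrResult, full: MvrResult) -> tuple[float, float]:
    """Compare nested weighted fits on the same variants.

    Returns ``(statistic, p)`` with statistic = 2 * (loglik_full -
    loglik_reduced) clipped at 0 and p from chi-square with df equal to the
    number of added exposures.
    """
    if reduced.n_snps != full.n_snps or reduced.outcome_trait != full.outcome_trait:
        raise ValueError("LRT requires the same rows and outcome in both fits")
    if not set(reduced.exposures) <= set(full.exposures):
        raise ValueError("reduced model exposures must nest within the full model")
    df = len(full.exposures) - len(reduced.exposures)
    if df < 1:
        return 0.0, 1.0
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    return stat, float(sps.chi2.sf(stat, df))
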