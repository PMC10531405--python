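"""Synchrony-behavior regression and population dimensionality.

* Multiple regression of a per-trial licking variable on the instantaneous
  synchrony of the four component populations plus session fraction correct
  (``y ~ syn_TC1 + syn_TC2 + syn_TC3 + syn_TC4 + fraction_correct``), with
  added-variable (partial-regression) adjustment whose slope equals the
  full-model coefficient.
* Between-animal change correlation: per animal, the difference of a
  variable between the best- and worst-performance sessions, regressed
  across animals.
* PCA dimensionality of a neurons x features matrix (e.g. condition-
  concatenated PSTHs): eigenvalue fractions, cumulative VAF_k, and the
  participation ratio d = 1 / sum(lambda_hat_i^2), with an optional k-means
  partition (k = 4) of the item scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

SYN_COLUMNS = ("syn_TC1", "syn_TC2", "syn_TC3", "syn_TC4")


@dataclass
class RegressionFit:
    response: str
    terms: list                    # term names incl. intercept
    coefficients: np.ndarray
    p_values: np.ndarray
    residuals: np.ndarray
    fitted: np.ndarray
    n: int
    model: object                  # statsmodels results

    def coefficient(self, term: str) -> float:
        return float(self.coefficients[self.terms.index(term)])

    def p_value(self, term: str) -> float:
        return float(self.p_values[self.terms.index(term)])


def synchrony_regression(table: pd.DataFrame, response: str,
                         predictors=SYN_COLUMNS + ("fraction_correct",)
                         ) -> RegressionFit:
    """OLS of a licking variable on per-component synchrony + performance.

    Rows where all four synchrony values are absent (NaN) are dropped
    (trials with no sampled component neurons); a synchrony value absent
    for a single component is coded 0.  Coefficient p-values are two-sided
    t tests.  Raises on a rank-deficient design with a collinearity report.
    """
    df = table.copy()
    syn_cols = [c for c in predictors if c.startswith("syn_")]
    if syn_cols:
        all_absent = df[syn_cols].isna().all(axis=1)
        df = df.loc[~all_absent]
        df[syn_cols] = df[syn_cols].fillna(0.0)
    df = df.dropna(subset=[response])
    X = sm.add_constant(df[list(predictors)].astype(float), has_constant="add")
    rank = np.linalg.matrix_rank(X.values)
    if rank < X.shape[1]:
        corr = df[list(predictors)].astype(float).corr().round(3)
        raise ValueError("rank-deficient design matrix; predictor "
                         f"correlations:\n{corr}")
    res = sm.OLS(df[response].astype(float), X).fit()
    return RegressionFit(response=response, terms=list(X.columns),
                         coefficients=res.params.values,
                         p_values=res.pvalues.values,
                         residuals=res.resid.values,
                         fitted=res.fittedvalues.values,
                         n=len(df), model=res)


def added_variable(table: pd.DataFrame, response: str, predictor: str,
                   predictors=SYN_COLUMNS + ("fraction_correct",)
                   ) -> tuple[np.ndarray, np.ndarray, float]:
    """Added-variable (partial regression) values for one predictor.

    Both the selected predictor and the response are regressed on all other
    predictors; their residuals, shifted by the respective means, are the
    adjusted values.  The slope of adjusted-y on adjusted-x equals the
    selected predictor's full-model coefficient.
    """
    df = table.copy()
    syn_cols = [c for c in predictors if c.startswith("syn_")]
    if syn_cols:
        df = df.loc[~df[syn_cols].isna().all(axis=1)]
        df[syn_cols] = df[syn_cols].fillna(0.0)
    df = df.dropna(subset=[response])
    others = [p for p in predictors if p != predictor]
    Xo = sm.add_constant(df[others].astype(float), has_constant="add")
    rx = sm.OLS(df[predictor].astype(float), Xo).fit().resid.values
    ry = sm.OLS(df[response].astype(float), Xo).fit().resid.values
    adj_x = rx + float(df[predictor].mean())
    adj_y = ry + float(df[response].mean())
    slope = float(np.polynomial.polynomial.polyfit(rx, ry, 1)[1])
    return adj_x, adj_y, slope


@dataclass
class ChangeCorrelation:
    slope: float
    intercept: float
    p_value: float
    n_animals: int


def change_correlation(delta_predictor, delta_response) -> ChangeCorrelation:
    """Univariate regression of per-animal changes (>= 3 animals).

    Each element is one animal's difference between its best- and
    worst-performance sessions.
    """
    x = np.asarray(delta_predictor, float)
    y = np.asarray(delta_response, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched changes for at least 3 animals")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    return ChangeCorrelation(slope=float(res.params[1]),
                             intercept=float(res.params[0]),
                             p_value=float(res.pvalues[1]), n_animals=x.size)


def session_change(values_by_session: dict, performance_by_session: dict) -> float:
    """Difference of a variable between the highest- and lowest-performance
    sessions of one animal."""
    best = max(performance_by_session, key=lambda s: performance_by_session[s])
    worst = min(performance_by_session, key=lambda s: performance_by_session[s])
    return float(values_by_session[best] - values_by_session[worst])


@dataclass
class SpectrumSummary:
    eigenvalues: np.ndarray
    lambda_hat: np.ndarray        # eigenvalue fractions, sum to 1
    vaf_k: np.ndarray             # cumulative fractions
    dimension: float              # participation ratio 1/sum(lambda_hat^2)
    kmeans_labels: np.ndarray | None = None
    flagged: bool = False


def pca_dimension(matrix: np.ndarray, kmeans_k: int | None = None,
                  seed: int = 0) -> SpectrumSummary:
    """Covariance-spectrum summary of an items x features matrix.

    Features are centered across items (covariance PCA, no standardization).
    ``kmeans_k`` additionally partitions the item scores with k-means
    (20 restarts, seeded).
    """
    X = np.asarray(matrix, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need an items x features matrix with >= 2 items")
    Xc = X - X.mean(axis=0, keepdims=True)
    if not np.any(Xc):
        z = np.zeros(1)
        return SpectrumSummary(eigenvalues=z, lambda_hat=z, vaf_k=z,
                               dimension=float("nan"), flagged=True)
    # eigenvalues of the feature covariance via SVD of the centered matrix
    s = np.linalg.svd(Xc, compute_uv=False)
    eig = (s ** 2) / (X.shape[0] - 1)
    eig = eig[eig > np.finfo(float).eps * eig[0]]
    lam_hat = eig / eig.sum()
    vaf_k = np.cumsum(lam_hat)
    d = 1.0 / float((lam_hat ** 2).sum())
    labels = None
    if kmeans_k is not None:
        from sklearn.cluster import KMeans
        U, S, _ = np.linalg.svd(Xc, full_matrices=False)
        scores = U[:, : eig.size] * S[: eig.size]
        km = KMeans(n_clusters=kmeans_k, n_init=20, random_state=seed)
        labels = km.fit_predict(scores)
    return SpectrumSummary(eigenvalues=eig, lambda_hat=lam_hat, vaf_k=vaf_k,
                           dimension=d, kmeans_labels=labels)


def participation_ratio(lambda_hat) -> float:
    """d = 1 / sum(lambda_hat_i^2) for a normalized spectrum."""
    lam = np.asarray(lambda_hat, float)
    return 1.0 / float((lam ** 2).sum())
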