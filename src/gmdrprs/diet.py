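"""Dietary patterns by factor analysis of food-group intakes.

Food-group columns are standardized and factored by principal-component
extraction on the correlation matrix; components with eigenvalue above
a retention threshold (default 1.5) are kept and varimax-rotated
(normalized Kaiser).  Loadings with |value| >= 0.40 are flagged as the
significant contributors that name each pattern.  Subjects are scored
by the regression method (scores have zero mean, unit variance and are
exactly uncorrelated on the fitting sample) and dichotomized at the
70th percentile for use as exposures.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.multivariate.factor_rotation import rotate_factors

__all__ = [
    "DietPatternAnalyzer",
    "extract_factors",
    "score_patterns",
    "pattern_exposures",
]


class DietPatternAnalyzer(BaseEstimator, TransformerMixin):
    """PCA-based factor analysis with varimax rotation, sklearn-style.

    Parameters
    ----------
    retention_threshold:
        Keep components with eigenvalue above this (default 1.5).
    loading_min:
        |loading| flagged as a significant contribution (default 0.40).
    rotate:
        Apply normalized-Kaiser varimax rotation (default True).

    Fitted attributes: ``eigenvalues_`` (all p of them; their sum equals
    the number of variables), ``n_factors_``, ``loadings_`` (variables x
    factors, sign-fixed so each factor's largest-|loading| variable
    loads positively), ``significant_`` (boolean mask at
    ``loading_min``), ``mean_`` / ``std_`` (standardization constants),
    ``score_coef_`` (regression-method scoring coefficients).
    """

    def __init__(
        self,
        retention_threshold: float = 1.5,
        loading_min: float = 0.40,
        rotate: bool = True,
    ) -> None:
        self.retention_threshold = retention_threshold
        self.loading_min = loading_min
        self.rotate = rotate

    def fit(self, X: pd.DataFrame, y=None) -> "DietPatternAnalyzer":
        X = pd.DataFrame(X)
        if X.shape[1] < 2:
            raise ValueError("need at least two food-group columns")
        if X.shape[0] <= X.shape[1]:
            raise ValueError("need more subjects than food groups")
        arr = X.to_numpy(dtype=float)
        self.mean_ = arr.mean(axis=0)
        self.std_ = arr.std(axis=0, ddof=0)
        if (self.std_ == 0).any():
            bad = list(X.columns[self.std_ == 0])
            raise ValueError(f"constant food-group columns: {bad[:5]}")
        z = (arr - self.mean_) / self.std_
        corr = z.T @ z / len(z)
        eigval, eigvec = np.linalg.eigh(corr)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        self.eigenvalues_ = eigval
        keep = eigval > self.retention_threshold
        k = int(keep.sum())
        if k < 1:
            raise ValueError(
                f"no eigenvalue exceeds {self.retention_threshold}; "
                "lower the retention threshold"
            )
        self.n_factors_ = k
        loadings = eigvec[:, :k] * np.sqrt(eigval[:k])
        if self.rotate and k > 1:
            # normalized-Kaiser varimax: rotate communality-normalized rows
            h = np.sqrt((loadings**2).sum(axis=1))
            h[h == 0] = 1.0
            rotated, _ = rotate_factors(loadings / h[:, None], "varimax", tol=1e-8)
            loadings = rotated * h[:, None]
        # rotation sign is arbitrary: fix so the dominant variable loads +
        for j in range(loadings.shape[1]):
            i = int(np.argmax(np.abs(loadings[:, j])))
            if loadings[i, j] < 0:
                loadings[:, j] = -loadings[:, j]
        names = [f"pattern_{j + 1}" for j in range(k)]
        self.loadings_ = pd.DataFrame(loadings, index=X.columns, columns=names)
        self.significant_ = self.loadings_.abs() >= self.loading_min
        # regression-method scoring: F = Z R^{-1} L (unit variance, exactly
        # uncorrelated on the fitting sample for PCA loadings)
        self.score_coef_ = np.linalg.solve(corr, loadings)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "score_coef_"):
            raise RuntimeError("DietPatternAnalyzer is not fitted")
        X = pd.DataFrame(X)
        z = (X.to_numpy(dtype=float) - self.mean_) / self.std_
        scores = z @ self.score_coef_
        return pd.DataFrame(scores, index=X.index, columns=self.loadings_.columns)

    def communalities(self) -> pd.Series:
        """Per-variable sum of squared loadings (rotation-invariant)."""
        return (self.loadings_**2).sum(axis=1)


def extract_factors(
    foods: pd.DataFrame, retention_threshold: float = 1.5, loading_min: float = 0.40
) -> DietPatternAnalyzer:
    """Fit the factor model on a food-group intake matrix."""
    return DietPatternAnalyzer(retention_threshold, loading_min).fit(foods)


def score_patterns(model: DietPatternAnalyzer, foods: pd.DataFrame) -> pd.DataFrame:
    """Per-subject standardized factor scores (regression method)."""
    return model.transform(foods)


def pattern_exposures(scores: pd.DataFrame, percentile: float = 70.0) -> pd.DataFrame:
    """Binary high/low per pattern: high = score >= the sample
    percentile (ties at the cutoff are high)."""
    if not np.isfinite(scores.to_numpy()).all():
        raise ValueError("scores must be finite")
    out = {}
    for col in scores.columns:
        thr = np.percentile(scores[col], percentile)
        out[f"{col}_high"] = (scores[col] >= thr).astype(int)
    return pd.DataFrame(out, index=scores.index)
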