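"""Cross-platform and trait association analytics.

Pearson correlation matrices over trait/platform pairs (pairwise-complete
observations), per-trial ordinary-least-squares regressions of grain yield on
spectral indices, and principal component analysis of the index-plus-yield
table (listwise-complete, correlation matrix by default since the variables
mix units).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import RegressionError


@dataclass
class CorrelationMatrix:
    """Pairwise-complete Pearson correlations with per-cell sample sizes."""

    r: pd.DataFrame
    n: pd.DataFrame

    @property
    def labels(self) -> list[str]:
        return list(self.r.columns)

    def to_long(self) -> pd.DataFrame:
        """Heatmap-ready long format (var1, var2, r, n)."""
        long = self.r.stack().rename("r").reset_index()
        long.columns = ["var1", "var2", "r"]
        long["n"] = self.n.stack().to_numpy()
        return long


def correlation_matrix(
    trait_table: pd.DataFrame, min_n: int = 3
) -> CorrelationMatrix:
    """Pearson correlation matrix over the numeric columns of ``trait_table``.

    Each cell uses the pairwise-complete observations; cells with fewer than
    ``min_n`` complete pairs, or with a constant column, are missing (NaN).
    """
    num = trait_table.select_dtypes(include=[np.number])
    r = num.corr(method="pearson", min_periods=min_n)
    notna = num.notna().astype(float)
    n = pd.DataFrame(
        notna.T.to_numpy() @ notna.to_numpy(),
        index=num.columns,
        columns=num.columns,
    ).astype(int)
    return CorrelationMatrix(r=r, n=n)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def linear_regression(y, x) -> RegressionResult:
    """Ordinary least squares of ``y`` on ``x``.

    ``r_squared`` equals the squared Pearson correlation of the pair.

    Raises
    ------
    RegressionError
        With fewer than 3 complete points or zero variance in ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise RegressionError(f"need >= 3 complete points, got {len(x)}")
    if np.ptp(x) == 0:
        raise RegressionError("zero variance in the predictor")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=len(x),
    )


@dataclass
class PCAResult:
    """Loadings, scores and percent variance explained per component.

    ``variance_explained`` sums to 100 over all components; each loading
    vector is oriented so its largest-magnitude element is positive.
    """

    loadings: pd.DataFrame         # variables x components
    scores: pd.DataFrame           # rows x components
    variance_explained: np.ndarray # percent per component
    center: bool
    scale: bool


def pca(
    trait_table: pd.DataFrame,
    center: bool = True,
    scale: bool = True,
    n_components: int | None = None,
) -> PCAResult:
    """Principal component analysis of the numeric columns.

    Rows with any missing value are dropped (listwise deletion). With
    ``scale=True`` (default) components are eigenvectors of the correlation
    matrix, otherwise of the covariance matrix. Components are labelled
    ``Dim1, Dim2, ...`` in decreasing order of explained variance.
    """
    num = trait_table.select_dtypes(include=[np.number]).dropna()
    if num.shape[1] < 2:
        raise ValueError("PCA needs at least 2 variables")
    if len(num) < num.shape[1]:
        warnings.warn(
            f"only {len(num)} complete rows for {num.shape[1]} variables; "
            "components beyond the row rank are degenerate"
        )
    X = num.to_numpy(dtype=float)
    if center:
        X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = num.columns[sd == 0].tolist()
            raise ValueError(f"constant column(s) cannot be scaled: {bad}")
        X = X / sd
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    eig = s**2 / max(len(num) - 1, 1)
    loadings = vt.T  # columns are components
    # deterministic orientation: largest-magnitude loading positive
    for j in range(loadings.shape[1]):
        k = np.argmax(np.abs(loadings[:, j]))
        if loadings[k, j] < 0:
            loadings[:, j] *= -1.0
    scores = X @ loadings
    k = n_components or loadings.shape[1]
    dims = [f"Dim{i + 1}" for i in range(loadings.shape[1])]
    return PCAResult(
        loadings=pd.DataFrame(loadings[:, :k], index=num.columns, columns=dims[:k]),
        scores=pd.DataFrame(scores[:, :k], index=num.index, columns=dims[:k]),
        variance_explained=100.0 * eig / eig.sum(),
        center=center,
        scale=scale,
    )
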