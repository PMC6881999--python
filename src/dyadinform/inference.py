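"""Adjusted linear models giving magnitude and direction of CFI effects.

The forests rank predictors but do not report direction; ordinary least
squares with the same adjustment set supplies signed coefficient estimates
and conventional standard errors per stratum and year.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import CollinearityError, MalformedInputError

__all__ = ["LinearFit", "fit_ols"]


@dataclass(frozen=True)
class LinearFit:
    """OLS coefficients and conventional standard errors."""

    coefficients: Mapping[str, float]  # includes "intercept"
    standard_errors: Mapping[str, float]
    n_used: int
    residual_variance: float

    def to_frame(self, **labels) -> pd.DataFrame:
        df = pd.DataFrame({
            "predictor": list(self.coefficients),
            "estimate": list(self.coefficients.values()),
            "se": [self.standard_errors[k] for k in self.coefficients],
        })
        for k, v in reversed(labels.items()):
            df.insert(0, k, v)
        return df


def _first_collinear_column(M: np.ndarray, names: Sequence[str]) -> str:
    """Name the first column linearly dependent on its predecessors."""
    for j in range(1, M.shape[1]):
        if np.linalg.matrix_rank(M[:, : j + 1]) <= np.linalg.matrix_rank(M[:, :j]):
            return names[j]
    return names[-1]


def fit_ols(X, y, predictor_names: Sequence[str] | None = None) -> LinearFit:
    """OLS with intercept; sigma^2 = RSS / (n - p - 1).

    Raises :class:`CollinearityError` naming the offending column when the
    intercept-augmented design is rank deficient, and
    :class:`MalformedInputError` when there are too few rows.
    """
    if isinstance(X, pd.DataFrame):
        if predictor_names is None:
            predictor_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if predictor_names is None:
        predictor_names = [f"x{j}" for j in range(p)]
    if n <= p + 1:
        raise MalformedInputError(
            f"need n > p + 1 rows for OLS with errors; got n={n}, p={p}")

    M = np.column_stack([np.ones(n), X])
    names = ["intercept"] + list(predictor_names)
    if np.linalg.matrix_rank(M) < M.shape[1]:
        raise CollinearityError(_first_collinear_column(M, names))

    res = sm.OLS(y, M).fit()
    coefs = dict(zip(names, map(float, res.params)))
    ses = dict(zip(names, map(float, res.bse)))
    return LinearFit(coefficients=coefs, standard_errors=ses,
                     n_used=n, residual_variance=float(res.mse_resid))
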