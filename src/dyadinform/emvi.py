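"""Seed-ensemble mean variable importance (eMVI) with percentile bounds.

A single random forest's split-frequency importance varies with the seed
used to grow it.  To separate signal from that Monte-Carlo noise, the same
data are fit R times (default 100) with seeds ``base_seed + 1 .. base_seed
+ R``; the eMVI is the mean importance per predictor over replicates and
the 95% uncertainty bounds are the empirical 2.5th and 97.5th percentiles
of the replicate values.  The bounds quantify seed variability only — they
are not data-resampling confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import MalformedInputError
from .forest import ForestConfig, fit_forest, split_importance

__all__ = ["ImportancePanel", "SeedEnsembleImportance", "compute_emvi",
           "compare_emvi", "ComparisonResult"]


@dataclass(frozen=True)
class ImportancePanel:
    """Per-predictor eMVI with uncertainty bounds and the raw replicates."""

    predictors: tuple[str, ...]
    emvi: np.ndarray
    ub_lower: np.ndarray
    ub_upper: np.ndarray
    replicates: np.ndarray  # shape (R, p), one importance vector per seed
    base_seed: int

    @property
    def n_replicates(self) -> int:
        return self.replicates.shape[0]

    def __getitem__(self, predictor: str) -> tuple[float, float, float]:
        """(emvi, ub_lower, ub_upper) for one predictor."""
        j = self._index(predictor)
        return float(self.emvi[j]), float(self.ub_lower[j]), float(self.ub_upper[j])

    def _index(self, predictor: str) -> int:
        try:
            return self.predictors.index(predictor)
        except ValueError:
            raise KeyError(f"unknown predictor {predictor!r}") from None

    def to_frame(self, **labels) -> pd.DataFrame:
        """Tidy one-row-per-predictor frame; extra label columns prepended."""
        df = pd.DataFrame({
            "predictor": list(self.predictors),
            "emvi": self.emvi,
            "ub_lower": self.ub_lower,
            "ub_upper": self.ub_upper,
            "R": self.n_replicates,
        })
        for k, v in reversed(labels.items()):
            df.insert(0, k, v)
        return df


@dataclass(frozen=True)
class ComparisonResult:
    larger: str
    emvi_a: float
    emvi_b: float
    bounds_overlap: bool


class SeedEnsembleImportance:
    """Estimator computing eMVI and percentile uncertainty bounds.

    scikit-learn style: configure in ``__init__``, call ``fit(X, y)``,
    read fitted attributes (``emvi_``, ``ub_lower_``, ``ub_upper_``,
    ``replicates_``, ``panel_``).

    Parameters
    ----------
    forest_config
        Hyperparameters of each replicate forest; its ``seed`` acts as the
        base seed, replicate r uses ``seed + r``.
    n_replicates
        Number of re-seeded forests (R); 100 by default.
    """

    def __init__(self, forest_config: ForestConfig | None = None,
                 n_replicates: int = 100):
        self.forest_config = forest_config
        self.n_replicates = n_replicates

    def get_params(self, deep: bool = True) -> dict:
        return {"forest_config": self.forest_config,
                "n_replicates": self.n_replicates}

    def set_params(self, **params) -> "SeedEnsembleImportance":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y, predictor_names: Sequence[str] | None = None
            ) -> "SeedEnsembleImportance":
        if self.n_replicates < 1:
            raise MalformedInputError("n_replicates must be >= 1")
        cfg = self.forest_config or ForestConfig()
        if isinstance(X, pd.DataFrame):
            if predictor_names is None:
                predictor_names = list(X.columns)
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        p = X.shape[1]
        if predictor_names is None:
            predictor_names = [f"x{j}" for j in range(p)]
        if len(predictor_names) != p:
            raise MalformedInputError("predictor_names length mismatch")

        reps = np.empty((self.n_replicates, p))
        for r in range(1, self.n_replicates + 1):
            trees = fit_forest(X, y, replace(cfg, seed=cfg.seed + r))
            reps[r - 1] = split_importance(
                trees, p, cfg.max_importance_depth, cfg.decay_exponent)

        self.replicates_ = reps
        self.emvi_ = reps.mean(axis=0)
        # linear-interpolation empirical percentiles of the replicate values
        self.ub_lower_, self.ub_upper_ = np.percentile(reps, [2.5, 97.5], axis=0)
        self.predictor_names_ = tuple(predictor_names)
        self.panel_ = ImportancePanel(
            predictors=self.predictor_names_, emvi=self.emvi_,
            ub_lower=self.ub_lower_, ub_upper=self.ub_upper_,
            replicates=reps, base_seed=cfg.seed)
        return self


def compute_emvi(X, y, cfg: ForestConfig, n_replicates: int = 100,
                 predictor_names: Sequence[str] | None = None) -> ImportancePanel:
    """Fit R re-seeded forests and return the eMVI panel."""
    est = SeedEnsembleImportance(forest_config=cfg, n_replicates=n_replicates)
    est.fit(X, y, predictor_names=predictor_names)
    return est.panel_


def compare_emvi(panel: ImportancePanel, predictor_a: str,
                 predictor_b: str) -> ComparisonResult:
    """Which predictor has the larger eMVI, and do their bounds overlap?

    No formal test is attached: the bounds reflect seed variability only,
    so overlap is a descriptive flag, not a hypothesis test.
    """
    ea, la, ua = panel[predictor_a]
    eb, lb, ub = panel[predictor_b]
    larger = predictor_a if ea >= eb else predictor_b
    overlap = (la <= ub) and (lb <= ua)
    return ComparisonResult(larger=larger, emvi_a=ea, emvi_b=eb,
                            bounds_overlap=overlap)
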