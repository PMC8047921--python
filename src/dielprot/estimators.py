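"""scikit-learn-style estimator facades over the three detectors.

Each estimator follows the fit / fitted-attribute convention (`results_`
etc. are set by :meth:`fit`), supports ``get_params`` / ``set_params`` and
clones cleanly, so the detectors compose with sklearn model-selection
utilities.  The heavy lifting stays in the functional modules
(:mod:`dielprot.presence`, :mod:`dielprot.jtk`, :mod:`dielprot.bgls`).
"""

from __future__ import annotations

import pandas as pd
from sklearn.base import BaseEstimator

from . import bgls as _bgls
from . import jtk as _jtk
from .io import LfqMatrix, SampleMeta
from .presence import McConfig, run_mc

__all__ = ["MonteCarloPresence", "JtkDetector", "BglsDetector"]


class MonteCarloPresence(BaseEstimator):
    """Monte-Carlo imputation, presence classification and group contrast.

    Parameters mirror :class:`dielprot.presence.McConfig`.  After
    :meth:`fit`, ``calls_`` holds the per-protein table (status, p-value
    interval, significance, confidence score).

    Examples
    --------
    >>> est = MonteCarloPresence(n_sims=200, seed=1,
    ...                          contrast=("day", "night"))
    >>> est.fit(norm_matrix, meta)            # doctest: +SKIP
    >>> est.calls_.query("significant")       # doctest: +SKIP
    """

    def __init__(self, n_sims: int = 2000, min_subjects: int = 3,
                 alpha: float = 0.05, ci_level: float = 0.95, seed: int = 0,
                 contrast: tuple[str, str] = ("day", "night"),
                 contrast_on: str = "daynight", equal_var: bool = True,
                 test_values: str = "zscore", confidence_variant: str = "half"):
        self.n_sims = n_sims
        self.min_subjects = min_subjects
        self.alpha = alpha
        self.ci_level = ci_level
        self.seed = seed
        self.contrast = contrast
        self.contrast_on = contrast_on
        self.equal_var = equal_var
        self.test_values = test_values
        self.confidence_variant = confidence_variant

    def _config(self) -> McConfig:
        return McConfig(n_sims=self.n_sims, min_subjects=self.min_subjects,
                        alpha=self.alpha, ci_level=self.ci_level, seed=self.seed,
                        contrast=tuple(self.contrast), contrast_on=self.contrast_on,
                        equal_var=self.equal_var, test_values=self.test_values,
                        confidence_variant=self.confidence_variant)

    def fit(self, X: LfqMatrix, meta: SampleMeta) -> "MonteCarloPresence":
        """Run the contrast on a log-normalized matrix."""
        self.calls_ = run_mc(X, meta, self._config())
        self.significant_ = set(self.calls_.loc[self.calls_["significant"],
                                                "protein_id"])
        self.exclusive_ = set(self.calls_.loc[self.calls_["status"].isin(
            ["OnlyA", "OnlyB"]), "protein_id"])
        return self

    def flagged_set(self) -> set:
        """Significant-or-exclusive proteins (the detector's hit set)."""
        return self.significant_ | self.exclusive_


class JtkDetector(BaseEstimator):
    """Best-reference JTK rhythmicity test over a protein matrix."""

    def __init__(self, periods: tuple[float, ...] = (24.0,), lag_step: float = 1.0,
                 p_threshold: float = 0.01, bonferroni: bool = True,
                 fdr_permutations: int = 1000, seed: int = 0):
        self.periods = periods
        self.lag_step = lag_step
        self.p_threshold = p_threshold
        self.bonferroni = bonferroni
        self.fdr_permutations = fdr_permutations
        self.seed = seed

    def _config(self) -> _jtk.JtkConfig:
        return _jtk.JtkConfig(periods=tuple(self.periods), lag_step=self.lag_step,
                              p_threshold=self.p_threshold,
                              bonferroni=self.bonferroni,
                              fdr_permutations=self.fdr_permutations,
                              seed=self.seed)

    def fit(self, X: pd.DataFrame, times) -> "JtkDetector":
        """``X``: proteins x observations values (NaN = missing), aligned to
        hour-of-day ``times``."""
        self.results_ = _jtk.jtk_matrix(X, times, self._config())
        self.flagged_ = set(self.results_.loc[self.results_["passes"],
                                              "protein_id"])
        return self

    def estimate_fdr(self, X: pd.DataFrame, times,
                     n_permutations: int | None = None) -> dict:
        self.fdr_ = _jtk.permutation_fdr(X, times, self._config(),
                                         n_permutations=n_permutations)
        return self.fdr_


class BglsDetector(BaseEstimator):
    """Bayesian generalized Lomb–Scargle periodogram, windowed in period."""

    def __init__(self, period_min: float = 23.0, period_max: float = 24.0,
                 n_grid: int = 101,
                 threshold: float = _bgls.DEFAULT_CONCENTRATION_THRESHOLD):
        self.period_min = period_min
        self.period_max = period_max
        self.n_grid = n_grid
        self.threshold = threshold

    def fit(self, X: pd.DataFrame, times) -> "BglsDetector":
        self.results_ = _bgls.bgls_matrix(X, times, period_min=self.period_min,
                                          period_max=self.period_max,
                                          n_grid=self.n_grid,
                                          threshold=self.threshold)
        self.flagged_ = set(self.results_.loc[self.results_["flagged"],
                                              "protein_id"])
        return self
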