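"""Multiple imputation of missing biomarker calls by chained equations.

Missing biomarker values arise mainly because small AFI+ areas yield too few
research biopsies for all nine assays, i.e. the missingness relates to
observed covariates (missing at random).  Each incomplete marker is imputed
by a binary logistic regression on the other eight markers plus the
per-biopsy histology grade (dummy-coded, five levels), cycled over markers
``n_cycles`` times per copy.  Imputation uncertainty is propagated by an
approximate posterior draw: coefficients are sampled from a normal centred
at the (penalised, if separation requires it) MLE with covariance equal to
the inverse observed information, and states are Bernoulli draws from the
resulting probabilities.

The result is an :class:`ImputedEnsemble` of the original database (to be
analysed complete-case) together with ``m`` completed copies, matching a
"five imputed data sets + the original database" analysis design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from scipy.special import expit

from ._logistic import fit_logit_safe
from .cohort import CohortTable, GRADES, MARKERS

logger = logging.getLogger(__name__)

__all__ = ["ImputedEnsemble", "impute"]


@dataclass
class ImputedEnsemble:
    """The original cohort plus ``m`` completed copies."""

    original: CohortTable
    imputed: list[CohortTable]
    m: int
    imputation_seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.imputed) != self.m:
            raise ValueError("len(imputed) must equal m")

    @property
    def n_databases(self) -> int:
        """Analysable databases: the m imputed copies plus the original."""
        return self.m + 1

    def databases(self) -> Iterator[tuple[str, CohortTable]]:
        """Yield ('original', cohort) then ('mi1', ...) .. ('mi{m}', ...)."""
        yield "original", self.original
        for i, c in enumerate(self.imputed, start=1):
            yield f"mi{i}", c


def _design(markers: np.ndarray, hist_dummies: np.ndarray, j: int) -> np.ndarray:
    """Intercept + other eight markers + histology dummies for target marker j."""
    others = np.delete(markers, j, axis=1)
    return np.column_stack([np.ones(len(markers)), others, hist_dummies])


def impute(
    cohort: CohortTable,
    m: int = 5,
    n_cycles: int = 10,
    seed: int | None = None,
) -> ImputedEnsemble:
    """Chained-equations multiple imputation of the nine marker columns.

    Returns the original cohort untouched plus ``m`` completed copies;
    deterministic given ``seed``.  Raises if any marker is missing in every
    biopsy (its imputation model would be inestimable).
    """
    X0 = cohort.marker_matrix().to_numpy(dtype=float)
    n = len(X0)
    miss = np.isnan(X0)
    if n > 0:
        fully_missing = [MARKERS[j] for j in range(len(MARKERS)) if miss[:, j].all()]
        if fully_missing:
            raise ValueError(f"markers 100% missing, cannot impute: {fully_missing}")

    hist = pd.get_dummies(
        pd.Categorical(cohort.biopsies["histology"], categories=GRADES),
        drop_first=True,
    ).to_numpy(dtype=float)
    if n == 0:
        hist = np.zeros((0, len(GRADES) - 1))

    rng = np.random.default_rng(seed)
    copies: list[CohortTable] = []
    incomplete = [j for j in range(len(MARKERS)) if miss[:, j].any()]
    for _ in range(m):
        X = X0.copy()
        # initial fill: draw from each marker's observed marginal
        for j in incomplete:
            obs = X0[~miss[:, j], j]
            p = obs.mean() if len(obs) else 0.5
            X[miss[:, j], j] = (rng.random(miss[:, j].sum()) < p).astype(float)
        for _cycle in range(n_cycles):
            for j in incomplete:
                obs_rows = ~miss[:, j]
                D = _design(X, hist, j)
                y = X0[obs_rows, j]
                if y.min() == y.max():
                    # degenerate marker: all observed calls identical
                    X[miss[:, j], j] = y[0]
                    continue
                fit = fit_logit_safe(D[obs_rows], y)
                cov = np.linalg.inv(fit.hessian + 1e-10 * np.eye(len(fit.beta)))
                try:
                    L = np.linalg.cholesky((cov + cov.T) / 2.0)
                except np.linalg.LinAlgError:
                    L = np.linalg.cholesky(
                        (cov + cov.T) / 2.0 + 1e-8 * np.eye(len(cov))
                    )
                beta = fit.beta + L @ rng.standard_normal(len(fit.beta))
                p_mis = expit(D[miss[:, j]] @ beta)
                X[miss[:, j], j] = (rng.random(len(p_mis)) < p_mis).astype(float)
        filled = cohort.copy()
        for jj, name in enumerate(MARKERS):
            filled.biopsies[name] = X[:, jj]
        copies.append(filled)
    return ImputedEnsemble(original=cohort, imputed=copies, m=m, imputation_seed=seed)
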