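"""Bootstrap inclusion-frequency selection of a small biomarker panel.

For each database of the imputed ensemble (the original, restricted to rows
with all nine markers observed, plus each completed copy) we draw ``B``
bootstrap resamples of the biopsy rows — with replacement, equal size — and
fit a backward-stepwise logistic regression of the HGD/EC endpoint on the
nine markers, eliminating by likelihood-ratio significance from the full
model (AIC elimination is available as an alternative).  A marker's inclusion
frequency in a database is the number of resamples whose selected model
retains it.  Markers whose *median* inclusion frequency over all databases
reaches the threshold (default 90 of B=100) form the panel.

The per-resample selection model is deliberately isolated behind
:func:`stepwise_logistic` so alternatives (forward selection, an L1 path)
can be substituted without touching the bootstrap machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from scipy.stats import chi2

from ._logistic import fit_logit_safe
from .cohort import CohortTable, MARKERS, PanelDefinition, endpoint_labels
from .imputation import ImputedEnsemble

logger = logging.getLogger(__name__)

__all__ = [
    "InclusionMatrix",
    "PanelSelection",
    "stepwise_logistic",
    "bootstrap_inclusion",
    "select_panel",
]


@dataclass
class InclusionMatrix:
    """Markers × databases inclusion counts out of B bootstrap resamples."""

    frequencies: pd.DataFrame  # index MARKERS, one column per database
    B: int
    threshold: int = 90

    def __post_init__(self) -> None:
        f = self.frequencies.to_numpy()
        if (f < 0).any() or (f > self.B).any():
            raise ValueError("inclusion frequencies must lie in [0, B]")

    @property
    def medians(self) -> pd.Series:
        """Per-marker median inclusion frequency over databases."""
        return self.frequencies.median(axis=1)


@dataclass(frozen=True)
class PanelSelection:
    """Outcome of thresholding the inclusion medians; may be empty."""

    members: tuple[str, ...]
    medians: pd.Series
    threshold: int
    degenerate: bool = False  # all nine markers selected

    @property
    def is_empty(self) -> bool:
        return len(self.members) == 0

    def to_panel(self, cutoff: int | None = None) -> PanelDefinition:
        if self.is_empty:
            raise ValueError("no panel selected (no marker reached the threshold)")
        if cutoff is None:
            cutoff = min(2, len(self.members))
        return PanelDefinition(members=self.members, cutoff=cutoff)


def stepwise_logistic(
    X: np.ndarray,
    y: np.ndarray,
    criterion: str = "lrt",
    alpha: float = 0.01,
) -> list[int]:
    """Backward-stepwise elimination from the full logistic model.

    ``X`` is the n × 9 marker matrix (no intercept column), ``y`` the binary
    endpoint.  Returns the indices of the retained columns (possibly empty).

    With ``criterion="lrt"`` (default) the variable with the largest
    likelihood-ratio p value is dropped while that p value exceeds ``alpha``
    — the stringent backward-elimination rule used with bootstrap inclusion
    frequencies (a lenient criterion would retain chance associations of the
    realised sample in most resamples, washing out the frequency contrast).
    ``criterion="aic"`` drops variables while AIC improves instead.
    """
    if criterion not in ("lrt", "aic"):
        raise ValueError(f"unknown criterion {criterion!r}")
    n = len(y)
    ones = np.ones((n, 1))

    def fit(cols: list[int], beta0=None):
        D = np.concatenate([ones, X[:, cols]], axis=1) if cols else ones
        return fit_logit_safe(D, y, beta0=beta0)

    current = list(range(X.shape[1]))
    cur_fit = fit(current)
    while current:
        best = None  # (trial_cols, trial_fit)
        if criterion == "aic":
            best_aic = cur_fit.aic
            for pos in range(len(current)):
                trial = current[:pos] + current[pos + 1 :]
                # warm-start from the current model minus the dropped slope
                f = fit(trial, beta0=np.delete(cur_fit.beta, pos + 1))
                if f.aic < best_aic - 1e-10:
                    best, best_aic = (trial, f), f.aic
        else:
            worst_p = alpha
            for pos in range(len(current)):
                trial = current[:pos] + current[pos + 1 :]
                f = fit(trial, beta0=np.delete(cur_fit.beta, pos + 1))
                lr = max(2.0 * (cur_fit.loglik - f.loglik), 0.0)
                p = float(chi2.sf(lr, 1))
                if p > worst_p:
                    best, worst_p = (trial, f), p
        if best is None:
            break
        current, cur_fit = best
    return current


def _database_arrays(
    ensemble: ImputedEnsemble, endpoint: str
) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """(name, X, y) per database; the original keeps only listwise-complete rows."""
    out = []
    for name, cohort in ensemble.databases():
        X = cohort.marker_matrix().to_numpy(dtype=float)
        y = endpoint_labels(cohort, level="biopsy", endpoint=endpoint).astype(float)
        if name == "original":
            complete = ~np.isnan(X).any(axis=1)
            X, y = X[complete], y[complete]
        out.append((name, X, y))
    return out


def bootstrap_inclusion(
    ensemble: ImputedEnsemble,
    B: int = 100,
    seed: int | None = None,
    endpoint: str = "HGD_EC",
    threshold: int = 90,
    criterion: str = "lrt",
    alpha: float = 0.01,
    max_redraws: int = 100,
) -> InclusionMatrix:
    """Accumulate stepwise-model inclusion counts over B resamples per database.

    Resamples whose endpoint is single-class are redrawn (logged) up to
    ``max_redraws`` times.  Deterministic given ``seed``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    dbs = _database_arrays(ensemble, endpoint)
    freq = np.zeros((len(MARKERS), len(dbs)), dtype=int)
    for j, (name, X, y) in enumerate(dbs):
        n = len(y)
        if n == 0:
            raise ValueError(f"database {name} has no analysable rows")
        for _ in range(B):
            for attempt in range(max_redraws):
                idx = rng.integers(0, n, size=n)
                if 0.0 < y[idx].mean() < 1.0:
                    break
                logger.info("single-class bootstrap resample in %s; redrawing", name)
            else:
                raise RuntimeError(
                    f"could not draw a two-class bootstrap resample from {name}"
                )
            retained = stepwise_logistic(X[idx], y[idx], criterion=criterion, alpha=alpha)
            freq[retained, j] += 1
    fdf = pd.DataFrame(freq, index=list(MARKERS), columns=[d[0] for d in dbs])
    return InclusionMatrix(frequencies=fdf, B=B, threshold=threshold)


def select_panel(incl: InclusionMatrix, threshold: int | None = None) -> PanelSelection:
    """Markers whose median inclusion frequency reaches the threshold.

    An empty selection is a regular result (no exception); selection of all
    nine markers is flagged degenerate.
    """
    thr = incl.threshold if threshold is None else threshold
    med = incl.medians
    members = tuple(m for m in MARKERS if med[m] >= thr)
    degenerate = len(members) == len(MARKERS)
    if degenerate:
        logger.warning("all nine markers reached the inclusion threshold (degenerate)")
    return PanelSelection(members=members, medians=med, threshold=thr, degenerate=degenerate)
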