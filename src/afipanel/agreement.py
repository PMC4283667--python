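"""Chance-corrected interobserver agreement (Cohen's and weighted κ).

Used for two reliability questions: agreement of expert pathologists on the
ordinal dysplasia scale (weighted κ, partial credit for near-misses) and
agreement of endoscopists on the location of an AFI+ area (plain κ on the
binary within-30° indicator).  Standard errors are the large-sample
(Fleiss–Cohen–Everitt) estimates; the three-rater summary is the mean of
pairwise κ values with a case-level jackknife SE.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["cohen_kappa", "weighted_kappa", "multi_rater_kappa"]


def _contingency(r1, r2, categories) -> np.ndarray:
    cat_idx = {c: i for i, c in enumerate(categories)}
    k = len(categories)
    tab = np.zeros((k, k))
    for a, b in zip(r1, r2):
        tab[cat_idx[a], cat_idx[b]] += 1
    return tab


def _weights(k: int, scheme: str) -> np.ndarray:
    """Agreement weights: 1 on the diagonal, decreasing with distance."""
    i = np.arange(k)
    d = np.abs(i[:, None] - i[None, :])
    if k == 1:
        return np.ones((1, 1))
    if scheme == "identity":
        return (d == 0).astype(float)
    if scheme == "linear":
        return 1.0 - d / (k - 1)
    if scheme == "quadratic":
        return 1.0 - (d / (k - 1)) ** 2
    raise ValueError(f"unknown weight scheme {scheme!r}")


def _kappa_from_table(tab: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted kappa and its asymptotic SE from a square contingency table."""
    n = tab.sum()
    p = tab / n
    pr = p.sum(axis=1)  # rater-1 marginals
    pc = p.sum(axis=0)  # rater-2 marginals
    po = float((w * p).sum())
    pe = float((w * np.outer(pr, pc)).sum())
    if np.isclose(pe, 1.0):
        warnings.warn(
            "expected agreement is 1 (a single category dominates); kappa reported as 1",
            RuntimeWarning,
            stacklevel=3,
        )
        return 1.0, 0.0
    kappa = (po - pe) / (1.0 - pe)
    # Fleiss, Cohen & Everitt large-sample variance of weighted kappa
    wbar_row = (w * pc[None, :]).sum(axis=1)  # \bar w_{i.}
    wbar_col = (w * pr[:, None]).sum(axis=0)  # \bar w_{.j}
    term = (w * (1.0 - pe) - (wbar_row[:, None] + wbar_col[None, :]) * (1.0 - po)) ** 2
    var = ((p * term).sum() - (po * pe - 2.0 * pe + po) ** 2) / (n * (1.0 - pe) ** 4)
    return float(kappa), float(np.sqrt(max(var, 0.0)))


def _categories(r1, r2, categories=None) -> list:
    if categories is not None:
        return list(categories)
    return sorted(set(r1) | set(r2))


def cohen_kappa(r1: Sequence, r2: Sequence, categories=None) -> tuple[float, float]:
    """Unweighted Cohen's κ between two raters → (kappa, asymptotic SE)."""
    r1, r2 = list(r1), list(r2)
    if len(r1) != len(r2) or len(r1) < 2:
        raise ValueError("rating vectors must have equal length >= 2")
    cats = _categories(r1, r2, categories)
    tab = _contingency(r1, r2, cats)
    return _kappa_from_table(tab, _weights(len(cats), "identity"))


def weighted_kappa(
    r1: Sequence, r2: Sequence, weights: str = "linear", categories=None
) -> tuple[float, float]:
    """Weighted κ on a shared *ordered* category set → (kappa, asymptotic SE).

    ``categories`` fixes the category order; by default the sorted union of
    observed labels is used, which is only correct when labels sort in their
    ordinal order.
    """
    r1, r2 = list(r1), list(r2)
    if len(r1) != len(r2) or len(r1) < 2:
        raise ValueError("rating vectors must have equal length >= 2")
    cats = _categories(r1, r2, categories)
    tab = _contingency(r1, r2, cats)
    return _kappa_from_table(tab, _weights(len(cats), weights))


def _kappa_point(tab: np.ndarray, w: np.ndarray) -> float:
    n = tab.sum()
    p = tab / n
    pr, pc = p.sum(axis=1), p.sum(axis=0)
    po = float((w * p).sum())
    pe = float((w * np.outer(pr, pc)).sum())
    if np.isclose(pe, 1.0):
        return 1.0
    return (po - pe) / (1.0 - pe)


def multi_rater_kappa(
    table: pd.DataFrame,
    weighted: bool = False,
    weights: str = "linear",
    categories=None,
    se: bool = True,
) -> tuple[float, float]:
    """Mean pairwise (weighted) κ over ≥2 raters, SE by case-level jackknife.

    ``table`` is cases × raters; rows with any missing rating are dropped.
    With exactly two raters the point estimate reduces to the pairwise κ
    (the SE is then the jackknife rather than the asymptotic estimate).
    Pass ``se=False`` to skip the jackknife (returns SE = NaN).
    """
    t = table.dropna(axis=0)
    if t.shape[1] < 2 or t.shape[0] < 2:
        raise ValueError("need >= 2 raters and >= 2 complete cases")
    cats = categories
    if cats is None:
        cats = sorted(set(np.asarray(t).ravel().tolist()))
    scheme = weights if weighted else "identity"
    k = len(cats)
    w = _weights(k, scheme)

    cat_idx = {c: i for i, c in enumerate(cats)}
    codes = np.array([[cat_idx[v] for v in t.iloc[:, j]] for j in range(t.shape[1])])
    n = t.shape[0]
    pairs = [(a, b) for a in range(len(codes)) for b in range(a + 1, len(codes))]
    tabs = []
    for a, b in pairs:
        tab = np.zeros((k, k))
        np.add.at(tab, (codes[a], codes[b]), 1.0)
        tabs.append(tab)
    point = float(np.mean([_kappa_point(tab, w) for tab in tabs]))
    if not se:
        return point, float("nan")
    # leave-one-case-out jackknife by downdating each pair table
    loo = np.zeros(n)
    for i in range(n):
        ks = []
        for (a, b), tab in zip(pairs, tabs):
            tab[codes[a][i], codes[b][i]] -= 1.0
            ks.append(_kappa_point(tab, w))
            tab[codes[a][i], codes[b][i]] += 1.0
        loo[i] = np.mean(ks)
    se_val = float(np.sqrt((n - 1) / n * ((loo - loo.mean()) ** 2).sum()))
    return point, se_val
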