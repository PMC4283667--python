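"""Count-of-positive-biomarkers classification and diagnostic evaluation.

The final diagnostic tool is deliberately simple: a biopsy or patient is
called high-risk when at least ``cutoff`` of the panel's markers are
positive.  This module scores records, aggregates biopsy-level calls to the
patient level (a marker is positive for a patient if positive in *any* of
the patient's AFI+ areas), picks the accuracy-optimal cut-off, computes
ROC/AUC with percentile-bootstrap confidence intervals, derives diagnostic
metrics with exact Clopper–Pearson intervals, and runs the exhaustive search
over all 36 two-marker and 84 three-marker panels.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.proportion import proportion_confint

from .cohort import CohortTable, MARKERS, PanelDefinition, endpoint_labels

__all__ = [
    "DiagnosticResult",
    "AUCResult",
    "panel_score",
    "panel_scores",
    "aggregate_patient",
    "aggregate_cohort",
    "roc_auc",
    "choose_cutoff",
    "diagnostic_metrics",
    "exhaustive_panel_search",
]


# ---------------------------------------------------------------------- #
# scoring and aggregation
# ---------------------------------------------------------------------- #
def panel_score(markers, panel: PanelDefinition, missing_policy: str = "undetermined"):
    """Count of positive panel members for one record.

    ``markers`` maps marker name → 1/0/NaN (or 'positive'/'negative'/'missing').
    With the default policy a record with any missing member scores
    ``None`` (undetermined); ``count-observed`` counts positives among the
    observed members instead.
    """
    if missing_policy not in ("undetermined", "count-observed"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    vals = []
    for m in panel.members:
        v = markers[m]
        if isinstance(v, str):
            v = {"positive": 1.0, "negative": 0.0, "missing": np.nan}[v]
        vals.append(float(v) if v is not None else np.nan)
    arr = np.asarray(vals, dtype=float)
    if np.isnan(arr).any() and missing_policy == "undetermined":
        return None
    return int(np.nansum(arr))


def panel_scores(
    table: pd.DataFrame, panel: PanelDefinition, missing_policy: str = "undetermined"
) -> np.ndarray:
    """Vectorised :func:`panel_score` over a marker table → float array with NaN
    for undetermined records."""
    if missing_policy not in ("undetermined", "count-observed"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    sub = table[list(panel.members)].to_numpy(dtype=float)
    scores = np.nansum(sub, axis=1)
    if missing_policy == "undetermined":
        scores = np.where(np.isnan(sub).any(axis=1), np.nan, scores)
    return scores


def aggregate_patient(
    biopsies: pd.DataFrame,
    markers: tuple[str, ...] = MARKERS,
    use_afi: str = "AFI+",
    fallback: bool = True,
) -> pd.Series:
    """Per-patient marker calls from one patient's biopsy rows.

    A marker is positive if positive in any contributing biopsy, negative if
    observed in at least one and positive in none, missing only if
    unobserved in all.  Contributing biopsies are those with
    ``afi_status == use_afi``; patients without any fall back to the other
    areas when ``fallback`` is true (otherwise all markers are missing).
    """
    if len(biopsies) == 0:
        raise ValueError("aggregate_patient requires at least one biopsy")
    contributing = biopsies[biopsies["afi_status"] == use_afi]
    if len(contributing) == 0 and fallback:
        contributing = biopsies
    out = {}
    for m in markers:
        col = contributing[m] if len(contributing) else pd.Series(dtype=float)
        if len(col) == 0 or col.isna().all():
            out[m] = np.nan
        else:
            out[m] = float((col == 1.0).any())
    return pd.Series(out)


def aggregate_cohort(
    cohort: CohortTable,
    markers: tuple[str, ...] = MARKERS,
    use_afi: str = "AFI+",
    fallback: bool = True,
    endpoint: str = "HGD_EC",
    protocol: str = "overall",
) -> pd.DataFrame:
    """Patient-level marker-call table with the per-patient endpoint label.

    Index is patient_id; columns are the marker calls plus ``label``.
    """
    groups = cohort.biopsies.groupby("patient_id", sort=False)
    calls = {
        pid: aggregate_patient(sub, markers=markers, use_afi=use_afi, fallback=fallback)
        for pid, sub in groups
    }
    table = pd.DataFrame.from_dict(calls, orient="index")
    table = table.reindex(cohort.patients["patient_id"])
    labels = endpoint_labels(cohort, level="patient", endpoint=endpoint, protocol=protocol)
    table["label"] = labels.astype(float)
    return table


# ---------------------------------------------------------------------- #
# ROC / AUC
# ---------------------------------------------------------------------- #
@dataclass(frozen=True)
class AUCResult:
    auc: float
    ci: tuple[float, float]
    n_boot: int

    def __post_init__(self) -> None:
        lo, hi = self.ci
        if not (lo - 1e-12 <= self.auc <= hi + 1e-12):
            raise ValueError("CI must bracket the AUC point estimate")


def _auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Trapezoidal/rank AUC (equals the Mann–Whitney statistic U/(n1*n0))."""
    labels = labels.astype(bool)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: both classes must be present")
    r = rankdata(scores)
    u = r[labels].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_auc(
    scores,
    labels,
    n_boot: int = 2000,
    seed: int | None = None,
    alpha: float = 0.05,
    max_redraws: int = 100,
) -> AUCResult:
    """AUC of a (typically integer) score with a percentile-bootstrap CI.

    Bootstrap resamples with a single outcome class are redrawn up to
    ``max_redraws`` times.  Deterministic given ``seed``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if np.isnan(scores).any():
        raise ValueError("scores contain NaN; resolve undetermined records first")
    point = _auc(scores, labels)
    if n_boot <= 0:
        return AUCResult(auc=point, ci=(point, point), n_boot=0)
    rng = np.random.default_rng(seed)
    n = len(scores)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        for _ in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            yb = labels[idx]
            if 0 < yb.sum() < n:
                break
        else:
            raise RuntimeError("could not draw a two-class bootstrap resample")
        boots[b] = _auc(scores[idx], yb)
    lo, hi = np.quantile(boots, [alpha / 2.0, 1.0 - alpha / 2.0])
    return AUCResult(auc=point, ci=(float(min(lo, point)), float(max(hi, point))), n_boot=n_boot)


# ---------------------------------------------------------------------- #
# cut-off choice and diagnostic metrics
# ---------------------------------------------------------------------- #
def _confusion(scores: np.ndarray, labels: np.ndarray, cutoff: int) -> tuple[int, int, int, int]:
    call = scores >= cutoff
    tp = int((call & labels).sum())
    fp = int((call & ~labels).sum())
    fn = int((~call & labels).sum())
    tn = int((~call & ~labels).sum())
    return tp, fp, fn, tn


def choose_cutoff(
    scores,
    labels,
    criterion: str = "accuracy",
    max_cutoff: int | None = None,
) -> int:
    """Cut-off in 1..max score maximising accuracy (default) or Youden's J.

    Ties break toward the *higher* cut-off (favouring specificity).
    """
    if criterion not in ("accuracy", "youden"):
        raise ValueError(f"unknown criterion {criterion!r}")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("cut-off choice requires both outcome classes")
    if max_cutoff is None:
        max_cutoff = max(int(np.nanmax(scores)), 1)
    best_c, best_val = 1, -np.inf
    for c in range(1, max_cutoff + 1):
        tp, fp, fn, tn = _confusion(scores, labels, c)
        if criterion == "accuracy":
            val = (tp + tn) / len(scores)
        else:
            val = tp / (tp + fn) + tn / (tn + fp) - 1.0
        if val >= best_val - 1e-12:  # ascending c, so ties move to the higher cutoff
            best_c, best_val = c, max(val, best_val)
    return int(best_c)


@dataclass(frozen=True)
class DiagnosticResult:
    """Confusion counts with derived proportions and exact binomial intervals."""

    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    sens_ci: tuple[float, float]
    spec_ci: tuple[float, float]
    ci_method: str = "clopper-pearson"

    def display(self, dp: int = 1) -> dict[str, str]:
        """Percentages rounded for presentation (point estimates at ``dp``)."""
        fmt = lambda x: f"{100.0 * x:.{dp}f}%"
        return {
            "sensitivity": fmt(self.sensitivity),
            "specificity": fmt(self.specificity),
            "ppv": fmt(self.ppv),
            "npv": fmt(self.npv),
            "accuracy": fmt(self.accuracy),
            "sens_ci": f"({fmt(self.sens_ci[0])} to {fmt(self.sens_ci[1])})",
            "spec_ci": f"({fmt(self.spec_ci[0])} to {fmt(self.spec_ci[1])})",
        }


def diagnostic_metrics(
    tp: int, fp: int, fn: int, tn: int, alpha: float = 0.05
) -> DiagnosticResult:
    """Sensitivity/specificity/PPV/NPV/accuracy with Clopper–Pearson intervals."""
    if tp + fn < 1 or tn + fp < 1:
        raise ValueError("need at least one positive and one negative reference case")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    ppv = tp / (tp + fp) if tp + fp else np.nan
    npv = tn / (tn + fn) if tn + fn else np.nan
    acc = (tp + tn) / (tp + fp + fn + tn)
    sens_ci = proportion_confint(tp, tp + fn, alpha=alpha, method="beta")
    spec_ci = proportion_confint(tn, tn + fp, alpha=alpha, method="beta")
    return DiagnosticResult(
        tp=tp, fp=fp, fn=fn, tn=tn,
        sensitivity=sens, specificity=spec, ppv=ppv, npv=npv, accuracy=acc,
        sens_ci=(float(sens_ci[0]), float(sens_ci[1])),
        spec_ci=(float(spec_ci[0]), float(spec_ci[1])),
    )


# ---------------------------------------------------------------------- #
# exhaustive panel search
# ---------------------------------------------------------------------- #
def enumerate_panels(sizes=(2, 3)) -> list[tuple[str, ...]]:
    """All marker subsets of the requested sizes (36 pairs + 84 triples)."""
    panels: list[tuple[str, ...]] = []
    for s in sorted(sizes):
        panels.extend(combinations(MARKERS, s))
    return panels


def exhaustive_panel_search(
    data,
    sizes=(2, 3),
    n_boot: int = 2000,
    seed: int | None = None,
    endpoint: str = "HGD_EC",
    fixed_resample: np.ndarray | None = None,
) -> pd.DataFrame:
    """Rank every candidate panel by mean best-cut-off accuracy over
    patient-level bootstrap resamples.

    ``data`` is an :class:`~afipanel.imputation.ImputedEnsemble` (the search
    runs on its original database), a :class:`CohortTable`, or a
    pre-aggregated patient table from :func:`aggregate_cohort`.  Each panel
    is evaluated complete-case on its own members.  ``fixed_resample`` (for
    consistency checks) bypasses resampling with given patient indices.
    """
    from .imputation import ImputedEnsemble  # local import to avoid cycle

    if isinstance(data, ImputedEnsemble):
        table = aggregate_cohort(data.original, endpoint=endpoint)
    elif isinstance(data, CohortTable):
        table = aggregate_cohort(data, endpoint=endpoint)
    else:
        table = data
    labels_all = table["label"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    rows = []
    for members in enumerate_panels(sizes):
        sub = table[list(members)].to_numpy(dtype=float)
        complete = ~np.isnan(sub).any(axis=1)
        s = np.nansum(sub[complete], axis=1)
        y = labels_all[complete].astype(bool)
        n = len(s)
        if n == 0 or y.all() or not y.any():
            rows.append(
                {"panel": "+".join(members), "size": len(members), "n_patients": n,
                 "best_cutoff": np.nan, "mean_accuracy": np.nan, "sd_accuracy": np.nan}
            )
            continue
        size = len(members)
        if fixed_resample is not None:
            idx = np.asarray(fixed_resample).reshape(1, -1)
        else:
            idx = rng.integers(0, n, size=(max(n_boot, 1), n))
        S, Y = s[idx], y[idx]
        accs = np.empty((len(idx), size))
        for ci, c in enumerate(range(1, size + 1)):
            accs[:, ci] = ((S >= c) == Y).mean(axis=1)
        best_per_boot = accs.max(axis=1)
        # best cutoff on the full (un-resampled) data, ties toward higher cutoff
        full_accs = [((s >= c) == y).mean() for c in range(1, size + 1)]
        best_cut = int(max(range(1, size + 1), key=lambda c: (full_accs[c - 1], c)))
        rows.append(
            {
                "panel": "+".join(members),
                "size": size,
                "n_patients": n,
                "best_cutoff": best_cut,
                "mean_accuracy": float(best_per_boot.mean()),
                "sd_accuracy": float(best_per_boot.std(ddof=1)) if len(idx) > 1 else 0.0,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values("mean_accuracy", ascending=False, kind="mergesort").reset_index(drop=True)
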