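"""Diagnostic accuracy of the panel on AFI+ versus AFI− areas.

AFI positivity is hypothesised to flag a field of molecular abnormality, so
the same biomarker panel read from a patient's AFI+ areas should out-perform
the panel read from the AFI− control area.  The comparison is restricted to
patients carrying both kinds of area, and uses a *paired* patient-level
bootstrap: within each database of the ensemble, both arms are evaluated on
the same resampled patients, the AUC (count score vs overall HGD/EC) is
computed per arm, and the two-sided p value comes from the bootstrap
distribution of the paired AUC differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

from .association import CrossTab, ZeroMarginError, chi_square
from .classify import _auc, aggregate_cohort, panel_scores
from .cohort import CohortTable, MARKERS, PanelDefinition, endpoint_labels
from .imputation import ImputedEnsemble

logger = logging.getLogger(__name__)

__all__ = ["PairedAUCComparison", "compare_afi_auc", "afi_marker_association", "box_summary"]


def box_summary(values: np.ndarray) -> dict[str, float]:
    """Median, quartiles and 1.5-IQR whisker ends of a bootstrap distribution."""
    v = np.asarray(values, dtype=float)
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    in_lo = v[v >= q1 - 1.5 * iqr]
    in_hi = v[v <= q3 + 1.5 * iqr]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(in_lo.min()),
        "whisker_high": float(in_hi.max()),
    }


@dataclass
class PairedAUCComparison:
    """Bootstrap AUC vectors per database and arm, with a two-sided p value."""

    per_database: dict[str, tuple[np.ndarray, np.ndarray]]  # name -> (AFI+ AUCs, AFI− AUCs)
    p_value: float
    summary: pd.DataFrame
    n_patients: int
    n_boot: int

    def wilcoxon_p(self) -> float:
        """Sensitivity analysis: Wilcoxon signed-rank on per-database mean AUCs."""
        a = np.array([v[0].mean() for v in self.per_database.values()])
        b = np.array([v[1].mean() for v in self.per_database.values()])
        if np.allclose(a, b):
            return 1.0
        return float(wilcoxon(a, b).pvalue)


def _arm_scores(
    cohort: CohortTable, panel: PanelDefinition, arm: str, patient_ids: pd.Series
) -> np.ndarray:
    """Patient-level count scores computed from one arm's biopsies only."""
    table = aggregate_cohort(cohort, markers=panel.members, use_afi=arm, fallback=False)
    table = table.reindex(patient_ids)
    return panel_scores(table, panel, missing_policy="undetermined")


def compare_afi_auc(
    ensemble: ImputedEnsemble,
    panel: PanelDefinition,
    n_boot: int = 2000,
    seed: int | None = None,
    endpoint: str = "HGD_EC",
    max_redraws: int = 100,
) -> PairedAUCComparison:
    """Paired bootstrap comparison of panel AUC from AFI+ vs AFI− areas.

    Patients must have at least one AFI+ and one AFI− biopsy (diffusely
    AFI-positive patients and patients without AFI+ areas are excluded).
    Shared resample indices pair the two arms; the p value is twice the
    fraction of bootstrap AUC differences ≤ 0 (floored at 1/n_boot, capped
    at 1).  Deterministic given ``seed``.
    """
    base = ensemble.original
    by_patient = base.biopsies.groupby("patient_id")["afi_status"]
    has_pos = by_patient.apply(lambda s: (s == "AFI+").any())
    has_neg = by_patient.apply(lambda s: (s == "AFI-").any())
    eligible = set(has_pos[has_pos & has_neg].index)

    rng = np.random.default_rng(seed)
    per_db: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    all_diffs: list[np.ndarray] = []
    summary_rows = []
    n_eligible = None
    for name, cohort in ensemble.databases():
        pids = cohort.patients["patient_id"]
        keep = pids.isin(eligible)
        pids = pids[keep]
        labels = endpoint_labels(cohort, level="patient", endpoint=endpoint, protocol="overall")[
            keep.to_numpy()
        ].astype(bool)
        s_pos = _arm_scores(cohort, panel, "AFI+", pids)
        s_neg = _arm_scores(cohort, panel, "AFI-", pids)
        ok = ~np.isnan(s_pos) & ~np.isnan(s_neg)
        s_pos, s_neg, y = s_pos[ok], s_neg[ok], labels[ok]
        n = len(y)
        if n_eligible is None:
            n_eligible = n
        if n == 0 or y.all() or not y.any():
            raise ValueError(f"database {name}: cannot compare arms (single-class or empty)")
        auc_pos = np.empty(n_boot)
        auc_neg = np.empty(n_boot)
        for b in range(n_boot):
            for _ in range(max_redraws):
                idx = rng.integers(0, n, size=n)
                yb = y[idx]
                if 0 < yb.sum() < n:
                    break
                logger.info("single-class paired resample in %s; redrawing", name)
            else:
                raise RuntimeError(f"could not draw two-class resample from {name}")
            auc_pos[b] = _auc(s_pos[idx], yb)
            auc_neg[b] = _auc(s_neg[idx], yb)
        per_db[name] = (auc_pos, auc_neg)
        all_diffs.append(auc_pos - auc_neg)
        for arm, v in (("AFI+", auc_pos), ("AFI-", auc_neg)):
            summary_rows.append({"database": name, "arm": arm, **box_summary(v)})

    diffs = np.concatenate(all_diffs)
    frac_le0 = float((diffs <= 0).mean())
    p = min(1.0, max(2.0 * frac_le0, 1.0 / n_boot))
    return PairedAUCComparison(
        per_database=per_db,
        p_value=p,
        summary=pd.DataFrame(summary_rows),
        n_patients=int(n_eligible or 0),
        n_boot=n_boot,
    )


def afi_marker_association(
    cohort: CohortTable, exclude_dysplastic: bool = False
) -> pd.DataFrame:
    """Per-marker 2×2 association with AFI status (χ² screening).

    Optionally excludes dysplastic areas (LGD or worse) so that dysplasia
    cannot confound the marker–AFI association.  Markers whose table has a
    zero margin get a NaN p value with the error recorded in the ``note``
    column.
    """
    b = cohort.biopsies
    if exclude_dysplastic:
        b = b[~b["histology"].isin(("LGD", "HGD", "EC"))]
    afi = (b["afi_status"] == "AFI+").to_numpy()
    rows = []
    for m in MARKERS:
        states = b[m].to_numpy(dtype=float)
        obs = ~np.isnan(states)
        counts = np.zeros((2, 2), dtype=int)
        np.add.at(counts, (states[obs].astype(int), afi[obs].astype(int)), 1)
        tab = CrossTab(counts=counts, n_missing=int((~obs).sum()), marker=m, endpoint="AFI")
        row = {
            "marker": m,
            "neg_afi_neg": counts[0, 0], "neg_afi_pos": counts[0, 1],
            "pos_afi_neg": counts[1, 0], "pos_afi_pos": counts[1, 1],
        }
        try:
            stat, p, _ = chi_square(tab)
            row.update({"chi2": stat, "p": p, "note": ""})
        except ZeroMarginError as exc:
            row.update({"chi2": np.nan, "p": np.nan, "note": str(exc)})
        rows.append(row)
    return pd.DataFrame(rows).set_index("marker")
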