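"""Per-biopsy biomarker–dysplasia association screening.

Complete-case 2×2 cross-tabulations per biomarker (missing calls excluded
marker by marker, not listwise, because missingness differs across assays)
and uncorrected Pearson χ² tests.  No continuity correction is applied and p
values are reported unadjusted, mirroring the screening stage this module
reproduces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .cohort import CohortTable, MARKERS, endpoint_labels

__all__ = ["CrossTab", "crosstab", "chi_square", "association_table", "ZeroMarginError"]


class ZeroMarginError(ValueError):
    """A row or column of the 2×2 table sums to zero; the χ² test is undefined."""


@dataclass(frozen=True)
class CrossTab:
    """2×2 counts: rows marker (negative, positive), columns endpoint (no, yes)."""

    counts: np.ndarray
    n_missing: int
    marker: str = ""
    endpoint: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.shape != (2, 2) or (c < 0).any():
            raise ValueError("counts must be a non-negative 2x2 table")
        object.__setattr__(self, "counts", c)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def column_percentages(self) -> np.ndarray:
        """Percentage of negative/positive calls within each endpoint column."""
        colsum = self.counts.sum(axis=0, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * self.counts / colsum


def crosstab(cohort: CohortTable, marker: str, endpoint: str = "HGD_EC") -> CrossTab:
    """Complete-case 2×2 table of ``marker`` against the biopsy-level endpoint."""
    if marker not in MARKERS:
        raise KeyError(f"unknown marker {marker!r}")
    states = cohort.biopsies[marker].to_numpy(dtype=float)
    labels = endpoint_labels(cohort, level="biopsy", endpoint=endpoint)
    obs = ~np.isnan(states)
    s = states[obs].astype(int)
    y = labels[obs].astype(int)
    counts = np.zeros((2, 2), dtype=int)
    np.add.at(counts, (s, y), 1)
    return CrossTab(counts=counts, n_missing=int((~obs).sum()), marker=marker, endpoint=endpoint)


def chi_square(tab: CrossTab | np.ndarray) -> tuple[float, float, int]:
    """Uncorrected Pearson χ² on a 2×2 table → (statistic, p value, df=1)."""
    counts = tab.counts if isinstance(tab, CrossTab) else np.asarray(tab, dtype=float)
    if counts.sum() == 0 or (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ZeroMarginError("a margin of the 2x2 table is zero; chi-square undefined")
    stat, p, dof, _ = chi2_contingency(counts, correction=False)
    return float(stat), float(p), int(dof)


def association_table(cohort: CohortTable) -> pd.DataFrame:
    """Per-marker association report over both endpoints.

    One row per biomarker: missing fraction, the complete-case 2×2 counts and
    within-endpoint column percentages, and the uncorrected χ² p value, for
    the HGD/EC and the any-dysplasia endpoint.  Markers whose table has a
    zero margin get a NaN p value.
    """
    if cohort.n_biopsies == 0:
        return pd.DataFrame()
    rows = []
    for marker in MARKERS:
        row: dict[str, object] = {"marker": marker}
        n_total = cohort.n_biopsies
        for endpoint in ("HGD_EC", "any_dysplasia"):
            tab = crosstab(cohort, marker, endpoint)
            pct = tab.column_percentages()
            key = "hgdec" if endpoint == "HGD_EC" else "anydys"
            row[f"{key}_neg_no"] = tab.counts[0, 0]
            row[f"{key}_neg_yes"] = tab.counts[0, 1]
            row[f"{key}_pos_no"] = tab.counts[1, 0]
            row[f"{key}_pos_yes"] = tab.counts[1, 1]
            row[f"{key}_pos_pct_no"] = pct[1, 0]
            row[f"{key}_pos_pct_yes"] = pct[1, 1]
            try:
                _, p, _ = chi_square(tab)
            except ZeroMarginError:
                p = np.nan
            row[f"{key}_p"] = p
            row["missing_frac"] = tab.n_missing / n_total if n_total else np.nan
        rows.append(row)
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame(rows).set_index("marker")
    # keep missing_frac first for readability
    cols = ["missing_frac"] + [c for c in df.columns if c != "missing_frac"]
    return df[cols]
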