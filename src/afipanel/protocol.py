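"""Protocol-yield comparison: Seattle histology vs AFI histology vs panel.

Reference standard is the overall per-patient histology (maximum of the
Seattle and AFI-targeted diagnoses).  Each diagnostic route is summarised by
the HGD/EC cases it detects, its sensitivity, and its biopsy burden (total,
per patient, and per case *diagnosed by that route*).  Paired significance
tests: exact McNemar on discordant case detections, Wilcoxon signed-rank on
per-patient biopsy counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon
from statsmodels.stats.contingency_tables import mcnemar

from .classify import aggregate_cohort, panel_scores
from .cohort import CohortTable, PanelDefinition, endpoint_labels

__all__ = [
    "PROTOCOLS",
    "ProtocolYield",
    "protocol_yield",
    "protocol_table",
    "paired_case_detection",
    "compare_sensitivity",
    "biopsy_count_comparison",
]

PROTOCOLS = ("seattle_histology", "afi_histology", "afi_biomarkers")

_COUNT_COL = {
    "seattle_histology": "n_biopsies_seattle",
    "afi_histology": "n_biopsies_afi",
    "afi_biomarkers": "n_biopsies_biomarker",
}


@dataclass(frozen=True)
class ProtocolYield:
    """Detection yield and biopsy burden of one diagnostic route."""

    protocol: str
    n_patients: int
    n_cases: int
    n_detected: int
    n_missed: int
    sensitivity: float
    total_biopsies: int
    biopsies_per_patient: float | None
    biopsies_per_case: float | None
    #: per-patient detection indicator over HGD/EC reference cases, in patient order
    case_detection: tuple[bool, ...] = ()

    def display(self) -> dict[str, object]:
        rnd = lambda x: None if x is None else round(x, 1)
        return {
            "protocol": self.protocol,
            "n_missed": self.n_missed,
            "sensitivity_pct": round(100.0 * self.sensitivity, 1),
            "total_biopsies": self.total_biopsies,
            "biopsies_per_patient": rnd(self.biopsies_per_patient),
            "biopsies_per_case": rnd(self.biopsies_per_case),
        }


def _panel_detection(
    cohort: CohortTable, panel: PanelDefinition, endpoint: str
) -> np.ndarray:
    """High-risk panel call per patient (NaN where undetermined)."""
    table = aggregate_cohort(cohort, markers=panel.members, endpoint=endpoint)
    scores = panel_scores(table, panel, missing_policy="undetermined")
    return np.where(np.isnan(scores), np.nan, (scores >= panel.cutoff).astype(float))


def protocol_yield(
    cohort: CohortTable,
    protocol: str,
    panel: PanelDefinition | None = None,
    endpoint: str = "HGD_EC",
) -> ProtocolYield:
    """Yield of one diagnostic route against the overall-histology reference.

    ``panel`` is required (and only used) for the ``afi_biomarkers`` route.
    Patients whose panel call is undetermined are excluded from that route's
    sensitivity but keep contributing biopsy counts.  Ratios are computed as
    exact rationals and exposed unrounded; ``display()`` rounds to 1 dp.
    With zero detected cases the per-case ratio is None (absent).
    """
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}; expected one of {PROTOCOLS}")
    if (protocol == "afi_biomarkers") != (panel is not None):
        raise ValueError("panel is required iff protocol == 'afi_biomarkers'")

    ref = endpoint_labels(cohort, level="patient", endpoint=endpoint, protocol="overall")
    if protocol == "seattle_histology":
        det = endpoint_labels(cohort, level="patient", endpoint=endpoint, protocol="seattle").astype(float)
    elif protocol == "afi_histology":
        det = endpoint_labels(cohort, level="patient", endpoint=endpoint, protocol="afi").astype(float)
    else:
        det = _panel_detection(cohort, panel, endpoint)

    evaluable = ~np.isnan(det)
    cases = ref & evaluable
    n_cases = int(cases.sum())
    detected = det[cases].astype(bool)
    n_detected = int(detected.sum())
    sens = n_detected / n_cases if n_cases else np.nan

    total = int(cohort.patients[_COUNT_COL[protocol]].sum())
    n_pat = cohort.n_patients
    per_patient = float(Fraction(total, n_pat)) if n_pat else None
    per_case = float(Fraction(total, n_detected)) if n_detected else None
    return ProtocolYield(
        protocol=protocol,
        n_patients=n_pat,
        n_cases=n_cases,
        n_detected=n_detected,
        n_missed=n_cases - n_detected,
        sensitivity=sens,
        total_biopsies=total,
        biopsies_per_patient=per_patient,
        biopsies_per_case=per_case,
        case_detection=tuple(bool(v) for v in detected),
    )


def protocol_table(
    cohort: CohortTable, panel: PanelDefinition, endpoint: str = "HGD_EC"
) -> pd.DataFrame:
    """Three-route comparison table (one row per protocol, display-rounded)."""
    rows = []
    for proto in PROTOCOLS:
        y = protocol_yield(
            cohort, proto, panel=panel if proto == "afi_biomarkers" else None, endpoint=endpoint
        )
        rows.append(y.display())
    return pd.DataFrame(rows).set_index("protocol")


def paired_case_detection(
    cohort: CohortTable,
    protocol_a: str,
    protocol_b: str,
    panel: PanelDefinition | None = None,
    endpoint: str = "HGD_EC",
) -> tuple[np.ndarray, np.ndarray]:
    """Aligned detection vectors over reference cases evaluable in both routes."""

    def detection(protocol: str) -> np.ndarray:
        if protocol == "seattle_histology":
            return endpoint_labels(cohort, "patient", endpoint, "seattle").astype(float)
        if protocol == "afi_histology":
            return endpoint_labels(cohort, "patient", endpoint, "afi").astype(float)
        if protocol == "afi_biomarkers":
            if panel is None:
                raise ValueError("panel required for afi_biomarkers")
            return _panel_detection(cohort, panel, endpoint)
        raise ValueError(f"unknown protocol {protocol!r}")

    ref = endpoint_labels(cohort, level="patient", endpoint=endpoint, protocol="overall")
    da, db = detection(protocol_a), detection(protocol_b)
    keep = ref & ~np.isnan(da) & ~np.isnan(db)
    return da[keep].astype(bool), db[keep].astype(bool)


def compare_sensitivity(det_a, det_b) -> float:
    """Exact McNemar p value for two paired case-detection vectors.

    Both vectors index the same reference-positive patients.  With no
    discordant pairs the test degenerates to p = 1.
    """
    a = np.asarray(det_a).astype(bool)
    b = np.asarray(det_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("detection vectors must have equal length")
    table = np.array(
        [
            [int((a & b).sum()), int((a & ~b).sum())],
            [int((~a & b).sum()), int((~a & ~b).sum())],
        ]
    )
    if table[0, 1] + table[1, 0] == 0:
        return 1.0
    return float(mcnemar(table, exact=True).pvalue)


def biopsy_count_comparison(
    cohort: CohortTable, protocol_a: str, protocol_b: str
) -> float:
    """Paired Wilcoxon signed-rank p value on per-patient biopsy counts."""
    for p in (protocol_a, protocol_b):
        if p not in PROTOCOLS:
            raise ValueError(f"unknown protocol {p!r}")
    x = cohort.patients[_COUNT_COL[protocol_a]].to_numpy(dtype=float)
    y = cohort.patients[_COUNT_COL[protocol_b]].to_numpy(dtype=float)
    if np.all(x == y):
        return 1.0
    return float(wilcoxon(x, y).pvalue)
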