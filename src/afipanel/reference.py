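"""Published summary counts of the original multicentre study, as fixed inputs.

The original cross-sectional study (157 training patients, 373 AFI-targeted
biopsies; 46 validation patients) deposited no per-patient data, but its
printed summary tables are complete enough to recompute several of its
statistics exactly: the per-biopsy 2×2 association tables, the per-patient
confusion counts of the three-biomarker panel, and the protocol biopsy-burden
arithmetic.  This module records those counts verbatim and provides
deterministic fixture cohorts that reproduce them, so the analysis code can
be exercised against the published numbers without access to raw data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import CohortTable, MARKERS

__all__ = [
    "TRAINING_ASSOCIATION",
    "TRAINING_MISSING_PCT",
    "TRAINING_PANEL_CONFUSION",
    "TRAINING_ANYDYS_CONFUSION",
    "VALIDATION_PANEL_DETECTION",
    "PROTOCOL_SUMMARY",
    "association_crosstab",
    "association_cohort",
    "protocol_cohort",
]

# Per-biopsy complete-case 2x2 counts per biomarker, training cohort.
# Layout: rows = marker (negative, positive), columns = endpoint (no, yes).
TRAINING_ASSOCIATION: dict[str, dict[str, list[list[int]]]] = {
    "HPP1_meth":   {"HGD_EC": [[59, 3], [199, 39]],   "any_dysplasia": [[56, 6], [177, 61]]},
    "RUNX3_meth":  {"HGD_EC": [[102, 6], [156, 36]],  "any_dysplasia": [[97, 11], [136, 56]]},
    "p16_meth":    {"HGD_EC": [[143, 12], [115, 30]], "any_dysplasia": [[132, 23], [101, 44]]},
    "p53_IHC":     {"HGD_EC": [[196, 3], [82, 41]],   "any_dysplasia": [[189, 10], [57, 66]]},
    "cyclinA_IHC": {"HGD_EC": [[238, 8], [42, 31]],   "any_dysplasia": [[223, 23], [28, 45]]},
    "tetraploidy": {"HGD_EC": [[182, 20], [81, 15]],  "any_dysplasia": [[171, 31], [66, 30]]},
    "aneuploidy":  {"HGD_EC": [[232, 10], [31, 25]],  "any_dysplasia": [[216, 26], [21, 35]]},
    "LOH17p":      {"HGD_EC": [[112, 7], [115, 35]],  "any_dysplasia": [[107, 12], [99, 51]]},
    "LOH9p":       {"HGD_EC": [[43, 5], [181, 36]],   "any_dysplasia": [[40, 8], [165, 52]]},
}

#: Published per-biomarker missing-value percentages (training cohort).
TRAINING_MISSING_PCT: dict[str, float] = {
    "HPP1_meth": 19.1,
    "RUNX3_meth": 19.1,
    "p16_meth": 19.1,
    "p53_IHC": 13.2,
    "cyclinA_IHC": 14.0,
    "tetraploidy": 19.7,
    "aneuploidy": 19.7,
    "LOH17p": 27.4,
    "LOH9p": 28.5,
}

#: Per-patient confusion counts of the three-biomarker panel (cut-off 2) for
#: HGD/EC in the 112 training patients with the full three-marker data set.
TRAINING_PANEL_CONFUSION = {"tp": 23, "fn": 1, "fp": 10, "tn": 78}

#: Same patients, any-grade-dysplasia endpoint.
TRAINING_ANYDYS_CONFUSION = {"tp": 29, "fn": 10, "fp": 4, "tn": 69}

#: External validation cohort: HGD/EC cases detected by the panel / total.
VALIDATION_PANEL_DETECTION = {"detected": 9, "cases": 9}

#: Protocol-yield summary of the per-patient analysis (n=112, 24 HGD/EC cases):
#: cases detected and total biopsies for each diagnostic route.
PROTOCOL_SUMMARY = {
    "n_patients": 112,
    "n_cases": 24,
    "detected": {"seattle_histology": 23, "afi_histology": 22, "afi_biomarkers": 23},
    "total_biopsies": {"seattle_histology": 1385, "afi_histology": 169, "afi_biomarkers": 310},
}


def association_crosstab(marker: str, endpoint: str = "HGD_EC") -> np.ndarray:
    """Published complete-case 2×2 table (marker neg/pos × endpoint no/yes)."""
    return np.asarray(TRAINING_ASSOCIATION[marker][endpoint], dtype=int)


def association_cohort(marker: str, endpoint: str = "HGD_EC") -> CohortTable:
    """Deterministic single-marker cohort whose cross-tabulation reproduces
    the published 2×2 counts for ``marker`` × ``endpoint``.

    All other markers are left missing; grades encode the endpoint (HGD for a
    positive endpoint row, LGD for any-dysplasia-negative splits collapse to
    NDBO).  Intended for exercising the association stage against published
    counts, not as a realistic cohort.
    """
    tab = association_crosstab(marker, endpoint)
    pos_grade = "HGD"
    rows = []
    k = 0
    for marker_state in (0, 1):
        for ep in (0, 1):
            for _ in range(tab[marker_state, ep]):
                row = {
                    "patient_id": f"P{k:04d}",
                    "area_id": "a1",
                    "afi_status": "AFI+",
                    "histology": pos_grade if ep else "NDBO",
                }
                for m in MARKERS:
                    row[m] = float(marker_state) if m == marker else np.nan
                rows.append(row)
                k += 1
    bdf = pd.DataFrame(rows)
    return CohortTable.from_biopsies(bdf)


def protocol_cohort() -> CohortTable:
    """Deterministic 112-patient cohort reproducing the protocol-yield table.

    24 HGD/EC cases; the Seattle arm misses one (detected on AFI histology),
    AFI histology misses two (detected on Seattle), and the three-biomarker
    panel (p53 IHC + cyclin A IHC + aneuploidy, cut-off 2) misses one and
    falsely flags ten controls.  Biopsy-burden counts sum to the published
    totals 1385 (Seattle), 169 (AFI histology) and 310 (panel biopsies).
    """
    panel = ("p53_IHC", "cyclinA_IHC", "aneuploidy")
    n_patients = PROTOCOL_SUMMARY["n_patients"]
    n_cases = PROTOCOL_SUMMARY["n_cases"]

    patients = []
    biopsy_rows = []

    def add_biopsy(pid: str, area: str, afi: str, grade: str, n_pos_markers: int) -> None:
        row = {
            "patient_id": pid,
            "area_id": area,
            "afi_status": afi,
            "histology": grade,
        }
        for m in MARKERS:
            row[m] = np.nan
        for m in panel[:n_pos_markers]:
            row[m] = 1.0
        for m in panel[n_pos_markers:]:
            row[m] = 0.0
        biopsy_rows.append(row)

    for i in range(n_patients):
        pid = f"P{i:03d}"
        is_case = i < n_cases
        # case 0: missed by Seattle; cases 1,2: missed by AFI histology;
        # case 3: missed by the biomarker panel.
        seattle_grade = "HGD" if (is_case and i != 0) else "NDBO"
        afi_grade = "HGD" if (is_case and i not in (1, 2)) else "NDBO"
        # panel call: cases positive except case 3; controls 24..33 false positive
        if is_case:
            n_pos = 1 if i == 3 else 2
        else:
            n_pos = 2 if i < n_cases + 10 else 0
        add_biopsy(pid, "a1", "AFI+", afi_grade, n_pos)
        patients.append(
            {
                "patient_id": pid,
                "histology_seattle": seattle_grade,
                "histology_afi": afi_grade,
                "histology_overall": "HGD" if is_case else "NDBO",
                # distribute counts so that totals match the published sums
                "n_biopsies_seattle": 13 if i < 41 else 12,  # 41*13 + 71*12 = 1385
                "n_biopsies_afi": 2 if i < 57 else 1,  # 57*2 + 55*1 = 169
                "n_biopsies_biomarker": 3 if i < 86 else 2,  # 86*3 + 26*2 = 310
            }
        )
    bdf = pd.DataFrame(biopsy_rows)
    pdf = pd.DataFrame(patients)
    return CohortTable(bdf, pdf)
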