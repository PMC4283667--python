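"""Domain types and delimited-text I/O for AFI-targeted biopsy cohorts.

A cohort couples two tables:

* a **biopsy table** — one row per AFI-targeted area (AFI+ or the single AFI−
  control area) with the consensus histology grade of that area and the
  ternary (positive / negative / missing) outcome of nine molecular
  biomarkers;
* a **patient table** — one row per patient with the per-protocol overall
  histology (Seattle-protocol biopsies, AFI-targeted biopsies, and their
  maximum) and biopsy-burden counts.

Histology grades follow the Vienna-style ordering
``NDBO < ID < LGD < HGD < EC``.  "Indefinite for dysplasia" (ID) is kept as a
raw grade at ingest and collapsed to non-dysplastic only when binary endpoint
labels are derived, so consensus-review grades survive a read/write
round-trip unchanged.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GRADES",
    "MARKERS",
    "HistologyGrade",
    "BiopsyRecord",
    "PatientRecord",
    "PanelDefinition",
    "CohortTable",
    "SchemaError",
    "CohortValidationError",
    "grade_rank",
    "grade_max",
    "endpoint_labels",
    "read_cohort",
    "write_cohort",
]

#: Ordered histology grades: non-dysplastic Barrett's, indefinite for
#: dysplasia, low-grade dysplasia, high-grade dysplasia, early cancer.
GRADES: tuple[str, ...] = ("NDBO", "ID", "LGD", "HGD", "EC")

#: The nine candidate biomarkers, in canonical column order.
MARKERS: tuple[str, ...] = (
    "HPP1_meth",
    "RUNX3_meth",
    "p16_meth",
    "p53_IHC",
    "cyclinA_IHC",
    "tetraploidy",
    "aneuploidy",
    "LOH17p",
    "LOH9p",
)

_GRADE_RANK: dict[str, int] = {g: i for i, g in enumerate(GRADES)}
_DYSPLASTIC = frozenset({"LGD", "HGD", "EC"})
_HGDEC = frozenset({"HGD", "EC"})

_AFI_POS = "AFI+"
_AFI_NEG = "AFI-"

_BIOPSY_META_COLS = ("patient_id", "area_id", "afi_status", "histology")
_PATIENT_COLS = (
    "patient_id",
    "histology_seattle",
    "histology_afi",
    "histology_overall",
    "n_biopsies_seattle",
    "n_biopsies_afi",
    "n_biopsies_biomarker",
)

_POS_TOKENS = {"1", "positive", "pos", "+"}
_NEG_TOKENS = {"0", "negative", "neg", "-"}


class SchemaError(ValueError):
    """A cohort file's column layout does not match the expected schema."""


class CohortValidationError(ValueError):
    """Cohort content violates a structural invariant."""


HistologyGrade = str  # one of GRADES; kept as plain strings for pandas friendliness


def grade_rank(grade: str) -> int:
    """Position of ``grade`` in the total order NDBO < ID < LGD < HGD < EC."""
    try:
        return _GRADE_RANK[grade]
    except KeyError:
        raise CohortValidationError(f"unknown histology grade {grade!r}") from None


def grade_max(*grades: str) -> str:
    """Highest of the given grades under the dysplasia ordering."""
    return max(grades, key=grade_rank)


def _is_dysplastic(grades: pd.Series) -> np.ndarray:
    return grades.isin(_DYSPLASTIC).to_numpy()


def _is_hgdec(grades: pd.Series) -> np.ndarray:
    return grades.isin(_HGDEC).to_numpy()


@dataclass(frozen=True)
class BiopsyRecord:
    """A single AFI-targeted area with ternary biomarker calls."""

    patient_id: str
    area_id: str
    afi_status: str  # "AFI+" or "AFI-"
    histology: str
    markers: Mapping[str, str]  # marker -> {"positive","negative","missing"}

    def __post_init__(self) -> None:
        if self.afi_status not in (_AFI_POS, _AFI_NEG):
            raise CohortValidationError(
                f"afi_status must be {_AFI_POS!r} or {_AFI_NEG!r}, got {self.afi_status!r}"
            )
        grade_rank(self.histology)
        if set(self.markers) != set(MARKERS):
            missing = set(MARKERS) - set(self.markers)
            extra = set(self.markers) - set(MARKERS)
            raise CohortValidationError(
                f"marker keys must be exactly the nine biomarkers "
                f"(missing={sorted(missing)}, unexpected={sorted(extra)})"
            )
        bad = {k: v for k, v in self.markers.items() if v not in ("positive", "negative", "missing")}
        if bad:
            raise CohortValidationError(f"invalid marker states: {bad}")


@dataclass(frozen=True)
class PatientRecord:
    """Per-patient protocol-level histology outcomes and biopsy counts."""

    patient_id: str
    histology_seattle: str
    histology_afi: str
    n_biopsies_seattle: int = 0
    n_biopsies_afi: int = 0
    n_biopsies_biomarker: int = 0

    @property
    def histology_overall(self) -> str:
        return grade_max(self.histology_seattle, self.histology_afi)

    def __post_init__(self) -> None:
        grade_rank(self.histology_seattle)
        grade_rank(self.histology_afi)
        for name in ("n_biopsies_seattle", "n_biopsies_afi", "n_biopsies_biomarker"):
            if getattr(self, name) < 0:
                raise CohortValidationError(f"{name} must be >= 0")


@dataclass(frozen=True)
class PanelDefinition:
    """A biomarker subset plus the count-of-positives cut-off for a high-risk call."""

    members: tuple[str, ...]
    cutoff: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))
        unknown = [m for m in self.members if m not in MARKERS]
        if unknown:
            raise CohortValidationError(f"unknown panel members: {unknown}")
        if len(set(self.members)) != len(self.members):
            raise CohortValidationError("panel members must be distinct")
        if len(self.members) < 1:
            raise CohortValidationError("panel needs at least one member")
        if not 1 <= self.cutoff <= len(self.members):
            raise CohortValidationError(
                f"cutoff must lie in [1, {len(self.members)}], got {self.cutoff}"
            )

    @property
    def size(self) -> int:
        return len(self.members)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return "+".join(self.members) + f" (cutoff {self.cutoff})"


class CohortTable:
    """Validated container for the biopsy and patient tables.

    Internally both tables are pandas DataFrames.  Marker columns are floats
    with 1.0 = positive, 0.0 = negative and NaN = missing; NaN is an explicit
    ternary state, not an absent key.
    """

    def __init__(self, biopsies: pd.DataFrame, patients: pd.DataFrame, *, validate: bool = True):
        self.biopsies = biopsies.reset_index(drop=True)
        self.patients = patients.reset_index(drop=True)
        if validate:
            self.validate()

    # ------------------------------------------------------------------ #
    # construction helpers
    # ------------------------------------------------------------------ #
    @classmethod
    def from_records(
        cls,
        biopsies: Iterable[BiopsyRecord],
        patients: Iterable[PatientRecord] | None = None,
    ) -> "CohortTable":
        """Build a cohort from record dataclasses.

        When ``patients`` is omitted a minimal patient table is derived: the
        AFI histology is the highest grade over each patient's biopsies and
        the Seattle histology defaults to NDBO.
        """
        rows = []
        for rec in biopsies:
            row: dict[str, object] = {
                "patient_id": rec.patient_id,
                "area_id": rec.area_id,
                "afi_status": rec.afi_status,
                "histology": rec.histology,
            }
            for m in MARKERS:
                state = rec.markers[m]
                row[m] = np.nan if state == "missing" else float(state == "positive")
            rows.append(row)
        bdf = pd.DataFrame(rows, columns=list(_BIOPSY_META_COLS) + list(MARKERS))
        if patients is None:
            pdf = cls._derive_patients(bdf)
        else:
            pdf = pd.DataFrame(
                [
                    {
                        "patient_id": p.patient_id,
                        "histology_seattle": p.histology_seattle,
                        "histology_afi": p.histology_afi,
                        "histology_overall": p.histology_overall,
                        "n_biopsies_seattle": p.n_biopsies_seattle,
                        "n_biopsies_afi": p.n_biopsies_afi,
                        "n_biopsies_biomarker": p.n_biopsies_biomarker,
                    }
                    for p in patients
                ],
                columns=list(_PATIENT_COLS),
            )
        return cls(bdf, pdf)

    @classmethod
    def from_biopsies(cls, biopsies: pd.DataFrame) -> "CohortTable":
        """Build a cohort from a biopsy table alone, deriving the patient table."""
        return cls(biopsies, cls._derive_patients(biopsies))

    @staticmethod
    def _derive_patients(biopsies: pd.DataFrame) -> pd.DataFrame:
        if len(biopsies) == 0:
            return pd.DataFrame(columns=list(_PATIENT_COLS))
        bad = ~biopsies["histology"].isin(GRADES)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortValidationError(
                f"unparseable histology grade {biopsies['histology'].iloc[row]!r} "
                f"in biopsy row {row}"
            )
        grp = biopsies.groupby("patient_id", sort=True)
        recs = []
        for pid, sub in grp:
            afi_grade = max(sub["histology"], key=grade_rank)
            recs.append(
                {
                    "patient_id": pid,
                    "histology_seattle": "NDBO",
                    "histology_afi": afi_grade,
                    "histology_overall": afi_grade,
                    "n_biopsies_seattle": 0,
                    "n_biopsies_afi": int((sub["afi_status"] == _AFI_POS).sum()),
                    "n_biopsies_biomarker": int(len(sub)),
                }
            )
        return pd.DataFrame(recs, columns=list(_PATIENT_COLS))

    # ------------------------------------------------------------------ #
    # validation
    # ------------------------------------------------------------------ #
    def validate(self) -> "CohortTable":
        b, p = self.biopsies, self.patients
        missing_cols = [c for c in _BIOPSY_META_COLS + MARKERS if c not in b.columns]
        if missing_cols:
            raise SchemaError(f"biopsy table lacks columns: {missing_cols}")
        extra = [c for c in b.columns if c not in _BIOPSY_META_COLS + MARKERS]
        if extra:
            raise SchemaError(f"unexpected biopsy columns: {extra}")
        missing_pcols = [c for c in _PATIENT_COLS if c not in p.columns]
        if missing_pcols:
            raise SchemaError(f"patient table lacks columns: {missing_pcols}")

        bad_grade = ~b["histology"].isin(GRADES)
        if bad_grade.any():
            row = int(np.flatnonzero(bad_grade.to_numpy())[0])
            raise CohortValidationError(
                f"unparseable histology grade {b['histology'].iloc[row]!r} in biopsy row {row}"
            )
        bad_afi = ~b["afi_status"].isin((_AFI_POS, _AFI_NEG))
        if bad_afi.any():
            row = int(np.flatnonzero(bad_afi.to_numpy())[0])
            raise CohortValidationError(
                f"invalid afi_status {b['afi_status'].iloc[row]!r} in biopsy row {row}"
            )
        dup = b.duplicated(subset=["patient_id", "area_id"])
        if dup.any():
            pair = b.loc[dup, ["patient_id", "area_id"]].iloc[0]
            raise CohortValidationError(
                f"duplicate (patient_id, area_id) = ({pair['patient_id']!r}, {pair['area_id']!r})"
            )
        for m in MARKERS:
            vals = b[m].dropna().unique()
            if not np.isin(vals, (0.0, 1.0)).all():
                raise CohortValidationError(f"marker column {m} contains values outside {{0,1,NA}}")

        for col in ("histology_seattle", "histology_afi", "histology_overall"):
            bad = ~p[col].isin(GRADES)
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise CohortValidationError(
                    f"unparseable grade {p[col].iloc[row]!r} in patient row {row} ({col})"
                )
        if p["patient_id"].duplicated().any():
            raise CohortValidationError("duplicate patient_id in patient table")
        expect = [
            grade_max(s, a) for s, a in zip(p["histology_seattle"], p["histology_afi"])
        ]
        if list(p["histology_overall"]) != expect:
            raise CohortValidationError(
                "histology_overall must equal max(histology_seattle, histology_afi)"
            )
        for col in ("n_biopsies_seattle", "n_biopsies_afi", "n_biopsies_biomarker"):
            if (p[col].to_numpy() < 0).any():
                raise CohortValidationError(f"{col} must be >= 0")
        known = set(p["patient_id"])
        orphans = set(b["patient_id"]) - known
        if orphans:
            raise CohortValidationError(f"biopsy rows reference unknown patients: {sorted(orphans)[:5]}")
        return self

    # ------------------------------------------------------------------ #
    # accessors
    # ------------------------------------------------------------------ #
    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_biopsies(self) -> int:
        return len(self.biopsies)

    def afi_split(self) -> tuple[int, int]:
        """(number of AFI+ rows, number of AFI− rows)."""
        pos = int((self.biopsies["afi_status"] == _AFI_POS).sum())
        return pos, len(self.biopsies) - pos

    def marker_matrix(self) -> pd.DataFrame:
        """Biopsy × marker matrix (floats; NaN = missing)."""
        return self.biopsies[list(MARKERS)]

    def records(self) -> Iterator[BiopsyRecord]:
        for _, row in self.biopsies.iterrows():
            markers = {}
            for m in MARKERS:
                v = row[m]
                markers[m] = "missing" if pd.isna(v) else ("positive" if v == 1.0 else "negative")
            yield BiopsyRecord(
                patient_id=str(row["patient_id"]),
                area_id=str(row["area_id"]),
                afi_status=str(row["afi_status"]),
                histology=str(row["histology"]),
                markers=markers,
            )

    def copy(self) -> "CohortTable":
        return CohortTable(self.biopsies.copy(), self.patients.copy(), validate=False)

    def equals(self, other: "CohortTable") -> bool:
        return self.biopsies.equals(other.biopsies) and self.patients.equals(other.patients)


def endpoint_labels(
    cohort: CohortTable,
    level: str = "biopsy",
    endpoint: str = "HGD_EC",
    protocol: str | None = None,
) -> np.ndarray:
    """Binary endpoint labels per biopsy or per patient.

    ``endpoint`` is ``"HGD_EC"`` (high-grade dysplasia or early cancer) or
    ``"any_dysplasia"`` (LGD or worse).  ID counts as non-dysplastic either
    way.  At patient level, ``protocol`` chooses which histology column
    defines the outcome (``seattle``, ``afi`` or ``overall``); at biopsy
    level ``protocol`` is ignored.
    """
    if endpoint not in ("HGD_EC", "any_dysplasia"):
        raise ValueError(f"unknown endpoint {endpoint!r}")
    pred = _is_hgdec if endpoint == "HGD_EC" else _is_dysplastic
    if level == "biopsy":
        return pred(cohort.biopsies["histology"])
    if level == "patient":
        if protocol not in ("seattle", "afi", "overall"):
            raise ValueError("patient-level labels require protocol in {'seattle','afi','overall'}")
        return pred(cohort.patients[f"histology_{protocol}"])
    raise ValueError(f"unknown level {level!r}")


# ---------------------------------------------------------------------- #
# delimited-text I/O
# ---------------------------------------------------------------------- #
def _parse_marker_cell(value: object, missing_token: str, row: int, col: str) -> float:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    s = str(value).strip()
    if s == "" or s == missing_token:
        return np.nan
    low = s.lower()
    if low in _POS_TOKENS:
        return 1.0
    if low in _NEG_TOKENS:
        return 0.0
    raise CohortValidationError(f"unparseable marker value {s!r} in row {row}, column {col}")


def read_cohort(
    biopsies_path,
    patients_path=None,
    *,
    sep: str = ",",
    missing_token: str = "NA",
) -> CohortTable:
    """Read a cohort from delimited-text biopsy (and optionally patient) tables.

    The biopsy header must name the nine biomarkers exactly.  Missing marker
    cells (``missing_token``, default ``"NA"``) map to the explicit missing
    state.  When ``patients_path`` is omitted the patient table is derived
    from the biopsies (AFI histology = highest biopsy grade).
    """
    bdf = pd.read_csv(biopsies_path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in _BIOPSY_META_COLS + MARKERS if c not in bdf.columns]
    if missing:
        raise SchemaError(f"biopsy file lacks columns: {missing}")
    extra = [c for c in bdf.columns if c not in _BIOPSY_META_COLS + MARKERS]
    if extra:
        raise SchemaError(f"unknown biomarker/metadata columns in biopsy file: {extra}")
    bdf = bdf[list(_BIOPSY_META_COLS) + list(MARKERS)]
    # normalise unicode minus in AFI status
    bdf["afi_status"] = bdf["afi_status"].str.replace("−", "-", regex=False)
    for m in MARKERS:
        bdf[m] = [
            _parse_marker_cell(v, missing_token, i, m) for i, v in enumerate(bdf[m])
        ]
        bdf[m] = bdf[m].astype(float)

    if patients_path is not None:
        pdf = pd.read_csv(patients_path, sep=sep, dtype=str, keep_default_na=False)
        lack = [c for c in _PATIENT_COLS if c not in pdf.columns]
        if lack:
            raise SchemaError(f"patient file lacks columns: {lack}")
        pdf = pdf[list(_PATIENT_COLS)]
        for col in ("n_biopsies_seattle", "n_biopsies_afi", "n_biopsies_biomarker"):
            try:
                pdf[col] = pdf[col].astype(int)
            except ValueError as exc:
                raise CohortValidationError(f"non-integer biopsy count in {col}") from exc
        return CohortTable(bdf, pdf)
    return CohortTable.from_biopsies(bdf)


def write_cohort(
    cohort: CohortTable,
    biopsies_path,
    patients_path=None,
    *,
    sep: str = ",",
    missing_token: str = "NA",
) -> None:
    """Write a cohort as delimited text with a fixed column order.

    Marker states serialise as ``1`` / ``0`` / ``missing_token``.
    """
    out = cohort.biopsies.copy()
    for m in MARKERS:
        col = out[m]
        out[m] = np.where(col.isna(), missing_token, col.fillna(0).astype(int).astype(str))
    out = out[list(_BIOPSY_META_COLS) + list(MARKERS)]
    out.to_csv(biopsies_path, sep=sep, index=False)
    if patients_path is not None:
        cohort.patients[list(_PATIENT_COLS)].to_csv(patients_path, sep=sep, index=False)
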