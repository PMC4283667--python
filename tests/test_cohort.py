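"""Data model: validation, endpoint labels, delimited-text round trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from afipanel import (
    CohortTable,
    GRADES,
    MARKERS,
    PanelDefinition,
    endpoint_labels,
    read_cohort,
    write_cohort,
)
from afipanel.cohort import (
    BiopsyRecord,
    CohortValidationError,
    PatientRecord,
    SchemaError,
    grade_max,
)

from conftest import make_biopsy_row


class TestValidation:
    def test_grade_ordering_is_total(self):
        assert grade_max(*GRADES) == "EC"
        assert grade_max("NDBO", "ID") == "ID"
        assert grade_max("LGD", "HGD") == "HGD"

    def test_all_marker_keys_required(self):
        markers = {m: "negative" for m in MARKERS}
        del markers["LOH9p"]
        with pytest.raises(CohortValidationError, match="LOH9p"):
            BiopsyRecord("p1", "a1", "AFI+", "NDBO", markers)

    def test_duplicate_area_rejected(self):
        rows = [make_biopsy_row("p1", "a1", "AFI+", "NDBO")] * 2
        with pytest.raises(CohortValidationError, match="duplicate"):
            CohortTable.from_biopsies(pd.DataFrame(rows))

    def test_bad_grade_names_row(self):
        rows = [make_biopsy_row("p1", "a1", "AFI+", "NDBO")]
        df = pd.DataFrame(rows)
        df.loc[0, "histology"] = "severe"
        with pytest.raises(CohortValidationError, match="row 0"):
            CohortTable.from_biopsies(df)

    def test_overall_is_max_of_protocols(self):
        rec = PatientRecord("p1", histology_seattle="LGD", histology_afi="HGD")
        assert rec.histology_overall == "HGD"

    def test_panel_cutoff_bounds(self):
        with pytest.raises(CohortValidationError):
            PanelDefinition(members=("p53_IHC", "aneuploidy"), cutoff=3)
        panel = PanelDefinition(members=("p53_IHC", "aneuploidy"), cutoff=2)
        assert panel.size == 2


class TestEndpointLabels:
    def test_id_is_non_dysplastic_for_both_endpoints(self, tiny_cohort):
        any_dys = endpoint_labels(tiny_cohort, "biopsy", "any_dysplasia")
        hgdec = endpoint_labels(tiny_cohort, "biopsy", "HGD_EC")
        id_rows = (tiny_cohort.biopsies["histology"] == "ID").to_numpy()
        assert not any_dys[id_rows].any()
        assert not hgdec[id_rows].any()

    def test_patient_level_uses_protocol_histology(self, tiny_cohort):
        pats = tiny_cohort.patients.copy()
        pats.loc[pats["patient_id"] == "p1", ["histology_seattle", "histology_overall"]] = ["LGD", "HGD"]
        cohort = CohortTable(tiny_cohort.biopsies, pats)
        seattle = endpoint_labels(cohort, "patient", "HGD_EC", protocol="seattle")
        overall = endpoint_labels(cohort, "patient", "HGD_EC", protocol="overall")
        i = int(np.flatnonzero((pats["patient_id"] == "p1").to_numpy())[0])
        assert not seattle[i] and overall[i]

    def test_protocol_required_at_patient_level(self, tiny_cohort):
        with pytest.raises(ValueError):
            endpoint_labels(tiny_cohort, "patient", "HGD_EC")

    def test_all_ndbo_cohort_all_negative(self):
        rows = [make_biopsy_row(f"p{i}", "a1", "AFI+", "NDBO") for i in range(5)]
        c = CohortTable.from_biopsies(pd.DataFrame(rows))
        assert not endpoint_labels(c, "biopsy", "any_dysplasia").any()

    def test_hgdec_implies_any_dysplasia(self, default_cohort):
        hgdec = endpoint_labels(default_cohort, "biopsy", "HGD_EC")
        any_dys = endpoint_labels(default_cohort, "biopsy", "any_dysplasia")
        assert (~hgdec | any_dys).all()


class TestIO:
    def test_round_trip_identity(self, tiny_cohort, tmp_path):
        write_cohort(tiny_cohort, tmp_path / "b.csv", tmp_path / "p.csv")
        back = read_cohort(tmp_path / "b.csv", tmp_path / "p.csv")
        assert back.equals(tiny_cohort)

    def test_round_trip_tab_delimited(self, tiny_cohort, tmp_path):
        write_cohort(tiny_cohort, tmp_path / "b.tsv", tmp_path / "p.tsv", sep="\t")
        back = read_cohort(tmp_path / "b.tsv", tmp_path / "p.tsv", sep="\t")
        assert back.equals(tiny_cohort)

    def test_all_missing_row(self, tmp_path):
        header = "patient_id,area_id,afi_status,histology," + ",".join(MARKERS)
        (tmp_path / "b.csv").write_text(header + "\np1,a1,AFI+,NDBO," + ",".join(["NA"] * 9) + "\n")
        c = read_cohort(tmp_path / "b.csv")
        assert c.n_biopsies == 1
        assert c.marker_matrix().isna().all().all()

    def test_unknown_column_is_schema_error(self, tmp_path):
        header = "patient_id,area_id,afi_status,histology,bogus_marker," + ",".join(MARKERS)
        (tmp_path / "b.csv").write_text(header + "\n")
        with pytest.raises(SchemaError, match="bogus_marker"):
            read_cohort(tmp_path / "b.csv")

    def test_empty_cohort_writes_header_only(self, tmp_path):
        empty = CohortTable.from_biopsies(
            pd.DataFrame(columns=["patient_id", "area_id", "afi_status", "histology", *MARKERS])
        )
        write_cohort(empty, tmp_path / "b.csv", tmp_path / "p.csv")
        lines = (tmp_path / "b.csv").read_text().strip().splitlines()
        assert len(lines) == 1 and lines[0].startswith("patient_id,")

    def test_synthetic_round_trip(self, default_cohort, tmp_path):
        write_cohort(default_cohort, tmp_path / "b.csv", tmp_path / "p.csv")
        back = read_cohort(tmp_path / "b.csv", tmp_path / "p.csv")
        assert back.biopsies[list(MARKERS)].equals(default_cohort.biopsies[list(MARKERS)])
        assert back.patients.equals(default_cohort.patients)


@settings(max_examples=25, deadline=None)
@given(
    grades=st.lists(st.sampled_from(GRADES), min_size=1, max_size=12),
    seed=st.integers(0, 2**20),
)
def test_label_implication_propertywise(grades, seed):
    """HGD/EC positivity implies any-dysplasia positivity record-wise."""
    rng = np.random.default_rng(seed)
    rows = [
        make_biopsy_row(f"p{i}", "a1", "AFI+" if rng.random() < 0.5 else "AFI-", g)
        for i, g in enumerate(grades)
    ]
    c = CohortTable.from_biopsies(pd.DataFrame(rows))
    hgdec = endpoint_labels(c, "biopsy", "HGD_EC")
    any_dys = endpoint_labels(c, "biopsy", "any_dysplasia")
    assert (~hgdec | any_dys).all()
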