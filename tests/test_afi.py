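"""AFI+ vs AFI− accuracy comparison and marker-AFI association."""

import numpy as np
import pandas as pd
import pytest

from afipanel import (
    MARKERS,
    PanelDefinition,
    afi_marker_association,
    compare_afi_auc,
    generate_cohort,
    impute,
    CohortTable,
)
from afipanel.afi import box_summary

from conftest import make_biopsy_row, planted_params

PANEL3 = PanelDefinition(members=("p53_IHC", "cyclinA_IHC", "aneuploidy"), cutoff=2)


def _ensemble(params):
    cohort = generate_cohort(params)
    return impute(cohort, m=2, n_cycles=4, seed=101)


class TestCompareAfiAuc:
    def test_enrichment_raises_afi_pos_auc(self):
        """With strong AFI enrichment the AFI+ arm wins in every database."""
        params = planted_params(n_patients=180, seed=55, afi_enrichment=2.5)
        cmp = compare_afi_auc(_ensemble(params), PANEL3, n_boot=300, seed=56)
        for name, (pos, neg) in cmp.per_database.items():
            assert np.median(pos) > np.median(neg), name
        assert cmp.p_value < 0.05

    def test_null_with_identical_per_arm_sampling_centred_at_zero(self):
        """When each patient contributes one AFI+ and one AFI− biopsy whose
        marker states are drawn iid from the same patient-level distribution,
        the paired AUC difference is centred at zero and rarely significant."""
        from afipanel import impute as _impute

        n_sig = 0
        medians = []
        for seed in range(6):
            rng = np.random.default_rng(800 + seed)
            rows = []
            for i in range(150):
                case = rng.random() < 0.25
                p = 0.7 if case else 0.2
                grade = "HGD" if case else "NDBO"
                for arm, area in (("AFI+", "a1"), ("AFI-", "a2")):
                    states = {
                        m: float(rng.random() < p) for m in PANEL3.members
                    }
                    rows.append(
                        make_biopsy_row(f"p{i}", area, arm, grade if arm == "AFI+" else "NDBO",
                                        **states)
                    )
            cohort = CohortTable.from_biopsies(pd.DataFrame(rows))
            ens = _impute(cohort, m=2, n_cycles=1, seed=1)
            cmp = compare_afi_auc(ens, PANEL3, n_boot=200, seed=900 + seed)
            diffs = np.concatenate([pos - neg for pos, neg in cmp.per_database.values()])
            medians.append(np.median(diffs))
            n_sig += cmp.p_value < 0.05
        assert abs(np.mean(medians)) < 0.05
        assert n_sig <= 1

    def test_single_resample_floors_p_at_one(self):
        params = planted_params(n_patients=150, seed=59)
        cmp = compare_afi_auc(_ensemble(params), PANEL3, n_boot=1, seed=60)
        assert cmp.p_value == 1.0

    def test_pairing_invariant_to_patient_order(self):
        params = planted_params(n_patients=150, seed=61)
        ens = _ensemble(params)
        cmp1 = compare_afi_auc(ens, PANEL3, n_boot=100, seed=62)
        # permute patient (and biopsy) row order in every database
        rng = np.random.default_rng(0)

        def permute(c):
            order = rng.permutation(c.patients.index)
            pats = c.patients.loc[order].reset_index(drop=True)
            return CohortTable(c.biopsies, pats)

        ens_perm = type(ens)(
            original=permute(ens.original),
            imputed=[permute(c) for c in ens.imputed],
            m=ens.m,
        )
        cmp2 = compare_afi_auc(ens_perm, PANEL3, n_boot=100, seed=62)
        assert cmp2.p_value == pytest.approx(cmp1.p_value)


class TestBoxSummary:
    def test_matches_quantile_oracle(self):
        rng = np.random.default_rng(8)
        v = rng.normal(size=500)
        s = box_summary(v)
        q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
        assert s["median"] == pytest.approx(med)
        assert s["q1"] == pytest.approx(q1) and s["q3"] == pytest.approx(q3)
        iqr = q3 - q1
        assert s["whisker_low"] == v[v >= q1 - 1.5 * iqr].min()
        assert s["whisker_high"] == v[v <= q3 + 1.5 * iqr].max()


class TestAfiMarkerAssociation:
    def test_enrichment_detected_after_excluding_dysplasia(self):
        cohort = generate_cohort(
            planted_params(n_patients=800, seed=63, afi_enrichment=1.5)
        )
        table = afi_marker_association(cohort, exclude_dysplastic=True)
        assert table.loc["aneuploidy", "p"] < 0.05
        assert table.loc["p53_IHC", "p"] < 0.05

    def test_null_enrichment_mostly_non_significant(self):
        n_sig = []
        for seed in range(5):
            cohort = generate_cohort(
                planted_params(n_patients=400, seed=70 + seed, afi_enrichment=0.0)
            )
            table = afi_marker_association(cohort, exclude_dysplastic=True)
            n_sig.append(int((table["p"] < 0.05).sum()))
        assert np.mean(n_sig) < 1.5  # ~0.45 expected under the null over 9 markers

    def test_all_afi_positive_surfaces_zero_margin_per_marker(self):
        rows = [
            make_biopsy_row(f"p{i}", "a1", "AFI+", "NDBO", p53_IHC=float(i % 2))
            for i in range(10)
        ]
        cohort = CohortTable.from_biopsies(pd.DataFrame(rows))
        table = afi_marker_association(cohort)
        assert table["p"].isna().all()
        assert (table["note"].str.len() > 0).all()
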