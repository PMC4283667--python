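"""Synthetic cohort generator: calibration, null behaviour, mechanisms."""

import numpy as np
import pytest
from scipy.stats import binomtest, chi2_contingency

from afipanel import (
    GeneratorParams,
    calibrate_agreement,
    crosstab,
    endpoint_labels,
    generate_cohort,
    generate_rater_panel,
    multi_rater_kappa,
    MARKERS,
)

from conftest import planted_params


def binomial_band(p: float, n: int, z: float = 1.96) -> tuple[float, float]:
    half = z * np.sqrt(p * (1 - p) / n)
    return p - half, p + half


class TestGenerateCohort:
    def test_deterministic_given_seed(self):
        a = generate_cohort(GeneratorParams(n_patients=40, seed=3))
        b = generate_cohort(GeneratorParams(n_patients=40, seed=3))
        assert a.equals(b)

    def test_zero_patients_empty_cohort(self):
        c = generate_cohort(GeneratorParams(n_patients=0, seed=1))
        assert c.n_patients == 0 and c.n_biopsies == 0

    def test_degenerate_grade_probs_permitted(self):
        c = generate_cohort(GeneratorParams(n_patients=30, grade_probs=(1, 0, 0, 0), seed=2))
        assert (c.patients["histology_overall"] == "NDBO").all()

    def test_ndbo_fraction_in_binomial_band(self, default_cohort):
        frac = (default_cohort.patients["histology_overall"] == "NDBO").mean()
        lo, hi = binomial_band(0.63, default_cohort.n_patients)
        assert lo <= frac <= hi

    def test_aneuploidy_rate_given_hgdec_in_band(self, default_cohort):
        col = default_cohort.biopsies["aneuploidy"]
        hgdec = endpoint_labels(default_cohort, "biopsy", "HGD_EC")
        obs = col.notna().to_numpy()
        sel = obs & hgdec
        rate = col[sel].mean()
        lo, hi = binomial_band(0.714, int(sel.sum()))
        assert lo <= rate <= hi

    def test_overall_grade_is_max_of_arms(self, default_cohort):
        p = default_cohort.patients
        from afipanel.cohort import grade_max

        expect = [grade_max(s, a) for s, a in zip(p["histology_seattle"], p["histology_afi"])]
        assert list(p["histology_overall"]) == expect

    def test_afi_area_count_capped_at_four(self, default_cohort):
        per_patient = (
            default_cohort.biopsies[default_cohort.biopsies["afi_status"] == "AFI+"]
            .groupby("patient_id")
            .size()
        )
        assert per_patient.max() <= 4

    def test_null_configuration_odds_ratio_near_one(self):
        c = generate_cohort(GeneratorParams.null(n_patients=5000, seed=11))
        for m in MARKERS:
            tab = crosstab(c, m, "HGD_EC").counts.astype(float) + 0.5
            or_ = tab[1, 1] * tab[0, 0] / (tab[0, 1] * tab[1, 0])
            assert 0.75 < or_ < 1.33, f"{m}: OR={or_:.2f}"

    def test_marginal_rate_is_mixture_of_conditionals(self):
        """Marginal positivity equals the prevalence-weighted conditional rates."""
        params = planted_params(n_patients=4000, seed=13)
        c = generate_cohort(params)
        y = endpoint_labels(c, "biopsy", "HGD_EC")
        prev = y.mean()
        for m in ("p53_IHC", "LOH9p"):
            p0, p1 = params.marker_pos_probs[m]
            expected = prev * p1 + (1 - prev) * p0
            col = c.biopsies[m]
            obs = col.notna().to_numpy()
            lo, hi = binomial_band(expected, int(obs.sum()))
            assert lo <= col[obs].mean() <= hi

    def test_mcar_missingness_independent_of_state(self):
        """Under MCAR the masked/observed split is independent of the true state."""
        n_sig = 0
        n_seeds = 10
        for seed in range(n_seeds):
            full = generate_cohort(
                planted_params(n_patients=1500, seed=seed, missing_probs={m: 0.0 for m in MARKERS})
            )
            rng = np.random.default_rng(1000 + seed)
            truth = full.biopsies["p53_IHC"].to_numpy()
            mask = rng.random(len(truth)) < 0.2
            tab = np.zeros((2, 2))
            np.add.at(tab, (mask.astype(int), truth.astype(int)), 1)
            _, p, _, _ = chi2_contingency(tab, correction=False)
            n_sig += p < 0.05
        assert n_sig <= 2  # ~5% type-I rate; allow slack over 10 seeds

    def test_mar_mechanism_runs_and_preserves_rough_missing_rate(self):
        c = generate_cohort(
            GeneratorParams(n_patients=800, missing_mechanism="MAR_on_area_size", seed=5)
        )
        frac = c.biopsies["LOH9p"].isna().mean()
        assert 0.18 <= frac <= 0.40  # target 0.285 under the MAR approximation


class TestRaterPanel:
    def test_maximum_agreement_gives_kappa_one(self):
        panel = generate_rater_panel(200, 1.0, seed=1)
        k, _ = multi_rater_kappa(panel, weighted=True)
        assert k == pytest.approx(1.0)

    def test_independent_raters_near_zero(self):
        panel = generate_rater_panel(2000, 0.0, seed=2)
        k, _ = multi_rater_kappa(panel, weighted=True, se=False)
        assert abs(k) < 0.08

    def test_calibrated_level_recovers_target_kappa(self):
        level = calibrate_agreement(0.56, n_cases=3000, seed=0)
        ks = [
            multi_rater_kappa(generate_rater_panel(500, level, seed=s), weighted=True, se=False)[0]
            for s in range(5)
        ]
        assert abs(np.mean(ks) - 0.56) < 0.05

    def test_rejects_too_few_cases(self):
        with pytest.raises(ValueError):
            generate_rater_panel(1, 0.5, seed=0)
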