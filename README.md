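# afipanel

Biomarker-panel discovery and validation for autofluorescence-guided
surveillance of Barrett's oesophagus.

## The problem

Endoscopic surveillance of Barrett's oesophagus (BO) relies on the Seattle
protocol — four-quadrant random biopsies every 2 cm — which is invasive,
poorly adhered to, and subject to sampling error and to the well-known
interobserver variability of a dysplasia diagnosis.  Autofluorescence
imaging (AFI) flags suspicious mucosa (AFI+ areas appear violet-purple) but
has too many false positives to replace random biopsies on its own.  A
promising alternative is to read a small panel of *molecular* biomarkers —
objective, binary assay outcomes — on a handful of AFI-targeted biopsies,
and call a patient high-risk for high-grade dysplasia or early cancer
(HGD/EC) from the number of abnormal markers.

`afipanel` implements the complete statistical pipeline for deriving and
validating such a panel from a cohort of per-biopsy ternary biomarker calls
(nine candidates: *HPP1*/*RUNX3*/*p16* methylation, p53 and cyclin A
immunohistochemistry, tetraploidy, aneuploidy, 17p and 9p LOH):

1. **Per-biopsy association screening** — complete-case 2×2 tables and
   uncorrected Pearson χ² per marker and endpoint (HGD/EC, any dysplasia).
2. **Multiple imputation** — chained-equations logistic imputation of
   missing marker calls (the nine markers + the histological diagnosis as
   model variables); five completed copies analysed alongside the original
   complete-case database.
3. **Bootstrap inclusion-frequency selection** — in each of the six
   databases, B=100 bootstrap resamples each fit a backward-stepwise
   logistic model of HGD/EC on the nine markers; markers whose *median*
   inclusion frequency over the databases reaches 90/100 form the panel.
4. **Count-of-positives classification** — a patient is high-risk when at
   least *c* panel markers are positive in any of their AFI+ biopsies; the
   cut-off *c* maximises accuracy; AUC with percentile-bootstrap CIs;
   exhaustive evaluation of all C(9,2)+C(9,3)=120 candidate panels;
   sensitivity/specificity with exact Clopper–Pearson intervals.
5. **AFI+ vs AFI− comparison** — paired patient-level bootstrap of the
   panel AUC computed from AFI+ versus AFI− areas.
6. **Protocol comparison** — detection yield and biopsy burden of Seattle
   histology vs AFI-targeted histology vs the biomarker panel, with exact
   McNemar and Wilcoxon signed-rank tests.
7. **Interobserver agreement** — Cohen's κ, linear/quadratic weighted κ and
   a multi-rater (mean pairwise, jackknife SE) summary.

Because the original study deposited no raw data, the package ships a
**synthetic-cohort generator** that emulates the study's structure —
grade mix, AFI+ area counts, marker positivity conditional on dysplasia, a
patient-level "molecular field" factor, AFI enrichment, and per-marker
missingness (MCAR or size-related MAR) — so that every stage is testable,
plus the study's published summary counts (`afipanel.reference`) from which
several published statistics can be recomputed exactly.

## Worked example

```python
import afipanel as ap

cohort = ap.generate_cohort(ap.GeneratorParams(seed=7))      # 157 patients
res = ap.PanelDiscovery(cohort, B=100, threshold=90, n_boot=500).fit(seed=11)
print(res.summary())
```

```
Biomarker panel discovery
============================================================
Endpoint:            HGD_EC
Cohort:              157 patients, 371 AFI-targeted biopsies
Databases:           original + 5 imputed
Bootstrap:           B=100 per database, threshold=90

Median inclusion frequencies:
  aneuploidy     100.0 *
  cyclinA_IHC     96.5 *
  p53_IHC         95.0 *
  tetraploidy     26.5
  LOH17p           4.0
  RUNX3_meth       3.0
  HPP1_meth        0.5
  p16_meth         0.5
  LOH9p            0.0

Selected panel:      p53_IHC+cyclinA_IHC+aneuploidy
Cut-off:             >= 3 positive markers
Evaluable patients:  116
Sensitivity:         76.0% (54.9% to 90.6%)
Specificity:         97.8% (92.3% to 99.7%)
Accuracy:            93.1%
AUC:                 0.97 (95% CI 0.94 to 0.99)
```

The three markers with genuine signal under the generator's defaults (p53
IHC, cyclin A IHC, aneuploidy) clear the inclusion threshold; the starred
rows are the selected panel.  The per-biopsy AUC of the count score is 0.97
(95% CI 0.94–0.99).  The fitted results object then classifies an external
cohort:

```python
validation = ap.generate_cohort(ap.GeneratorParams(n_patients=46, seed=99))
print(res.evaluate(validation).display())
# sensitivity 60.0% (14.7% to 94.7%), specificity 100.0% (87.7% to 100.0%)
```

(The wide external interval reflects the handful of HGD/EC cases in a
46-patient cohort.)

The same stages are available from the shell:

```bash
afipanel generate --seed 7 --outdir cohort/
afipanel associate cohort/biopsies.csv --patients cohort/patients.csv
afipanel evaluate  cohort/biopsies.csv --patients cohort/patients.csv --seed 11
afipanel run-all --seed 7 --outdir run/        # full pipeline + figures
```

## Cohort file format

Two delimited text files (comma by default, `NA` for a missing marker call):

* `biopsies.csv` — one row per AFI-targeted area:
  `patient_id, area_id, afi_status (AFI+/AFI-), histology
  (NDBO/ID/LGD/HGD/EC)` plus one `1/0/NA` column per biomarker
  (`HPP1_meth, RUNX3_meth, p16_meth, p53_IHC, cyclinA_IHC, tetraploidy,
  aneuploidy, LOH17p, LOH9p`).
* `patients.csv` — one row per patient: `patient_id, histology_seattle,
  histology_afi, histology_overall, n_biopsies_seattle, n_biopsies_afi,
  n_biopsies_biomarker`.

`histology_overall` must equal the grade-ordering maximum of the two
protocol columns; "indefinite for dysplasia" (ID) is kept at ingest and
collapsed to non-dysplastic only when endpoint labels are derived.

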