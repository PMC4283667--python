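# Methods

This note records the statistical models, the synthetic-data assumptions and
the design choices behind `afipanel`, in the spirit of a model reference
rather than a tutorial.

## Endpoints and grade handling

Histology grades form a total order NDBO < ID < LGD < HGD < EC.  Two binary
endpoints are derived at label time: **HGD/EC** (grade ∈ {HGD, EC}, the
composite that triggers therapy) and **any dysplasia** (grade ∈ {LGD, HGD,
EC}).  "Indefinite for dysplasia" always maps to non-dysplastic, reflecting
consensus-review practice; the raw grade is preserved on disk and in memory
so the collapse is reversible.  A patient's overall histology is the
grade-ordering maximum of the Seattle-protocol and AFI-targeted diagnoses,
enforced as a container invariant.

## Per-biopsy association screening

Each biomarker is cross-tabulated against each endpoint complete-case *per
marker* (not listwise), because missingness differs by assay (13–29%).  The
test is the uncorrected Pearson χ² on the 2×2 table: with the published
counts, the uncorrected statistic reproduces the printed p = 0.02 for the
HPP1 × HGD/EC table whereas the Yates-corrected one (0.03) does not, so no
continuity correction is applied.  P values are reported unadjusted.  Two
published values do not recompute exactly from the published tables and are
deliberately not forced: the 9p LOH × HGD/EC p value (printed 0.29,
recomputed 0.28) and the 17p LOH missing percentage (printed 27.4%, implied
by its own 2×2 27.9%).

## Multiple imputation

Missing marker calls are imputed by chained equations: each incomplete
marker is regressed on the other eight markers plus the per-biopsy
histology grade (five levels, dummy-coded; the *area* diagnosis, not the
binary endpoint), cycled 10 times per copy, m = 5 copies.  Uncertainty is
propagated by an approximate posterior draw: coefficients are sampled from
N(β̂, I⁻¹) where I is the observed information of the (ridge-penalised, if
separation requires — the fallback is logged) maximum-likelihood fit, and
cells are Bernoulli draws.  Observed cells are never modified; the original
database travels alongside the copies and is analysed complete-case, scoped
per operation (per marker for associations, listwise on the nine markers
inside its bootstrap selection, listwise on panel members for
classification).  AFI status is not an imputation covariate.

A consequence worth knowing: posterior-draw imputation preserves marginals
and uncertainty but *cannot* beat the majority-class rate in per-cell
accuracy for a marker without predictive signal (a draw from Bernoulli(p)
has expected accuracy p² + (1−p)², below max(p, 1−p)); the tests therefore
score the across-copies consensus, which does beat the base rate where
signal exists.

## Bootstrap inclusion-frequency selection

For each of the six databases, B = 100 bootstrap resamples (biopsy rows,
with replacement, equal size; single-class resamples are redrawn) each fit
a backward-stepwise logistic regression of HGD/EC on the nine markers.
The elimination rule is the likelihood-ratio test with a removal threshold
of α = 0.01: the variable with the largest p value is dropped while that p
exceeds α.  A marker's inclusion frequency is the number of resamples whose
final model retains it; markers whose median over the six databases reaches
90/100 form the panel (raising the threshold can only shrink the selection).

The stringent α matters.  Bootstrap resamples condition on the realised
sample, so any null marker that shows a chance association *in that sample*
is retained by a lenient rule in most resamples: with AIC elimination
(retain at χ² > 2) null markers routinely reach median inclusion 70–85/100,
destroying the contrast the frequencies are meant to express.  At α = 0.01
a planted three-marker signal (odds ratio ≈ 20, ~10 events per candidate
predictor) reaches median ≥ 90 while six null markers stay below 50 in 19
of 20 seeds.  AIC elimination remains available (`criterion="aic"`).

## Count-of-positives classifier

The diagnostic score of a panel is the count of positive members; a record
with any missing member is *undetermined* by default (a count-observed
policy exists).  Per-patient marker calls use an any-positive rule over the
patient's AFI+ biopsies — the panel is explicitly a test on AFI-targeted
tissue — with a configurable fallback to AFI− biopsies for patients without
AFI+ areas.  The cut-off maximises accuracy (Youden optional), ties broken
toward the higher cut-off (higher specificity).  AUC is the rank statistic
(identical to Mann–Whitney U/(n₁n₀)), with percentile-bootstrap CIs.
Sensitivity and specificity carry exact Clopper–Pearson intervals; point
estimates are kept as exact rationals and rounded only for display (1 dp).
Note the published intervals for 23/24 and 78/88 match no standard method
exactly; the exact intervals reported here differ in the second digit.

The exhaustive search evaluates all 36 pairs and 84 triples on patient-level
bootstrap resamples (n_boot = 2000 by default), each panel complete-case on
its own members, ranked by mean best-cut-off accuracy.

## AFI+ versus AFI− comparison

Restricted to patients with at least one area of each kind, the same panel
is read twice per patient — once from AFI+ areas, once from AFI− areas —
and the two AUCs are computed on *shared* patient-level bootstrap resamples
(paired design).  The two-sided p value is twice the fraction of bootstrap
AUC differences ≤ 0, floored at 1/n_boot; a Wilcoxon on per-database mean
AUCs is available as a sensitivity analysis.  The 2000 resamples are drawn
per database.

One structural caveat: with multiple AFI+ areas against a single AFI−
control area, any-positive aggregation makes the arms asymmetric even when
markers are unrelated to AFI status (more areas accumulate more false
positives), so the clean null — difference centred at zero — only holds
under identical per-arm sampling.  The test suite constructs that case
explicitly.

## Protocol comparison

Reference standard is overall histology.  Each route (Seattle histology,
AFI histology, panel on AFI+ areas) reports detected/missed HGD/EC cases,
sensitivity, total biopsies, biopsies per patient, and biopsies per case
*diagnosed by that route* — the per-route denominator is what reproduces
the published ratios exactly (1385/23 = 60.2, 169/22 = 7.7, 310/23 = 13.5).
Sensitivities are compared by exact McNemar on paired detections (p = 1
when no pairs are discordant); biopsy burdens by Wilcoxon signed-rank on
per-patient counts.

## Agreement statistics

Weighted κ uses linear weights by default (quadratic optional) with the
Fleiss–Cohen–Everitt large-sample SE; unweighted Cohen's κ is the identity-
weight special case.  The three-rater summary is the mean of pairwise κ
values with a case-level jackknife SE; Fleiss' κ on pooled category counts
is deliberately not used.  When a single category exhausts both raters the
statistic is degenerate and reported as κ = 1 with a warning.

## Synthetic cohort generator

The generator emulates the study design: per patient, an overall grade
drawn from (0.630, 0.134, 0.153, 0.083) over (NDBO, LGD, HGD, EC); an AFI+
area count min(Poisson(229/157), 4); one AFI− control area except for a
diffuse-positivity fraction (8/157); Seattle biopsy counts Poisson(12.4);
1–3 research biopsies per AFI+ area (mean ≈ 1.9, i.e. ≈ 2.8 per patient).
Detection of a dysplastic patient's grade by the Seattle and AFI arms is
drawn jointly (defaults 0.96/0.92) conditional on at least one success, so
the overall grade equals the maximum over arms by construction; a detected
AFI case has its grade assigned to one AFI+ area (the count is
zero-truncated in that case — AFI detection presumes a flagged area) and
secondary areas carry it with probability 0.6.

Marker states follow a logistic model: intercept by *area* endpoint
(defaults = the published conditional positivity rates, e.g. aneuploidy
71.4% | HGD/EC vs 11.8% | not), plus a centred AFI+ enrichment term (0.5
log-odds), a patient-level standard-normal field factor (SD 0.5 log-odds,
inducing inter-marker correlation), and a field shift growing with the
patient's overall dysplasia status (2.5 log-odds × {0, ½, 1} for
NDBO/LGD/HGD-EC) — molecular abnormality concentrates in dysplastic
patients even in their non-dysplastic areas, which is the premise that
makes a per-patient panel work.  Intercepts are rescaled by the
logit-normal approximation (÷√(1 + c²σ²), c = 16√3/15π) and the latent
terms are centred within endpoint strata, so the *conditional* rates stay
at their targets despite the extra variance.  The field-shift magnitude was
calibrated once, at design time, against the published per-patient
operating point (sensitivity 95.8% / specificity 88.6% at cut-off 2); with
the frozen defaults the generator yields ≈ 95% / 86% at cut-off 2, and the
accuracy-maximising cut-off is 3 in most seeds, with 2 a near-tie — the
generator reproduces the published operating point more faithfully than the
published cut-off preference.

Missingness is per-marker (published fractions 0.132–0.285), MCAR by
default; the MAR mechanism ties missingness to a simulated area-size
covariate (larger dysplastic areas yield more research biopsies, hence
fewer missing assays).  A `GeneratorParams.null()` preset zeroes the
endpoint effects *and* the AFI enrichment *and* the field shift: because
dysplasia is preferentially assigned to AFI+ areas, leaving enrichment on
would induce a marginal marker–endpoint association even with
endpoint-identical rates.

Rater panels draw a latent severity per case and threshold
√a·t + √(1−a)·e at the normal quantiles of a five-grade prevalence vector;
a = 1 gives identical raters, a = 0 independent ones, and a ≈ 0.844
(calibrated by simulated bisection) reproduces a weighted κ of ≈ 0.56.

What the generator does **not** emulate: spatial structure of areas,
longitudinal progression, assay batch effects, and between-centre
heterogeneity.  Passing tests on synthetic cohorts demonstrate that the
*pipeline* behaves correctly under the stated data-generating assumptions,
not that the published biological effect sizes are correct.

## Numerical choices

* Inner-loop logistic fits (stepwise selection, imputation) use a dense
  Newton/IRLS solver with warm starts, step damping, separation detection
  and a logged ridge (L2 = 1) fallback; it is cross-checked against
  statsmodels' `Logit` in the unit tests.  One-off fits elsewhere use the
  standard library stack.
* All randomness flows through `numpy.random.default_rng`; pipeline stages
  derive independent seeds from the root seed by SHA-256 of the stage name,
  and re-running a configuration reproduces every artefact byte for byte.
* Bootstrap resamples with a single outcome class are redrawn (capped at
  100 attempts, logged); cut-off ties break toward specificity; quantities
  displayed at 1 dp are computed as exact rationals first.
* Benchmark problem sizes used by the test suite: planted-signal selection
  at ~300 biopsies (~10 events per candidate predictor), search recovery at
  157 patients with n_boot = 200, imputation mask-and-recover at ~5000
  biopsies, type-I calibration pooled over 200 seeded null cohorts.

## Known limitations

* The per-bootstrap selection model of the original analysis is described
  only in its online supplement; the α = 0.01 backward LRT rule is this
  package's documented choice, selected for the operating characteristics
  described above.
* The per-patient any-positive aggregation rule is an assumption (the
  source describes the panel "on AFI+ areas" without stating the
  aggregation); it is prominent, configurable, and its consequences for
  multi-area patients are discussed above.
* How patients with no AFI+ areas or diffuse AFI positivity enter the
  per-patient call is configurable (fallback on/off) rather than resolved.
* Clopper–Pearson intervals differ slightly from the published CIs, whose
  method is unstated and matches no standard construction we tried.
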