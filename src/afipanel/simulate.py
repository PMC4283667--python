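"""Synthetic cohorts with the statistical structure of an AFI biomarker study.

The generator emulates the sampling design of a cross-sectional Barrett's
surveillance study: each patient receives Seattle-protocol biopsies plus up
to four AFI+ targeted areas and one AFI− control area; every AFI-targeted
area carries a histology grade and nine ternary biomarker calls with
marker-specific missingness.  Default parameters reproduce the published
cohort's grade mix (63% NDBO / 13.4% LGD / 15.3% HGD / 8.3% EC), its AFI+
area rate (229 areas over 157 patients), the per-marker positivity rates
conditional on HGD/EC, and the per-marker missing-value fractions
(13.2–28.5%).

Biomarker states are drawn from a logistic model

    logit P(positive) = a_m(endpoint) + gamma * (AFI+ - mean)
                        + lambda * Z_patient + delta * level_patient

where ``Z_patient`` is a patient-level standard-normal "molecular field"
factor shared by all markers (inducing inter-marker correlation), ``gamma``
enriches positivity in AFI+ areas independently of dysplasia, and ``delta``
shifts the field with the patient's overall dysplasia status — molecular
abnormality concentrates in dysplastic patients even in their
non-dysplastic areas.  The intercepts ``a_m`` are calibrated so the
conditional positivity rates given the *area* endpoint match the requested
values despite the latent terms (logit-scale normal-mixing approximation
plus within-stratum centring).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .cohort import CohortTable, GRADES, MARKERS

__all__ = [
    "GeneratorParams",
    "generate_cohort",
    "generate_rater_panel",
    "calibrate_agreement",
]

# logistic ~ probit scaling constant: expit(x) ~= Phi(c*x)
_PROBIT_C = 16.0 * np.sqrt(3.0) / (15.0 * np.pi)

#: Default positivity probabilities conditional on the area's HGD/EC status,
#: (P(pos | no HGD/EC), P(pos | HGD/EC)).
_DEFAULT_MARKER_POS = {
    "HPP1_meth": (0.771, 0.929),
    "RUNX3_meth": (0.605, 0.857),
    "p16_meth": (0.446, 0.714),
    "p53_IHC": (0.295, 0.932),
    "cyclinA_IHC": (0.150, 0.795),
    "tetraploidy": (0.308, 0.429),
    "aneuploidy": (0.118, 0.714),
    "LOH17p": (0.507, 0.833),
    "LOH9p": (0.808, 0.878),
}

#: Alternative preset: rates conditional on any-grade dysplasia.
ANY_DYSPLASIA_MARKER_POS = {
    "HPP1_meth": (0.760, 0.910),
    "RUNX3_meth": (0.584, 0.836),
    "p16_meth": (0.433, 0.657),
    "p53_IHC": (0.232, 0.868),
    "cyclinA_IHC": (0.112, 0.662),
    "tetraploidy": (0.278, 0.482),
    "aneuploidy": (0.089, 0.574),
    "LOH17p": (0.481, 0.810),
    "LOH9p": (0.805, 0.867),
}

_DEFAULT_MISSING = {
    "HPP1_meth": 0.191,
    "RUNX3_meth": 0.191,
    "p16_meth": 0.191,
    "p53_IHC": 0.132,
    "cyclinA_IHC": 0.140,
    "tetraploidy": 0.197,
    "aneuploidy": 0.197,
    "LOH17p": 0.274,
    "LOH9p": 0.285,
}


@dataclass(frozen=True)
class GeneratorParams:
    """Tunable knobs of the synthetic cohort generator.

    Defaults encode the published training cohort's structure; see module
    docstring.  ``marker_pos_probs`` maps each biomarker to
    ``(P(pos | endpoint negative area), P(pos | endpoint positive area))``
    where the conditioning endpoint is HGD/EC by default.
    """

    n_patients: int = 157
    #: probabilities of patient overall grade (NDBO, LGD, HGD, EC); ID is not
    #: generated (consensus review collapses it before analysis).
    grade_probs: tuple[float, float, float, float] = (0.630, 0.134, 0.153, 0.083)
    #: mean AFI+ areas per patient (truncated-Poisson mean before the cap of 4)
    afi_pos_rate_per_patient: float = 229.0 / 157.0
    #: fraction of patients with diffuse AFI positivity (no AFI− control area)
    diffuse_positivity_frac: float = 8.0 / 157.0
    #: probability a *secondary* AFI+ area of a dysplastic patient carries the
    #: patient's grade (one area always carries it when AFI detects)
    p_area_hgdec_given_patient: float = 0.6
    #: detection probabilities of the patient's overall grade by each arm,
    #: conditioned so that at least one arm detects (overall = max of arms)
    p_seattle_detect: float = 0.96
    p_afi_detect: float = 0.92
    marker_pos_probs: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_MARKER_POS)
    )
    #: log-odds increment of marker positivity in AFI+ areas, independent of
    #: dysplasia (the "field effect" AFI is hypothesised to flag)
    afi_enrichment: float = 0.5
    #: SD (log-odds scale) of the shared patient-level latent factor
    latent_corr: float = 0.5
    #: log-odds shift of the latent field with the patient's overall dysplasia
    #: status (0 for NDBO, half for LGD, full for HGD/EC): molecular
    #: abnormality concentrates in dysplastic patients, not just in the
    #: dysplastic areas themselves.  Calibrated so the published panel's
    #: per-patient operating point is approximately reproduced.
    field_dysplasia_shift: float = 2.5
    missing_probs: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_MISSING))
    missing_mechanism: str = "MCAR"  # or "MAR_on_area_size"
    #: log-odds effect of (negated, standardised) area size on missingness
    mar_strength: float = 1.0
    #: mean Seattle-protocol biopsies per patient
    seattle_biopsy_rate: float = 12.4
    seed: int | None = None

    def __post_init__(self) -> None:
        gp = np.asarray(self.grade_probs, float)
        if gp.min() < 0 or abs(gp.sum() - 1.0) > 1e-8:
            raise ValueError("grade_probs must be non-negative and sum to 1")
        for m, (p0, p1) in self.marker_pos_probs.items():
            if not (0 <= p0 <= 1 and 0 <= p1 <= 1):
                raise ValueError(f"marker_pos_probs[{m}] outside [0,1]")
        for m, q in self.missing_probs.items():
            if not 0 <= q <= 1:
                raise ValueError(f"missing_probs[{m}] outside [0,1]")
        if self.missing_mechanism not in ("MCAR", "MAR_on_area_size"):
            raise ValueError("missing_mechanism must be 'MCAR' or 'MAR_on_area_size'")

    @classmethod
    def null(cls, **overrides) -> "GeneratorParams":
        """A no-signal configuration: marker rates identical across endpoints,
        no latent field, no AFI enrichment.  Baseline rates are the
        endpoint-negative defaults."""
        flat = {m: (p0, p0) for m, (p0, _) in _DEFAULT_MARKER_POS.items()}
        base = dict(
            marker_pos_probs=flat,
            latent_corr=0.0,
            afi_enrichment=0.0,
            field_dysplasia_shift=0.0,
        )
        base.update(overrides)
        return cls(**base)

    def with_(self, **overrides) -> "GeneratorParams":
        return replace(self, **overrides)


def generate_cohort(params: GeneratorParams | None = None, **overrides) -> CohortTable:
    """Draw a synthetic cohort; deterministic given ``params.seed``.

    Patient overall grade equals the maximum grade over the diagnostic arms by
    construction: detection indicators for the Seattle and AFI arms are drawn
    conditional on at least one success, and the detecting AFI arm assigns the
    patient's grade to one random AFI+ area.
    """
    if params is None:
        params = GeneratorParams(**overrides)
    elif overrides:
        params = params.with_(**overrides)
    rng = np.random.default_rng(params.seed)

    grades4 = ("NDBO", "LGD", "HGD", "EC")
    gidx = rng.choice(4, size=params.n_patients, p=np.asarray(params.grade_probs))

    patient_rows = []
    area_meta = []  # (patient_idx, afi_pos, grade)
    ps, pa = params.p_seattle_detect, params.p_afi_detect
    joint = np.array([ps * pa, ps * (1 - pa), (1 - ps) * pa])
    joint = joint / joint.sum()

    for i in range(params.n_patients):
        g = grades4[gidx[i]]
        diffuse = rng.random() < params.diffuse_positivity_frac
        n_pos = int(min(rng.poisson(params.afi_pos_rate_per_patient), 4))
        if diffuse:
            n_pos = max(n_pos, 1)
        has_neg = not diffuse

        if g == "NDBO":
            d_seattle = d_afi = True
        else:
            which = rng.choice(3, p=joint)
            d_seattle = which in (0, 1)
            d_afi = which in (0, 2)
            if d_afi and n_pos == 0:
                # AFI detection presumes a flagged area: zero-truncate the
                # AFI+ area count for detected dysplastic patients
                n_pos = 1

        area_grades = ["NDBO"] * n_pos
        if g != "NDBO" and n_pos > 0:
            if d_afi:
                area_grades[rng.integers(n_pos)] = g
            for j in range(n_pos):
                if area_grades[j] == "NDBO" and rng.random() < params.p_area_hgdec_given_patient:
                    area_grades[j] = g
        for j in range(n_pos):
            area_meta.append((i, True, area_grades[j]))
        if has_neg:
            area_meta.append((i, False, "NDBO"))

        afi_grade = max(["NDBO"] + area_grades, key=GRADES.index) if n_pos else "NDBO"
        seattle_grade = g if (g != "NDBO" and d_seattle) else "NDBO"
        overall = max(seattle_grade, afi_grade, key=GRADES.index)
        n_seattle = max(int(rng.poisson(params.seattle_biopsy_rate)), 4)
        # 1-3 research biopsies per AFI+ area, mean ~1.9 => ~2.8 per patient
        n_biom = int((1 + rng.binomial(2, 0.45, size=n_pos)).sum()) if n_pos else 0
        patient_rows.append(
            {
                "patient_id": f"S{i:05d}",
                "histology_seattle": seattle_grade,
                "histology_afi": afi_grade,
                "histology_overall": overall,
                "n_biopsies_seattle": n_seattle,
                "n_biopsies_afi": n_pos,
                "n_biopsies_biomarker": n_biom,
            }
        )

    n_areas = len(area_meta)
    pcols = [
        "patient_id",
        "histology_seattle",
        "histology_afi",
        "histology_overall",
        "n_biopsies_seattle",
        "n_biopsies_afi",
        "n_biopsies_biomarker",
    ]
    patients_df = pd.DataFrame(patient_rows, columns=pcols)
    if n_areas == 0:
        biopsies = pd.DataFrame(
            columns=["patient_id", "area_id", "afi_status", "histology", *MARKERS]
        )
        for m in MARKERS:
            biopsies[m] = biopsies[m].astype(float)
        return CohortTable(biopsies, patients_df)

    pat_idx = np.array([a[0] for a in area_meta])
    afi_pos = np.array([a[1] for a in area_meta], dtype=bool)
    area_grade = np.array([a[2] for a in area_meta])
    hgdec = np.isin(area_grade, ("HGD", "EC"))

    afi_frac = float(afi_pos.mean())
    z = rng.standard_normal(params.n_patients)  # patient-level molecular field
    # the field's mean tracks the patient's overall dysplasia status
    level_map = {"NDBO": 0.0, "ID": 0.0, "LGD": 0.5, "HGD": 1.0, "EC": 1.0}
    level = np.array(
        [level_map[g] for g in patients_df["histology_overall"]], dtype=float
    )
    fshift = params.field_dysplasia_shift * level[pat_idx]
    # centre the field shift and the AFI term within each endpoint stratum so
    # the requested conditional positivity rates stay calibrated
    fshift_c = fshift.copy()
    extra_var = np.empty(2)
    for g, mask in ((0, ~hgdec), (1, hgdec)):
        if mask.any():
            fshift_c[mask] = fshift[mask] - fshift[mask].mean()
            extra_var[g] = (
                params.latent_corr**2
                + params.afi_enrichment**2 * afi_frac * (1 - afi_frac)
                + float(np.var(fshift[mask]))
            )
        else:
            extra_var[g] = params.latent_corr**2

    cols: dict[str, np.ndarray] = {}
    # area size covariate for the MAR mechanism: dysplastic AFI+ areas tend
    # to be larger; smaller areas yield fewer research biopsies -> missing.
    size = 0.5 * hgdec.astype(float) + rng.standard_normal(n_areas)
    scale = np.sqrt(1.0 + _PROBIT_C**2 * extra_var)
    for m in MARKERS:
        p0, p1 = params.marker_pos_probs[m]
        a0 = float(logit(np.clip(p0, 1e-9, 1 - 1e-9)) * scale[0])
        a1 = float(logit(np.clip(p1, 1e-9, 1 - 1e-9)) * scale[1])
        eta = (
            np.where(hgdec, a1, a0)
            + params.afi_enrichment * (afi_pos.astype(float) - afi_frac)
            + params.latent_corr * z[pat_idx]
            + fshift_c
        )
        state = (rng.random(n_areas) < expit(eta)).astype(float)
        q = params.missing_probs.get(m, 0.0)
        if q > 0:
            if params.missing_mechanism == "MCAR":
                mask = rng.random(n_areas) < q
            else:
                base = logit(np.clip(q, 1e-9, 1 - 1e-9))
                base *= np.sqrt(1.0 + _PROBIT_C**2 * params.mar_strength**2)
                mask = rng.random(n_areas) < expit(base - params.mar_strength * size)
            state[mask] = np.nan
        cols[m] = state

    area_counter: dict[int, int] = {}
    area_ids = []
    for i in pat_idx:
        area_counter[i] = area_counter.get(i, 0) + 1
        area_ids.append(f"a{area_counter[i]}")
    biopsies = pd.DataFrame(
        {
            "patient_id": [f"S{i:05d}" for i in pat_idx],
            "area_id": area_ids,
            "afi_status": np.where(afi_pos, "AFI+", "AFI-"),
            "histology": area_grade,
            **cols,
        }
    )
    return CohortTable(biopsies, patients_df)


# ---------------------------------------------------------------------- #
# interobserver rating panels
# ---------------------------------------------------------------------- #
def generate_rater_panel(
    n_cases: int,
    agreement_level: float,
    seed: int | None = None,
    n_raters: int = 3,
    grade_probs: tuple[float, ...] = (0.50, 0.12, 0.16, 0.14, 0.08),
) -> pd.DataFrame:
    """Ordinal dysplasia grades from ``n_raters`` raters on shared cases.

    Each case has a latent severity ``t ~ N(0,1)``; rater ``k`` observes
    ``sqrt(a)*t + sqrt(1-a)*e_k`` thresholded into the five grades at the
    normal quantiles of ``grade_probs``.  ``agreement_level`` = ``a`` in
    [0,1]: 1 gives identical raters (weighted kappa 1), 0 independent raters
    (kappa ~ 0); intermediate values yield tunable expected agreement.
    """
    if n_cases < 2:
        raise ValueError("need at least 2 cases")
    if not 0.0 <= agreement_level <= 1.0:
        raise ValueError("agreement_level must lie in [0,1]")
    from scipy.stats import norm

    probs = np.asarray(grade_probs, float)
    if abs(probs.sum() - 1.0) > 1e-8:
        raise ValueError("grade_probs must sum to 1")
    cuts = norm.ppf(np.cumsum(probs)[:-1])
    rng = np.random.default_rng(seed)
    t = rng.standard_normal(n_cases)
    a = agreement_level
    data = {}
    shared = np.sqrt(a) * t
    for k in range(n_raters):
        e = rng.standard_normal(n_cases)
        latent = shared + np.sqrt(1.0 - a) * e
        data[f"rater{k + 1}"] = np.asarray(GRADES)[np.searchsorted(cuts, latent)]
    return pd.DataFrame(data, index=[f"case{i}" for i in range(n_cases)])


def calibrate_agreement(
    target_kappa: float,
    n_cases: int = 4000,
    seed: int = 0,
    tol: float = 0.01,
    max_iter: int = 30,
) -> float:
    """Bisection on ``agreement_level`` so the simulated mean pairwise
    linear-weighted kappa of a 3-rater panel hits ``target_kappa``."""
    from .agreement import multi_rater_kappa

    def kappa_at(a: float) -> float:
        panel = generate_rater_panel(n_cases, a, seed=seed)
        k, _ = multi_rater_kappa(panel, weighted=True, se=False)
        return k

    lo, hi = 0.0, 1.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        k = kappa_at(mid)
        if abs(k - target_kappa) < tol:
            return mid
        if k < target_kappa:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
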