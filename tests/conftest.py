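"""Shared fixtures: small handmade cohorts and seeded synthetic data."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from afipanel import CohortTable, GeneratorParams, MARKERS, generate_cohort


def make_biopsy_row(pid, area, afi, grade, **marker_states):
    """One biopsy-row dict; unspecified markers default to negative."""
    row = {"patient_id": pid, "area_id": area, "afi_status": afi, "histology": grade}
    for m in MARKERS:
        row[m] = 0.0
    for m, v in marker_states.items():
        assert m in MARKERS
        row[m] = v
    return row


@pytest.fixture
def tiny_cohort() -> CohortTable:
    """Four patients / six biopsies covering grades, AFI states and missingness."""
    rows = [
        make_biopsy_row("p1", "a1", "AFI+", "HGD", p53_IHC=1.0, cyclinA_IHC=1.0, aneuploidy=np.nan),
        make_biopsy_row("p1", "a2", "AFI-", "NDBO", p53_IHC=0.0),
        make_biopsy_row("p2", "a1", "AFI+", "LGD", aneuploidy=1.0, LOH9p=np.nan),
        make_biopsy_row("p2", "a2", "AFI-", "NDBO"),
        make_biopsy_row("p3", "a1", "AFI+", "ID", tetraploidy=1.0),
        make_biopsy_row("p4", "a1", "AFI-", "EC", p53_IHC=1.0, cyclinA_IHC=1.0, aneuploidy=1.0),
    ]
    return CohortTable.from_biopsies(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def default_cohort() -> CohortTable:
    """One seeded cohort at generator defaults (study-sized)."""
    return generate_cohort(GeneratorParams(seed=20240901))


def planted_params(n_patients: int = 126, seed: int = 0, **overrides) -> GeneratorParams:
    """Three strong markers (OR ~ 20) and six null markers, no latent terms.

    0.75 vs 0.13 positivity gives an odds ratio of (0.75/0.25)/(0.13/0.87)
    ~= 20; the remaining markers are endpoint-independent at 0.30.
    """
    signal = ("p53_IHC", "cyclinA_IHC", "aneuploidy")
    probs = {m: ((0.13, 0.75) if m in signal else (0.30, 0.30)) for m in MARKERS}
    base = dict(
        n_patients=n_patients,
        # enriched case prevalence: ~30% of areas carry HGD/EC, giving ~10
        # events per candidate predictor at the 300-biopsy benchmark size
        grade_probs=(0.50, 0.12, 0.23, 0.15),
        marker_pos_probs=probs,
        latent_corr=0.0,
        afi_enrichment=0.0,
        field_dysplasia_shift=0.0,
        missing_probs={m: 0.10 for m in MARKERS},
        seed=seed,
    )
    base.update(overrides)
    return GeneratorParams(**base)
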