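"""statsmodels-style facade over the panel-discovery pipeline.

:class:`PanelDiscovery` is constructed from cohort data and configuration;
``fit()`` runs the discovery stages — multiple imputation, bootstrap
inclusion-frequency selection, cut-off choice, per-patient evaluation — and
returns a :class:`PanelDiscoveryResults` carrying the selected panel, its
diagnostic estimates with intervals, and a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import (
    AUCResult,
    DiagnosticResult,
    aggregate_cohort,
    choose_cutoff,
    diagnostic_metrics,
    panel_scores,
    roc_auc,
)
from .cohort import CohortTable, PanelDefinition, endpoint_labels, read_cohort
from .imputation import ImputedEnsemble, impute
from .selection import InclusionMatrix, PanelSelection, bootstrap_inclusion, select_panel

__all__ = ["PanelDiscovery", "PanelDiscoveryResults"]


class PanelDiscovery:
    """Biomarker-panel discovery model over an AFI-targeted biopsy cohort.

    Parameters
    ----------
    cohort : CohortTable
        Biopsy and patient tables (missing marker calls allowed).
    endpoint : str
        Diagnostic endpoint, ``"HGD_EC"`` (default) or ``"any_dysplasia"``.
    m, n_cycles : int
        Number of imputed copies and chained-equation cycles.
    B, threshold : int
        Bootstrap resamples per database and the median inclusion-frequency
        threshold for panel membership.
    n_boot : int
        Resamples for the AUC confidence interval.
    """

    def __init__(
        self,
        cohort: CohortTable,
        *,
        endpoint: str = "HGD_EC",
        m: int = 5,
        n_cycles: int = 10,
        B: int = 100,
        threshold: int = 90,
        n_boot: int = 2000,
    ):
        self.cohort = cohort
        self.endpoint = endpoint
        self.m = m
        self.n_cycles = n_cycles
        self.B = B
        self.threshold = threshold
        self.n_boot = n_boot

    @classmethod
    def from_files(cls, biopsies_path, patients_path=None, **kwargs) -> "PanelDiscovery":
        return cls(read_cohort(biopsies_path, patients_path), **kwargs)

    @classmethod
    def from_dataframe(cls, biopsies: pd.DataFrame, patients: pd.DataFrame | None = None, **kwargs):
        if patients is None:
            cohort = CohortTable.from_biopsies(biopsies)
        else:
            cohort = CohortTable(biopsies, patients)
        return cls(cohort, **kwargs)

    def fit(self, seed: int | None = None) -> "PanelDiscoveryResults":
        """Run imputation, selection and evaluation; deterministic given seed."""
        ss = np.random.SeedSequence(seed)
        s_imp, s_sel, s_auc = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3))

        ensemble = impute(self.cohort, m=self.m, n_cycles=self.n_cycles, seed=s_imp)
        incl = bootstrap_inclusion(
            ensemble, B=self.B, seed=s_sel, endpoint=self.endpoint, threshold=self.threshold
        )
        selection = select_panel(incl)

        panel = None
        cutoff = None
        metrics = None
        auc = None
        n_eval = 0
        if not selection.is_empty:
            panel = selection.to_panel()
            table = aggregate_cohort(self.cohort, markers=panel.members, endpoint=self.endpoint)
            scores = panel_scores(table, panel)
            ok = ~np.isnan(scores)
            s, y = scores[ok], table["label"].to_numpy(dtype=bool)[ok]
            n_eval = int(ok.sum())
            if 0 < y.sum() < len(y):
                cutoff = choose_cutoff(s, y, max_cutoff=panel.size)
                panel = PanelDefinition(members=panel.members, cutoff=cutoff)
                tp = int(((s >= cutoff) & y).sum())
                fp = int(((s >= cutoff) & ~y).sum())
                fn = int(((s < cutoff) & y).sum())
                tn = int(((s < cutoff) & ~y).sum())
                metrics = diagnostic_metrics(tp, fp, fn, tn)
                auc = roc_auc(s, y, n_boot=self.n_boot, seed=s_auc)
        return PanelDiscoveryResults(
            model=self,
            ensemble=ensemble,
            inclusion=incl,
            selection=selection,
            panel=panel,
            metrics=metrics,
            auc=auc,
            n_evaluable=n_eval,
            seed=seed,
        )


@dataclass
class PanelDiscoveryResults:
    """Fitted panel-discovery results (selection, estimates, uncertainties)."""

    model: PanelDiscovery
    ensemble: ImputedEnsemble
    inclusion: InclusionMatrix
    selection: PanelSelection
    panel: PanelDefinition | None
    metrics: DiagnosticResult | None
    auc: AUCResult | None
    n_evaluable: int
    seed: int | None = None

    def predict(self, cohort: CohortTable) -> pd.Series:
        """Per-patient high-risk calls (1/0, NaN undetermined) on new data."""
        if self.panel is None:
            raise ValueError("no panel was selected; nothing to predict with")
        table = aggregate_cohort(cohort, markers=self.panel.members, endpoint=self.model.endpoint)
        scores = panel_scores(table, self.panel)
        calls = np.where(np.isnan(scores), np.nan, (scores >= self.panel.cutoff).astype(float))
        return pd.Series(calls, index=table.index, name="high_risk")

    def evaluate(self, cohort: CohortTable) -> DiagnosticResult:
        """Diagnostic metrics of the fitted panel on an external cohort."""
        calls = self.predict(cohort)
        labels = endpoint_labels(
            cohort, level="patient", endpoint=self.model.endpoint, protocol="overall"
        ).astype(float)
        ok = ~calls.isna().to_numpy()
        c, y = calls.to_numpy()[ok].astype(bool), labels[ok].astype(bool)
        return diagnostic_metrics(
            tp=int((c & y).sum()), fp=int((c & ~y).sum()),
            fn=int((~c & y).sum()), tn=int((~c & ~y).sum()),
        )

    def summary(self) -> str:
        lines = []
        add = lines.append
        add("Biomarker panel discovery")
        add("=" * 60)
        add(f"Endpoint:            {self.model.endpoint}")
        add(f"Cohort:              {self.model.cohort.n_patients} patients, "
            f"{self.model.cohort.n_biopsies} AFI-targeted biopsies")
        add(f"Databases:           original + {self.ensemble.m} imputed")
        add(f"Bootstrap:           B={self.inclusion.B} per database, "
            f"threshold={self.inclusion.threshold}")
        add("")
        add("Median inclusion frequencies:")
        med = self.inclusion.medians.sort_values(ascending=False)
        for name, v in med.items():
            flag = " *" if name in self.selection.members else ""
            add(f"  {name:<14}{v:6.1f}{flag}")
        add("")
        if self.panel is None:
            add("No panel selected (no marker reached the threshold).")
        else:
            add(f"Selected panel:      {'+'.join(self.panel.members)}")
            add(f"Cut-off:             >= {self.panel.cutoff} positive markers")
            add(f"Evaluable patients:  {self.n_evaluable}")
            if self.metrics is not None:
                d = self.metrics.display()
                add(f"Sensitivity:         {d['sensitivity']} {d['sens_ci']}")
                add(f"Specificity:         {d['specificity']} {d['spec_ci']}")
                add(f"Accuracy:            {d['accuracy']}")
            if self.auc is not None:
                add(f"AUC:                 {self.auc.auc:.2f} "
                    f"(95% CI {self.auc.ci[0]:.2f} to {self.auc.ci[1]:.2f})")
        return "\n".join(lines)
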