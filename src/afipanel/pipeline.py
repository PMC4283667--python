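"""Config-driven end-to-end orchestration of the discovery pipeline.

Stage order mirrors the study design: generate (or load) a cohort →
per-biopsy association screening → multiple imputation → bootstrap panel
selection → per-patient evaluation (cut-off, metrics, AUC, exhaustive panel
search) → AFI+/AFI− comparison → protocol comparison → rater agreement →
external validation on a held-out cohort.  Every stage's randomness is
derived from the single run seed by hashing the stage name, so re-running
the same config reproduces every number bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .afi import compare_afi_auc
from .agreement import multi_rater_kappa
from .association import association_table
from .classify import exhaustive_panel_search
from .cohort import CohortTable, PanelDefinition, read_cohort, write_cohort
from .imputation import impute
from .model import PanelDiscovery
from .protocol import (
    biopsy_count_comparison,
    compare_sensitivity,
    paired_case_detection,
    protocol_table,
)
from .simulate import GeneratorParams, generate_cohort, generate_rater_panel

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the root seed (< 2**31)."""
    h = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % 2**31


@dataclass
class RunConfig:
    """Reproducibility contract for a full pipeline run."""

    seed: int = 0
    outdir: str = "afipanel_run"
    # cohort source: synthetic by default, or two CSV paths
    biopsies_path: str | None = None
    patients_path: str | None = None
    generator: dict = field(default_factory=dict)  # GeneratorParams overrides
    validation_n_patients: int = 46
    endpoint: str = "HGD_EC"
    m: int = 5
    n_cycles: int = 10
    B_selection: int = 100
    B_evaluation: int = 2000
    threshold: int = 90
    n_boot_auc: int = 2000
    n_boot_afi: int = 2000
    rater_cases: int = 20
    #: latent common-signal weight; 0.844 yields expected weighted kappa ~0.56
    rater_agreement_level: float = 0.844

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the consolidated report dict.

    Writes per-stage CSV/JSON artefacts plus figures and a manifest into
    ``config.outdir``.  Stage failures raise with the stage name; artefacts
    written before the failure are retained.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict(), "version": __version__}

    def stage(name):
        logger.info("stage: %s", name)
        return stage_seed(config.seed, name)

    # -- cohort ---------------------------------------------------------- #
    s = stage("generate")
    if config.biopsies_path:
        cohort = read_cohort(config.biopsies_path, config.patients_path)
        gen_params = None
    else:
        gen_params = GeneratorParams(**{**config.generator, "seed": s})
        cohort = generate_cohort(gen_params)
    write_cohort(cohort, out / "biopsies.csv", out / "patients.csv")
    if gen_params is not None:
        _write_json(out / "generator_params.json", asdict(gen_params))
    report["cohort"] = {
        "n_patients": cohort.n_patients,
        "n_biopsies": cohort.n_biopsies,
        "afi_split": list(cohort.afi_split()),
    }

    # -- association ----------------------------------------------------- #
    stage("associate")
    assoc = association_table(cohort)
    assoc.to_csv(out / "association.csv")
    (out / "association.md").write_text(assoc.round(4).to_markdown() + "\n")
    report["association_significant_hgdec"] = (
        assoc["hgdec_p"].lt(0.05).sum() if len(assoc) else 0
    )

    # -- discovery fit (imputation + selection + evaluation) ------------- #
    model = PanelDiscovery(
        cohort,
        endpoint=config.endpoint,
        m=config.m,
        n_cycles=config.n_cycles,
        B=config.B_selection,
        threshold=config.threshold,
        n_boot=config.n_boot_auc,
    )
    res = model.fit(seed=stage("discover"))
    res.inclusion.frequencies.to_csv(out / "inclusion_matrix.csv")
    _plot_inclusion(res.inclusion, out / "inclusion.png")
    (out / "summary.txt").write_text(res.summary() + "\n")
    report["inclusion_medians"] = res.inclusion.medians.to_dict()
    if res.panel is None:
        report["panel"] = None
        _write_json(out / "manifest.json", report)
        logger.warning("no panel selected; downstream stages skipped")
        return report
    report["panel"] = {"members": list(res.panel.members), "cutoff": res.panel.cutoff}
    report["internal"] = {
        "n_evaluable": res.n_evaluable,
        "sensitivity": res.metrics.sensitivity if res.metrics else None,
        "specificity": res.metrics.specificity if res.metrics else None,
        "auc": res.auc.auc if res.auc else None,
        "auc_ci": list(res.auc.ci) if res.auc else None,
    }

    # -- exhaustive search ------------------------------------------------ #
    ranking = exhaustive_panel_search(
        res.ensemble,
        n_boot=config.B_evaluation,
        seed=stage("search"),
        endpoint=config.endpoint,
    )
    ranking.to_csv(out / "panel_ranking.csv", index=False)
    report["search_top_panel"] = ranking.iloc[0]["panel"] if len(ranking) else None

    # -- AFI+ vs AFI− ----------------------------------------------------- #
    try:
        cmp = compare_afi_auc(
            res.ensemble, res.panel, n_boot=config.n_boot_afi, seed=stage("compare-afi"),
            endpoint=config.endpoint,
        )
        cmp.summary.to_csv(out / "afi_comparison.csv", index=False)
        _plot_afi(cmp, out / "afi_comparison.png")
        report["afi_comparison"] = {"p_value": cmp.p_value, "n_patients": cmp.n_patients}
    except ValueError as exc:
        logger.warning("AFI comparison skipped: %s", exc)
        report["afi_comparison"] = {"error": str(exc)}

    # -- protocol comparison ---------------------------------------------- #
    ptable = protocol_table(cohort, res.panel, endpoint=config.endpoint)
    ptable.to_csv(out / "protocol_comparison.csv")
    det_seattle, det_panel = paired_case_detection(
        cohort, "seattle_histology", "afi_biomarkers", panel=res.panel, endpoint=config.endpoint
    )
    report["protocol"] = {
        "table": ptable.to_dict(orient="index"),
        "mcnemar_seattle_vs_panel": compare_sensitivity(det_seattle, det_panel),
        "wilcoxon_biopsy_counts": biopsy_count_comparison(
            cohort, "seattle_histology", "afi_biomarkers"
        ),
    }

    # -- rater agreement --------------------------------------------------- #
    panel_ratings = generate_rater_panel(
        config.rater_cases, config.rater_agreement_level, seed=stage("agree")
    )
    kw, se = multi_rater_kappa(panel_ratings, weighted=True)
    report["agreement"] = {"weighted_kappa": kw, "se": se, "n_cases": config.rater_cases}

    # -- external validation ----------------------------------------------- #
    if gen_params is not None and config.validation_n_patients > 0:
        vparams = gen_params.with_(
            n_patients=config.validation_n_patients, seed=stage("validate")
        )
        vcohort = generate_cohort(vparams)
        write_cohort(vcohort, out / "validation_biopsies.csv", out / "validation_patients.csv")
        try:
            vmetrics = res.evaluate(vcohort)
            report["external"] = {
                "n_patients": vcohort.n_patients,
                "sensitivity": vmetrics.sensitivity,
                "specificity": vmetrics.specificity,
            }
        except ValueError as exc:
            report["external"] = {"error": str(exc)}

    _write_json(out / "manifest.json", report)
    return report


def _plot_inclusion(incl, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ax = incl.frequencies.plot.bar(figsize=(10, 4))
    ax.axhline(incl.threshold, color="k", linestyle="--", linewidth=1)
    ax.set_ylabel(f"inclusion frequency / {incl.B}")
    ax.set_title("Bootstrap inclusion frequencies per database")
    plt.tight_layout()
    plt.savefig(path, dpi=110)
    plt.close()


def _plot_afi(cmp, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(cmp.per_database)
    data, positions, colors = [], [], []
    for i, name in enumerate(names):
        pos, neg = cmp.per_database[name]
        data += [pos, neg]
        positions += [3 * i, 3 * i + 1]
        colors += ["tab:purple", "tab:green"]
    fig, ax = plt.subplots(figsize=(10, 4))
    bp = ax.boxplot(data, positions=positions, patch_artist=True, widths=0.8)
    for patch, c in zip(bp["boxes"], colors):
        patch.set_facecolor(c)
    ax.set_xticks([3 * i + 0.5 for i in range(len(names))])
    ax.set_xticklabels(names)
    ax.set_ylabel("bootstrap AUC")
    ax.set_title(f"Panel AUC from AFI+ (purple) vs AFI- (green) areas; p={cmp.p_value:.3g}")
    plt.tight_layout()
    plt.savefig(path, dpi=110)
    plt.close()
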