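"""End-to-end cohort analysis: one call replaying every stage on one cohort.

Stage order mirrors the published analysis: expression profiling
(IQR + clustering), panel scoring, median-split survival comparisons per
panel, the Th-1/Th-2 quadrant analysis with per-quadrant hazards and
checkpoint-expression overlay, variable importance (RSF + PCA + Cox),
maximally selected expression cutoffs, and the graphical-lasso network.

Every stage writes its tables under ``out_dir`` and contributes to a single
machine-readable ``report.json`` (schema version recorded, explicit nulls
for stages that were skipped, every seed echoed).  Re-running the same
config reproduces the report exactly: deterministic stages bit-for-bit,
stochastic stages through their recorded seeds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import network_from_expression
from .data_model import (
    Cohort,
    align_cohort,
    load_panels,
    read_clinical,
    read_expression,
)
from .exceptions import ConfigError, PcnslImmuneError
from .importance import RSFParams, importance_table
from .profiling import hierarchical_cluster, iqr_rank
from .scoring import compute_all_scores
from .stratification import (
    median_split,
    optimal_cutoff,
    overlay_by_quadrant,
    quadrant_hazards,
    quadrant_split,
)
from .survival import SurvivalComparison, compare_groups

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Everything one pipeline run needs; all seeds are recorded in the report."""

    out_dir: str | Path
    expression_path: str | Path | None = None
    clinical_path: str | Path | None = None
    panels: str = "pcnsl2019"
    seed: int = 0
    th1_panel: str = "Th1"
    th2_panel: str = "Th2"
    reference_quadrant: str = "Th1hiTh2lo"
    min_group_frac: float = 0.1
    ties: str = "efron"
    cutoff_permutations: int = 0
    n_cutoff_variants: int = 5          # top-IQR variants scanned for cutoffs
    rsf_params: RSFParams | None = None
    run_importance: bool = True
    network_rho: float | None = None    # None = EBIC-selected

    def validate_paths(self) -> None:
        for label, p in (("expression", self.expression_path), ("clinical", self.clinical_path)):
            if p is None:
                raise ConfigError(f"RunConfig.{label}_path is required")
            if not Path(p).exists():
                raise ConfigError(f"{label} file not found: {p}")


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    return obj


def _comparison_payload(comp: SurvivalComparison) -> dict:
    return {
        "groups": {
            lab: {"n": int(curve.n_risk[0]) if curve.n_risk.size else 0,
                  "median_survival": curve.median}
            for lab, curve in comp.curves.items()
        },
        "logrank_statistic": comp.logrank.statistic,
        "logrank_df": comp.logrank.df,
        "logrank_p": comp.logrank.p_value,
        "reference": comp.reference,
        "hr": comp.hr,
        "ci95": list(comp.ci95) if comp.ci95 else None,
        "hr_p": comp.hr_p,
        "notes": dict(comp.notes),
    }


def run_pipeline(cfg: RunConfig, cohort: Cohort | None = None) -> dict:
    """Run every stage on a cohort and write the output directory.

    The cohort is read from ``cfg.expression_path``/``cfg.clinical_path``
    unless one is passed in directly.  A stage failure aborts the run with
    the stage name while keeping the outputs already written on disk.
    """
    if cohort is None:
        cfg.validate_paths()
        cohort = align_cohort(read_expression(cfg.expression_path), read_clinical(cfg.clinical_path))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panels = load_panels(cfg.panels)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
        "seed": cfg.seed,
        "n_samples": cohort.n_samples,
        "panels": {name: len(p) for name, p in panels.items()},
        "stages": {},
    }
    stage = "profiling"
    try:
        iqr = iqr_rank(cohort.expression)
        iqr.to_csv(out / "iqr.tsv", sep="\t", header=True)
        dend = hierarchical_cluster(cohort.expression, axis="samples")
        (out / "dendrogram_samples.nwk").write_text(dend.to_newick() + "\n")
        pd.Series(dend.leaf_order, name="sample").to_csv(out / "leaf_order.tsv", sep="\t", index=False)
        report["stages"]["profiling"] = {
            "top_iqr": _jsonify(iqr.head(10).to_dict()),
            "linkage": dend.linkage,
            "metric": dend.metric,
            "dropped_rows": dend.dropped,
        }

        stage = "scoring"
        scores = compute_all_scores(cohort, panels)
        score_frame = pd.DataFrame({name: sv.scores for name, sv in scores.items()})
        score_frame.to_csv(out / "scores.tsv", sep="\t", index_label="sample")
        report["stages"]["scoring"] = {
            name: {"checksum": sv.checksum, "transform": sv.transform,
                   "median": float(sv.scores.median())}
            for name, sv in scores.items()
        }

        stage = "median_split_survival"
        median_payload = {}
        for name, sv in scores.items():
            assignment = median_split(sv, source=name)
            comp = compare_groups(
                cohort.clinical.os_days, cohort.clinical.event,
                assignment.labels.to_numpy(), reference="low", ties=cfg.ties,
            )
            median_payload[name] = {
                "threshold": assignment.rule.thresholds[0],
                "counts": assignment.counts,
                **_comparison_payload(comp),
            }
        report["stages"]["median_split_survival"] = _jsonify(median_payload)

        stage = "quadrants"
        quad_payload = None
        if cfg.th1_panel in scores and cfg.th2_panel in scores:
            quad = quadrant_split(scores[cfg.th1_panel], scores[cfg.th2_panel],
                                  sources=(cfg.th1_panel, cfg.th2_panel))
            quad.labels.rename("quadrant").to_csv(out / "quadrants.tsv", sep="\t",
                                                  index_label="sample", header=True)
            hazards = quadrant_hazards(quad, cohort.clinical, reference=cfg.reference_quadrant)
            overlay = overlay_by_quadrant(scores, quad)
            overlay.to_csv(out / "overlay_by_quadrant.tsv", sep="\t", index=False)
            quad_payload = {
                "thresholds": list(quad.rule.thresholds),
                "counts": quad.counts,
                "hazards_vs_reference": {q: _comparison_payload(c) for q, c in hazards.items()},
                "overlay_anova_p": overlay.groupby("feature")["anova_p"].first().to_dict(),
            }
        report["stages"]["quadrants"] = _jsonify(quad_payload)

        stage = "importance"
        imp_payload = None
        if cfg.run_importance:
            params = cfg.rsf_params or RSFParams(n_trees=50, seed=cfg.seed)
            table = importance_table(cohort, params, vimp_seed=cfg.seed)
            table.to_csv(out / "importance.tsv", sep="\t", index_label="variant")
            imp_payload = {
                "rsf_seed": params.seed,
                "vimp_seed": cfg.seed,
                "n_trees": params.n_trees,
                "index_method": table.attrs["index_method"],
                "top_variants": _jsonify(table.head(10)["index"].to_dict()),
            }
        report["stages"]["importance"] = imp_payload

        stage = "cutoffs"
        cut_payload = {}
        candidates = iqr.head(cfg.n_cutoff_variants).index.tolist()
        for v in candidates:
            vals = cohort.expression.data.loc[v]
            try:
                rule, comp = optimal_cutoff(
                    vals, cohort.clinical.os_days, cohort.clinical.event,
                    min_group_frac=cfg.min_group_frac, source=v,
                    n_permutations=cfg.cutoff_permutations, seed=cfg.seed,
                )
            except PcnslImmuneError as exc:
                cut_payload[v] = {"error": str(exc)}
                continue
            cut_payload[v] = {"cutoff": rule.thresholds[0], **_comparison_payload(comp)}
        report["stages"]["cutoffs"] = _jsonify(cut_payload)

        stage = "network"
        net = network_from_expression(cohort.expression, rho=cfg.network_rho)
        net.edges.to_csv(out / "network_edges.tsv", sep="\t", index=False)
        report["stages"]["network"] = _jsonify({
            "rho": net.rho,
            "n_edges": len(net.edges),
            "hubs": net.hubs,
            "max_degree": int(net.degrees.max()) if len(net.degrees) else 0,
        })
    except Exception as exc:
        (out / "report.json").write_text(json.dumps(_jsonify(report), indent=2))
        raise PcnslImmuneError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "report.json").write_text(json.dumps(_jsonify(report), indent=2))
    logger.info("pipeline complete: %s", out / "report.json")
    return report
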