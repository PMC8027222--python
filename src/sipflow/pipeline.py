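"""End-to-end orchestration: per-dataset DE analysis and the cross-dataset
integration, as plain functions over bundles so the CLI, the analysis scripts
and the simulator benchmarks all share one code path.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import integrate, normfilter, stagewise, testing
from .ingest import ExperimentBundle
from .nbglm import build_design, estimate_dispersions, fit_glm
from .normfilter import FilterResult
from .testing import ThresholdSpec


@dataclass
class PipelineConfig:
    """Knobs of the workflow, with the study's defaults."""

    fold_change: float = 3.0          # tau = log(3) on the model scale
    alpha: float = 0.05               # OFDR target of the stage-wise procedure
    alpha_equiv: float = 0.05         # per-timepoint TOST level
    cpm_threshold: float = 1.0
    min_samples: int | None = None    # default: smallest group size
    prior_df: float = 10.0            # dispersion shrinkage strength
    equivalence_mode: str = "all_shared_timepoints"  # or "de_timepoints_only"
    seed: int = 1

    def __post_init__(self) -> None:
        if not self.fold_change > 1:
            raise ValueError("fold_change must exceed 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @property
    def threshold(self) -> ThresholdSpec:
        return ThresholdSpec(self.fold_change)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class DatasetResult:
    """Everything the integration and the reports need from one dataset."""

    bundle: ExperimentBundle
    factors: pd.DataFrame
    filter: FilterResult
    kept_genes: list[str]
    contrasts: pd.DataFrame           # long per-gene per-timepoint table
    decisions: stagewise.DecisionTable
    lfc: pd.DataFrame                 # genes x timepoints, log2
    dispersions: object
    timepoints: list[int]


def run_dataset(bundle: ExperimentBundle,
                cfg: PipelineConfig | None = None) -> DatasetResult:
    """Normalize, filter, fit NB GLMs and test one dataset.

    Produces per-timepoint ordinary/threshold/equivalence p-values and the
    stage-wise OFDR decisions over the kept genes.
    """
    cfg = cfg or PipelineConfig()
    factors = normfilter.tmm_factors(bundle)
    filt = normfilter.filter_low(bundle, factors,
                                 cpm_threshold=cfg.cpm_threshold,
                                 min_samples=cfg.min_samples)
    kept = filt.kept
    counts = bundle.counts.counts.loc[kept].to_numpy()
    offsets = np.log(factors.loc[bundle.counts.sample_ids,
                                 "effective_size"].to_numpy())
    design = build_design(bundle.samples, "timepoint_by_condition",
                          offsets=offsets)
    design_red = build_design(bundle.samples, "timepoint_only",
                              offsets=offsets)

    disp = estimate_dispersions(counts, design, prior_df=cfg.prior_df)
    fit = fit_glm(counts, design, disp.tagwise, gene_ids=kept)
    fit_red = fit_glm(counts, design_red, disp.tagwise, gene_ids=kept)

    contrasts = testing.treatment_contrasts(design)
    thr = cfg.threshold
    table = testing.contrast_results(fit, contrasts, thr, gene_ids=kept)
    tps = [c.timepoint for c in contrasts]
    p_confirm = np.column_stack(
        [testing.test_de_threshold(fit, c, thr) for c in contrasts])
    p_equiv = np.column_stack(
        [testing.test_equivalence(fit, c, thr) for c in contrasts])
    p_screen = testing.screen_omnibus(fit, fit_red)
    decisions = stagewise.stagewise_decisions(
        p_screen, p_confirm, alpha=cfg.alpha, p_equiv=p_equiv,
        alpha_equiv=cfg.alpha_equiv, genes=kept, timepoints=tps)
    lfc = table.pivot(index="gene_id", columns="timepoint", values="lfc_log2")
    lfc = lfc.reindex(kept)
    return DatasetResult(bundle=bundle, factors=factors, filter=filt,
                         kept_genes=kept, contrasts=table, decisions=decisions,
                         lfc=lfc, dispersions=disp, timepoints=tps)


def run_integration(res_plus: DatasetResult, res_minus: DatasetResult,
                    cfg: PipelineConfig | None = None,
                    build_evidence: bool = True
                    ) -> integrate.GeneClassification:
    """Classify genes over the timepoints shared by both datasets."""
    cfg = cfg or PipelineConfig()
    shared = integrate.shared_timepoints(res_plus.bundle.samples,
                                         res_minus.bundle.samples)
    return integrate.classify_genes(
        res_plus.decisions, res_minus.decisions,
        res_plus.filter, res_minus.filter, shared,
        lfc_plus=res_plus.lfc, lfc_minus=res_minus.lfc,
        equivalence_mode=cfg.equivalence_mode,
        build_evidence=build_evidence)


def write_dataset_outputs(res: DatasetResult, outdir: str | Path,
                          prefix: str) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    res.factors.to_csv(outdir / f"{prefix}_norm_factors.tsv", sep="\t")
    res.contrasts.to_csv(outdir / f"{prefix}_contrasts.tsv", sep="\t",
                         index=False)
    res.decisions.frame().to_csv(outdir / f"{prefix}_decisions.tsv", sep="\t",
                                 index=False)
    filt = pd.DataFrame({
        "gene_id": res.filter.kept + res.filter.filtered,
        "status": (["kept"] * len(res.filter.kept)
                   + ["filtered"] * len(res.filter.filtered)),
    })
    filt.to_csv(outdir / f"{prefix}_filter.tsv", sep="\t", index=False)
    disp = res.dispersions
    pd.DataFrame({
        "gene_id": res.kept_genes,
        "ave_log_cpm": disp.ave_log_cpm,
        "dispersion_raw": disp.raw,
        "dispersion_trended": disp.trended,
        "dispersion_tagwise": disp.tagwise,
    }).to_csv(outdir / f"{prefix}_dispersions.tsv", sep="\t", index=False)


def run_pipeline(bundle_plus: ExperimentBundle, bundle_minus: ExperimentBundle,
                 cfg: PipelineConfig | None = None,
                 outdir: str | Path | None = None) -> dict:
    """Full two-dataset workflow; optionally writes all result tables.

    Returns a dict with both :class:`DatasetResult` objects, the
    classification and the report.
    """
    cfg = cfg or PipelineConfig()
    res_plus = run_dataset(bundle_plus, cfg)
    res_minus = run_dataset(bundle_minus, cfg)
    cls = run_integration(res_plus, res_minus, cfg)
    report = integrate.classification_report(cls)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_dataset_outputs(res_plus, outdir, "MTplus")
        write_dataset_outputs(res_minus, outdir, "MTminus")
        cls.table.to_csv(outdir / "classification.tsv", sep="\t", index=False)
        cls.evidence.to_csv(outdir / "evidence.tsv", sep="\t", index=False)
        manifest = {
            "config": asdict(cfg),
            "config_digest": cfg.digest(),
            "n_genes_plus": res_plus.bundle.n_genes,
            "n_genes_minus": res_minus.bundle.n_genes,
            "class_counts": {k: int(v) for k, v in cls.counts().items()},
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"plus": res_plus, "minus": res_minus, "classification": cls,
            "report": report}
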