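"""Synthetic two-mating-type time-series generator with planted gene classes,
plus evaluation harnesses for classification recovery and OFDR control.

The generator emulates the study layout: an MT+ experiment with a dark
control at 0 h plus five post-illumination timepoints x {control, treated} x
3 replicates, and an MT- side made of two batches (15 min/1 h/3 h, and 10 h).
Counts are negative binomial with a gene-wise mean-dispersion trend, a
dark-to-light temporal trend shared by both conditions (so the cell-means
design absorbs it), and per-sample library sizes. Planted classes:

* SRB   — responsive above the fold-change margin in both datasets;
* SRP   — responsive in MT+, true fold change inside the margin in MT-;
* SRM   — the mirror image;
* filtered_minus / filtered_plus — responsive in one dataset, essentially
  unexpressed (below the CPM filter) in the other: the "diamond" genes;
* null  — true log2 fold changes within +/-0.2 everywhere.

MT- effect magnitudes default to 1.25x the MT+ magnitudes, echoing the
stronger response of that mating type.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .ingest import CountMatrix, ExperimentBundle, bundle, make_sample_table
from .integrate import GeneClassification
from .pipeline import PipelineConfig, run_dataset, run_integration

TRUE_CLASSES = ("SRB", "SRP", "SRM", "filtered_minus", "filtered_plus", "null")

#: expected integrative call for each planted class ("diamond" genes are
#: responsive in one dataset and filtered in the other, so their correct call
#: is the corresponding one-sided class)
EXPECTED_CALL = {
    "SRB": "SRB", "SRP": "SRP", "SRM": "SRM",
    "filtered_minus": "SRP", "filtered_plus": "SRM",
    "null": "nonresponsive",
}


@dataclass
class SimConfig:
    """Study-shaped simulation settings (defaults are the desk-scale study
    conditions)."""

    n_genes: int = 10000
    timepoints_plus: tuple = (0, 15, 60, 180, 360, 540)   # 0 = control-only
    timepoints_minus_a: tuple = (15, 60, 180)
    timepoints_minus_b: tuple = (600,)
    reps: int = 3
    n_srb: int = 200
    n_srp: int = 100
    n_srm: int = 100
    n_filtered_minus: int = 100
    n_filtered_plus: int = 100
    lfc_range_log2: tuple = (np.log2(3.0) + 0.5, 4.0)
    null_lfc_max_log2: float = 0.2
    minus_lfc_scale: float = 1.25
    baseline_meanlog: float = float(np.log(30.0))
    baseline_sdlog: float = 1.5
    responder_meanlog: float = float(np.log(100.0))
    responder_sdlog: float = 1.0
    filtered_mean: float = 0.05          # mean counts of the unexpressed side
    disp_a: float = 1.0                  # phi = a/mu + b
    disp_b: float = 0.05
    disp_cap: float = 5.0
    lib_size_range: tuple = (0.5e6, 2.0e6)
    trend_sd_log2: float = 1.0           # dark-to-light amplitude spread
    trend_on: bool = True
    seed: int = 1

    def __post_init__(self) -> None:
        total = (self.n_srb + self.n_srp + self.n_srm
                 + self.n_filtered_minus + self.n_filtered_plus)
        if total > self.n_genes:
            raise ValueError(f"class counts ({total}) exceed n_genes")
        if self.lfc_range_log2[0] <= np.log2(3.0) - 1e-12:
            raise ValueError("responder LFCs must exceed the log2(3) margin")
        if self.null_lfc_max_log2 >= np.log2(3.0):
            raise ValueError("null LFCs must stay inside the margin")

    def scaled(self, n_genes: int) -> "SimConfig":
        """Same scenario at a different gene count, class sizes pro-rated."""
        f = n_genes / self.n_genes
        return replace(
            self, n_genes=n_genes,
            n_srb=int(round(self.n_srb * f)),
            n_srp=int(round(self.n_srp * f)),
            n_srm=int(round(self.n_srm * f)),
            n_filtered_minus=int(round(self.n_filtered_minus * f)),
            n_filtered_plus=int(round(self.n_filtered_plus * f)),
        )


@dataclass
class TruthTable:
    """Planted ground truth: class, per-(dataset, timepoint) log2 LFCs,
    baselines and dispersions."""

    table: pd.DataFrame

    def lfc_matrix(self, dataset: str, timepoints: list[int]) -> np.ndarray:
        cols = [f"lfc_{dataset}_t{t}" for t in timepoints]
        return self.table[cols].to_numpy(dtype=float)

    def classes(self) -> pd.Series:
        return self.table["true_class"]


def _trend_shape(t: np.ndarray) -> np.ndarray:
    # saturating response to illumination, 0 at the dark timepoint
    return np.log1p(np.asarray(t, dtype=float)) / np.log1p(600.0)


def _sample_table(dataset: str, mating_type: str, cells: list[tuple],
                  reps: int, batch_of) -> pd.DataFrame:
    rows = []
    for t, cond in cells:
        for r in range(1, reps + 1):
            rows.append({
                "sample_id": f"{dataset}_t{t}_{cond}_r{r}",
                "dataset": dataset,
                "mating_type": mating_type,
                "timepoint": t,
                "condition": cond,
                "replicate": r,
                "experiment_batch": batch_of(t),
            })
    return make_sample_table(pd.DataFrame(rows))


def simulate_experiment(cfg: SimConfig | None = None
                        ) -> tuple[ExperimentBundle, ExperimentBundle,
                                   TruthTable]:
    """Draw both datasets and the ground truth, reproducibly from cfg.seed."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    G = cfg.n_genes
    gene_ids = [f"g{i:05d}" for i in range(G)]

    sizes = [cfg.n_srb, cfg.n_srp, cfg.n_srm,
             cfg.n_filtered_minus, cfg.n_filtered_plus]
    sizes.append(G - sum(sizes))
    classes = np.repeat(TRUE_CLASSES, sizes)

    responder_like = np.isin(classes, ("SRB", "SRP", "SRM",
                                       "filtered_minus", "filtered_plus"))
    base = np.exp(rng.normal(cfg.baseline_meanlog, cfg.baseline_sdlog, G))
    base_resp = np.exp(rng.normal(cfg.responder_meanlog, cfg.responder_sdlog,
                                  G))
    base = np.where(responder_like, base_resp, base)
    base_plus = np.where(classes == "filtered_plus", cfg.filtered_mean, base)
    base_minus = np.where(classes == "filtered_minus", cfg.filtered_mean, base)

    def _phi(b: np.ndarray) -> np.ndarray:
        return np.minimum(cfg.disp_a / np.maximum(b, 1e-8) + cfg.disp_b,
                          cfg.disp_cap)

    phi_plus, phi_minus = _phi(base_plus), _phi(base_minus)
    amp = (rng.normal(0.0, cfg.trend_sd_log2, G) if cfg.trend_on
           else np.zeros(G))

    lo, hi = cfg.lfc_range_log2
    mag = rng.uniform(lo, hi, G)
    sign = rng.choice([-1.0, 1.0], G)
    effect = mag * sign
    null_small_plus = rng.uniform(-cfg.null_lfc_max_log2,
                                  cfg.null_lfc_max_log2, G)
    null_small_minus = rng.uniform(-cfg.null_lfc_max_log2,
                                   cfg.null_lfc_max_log2, G)
    resp_plus = np.isin(classes, ("SRB", "SRP", "filtered_minus"))
    resp_minus = np.isin(classes, ("SRB", "SRM", "filtered_plus"))
    lfc_plus = np.where(resp_plus, effect, null_small_plus)
    lfc_minus = np.where(resp_minus, effect * cfg.minus_lfc_scale,
                         null_small_minus)

    cells_plus = [(0, "control")] + [
        (t, c) for t in cfg.timepoints_plus if t != 0
        for c in ("control", "treated")]
    cells_minus = [(t, c)
                   for t in (*cfg.timepoints_minus_a, *cfg.timepoints_minus_b)
                   for c in ("control", "treated")]
    samples_plus = _sample_table(
        "MTplus", "MTplus", cells_plus, cfg.reps, lambda t: "plusA")
    samples_minus = _sample_table(
        "MTminus", "MTminus", cells_minus, cfg.reps,
        lambda t: "minusB" if t in cfg.timepoints_minus_b else "minusA")

    def _draw(samples: pd.DataFrame, baseline, phi, lfc_log2) -> pd.DataFrame:
        lib = rng.uniform(*cfg.lib_size_range, len(samples))
        cols = {}
        for j, row in samples.iterrows():
            t = int(row["timepoint_min"])
            treated = row["condition"] == "treated"
            log2_mu = (np.log2(baseline) + amp * _trend_shape(t)
                       + (lfc_log2 if treated else 0.0))
            mu = np.exp2(log2_mu) * (lib[j] / 1e6)
            lam = rng.gamma(shape=1.0 / phi, scale=phi * mu)
            cols[row["sample_id"]] = rng.poisson(lam)
        return pd.DataFrame(cols, index=gene_ids)

    counts_plus = _draw(samples_plus, base_plus, phi_plus, lfc_plus)
    counts_minus = _draw(samples_minus, base_minus, phi_minus, lfc_minus)
    bundle_plus = bundle(CountMatrix(counts_plus), samples_plus)
    bundle_minus = bundle(CountMatrix(counts_minus), samples_minus)

    truth = pd.DataFrame({"gene_id": gene_ids, "true_class": classes,
                          "baseline_plus": base_plus,
                          "baseline_minus": base_minus,
                          "dispersion_plus": phi_plus,
                          "dispersion_minus": phi_minus,
                          "trend_amplitude": amp}).set_index("gene_id")
    for t in cfg.timepoints_plus:
        if t != 0:
            truth[f"lfc_plus_t{t}"] = lfc_plus
    for t in (*cfg.timepoints_minus_a, *cfg.timepoints_minus_b):
        truth[f"lfc_minus_t{t}"] = lfc_minus
    return bundle_plus, bundle_minus, TruthTable(truth)


def evaluate_classification(cls: GeneClassification,
                            truth: TruthTable) -> dict:
    """Per-class recall/precision, key-gene FDP and the confusion matrix.

    Expected calls follow :data:`EXPECTED_CALL`; the false-discovery
    proportion counts genes claimed SRB/SRP/SRM whose planted class is null.
    """
    table = cls.table.set_index("gene_id")
    genes = truth.table.index
    missing = genes.difference(table.index)
    if len(missing):
        raise ValueError(f"classification lacks genes, e.g. {list(missing)[:5]}")
    claimed = table.loc[genes, "gene_class"].to_numpy()
    true_cls = truth.classes().to_numpy()
    expected = np.array([EXPECTED_CALL[c] for c in true_cls])

    metrics: dict = {}
    for c in ("SRB", "SRP", "SRM"):
        is_expected = expected == c
        is_claimed = claimed == c
        tp = int((is_expected & is_claimed).sum())
        metrics[f"recall_{c}"] = (tp / is_expected.sum()
                                  if is_expected.any() else np.nan)
        metrics[f"precision_{c}"] = (tp / is_claimed.sum()
                                     if is_claimed.any() else np.nan)
    discovered = np.isin(claimed, ("SRB", "SRP", "SRM"))
    n_disc = int(discovered.sum())
    metrics["fdp_key_genes"] = (
        float((discovered & (true_cls == "null")).sum() / n_disc)
        if n_disc else 0.0)
    metrics["n_discovered"] = n_disc
    metrics["confusion"] = pd.crosstab(
        pd.Series(true_cls, name="truth"), pd.Series(claimed, name="claimed"))
    return metrics


def _dataset_ofdr(decisions, truth: TruthTable, dataset: str,
                  timepoints: list[int], fold_change: float) -> float:
    """Fraction of genes without a true above-margin fold change among all
    genes with any confirmed rejection."""
    lfc = truth.lfc_matrix(dataset, timepoints)
    truly_resp = (np.abs(lfc) >= np.log2(fold_change)).any(axis=1)
    resp_map = pd.Series(truly_resp, index=truth.table.index)
    rejected = np.asarray(decisions.genes)[decisions.any_confirmed()]
    if len(rejected) == 0:
        return 0.0
    return float((~resp_map.loc[rejected]).mean())


def run_ofdr_experiment(cfg: SimConfig | None = None, n_reps: int = 25,
                        alpha: float = 0.05,
                        pipeline_cfg: PipelineConfig | None = None) -> dict:
    """Replicate the full per-dataset stage-wise workflow and measure the
    empirical gene-level OFDR, key-gene FDP and per-class recovery.

    Replicate r uses seed cfg.seed + r; results are averaged with Monte-Carlo
    standard errors.
    """
    cfg = cfg or SimConfig()
    if n_reps < 1:
        raise ValueError("need at least one replicate")
    pcfg = pipeline_cfg or PipelineConfig(alpha=alpha)
    rows = []
    for r in range(n_reps):
        rep_cfg = replace(cfg, seed=cfg.seed + r)
        b_plus, b_minus, truth = simulate_experiment(rep_cfg)
        res_plus = run_dataset(b_plus, pcfg)
        res_minus = run_dataset(b_minus, pcfg)
        cls = run_integration(res_plus, res_minus, pcfg, build_evidence=False)
        ev = evaluate_classification(cls, truth)
        rows.append({
            "seed": rep_cfg.seed,
            "ofdr_plus": _dataset_ofdr(res_plus.decisions, truth, "plus",
                                       res_plus.timepoints, pcfg.fold_change),
            "ofdr_minus": _dataset_ofdr(res_minus.decisions, truth, "minus",
                                        res_minus.timepoints,
                                        pcfg.fold_change),
            "fdp_key_genes": ev["fdp_key_genes"],
            "recall_SRB": ev["recall_SRB"],
            "recall_SRP": ev["recall_SRP"],
            "recall_SRM": ev["recall_SRM"],
            "precision_SRB": ev["precision_SRB"],
            "precision_SRP": ev["precision_SRP"],
            "precision_SRM": ev["precision_SRM"],
        })
    reps = pd.DataFrame(rows)
    ofdr_all = np.concatenate([reps["ofdr_plus"], reps["ofdr_minus"]])
    summary = {
        "alpha": alpha,
        "n_reps": n_reps,
        "mean_ofdr": float(ofdr_all.mean()),
        "se_ofdr": float(ofdr_all.std(ddof=1) / np.sqrt(len(ofdr_all))),
        "mean_ofdr_plus": float(reps["ofdr_plus"].mean()),
        "mean_ofdr_minus": float(reps["ofdr_minus"].mean()),
        "mean_fdp_key_genes": float(reps["fdp_key_genes"].mean()),
        "se_fdp_key_genes": float(reps["fdp_key_genes"].std(ddof=1)
                                  / np.sqrt(n_reps)) if n_reps > 1 else 0.0,
    }
    for c in ("SRB", "SRP", "SRM"):
        summary[f"mean_recall_{c}"] = float(reps[f"recall_{c}"].mean())
        summary[f"mean_precision_{c}"] = float(reps[f"precision_{c}"].mean())
    return {"summary": summary, "replicates": reps}


def run_enrichment_fdr_experiment(n_terms: int = 500,
                                  term_size_range: tuple = (5, 200),
                                  universe_size: int = 8000,
                                  set_size: int = 300, n_reps: int = 50,
                                  alpha: float = 0.05, seed: int = 1) -> dict:
    """Empirical FDR of hypergeometric enrichment under random gene sets.

    The annotation is simulated once (from ``seed``); each replicate draws a
    uniformly random gene set, so every BH-significant term is a false call.
    A replicate's false-call fraction is 1 if it has any significant term,
    else 0.
    """
    from .enrich import hypergeom_enrich

    rng = np.random.default_rng(seed)
    universe = [f"g{i:05d}" for i in range(universe_size)]
    annotation = {
        f"T{j:04d}": set(rng.choice(universe,
                                    rng.integers(term_size_range[0],
                                                 term_size_range[1] + 1),
                                    replace=False))
        for j in range(n_terms)
    }
    fdp = []
    for r in range(n_reps):
        rep_rng = np.random.default_rng(seed + r)
        gene_set = rep_rng.choice(universe, set_size, replace=False)
        res = hypergeom_enrich(gene_set, universe, annotation, alpha=alpha)
        n_sig = int(res["significant"].sum())
        fdp.append(1.0 if n_sig > 0 else 0.0)
    fdp = np.asarray(fdp)
    return {
        "alpha": alpha,
        "n_reps": n_reps,
        "mean_fdr": float(fdp.mean()),
        "se_fdr": float(fdp.std(ddof=1) / np.sqrt(n_reps)),
        "per_replicate": fdp,
    }
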