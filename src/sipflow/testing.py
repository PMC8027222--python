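"""Per-gene, per-timepoint hypothesis tests on fitted NB GLMs.

Four tests share one fitted model:

* ordinary Wald DE test of H0: contrast effect = 0;
* a fold-change-threshold (TREAT-style) test of H0: |effect| <= tau, whose
  rejection claims biologically meaningful differential expression;
* a TOST equivalence test of H0: |effect| >= tau, whose rejection is positive
  evidence that the effect lies inside the fold-change margin;
* a likelihood-ratio omnibus screen of any treatment effect at any timepoint.

Effects are natural-log fold changes internally; results report log2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .nbglm import DesignMatrix, GLMFit

LOG2E_RATIO = np.log(2.0)  # natural-log units per log2 unit


@dataclass(frozen=True)
class ThresholdSpec:
    """Fold-change margin tau used by both the threshold-DE and equivalence
    tests. ``fold_change=3`` gives tau = log(3) on the model (natural-log)
    scale and log2(3) on the reporting scale."""

    fold_change: float = 3.0

    def __post_init__(self) -> None:
        # fold_change = 1 (tau = 0) is the degenerate margin at which the
        # threshold test reduces to the ordinary test
        if not self.fold_change >= 1.0:
            raise ValueError("fold_change must be at least 1")

    @property
    def tau_natural(self) -> float:
        return float(np.log(self.fold_change))

    @property
    def tau_log2(self) -> float:
        return float(np.log2(self.fold_change))


@dataclass(frozen=True)
class Contrast:
    """A named linear combination of design coefficients."""

    name: str
    weights: tuple
    timepoint: int

    def vector(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)


def treatment_contrasts(design: DesignMatrix) -> list[Contrast]:
    """Treated-minus-control contrast at every timepoint with both arms."""
    cols = design.colnames
    out = []
    tps = sorted({int(c.split("_")[0][1:]) for c in cols if "_" in c})
    for t in tps:
        trt, ctl = f"t{t}_treated", f"t{t}_control"
        if trt in cols and ctl in cols:
            w = np.zeros(len(cols))
            w[cols.index(trt)] = 1.0
            w[cols.index(ctl)] = -1.0
            out.append(Contrast(name=f"t{t}_treated_vs_control",
                                weights=tuple(w), timepoint=t))
    return out


def contrast_estimate(fit: GLMFit, contrast: Contrast
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene contrast effect (natural log) and its Wald standard error."""
    c = contrast.vector()
    est = fit.beta @ c
    var = np.einsum("p,gpq,q->g", c, fit.cov, c)
    se = np.sqrt(np.maximum(var, 0.0))
    return est, se


def _safe_z(est: np.ndarray, se: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    bad = ~np.isfinite(se) | (se <= 0)
    se_safe = np.where(bad, 1.0, se)
    return np.where(bad, 0.0, est / se_safe), bad


def test_de(fit: GLMFit, contrast: Contrast) -> np.ndarray:
    """Two-sided Wald p-value for H0: effect = 0. Degenerate SEs give p=1."""
    est, se = contrast_estimate(fit, contrast)
    z, bad = _safe_z(est, se)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return np.where(bad, 1.0, p)


def test_de_threshold(fit: GLMFit, contrast: Contrast,
                      thr: ThresholdSpec) -> np.ndarray:
    """TREAT-style p-value for H0: |effect| <= tau.

    With t = |estimate|/se and tau_s = tau/se,
    p = P(Z > t - tau_s) + P(Z > t + tau_s); at tau = 0 this reduces to the
    ordinary two-sided Wald test.
    """
    est, se = contrast_estimate(fit, contrast)
    z, bad = _safe_z(est, se)
    t = np.abs(z)
    tau_s = thr.tau_natural / np.where(bad | (se <= 0), 1.0, se)
    p = stats.norm.sf(t - tau_s) + stats.norm.sf(t + tau_s)
    return np.where(bad, 1.0, np.minimum(p, 1.0))


def test_equivalence(fit: GLMFit, contrast: Contrast,
                     thr: ThresholdSpec) -> np.ndarray:
    """TOST p-value for H0: |effect| >= tau (rejection claims equivalence).

    p1 = 1 - Phi((b + tau)/se), p2 = Phi((b - tau)/se), p = max(p1, p2).
    Genes with a degenerate cell (not expressed in one arm) get p = 1: absence
    of expression is never evidence of equivalence.
    """
    est, se = contrast_estimate(fit, contrast)
    bad = ~np.isfinite(se) | (se <= 0)
    se_safe = np.where(bad, 1.0, se)
    tau = thr.tau_natural
    p1 = stats.norm.sf((est + tau) / se_safe)
    p2 = stats.norm.cdf((est - tau) / se_safe)
    p = np.maximum(p1, p2)
    c = contrast.vector()
    involved = np.abs(c) > 0
    degenerate = fit.low_cell[:, involved].any(axis=1)
    return np.where(bad | degenerate, 1.0, p)


def screen_omnibus(fit_full: GLMFit, fit_reduced: GLMFit) -> np.ndarray:
    """Likelihood-ratio screen of any treatment effect at any timepoint.

    The statistic is the deviance difference between the no-treatment
    (timepoint-only) fit and the full cell-means fit, referred to chi-square
    with df = number of extra parameters. Both fits must use the same
    dispersions.
    """
    df = fit_full.design.n_params - fit_reduced.design.n_params
    if df < 1:
        raise ValueError("reduced design is not nested below the full design")
    stat = fit_reduced.deviance - fit_full.deviance
    if np.any(stat < -1e-6 * (1 + np.abs(fit_full.deviance))):
        worst = float(np.min(stat))
        raise RuntimeError(f"negative LRT statistic ({worst:.3g}): fit failure")
    stat = np.maximum(stat, 0.0)
    return stats.chi2.sf(stat, df)


def contrast_results(fit: GLMFit, contrasts: list[Contrast],
                     thr: ThresholdSpec,
                     gene_ids: list[str] | None = None) -> pd.DataFrame:
    """Long table of per-gene, per-timepoint effects and p-values.

    Columns: gene_id, timepoint, lfc_log2, se_log2, p_de, p_threshold,
    p_equiv, degenerate.
    """
    gene_ids = gene_ids if gene_ids is not None else fit.gene_ids
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(fit.beta.shape[0])]
    frames = []
    for con in contrasts:
        est, se = contrast_estimate(fit, con)
        involved = np.abs(con.vector()) > 0
        degenerate = fit.low_cell[:, involved].any(axis=1)
        frames.append(pd.DataFrame({
            "gene_id": gene_ids,
            "timepoint": con.timepoint,
            "lfc_log2": est / LOG2E_RATIO,
            "se_log2": se / LOG2E_RATIO,
            "p_de": test_de(fit, con),
            "p_threshold": test_de_threshold(fit, con, thr),
            "p_equiv": test_equivalence(fit, con, thr),
            "degenerate": degenerate,
        }))
    return pd.concat(frames, ignore_index=True)
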