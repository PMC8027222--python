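"""Stage-wise multiple testing: BH screening plus per-timepoint confirmation.

The procedure controls the gene-level overall FDR (OFDR): the expected
fraction of false-positive genes among all genes with at least one rejected
confirmation. Stage I applies Benjamini-Hochberg to an omnibus screening
p-value per gene at level alpha; the R passing genes enter Stage II, where
each gene's per-timepoint fold-change-threshold tests are judged at the
adjusted level alpha*R/m with a Sidak correction across that gene's T
confirmation hypotheses.

Equivalence calls are recorded per timepoint at an unadjusted level: they
support the *other* dataset's specificity claim rather than a discovery in
this dataset, so they do not consume the OFDR budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and within [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DecisionTable:
    """Per-gene screening and per-timepoint confirmation decisions.

    ``confirmed`` and ``equivalent`` are genes x timepoints boolean frames
    (columns = timepoint minutes); the table is a pure function of the stored
    p-values and levels.
    """

    genes: list[str]
    timepoints: list[int]
    screen_p: np.ndarray
    screen_padj: np.ndarray
    screened: np.ndarray
    confirmed: pd.DataFrame
    equivalent: pd.DataFrame
    alpha: float
    alpha_confirm: float
    p_confirm: np.ndarray = field(repr=False, default=None)
    p_equiv: np.ndarray = field(repr=False, default=None)

    def any_confirmed(self) -> np.ndarray:
        return self.confirmed.to_numpy().any(axis=1)

    def frame(self) -> pd.DataFrame:
        out = pd.DataFrame({
            "gene_id": self.genes,
            "screen_padj": self.screen_padj,
            "screened": self.screened,
        })
        for t in self.timepoints:
            out[f"de_confirmed_t{t}"] = self.confirmed[t].to_numpy()
            out[f"equiv_called_t{t}"] = self.equivalent[t].to_numpy()
        return out


def stagewise_decisions(p_screen: np.ndarray, p_confirm: np.ndarray,
                        alpha: float = 0.05,
                        p_equiv: np.ndarray | None = None,
                        alpha_equiv: float = 0.05,
                        genes: list[str] | None = None,
                        timepoints: list[int] | None = None) -> DecisionTable:
    """Two-stage decisions from screening and confirmation p-values.

    ``p_screen`` has one entry per gene; ``p_confirm`` (and optionally
    ``p_equiv``) are genes x timepoints. NaN confirmation entries are treated
    as untestable (never rejected, not counted in the Sidak correction).
    """
    p_screen = np.asarray(p_screen, dtype=float)
    p_confirm = np.atleast_2d(np.asarray(p_confirm, dtype=float))
    m, T = p_confirm.shape
    if p_screen.shape != (m,):
        raise ValueError(
            f"p_screen has {p_screen.shape} entries for {m} confirmation rows")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    genes = genes if genes is not None else [f"g{i}" for i in range(m)]
    timepoints = timepoints if timepoints is not None else list(range(T))

    padj = bh_adjust(p_screen)
    screened = padj <= alpha
    R = int(screened.sum())
    alpha_confirm = alpha * R / m if m else 0.0

    n_tests = np.isfinite(p_confirm).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sidak = 1.0 - (1.0 - alpha_confirm) ** (1.0 / np.maximum(n_tests, 1))
    conf = screened[:, None] & (np.nan_to_num(p_confirm, nan=1.0)
                                <= sidak[:, None])
    if p_equiv is None:
        eq = np.zeros_like(conf)
    else:
        p_equiv = np.atleast_2d(np.asarray(p_equiv, dtype=float))
        if p_equiv.shape != p_confirm.shape:
            raise ValueError("p_equiv shape must match p_confirm")
        eq = np.nan_to_num(p_equiv, nan=1.0) <= alpha_equiv
    return DecisionTable(
        genes=list(genes), timepoints=list(timepoints),
        screen_p=p_screen, screen_padj=padj, screened=screened,
        confirmed=pd.DataFrame(conf, index=genes, columns=timepoints),
        equivalent=pd.DataFrame(eq, index=genes, columns=timepoints),
        alpha=alpha, alpha_confirm=alpha_confirm,
        p_confirm=p_confirm, p_equiv=p_equiv,
    )
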