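"""Library-size normalization (TMM), CPM transforms and low-expression filtering.

TMM (trimmed mean of M-values) rescales raw library sizes so that the bulk of
genes show no fold change between samples; counts per million are then taken
relative to the effective (TMM-scaled) library size. Genes too lowly expressed
to be testable are removed per dataset, and that "filtered" status later feeds
the integration logic as one form of non-response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ingest import ExperimentBundle


def library_sizes(bundle: ExperimentBundle) -> pd.Series:
    """Total counts per sample. An all-zero column yields 1 with a warning."""
    totals = bundle.counts.counts.sum(axis=0).astype(float)
    if (totals == 0).any():
        zero = list(totals.index[totals == 0])
        warnings.warn(f"all-zero sample columns {zero}; library size set to 1")
        totals[totals == 0] = 1.0
    totals.name = "library_size"
    return totals


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              trim_logratio: float, trim_abundance: float) -> float:
    """edgeR-style TMM factor of one sample against the reference (log2 scale
    returned as a plain ratio)."""
    keep = (obs > 0) & (ref > 0)
    if keep.sum() < 2:
        warnings.warn("fewer than 2 positive shared genes with reference; "
                      "TMM factor set to 1")
        return 1.0
    o, r = obs[keep], ref[keep]
    p_o, p_r = o / n_obs, r / n_ref
    m = np.log2(p_o / p_r)                      # gene-wise log ratios
    a = 0.5 * np.log2(p_o * p_r)                # average abundance
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    # double trim: drop extremes of M and of A
    n = len(m)
    lo_m = np.floor(n * trim_logratio) + 1
    lo_a = np.floor(n * trim_abundance) + 1
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep2 = ((rank_m >= lo_m) & (rank_m <= n + 1 - lo_m)
             & (rank_a >= lo_a) & (rank_a <= n + 1 - lo_a))
    if not keep2.any() or w[keep2].sum() == 0:
        return 1.0
    f = np.sum(w[keep2] * m[keep2]) / np.sum(w[keep2])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_factors(bundle: ExperimentBundle, trim_logratio: float = 0.30,
                trim_abundance: float = 0.05) -> pd.DataFrame:
    """Trimmed-mean-of-M-values scaling factors per sample.

    The reference sample is the one whose upper-quartile CPM is closest to the
    mean upper-quartile; factors are rescaled to geometric mean 1. Returns a
    frame with ``library_size``, ``tmm_factor`` and ``effective_size``.
    """
    counts = bundle.counts.values.astype(float)
    lib = library_sizes(bundle).to_numpy()
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    q75 = np.array([np.quantile(counts[:, j] / lib[j], 0.75)
                    for j in range(counts.shape[1])])
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    factors = np.array([
        _tmm_pair(counts[:, j], counts[:, ref_idx], lib[j], lib[ref_idx],
                  trim_logratio, trim_abundance)
        for j in range(counts.shape[1])
    ])
    factors = factors / np.exp(np.mean(np.log(factors)))
    out = pd.DataFrame({
        "library_size": lib,
        "tmm_factor": factors,
        "effective_size": lib * factors,
    }, index=bundle.counts.sample_ids)
    out.index.name = "sample_id"
    return out


def cpm(bundle: ExperimentBundle, factors: pd.DataFrame, log2: bool = False,
        prior_count: float = 2.0) -> pd.DataFrame:
    """Counts per million relative to effective library sizes.

    With ``log2=True`` a moderated log is used: the prior count is scaled by
    each sample's relative effective size so that the transform is consistent
    across libraries of different depth.
    """
    eff = factors.loc[bundle.counts.sample_ids, "effective_size"].to_numpy()
    counts = bundle.counts.values.astype(float)
    if not log2:
        mat = counts / eff * 1e6
    else:
        rel = eff / eff.mean()
        prior = prior_count * rel
        adj_size = eff + 2 * prior
        mat = np.log2((counts + prior) / adj_size * 1e6)
    return pd.DataFrame(mat, index=bundle.counts.gene_ids,
                        columns=bundle.counts.sample_ids)


@dataclass
class FilterResult:
    """Partition of genes into testable ("kept") and too-low ("filtered")."""

    kept: list[str]
    filtered: list[str]
    cpm_threshold: float
    min_samples: int

    def __post_init__(self) -> None:
        overlap = set(self.kept) & set(self.filtered)
        if overlap:
            raise ValueError(f"genes in both partitions: {sorted(overlap)[:5]}")

    def is_filtered(self, gene: str) -> bool:
        return gene in self._filtered_set

    @property
    def _filtered_set(self) -> set:
        if not hasattr(self, "_fs"):
            self._fs = set(self.filtered)
        return self._fs


def smallest_group_size(bundle: ExperimentBundle) -> int:
    sizes = bundle.samples.groupby(["timepoint_min", "condition"],
                                   observed=True).size()
    return int(sizes.min())


def filter_low(bundle: ExperimentBundle, factors: pd.DataFrame,
               cpm_threshold: float = 1.0,
               min_samples: int | None = None) -> FilterResult:
    """Keep genes with CPM >= threshold in at least ``min_samples`` samples.

    ``min_samples`` defaults to the smallest (timepoint, condition) group so
    a gene expressed in a single experimental cell can survive.
    """
    if min_samples is None:
        min_samples = smallest_group_size(bundle)
    mat = cpm(bundle, factors, log2=False)
    ok = (mat.to_numpy() >= cpm_threshold).sum(axis=1) >= min_samples
    genes = np.asarray(bundle.counts.gene_ids)
    return FilterResult(kept=list(genes[ok]), filtered=list(genes[~ok]),
                        cpm_threshold=cpm_threshold, min_samples=min_samples)
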