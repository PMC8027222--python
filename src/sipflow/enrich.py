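"""Over-representation analysis of gene sets against term annotations.

One-sided hypergeometric tests (upper tail) per term, BH-adjusted within each
call, with the testable-gene universe as background to avoid detection bias.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .stagewise import bh_adjust


def read_annotation(path: str | Path,
                    names_path: str | Path | None = None
                    ) -> dict[str, set[str]]:
    """Read a two-column (term_id, gene_id) TSV into term -> gene-set."""
    df = pd.read_csv(path, sep="\t", header=None, names=["term_id", "gene_id"],
                     dtype=str, comment="#")
    ann: dict[str, set[str]] = {}
    for term, genes in df.groupby("term_id")["gene_id"]:
        ann[term] = set(genes)
    return ann


def hypergeom_enrich(gene_set, universe, annotation: dict[str, set[str]],
                     min_term: int = 5, alpha: float = 0.05) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``gene_set`` within ``universe``.

    Term gene sets are restricted to the universe; terms with fewer than
    ``min_term`` universe genes are skipped. Returns a frame with overlap k,
    set size n, term size K, universe N, p and BH-adjusted p, sorted by p.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    gene_set = set(gene_set)
    if not gene_set <= universe:
        extra = sorted(gene_set - universe)
        raise ValueError(f"gene set not within universe, e.g. {extra[:5]}")
    N, n = len(universe), len(gene_set)
    rows = []
    for term in sorted(annotation):
        term_genes = annotation[term] & universe
        K = len(term_genes)
        if K < min_term:
            continue
        k = len(term_genes & gene_set)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term_id": term, "overlap": k, "set_size": n,
                     "term_size": K, "universe": N, "p": min(p, 1.0)})
    result = pd.DataFrame(rows, columns=["term_id", "overlap", "set_size",
                                         "term_size", "universe", "p"])
    if len(result):
        result["padj"] = bh_adjust(result["p"].to_numpy())
        result["significant"] = result["padj"] <= alpha
        result = result.sort_values("p", kind="stable").reset_index(drop=True)
    else:
        result["padj"] = []
        result["significant"] = []
    return result


def enrich_per_timepoint(de_genes: dict[int, list[str]], universe,
                         annotation: dict[str, set[str]],
                         min_term: int = 5, alpha: float = 0.05
                         ) -> pd.DataFrame:
    """Run enrichment per timepoint (one BH family each) and stack results."""
    frames = []
    for t, genes in sorted(de_genes.items()):
        res = hypergeom_enrich(genes, universe, annotation,
                               min_term=min_term, alpha=alpha)
        res.insert(0, "timepoint", t)
        frames.append(res)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)
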