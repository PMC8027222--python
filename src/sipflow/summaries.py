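"""Sample- and gene-level display computations: leading-logFC MDS, CPM
trajectory tables and per-mating-type z-scored heatmap matrices.

All outputs are plain tables; rendering is left to the caller so tests can
target numbers rather than pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def leading_logfc_distance(logcpm: pd.DataFrame, top_n: int = 500
                           ) -> pd.DataFrame:
    """Pairwise sample distance = RMS of the ``top_n`` largest absolute
    log2-CPM differences between the two samples (pairwise gene selection).

    With fewer than ``top_n`` genes all genes are used, making this the plain
    RMS log-CPM distance.
    """
    mat = logcpm.to_numpy(dtype=float)
    G, S = mat.shape
    k = min(top_n, G)
    d = np.zeros((S, S))
    for i in range(S):
        diff = mat[:, i][:, None] - mat[:, i + 1:]
        if diff.shape[1] == 0:
            continue
        sq = diff ** 2
        if k < G:
            part = np.partition(sq, G - k, axis=0)[G - k:, :]
        else:
            part = sq
        d_i = np.sqrt(part.mean(axis=0))
        d[i, i + 1:] = d_i
        d[i + 1:, i] = d_i
    return pd.DataFrame(d, index=logcpm.columns, columns=logcpm.columns)


@dataclass
class MDSEmbedding:
    coordinates: pd.DataFrame     # samples x k
    eigenvalues: np.ndarray       # non-increasing
    top_n: int | None = None


def classical_mds(dist: pd.DataFrame, k: int = 2,
                  top_n: int | None = None) -> MDSEmbedding:
    """Torgerson classical MDS of a symmetric zero-diagonal distance matrix.

    Double-centers -D^2/2, eigendecomposes, and scales the top-k eigenvectors
    by the square roots of their (positive) eigenvalues. Axis signs follow the
    convention that the first nonzero loading is positive.
    """
    D = dist.to_numpy(dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    n_pos = int((vals > 1e-12 * max(vals[0], 1.0)).sum())
    if k > n_pos:
        import warnings
        warnings.warn(f"only {n_pos} positive eigenvalues; truncating k={k}")
        k = max(n_pos, 1)
    coords = vecs[:, :k] * np.sqrt(np.maximum(vals[:k], 0.0))
    for j in range(coords.shape[1]):
        nz = np.nonzero(np.abs(coords[:, j]) > 1e-12)[0]
        if len(nz) and coords[nz[0], j] < 0:
            coords[:, j] = -coords[:, j]
    frame = pd.DataFrame(coords, index=dist.index,
                         columns=[f"dim{j + 1}" for j in range(k)])
    return MDSEmbedding(coordinates=frame, eigenvalues=vals, top_n=top_n)


def zscore_by_group(cpm: pd.DataFrame, grouping) -> tuple[pd.DataFrame,
                                                          pd.Series]:
    """Standardize each gene to zero mean / unit variance within each group
    of samples (e.g. per mating type). Zero-variance rows become 0 and are
    flagged."""
    grouping = pd.Series(np.asarray(grouping), index=cpm.columns)
    out = cpm.astype(float).copy()
    flagged = pd.Series(False, index=cpm.index)
    for grp, cols in grouping.groupby(grouping).groups.items():
        cols = list(cols)
        if len(cols) < 2:
            raise ValueError(f"group {grp!r} has fewer than 2 samples")
        block = cpm[cols].to_numpy(dtype=float)
        mean = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, ddof=1, keepdims=True)
        zero = sd[:, 0] == 0
        sd[zero, 0] = 1.0
        scaled = (block - mean) / sd
        scaled[zero, :] = 0.0
        out[cols] = scaled
        flagged |= pd.Series(zero, index=cpm.index)
    return out, flagged


def cpm_trajectories(cpm: pd.DataFrame, samples: pd.DataFrame,
                     genes: list[str]) -> pd.DataFrame:
    """Long table of replicate and mean CPM per (gene, timepoint, condition),
    the data behind expression-versus-time trajectory plots."""
    missing = [g for g in genes if g not in cpm.index]
    if missing:
        raise KeyError(f"unknown genes: {missing}")
    rows = []
    for gene in genes:
        vals = cpm.loc[gene]
        for (tp, cond), grp in samples.groupby(["timepoint_min", "condition"],
                                               observed=True):
            reps = vals[grp["sample_id"]].to_numpy(dtype=float)
            for rep_id, v in zip(grp["replicate"], reps):
                rows.append({"gene_id": gene, "timepoint": int(tp),
                             "condition": cond, "replicate": int(rep_id),
                             "cpm": float(v), "mean_cpm": float(reps.mean())})
    return pd.DataFrame(rows)
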