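"""Negative-binomial GLM core: design construction, vectorized IRLS fitting,
deviance, and dispersion estimation with empirical-Bayes shrinkage.

Counts for gene g in sample i are modelled as NB(mu_gi, phi_g) with
Var = mu + phi*mu^2, log link and per-sample offsets (log effective library
size). The design is a cell-means parameterization: one coefficient per
(timepoint, condition) cell, which absorbs the dark-to-light temporal trend
shared by both conditions and leaves the per-timepoint treatment effects as
simple coefficient differences.

Dispersions are estimated by maximizing the Cox-Reid adjusted profile
likelihood (APL) on a log grid, with a mean-dispersion trend formed from
abundance bins and per-gene (tagwise) estimates shrunk toward the trend by
weighted-likelihood empirical Bayes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, xlogy

_ETA_MIN, _ETA_MAX = -30.0, 30.0
_MU_FLOOR = 1e-8
#: cells with fitted mean (per unit library) below this are flagged degenerate
LOW_CELL_LOG_MEAN = np.log(1e-6)


class RankError(ValueError):
    """Design matrix is rank deficient."""


@dataclass
class DesignMatrix:
    colnames: list[str]
    X: np.ndarray                 # samples x p
    offsets: np.ndarray           # per-sample log effective library size

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.colnames):
            raise ValueError("X shape does not match colnames")
        if self.offsets.shape != (self.X.shape[0],):
            raise ValueError("offsets must have one entry per sample")
        rank = np.linalg.matrix_rank(self.X)
        if rank < self.X.shape[1]:
            aliased = _aliased_columns(self.X, self.colnames)
            raise RankError(f"design not full rank; aliased columns: {aliased}")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_params(self) -> int:
        return self.X.shape[1]


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Columns flagged by pivoted QR as linearly dependent on earlier ones."""
    from scipy.linalg import qr

    _, r, piv = qr(X, pivoting=True, mode="economic")
    diag = np.abs(np.diag(r))
    bad = diag < 1e-10 * max(diag[0], 1.0)
    return [names[piv[i]] for i in np.where(bad)[0]]


def build_design(samples: pd.DataFrame,
                 parameterization: str = "timepoint_by_condition",
                 offsets: np.ndarray | None = None) -> DesignMatrix:
    """Cell-means design over the (timepoint, condition) cells present.

    ``timepoint_by_condition`` gives one indicator column per nonempty cell,
    named ``t{minutes}_{condition}``; a control-only timepoint (the 0 h dark
    sample) contributes a single column. ``timepoint_only`` pools conditions
    within each timepoint — the reduced design for the omnibus screen.
    """
    tp = np.asarray([int(t) for t in samples["timepoint_min"]])
    cond = samples["condition"].to_numpy()
    if parameterization == "timepoint_by_condition":
        labels = [f"t{t}_{c}" for t, c in zip(tp, cond)]
    elif parameterization == "timepoint_only":
        labels = [f"t{t}" for t in tp]
    else:
        raise ValueError(f"unknown parameterization {parameterization!r}")

    def _key(name: str) -> tuple:
        parts = name.split("_")
        return (int(parts[0][1:]), parts[1] if len(parts) > 1 else "")

    colnames = sorted(set(labels), key=_key)
    X = np.zeros((len(labels), len(colnames)))
    for i, lab in enumerate(labels):
        X[i, colnames.index(lab)] = 1.0
    if offsets is None:
        offsets = np.zeros(len(labels))
    return DesignMatrix(colnames=colnames, X=X, offsets=offsets)


def nb_deviance(y: np.ndarray, mu: np.ndarray, dispersion) -> np.ndarray:
    """Negative-binomial residual deviance, summed over samples (last axis).

    2*sum[ y*log(y/mu) - (y + 1/phi)*log((1 + phi*y)/(1 + phi*mu)) ], with
    y*log(y/mu) := 0 at y = 0; the Poisson limit is used for tiny phi.
    """
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), _MU_FLOOR)
    phi = np.asarray(dispersion, dtype=float)
    if phi.ndim == 1:
        phi = phi[:, None]
    phi_b = np.broadcast_to(phi, y.shape) if phi.shape != y.shape else phi
    pois = xlogy(y, y) - xlogy(y, mu) - (y - mu)
    safe_phi = np.where(phi_b > 0, phi_b, 1.0)
    nb = (xlogy(y, y) - xlogy(y, mu)
          - (y + 1.0 / safe_phi) * (np.log1p(safe_phi * y)
                                    - np.log1p(safe_phi * mu)))
    unit = np.where(phi_b < 1e-12, pois, nb)
    dev = 2.0 * unit.sum(axis=-1)
    return np.maximum(dev, 0.0)


def nb_loglik(y: np.ndarray, mu: np.ndarray, dispersion) -> np.ndarray:
    """NB log-likelihood summed over samples (last axis); Poisson limit for
    tiny phi."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), _MU_FLOOR)
    phi = np.asarray(dispersion, dtype=float)
    if phi.ndim == 1:
        phi = phi[:, None]
    phi_b = np.broadcast_to(phi, y.shape) if phi.shape != y.shape else phi
    safe_phi = np.where(phi_b > 1e-12, phi_b, 1.0)
    r = 1.0 / safe_phi
    nb = (gammaln(y + r) - gammaln(r) - gammaln(y + 1)
          + xlogy(y, mu) + r * np.log(r) - (y + r) * np.log(r + mu))
    pois = xlogy(y, mu) - mu - gammaln(y + 1)
    return np.where(phi_b < 1e-12, pois, nb).sum(axis=-1)


@dataclass
class GLMFit:
    """Vectorized per-gene NB regression results (natural-log coefficients)."""

    beta: np.ndarray              # genes x p
    se: np.ndarray                # genes x p
    mu: np.ndarray                # genes x samples
    deviance: np.ndarray          # genes
    converged: np.ndarray         # genes, bool
    dispersion: np.ndarray        # genes
    cov: np.ndarray               # genes x p x p
    design: DesignMatrix
    gene_ids: list[str] | None = None
    low_cell: np.ndarray = field(default=None)  # genes x p, degenerate cells

    def __post_init__(self) -> None:
        if self.low_cell is None:
            self.low_cell = self.beta <= LOW_CELL_LOG_MEAN


def fit_glm(counts: np.ndarray, design: DesignMatrix, dispersion,
            max_iter: int = 50, tol: float = 1e-8,
            init_mu: np.ndarray | None = None,
            gene_ids: list[str] | None = None) -> GLMFit:
    """Fit NB GLMs for all genes at once by IRLS.

    ``counts`` is genes x samples; ``dispersion`` a scalar or per-gene vector.
    Convergence is declared when the relative deviance change falls below
    ``tol``; non-converged genes return their last iterate flagged.
    """
    y = np.atleast_2d(np.asarray(counts, dtype=float))
    G, n = y.shape
    X, off = design.X, design.offsets
    p = X.shape[1]
    phi = np.broadcast_to(np.asarray(dispersion, dtype=float).reshape(-1), (G,))
    phi_col = phi[:, None]

    if init_mu is None:
        mu = np.maximum(y, np.maximum(y.mean(axis=1, keepdims=True), 1.0) / 6.0)
    else:
        mu = np.maximum(np.asarray(init_mu, dtype=float), _MU_FLOOR)
    eta = np.log(mu)
    dev = nb_deviance(y, mu, phi_col)

    XXr = (X[:, :, None] * X[:, None, :]).reshape(n, p * p)
    eye = np.eye(p)
    beta = np.zeros((G, p))
    converged = np.zeros(G, dtype=bool)
    have_prev = False

    for it in range(max_iter):
        W = mu / (1.0 + phi_col * mu)
        z = (eta - off) + (y - mu) / mu
        XtWX = (W @ XXr).reshape(G, p, p)
        ridge = 1e-10 * np.maximum(
            XtWX.reshape(G, -1)[:, :: p + 1].max(axis=1), 1.0)
        XtWz = (W * z) @ X
        beta_new = np.linalg.solve(XtWX + ridge[:, None, None] * eye,
                                   XtWz[:, :, None])[:, :, 0]

        # step halving toward the previous iterate where deviance worsens
        step = beta_new - beta if have_prev else beta_new
        base = beta if have_prev else np.zeros_like(beta_new)
        frac = np.ones(G)
        for _ in range(8):
            cand = base + frac[:, None] * step
            eta_new = np.clip(cand @ X.T + off, _ETA_MIN, _ETA_MAX)
            mu_new = np.maximum(np.exp(eta_new), _MU_FLOOR)
            dev_new = nb_deviance(y, mu_new, phi_col)
            if not have_prev:
                break
            bad = dev_new > dev + 1e-8
            if not bad.any():
                break
            frac = np.where(bad, frac / 2.0, frac)
        rel_change = np.abs(dev - dev_new) / (np.abs(dev) + 1.0)
        beta, eta, mu, dev = base + frac[:, None] * step, eta_new, mu_new, dev_new
        have_prev = True
        converged = rel_change < tol
        if converged.all():
            break

    W = mu / (1.0 + phi_col * mu)
    XtWX = (W @ XXr).reshape(G, p, p)
    ridge = 1e-10 * np.maximum(XtWX.reshape(G, -1)[:, :: p + 1].max(axis=1), 1.0)
    cov = np.linalg.inv(XtWX + ridge[:, None, None] * eye)
    se = np.sqrt(np.maximum(np.diagonal(cov, axis1=1, axis2=2), 0.0))
    return GLMFit(beta=beta, se=se, mu=mu, deviance=dev, converged=converged,
                  dispersion=np.array(phi), cov=cov, design=design,
                  gene_ids=gene_ids)


def fit_gene(counts_g: np.ndarray, design: DesignMatrix, dispersion: float,
             max_iter: int = 50, tol: float = 1e-8) -> GLMFit:
    """Single-gene convenience wrapper around :func:`fit_glm`."""
    return fit_glm(np.asarray(counts_g)[None, :], design, dispersion,
                   max_iter=max_iter, tol=tol)


def average_log_cpm(counts: np.ndarray, offsets: np.ndarray,
                    prior: float = 0.5) -> np.ndarray:
    """log2 of the mean CPM per gene (prior-guarded), used as the abundance
    axis for the dispersion trend."""
    cpm = np.asarray(counts, dtype=float) / np.exp(offsets) * 1e6
    return np.log2(cpm.mean(axis=1) + prior)


@dataclass
class DispersionEstimates:
    common: float
    trended: np.ndarray
    tagwise: np.ndarray
    raw: np.ndarray
    prior_df: float
    ave_log_cpm: np.ndarray


def _parabolic_argmax(logx: np.ndarray, vals: np.ndarray) -> np.ndarray:
    """Refine a grid argmax by the vertex of the local parabola (in log-x).

    ``vals`` is (..., K) over the grid ``logx``; returns log-x of the maximum,
    clamped to the bracketing grid interval.
    """
    vals = np.atleast_2d(vals)
    i = np.argmax(vals, axis=-1)
    h = logx[1] - logx[0]
    i_in = np.clip(i, 1, len(logx) - 2)
    rows = np.arange(vals.shape[0])
    ym, y0, yp = (vals[rows, i_in - 1], vals[rows, i_in], vals[rows, i_in + 1])
    denom = ym - 2 * y0 + yp
    shift = np.where(np.abs(denom) > 1e-12,
                     0.5 * h * (ym - yp) / np.where(denom == 0, 1, denom), 0.0)
    shift = np.clip(shift, -h, h)
    out = np.where((i > 0) & (i < len(logx) - 1), logx[i_in] + shift, logx[i])
    return out


def _abundance_bins(ave: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-count bin index per gene along the abundance axis."""
    order = np.argsort(ave, kind="stable")
    idx = np.empty_like(order)
    idx[order] = np.arange(len(ave))
    return np.minimum((idx * n_bins) // len(ave), n_bins - 1)


def estimate_dispersions(counts: np.ndarray, design: DesignMatrix,
                         prior_df: float = 10.0,
                         grid_range: tuple[float, float] = (1e-4, 5.0),
                         grid_n: int = 15, rel_grid_n: int = 13,
                         n_bins: int | None = None,
                         gene_ids: list[str] | None = None
                         ) -> DispersionEstimates:
    """Cox-Reid APL dispersion estimation with trend and EB shrinkage.

    Stage 1 evaluates the APL on an absolute log grid to get the common
    dispersion and an abundance-binned trend. Stage 2 re-evaluates on a grid
    of deviations relative to the trend; the tagwise estimate maximizes
    APL_g + prior_df * (bin-average APL), so prior_df -> inf recovers the
    trend and prior_df -> 0 the per-gene maximum.
    """
    y = np.atleast_2d(np.asarray(counts, dtype=float))
    G, n = y.shape
    if n - design.n_params < 1:
        raise ValueError("no residual degrees of freedom; supply a dispersion")
    ave = average_log_cpm(y, design.offsets)
    if n_bins is None:
        n_bins = int(np.clip(G // 100, 1, 50))
        if G >= 2000:
            n_bins = max(n_bins, 20)
    bins = _abundance_bins(ave, n_bins)

    def _apl_at(phi_vec: np.ndarray, init_mu=None):
        fit = fit_glm(y, design, phi_vec, max_iter=25, tol=1e-6,
                      init_mu=init_mu)
        W = fit.mu / (1.0 + phi_vec[:, None] * fit.mu)
        XXr = (design.X[:, :, None] * design.X[:, None, :]).reshape(
            n, design.n_params ** 2)
        XtWX = (W @ XXr).reshape(G, design.n_params, design.n_params)
        sign, logdet = np.linalg.slogdet(
            XtWX + 1e-12 * np.eye(design.n_params))
        ll = nb_loglik(y, fit.mu, phi_vec[:, None])
        return ll - 0.5 * logdet, fit.mu

    # stage 1: absolute grid
    log_grid = np.linspace(np.log(grid_range[0]), np.log(grid_range[1]), grid_n)
    apl1 = np.empty((G, grid_n))
    warm = None
    for k, lg in enumerate(log_grid):
        apl1[:, k], warm = _apl_at(np.full(G, np.exp(lg)), init_mu=warm)
    common = float(np.exp(_parabolic_argmax(log_grid, apl1.sum(axis=0))[0]))
    raw = np.exp(_parabolic_argmax(log_grid, apl1))

    bin_apl1 = np.zeros((n_bins, grid_n))
    np.add.at(bin_apl1, bins, apl1)
    trend0_bin = np.exp(_parabolic_argmax(log_grid, bin_apl1))
    trend0 = trend0_bin[bins]

    # stage 2: grid of deviations r relative to the stage-1 trend
    log_r = np.linspace(np.log(1e-2), np.log(1e2), rel_grid_n)
    apl2 = np.empty((G, rel_grid_n))
    warm = None
    for k, lr in enumerate(log_r):
        apl2[:, k], warm = _apl_at(trend0 * np.exp(lr), init_mu=warm)
    bin_counts = np.bincount(bins, minlength=n_bins).astype(float)
    bin_apl2 = np.zeros((n_bins, rel_grid_n))
    np.add.at(bin_apl2, bins, apl2)
    bin_mean2 = bin_apl2 / np.maximum(bin_counts[:, None], 1.0)

    r_trend_bin = _parabolic_argmax(log_r, bin_mean2)
    trended = trend0 * np.exp(r_trend_bin[bins])
    weighted = apl2 + prior_df * bin_mean2[bins]
    r_tag = _parabolic_argmax(log_r, weighted)
    tagwise = trend0 * np.exp(r_tag)
    return DispersionEstimates(common=common, trended=trended, tagwise=tagwise,
                               raw=raw, prior_df=prior_df, ave_log_cpm=ave)
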