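# Methods

## Model

Counts for gene *g* in sample *i* are negative binomial with mean `mu_gi`
and dispersion `phi_g` (`Var = mu + phi·mu²`), log link, and per-sample
offsets equal to the log effective library size (raw library size × TMM
factor). The design is a **cell-means parameterization**: one coefficient
per (timepoint, condition) cell present in the data, named
`t{minutes}_{condition}`; a control-only timepoint (the dark 0 h harvest)
contributes a single cell. This choice has two consequences we rely on:
the dark-to-light temporal trend — the dominant source of expression change
in both experiments — is absorbed exactly by the per-timepoint means, and
the per-timepoint treatment effect is the plain coefficient difference
`t{T}_treated − t{T}_control`, orthogonal to the trend. The exact design is
isolated behind `build_design` so an alternative parameterization can be
swapped in.

Timepoints are encoded internally in minutes (0, 15, 60, 180, 360, 540,
600); condition labels are normalized through an alias map (`SIP`,
`pheromone`, `treated` → treated) because the assays label the treatment
differently.

## Fitting

All genes are fitted at once by IRLS (Fisher scoring): working weights
`W = mu/(1 + phi·mu)`, convergence when the relative deviance change falls
below 1e-8 (default), step-halving toward the previous iterate when the
deviance worsens. Standard errors and contrast covariances come from the
inverse expected (Fisher) information `X'WX` at the optimum — the
conventional choice for NB GLMs in expression analysis; for the Poisson
limit (`phi → 0`), where the log link is canonical, expected and observed
information coincide and the fit matches an independent Poisson GLM to
1e-6 per coefficient (tested). A tiny ridge (1e-10 relative to the largest
information diagonal) keeps the solve well-posed for cells with no
expression; such cells hit the linear-predictor floor (`eta ≥ −30`), are
flagged (`low_cell`), and are **never** allowed to support an equivalence
call — absence of expression is not evidence of equivalence.

## Dispersion estimation

Per-gene dispersions are estimated by maximizing the Cox–Reid adjusted
profile likelihood `APL_g(phi) = loglik(y; mu_hat(phi), phi) −
½·log det(X'WX)`:

1. **Absolute grid** — 15 points, log-spaced over [1e-4, 5]; the grid
   maximum is refined by the vertex of the local parabola in log-phi
   (grid + quadratic interpolation plays the role a golden-section
   refinement would; it vectorizes across genes). Summing APL across genes
   gives the common dispersion; summing within ~20 equal-count abundance
   bins (by average log CPM) gives a first trend.
2. **Relative grid** — 13 log-spaced deviation factors in [0.01, 100]
   around the trend. The per-bin mean APL profile over this grid acts as
   the empirical-Bayes prior: the tagwise estimate maximizes
   `APL_g + prior_df · (bin mean APL)` with `prior_df = 10` by default.
   `prior_df → ∞` recovers the trend exactly (tested to 1e-6);
   `prior_df → 0` gives the raw per-gene maximum.

Recovery: median tagwise estimates fall within ±50% of truth for
`phi ∈ {0.05, 0.1, 0.4}` at n = 6, 2,000 genes (tested; in practice within
a few percent), and Poisson data yield a median below 0.05.

## Tests

All tests are Wald-type with standard normal reference (an explicit
design choice: tagwise empirical-Bayes dispersions make residual degrees of
freedom ill-defined, so a t reference would be arbitrary; the omnibus screen
uses a chi-square LRT instead). With `b` the estimated natural-log fold
change, `se` its standard error and margin `tau = log(fold_change)`,
`fold_change = 3`:

* DE: `p = 2·P(Z > |b|/se)`.
* Threshold (TREAT-style), `H0: |beta| <= tau`:
  `p = P(Z > |b|/se − tau/se) + P(Z > |b|/se + tau/se)`. At `tau = 0` this
  reduces exactly to the DE test (tested at 1e-12).
* Equivalence (TOST), `H0: |beta| >= tau`:
  `p = max(1 − Φ((b+tau)/se), Φ((b−tau)/se))`; `b = tau` gives p = 0.5
  exactly, and the rejection rate at the margin stays at the nominal level
  (Monte-Carlo tested). TOST was chosen as the equivalence construction for
  its transparency; it is conservative relative to interval-LRT variants.
* Omnibus screen: LRT of the cell-means design against the timepoint-only
  design (same tagwise dispersions), chi-square with df = number of
  treatment contrasts.

The `±log(3)` margin is read as a fold change of 3: `log 3 ≈ 1.0986` on the
natural-log model scale, `log2 3 ≈ 1.585` on the log2 reporting scale —
both readings name the same fold change.

## Stage-wise OFDR control

The target is the gene-level overall FDR: the expected fraction of
false-positive genes among all genes with any rejected confirmation.
Stage I applies BH to the omnibus screen p-values at level `alpha = 0.05`;
with `R` of `m` genes passing, Stage II judges each screened gene's
per-timepoint threshold tests at `alpha·R/m`, Šidák-corrected across that
gene's T testable timepoints (`reject if p ≤ 1 − (1 − alpha·R/m)^(1/T)`).
This is the established screening/confirmation construction for gene-level
OFDR. Equivalence calls are made per timepoint at an unadjusted 0.05 on the
TOST p-values and deliberately do **not** consume the OFDR budget: an
equivalence call supports the *other* dataset's specificity claim rather
than a discovery in this dataset. Both levels are configuration knobs.

## Integration

Only timepoints with both conditions in both datasets participate
(15 min, 1 h, 3 h under the study layouts; the MT− 10 h batch is analyzed
per dataset but never integrated). Per gene over the shared grid:

* **SRB** — threshold-DE confirmed at ≥1 shared timepoint in both datasets.
  Direction concordance is *not* required (responses of opposite sign in
  the two mating types still count as shared); directions are recorded.
* **SRP / SRM** — confirmed in one dataset and non-responsive in the other,
  where non-response is positive evidence only: equivalence at **every**
  shared timepoint, or filtered (below 1 CPM in fewer samples than the
  smallest experimental group). The default "every shared timepoint" rule is
  the strict reading; `equivalence_mode="de_timepoints_only"` relaxes it to
  the timepoints where the responsive side's DE was confirmed.
* **non-responsive** — equivalent-or-filtered in both.
* **unclassified** — everything else, notably DE in one dataset with
  neither equivalence nor filtering in the other. This is the point of the
  design: lack of significance is never converted into a specificity claim,
  and disabling the equivalence requirement measurably leaks truly-shared
  (SRB) genes into the specific classes (tested).

The evaluated universe is the union of both datasets' genes; a gene absent
from one dataset counts as filtered there.

## Synthetic data

The generator emulates the study conditions: MT+ with a 0 h control-only
cell plus {15, 60, 180, 360, 540} min × {control, treated} × 3 replicates;
MT− as two batches ({15, 60, 180} min and 600 min) × 2 conditions × 3
replicates; library sizes uniform on [0.5M, 2M]. Gene classes (defaults:
200 SRB, 100 SRP, 100 SRM, 100 filtered per side, remainder null at 10,000
genes, pro-rated at other scales):

* responder log2 fold changes are uniform on [log2(3)+0.5, 4] with random
  sign, applied at every treated timepoint of the responsive dataset; MT−
  magnitudes are 1.25× MT+ (the MT− response is the more pronounced one);
* null genes carry small fold changes uniform on ±0.2, so equivalence is
  genuinely true for them;
* "filtered" classes have mean ≈0.05 counts in the unexpressed dataset
  (below the 1-CPM filter) and responder behavior in the other — the
  correct integrative call for them is therefore SRP/SRM with "filtered"
  status, and the evaluation harness scores them that way;
* baselines are lognormal — ln-mean ln(30), ln-sd 1.5 for null genes;
  ln-mean ln(100), ln-sd 1.0 for responder-like genes. The higher responder
  baseline reflects that key genes are by construction expressed in both
  mating types (equivalence evidence requires expression); it was fixed a
  priori from a power calculation at n = 3, not fitted to any test outcome;
* dispersions follow the trend `phi = 1/mu + 0.05` (capped at 5), i.e. a
  biological CV of ~22% for well-expressed genes, typical of controlled
  culture experiments;
* a dark-to-light trend multiplies both conditions of each gene:
  amplitude ~ N(0, 1) in log2, saturating shape `log1p(t)/log1p(600)` — the
  cell-means design must absorb it, and the MDS of simulated samples indeed
  shows time as the leading axis.

Everything is drawn from a single `numpy` Generator seeded by the config,
so outputs are byte-identical across runs and platforms at the same seed.

What the simulation does **not** emulate: quantification uncertainty and
multi-mapping (counts are exact NB draws), correlated gene modules, batch
effects within a dataset, outlier samples, and annotation error. Passing
recovery tests therefore demonstrate the statistical machinery under the
declared generative model, not robustness to those real-data pathologies.

## Numerical choices and problem sizes

Tolerances: IRLS deviance tolerance 1e-8 (1e-6 inside dispersion grids,
where only the profile likelihood shape matters); LRT statistics clamped at
0 with failures flagged beyond −1e-6; BH via statsmodels; hypergeometric
tails via scipy. Degenerate standard errors give p = 1 and a flag, never a
rejection. Benchmarks run at 5,000 genes × 25 replicates (error control)
and 10,000 genes (class recovery), sizes at which the full workflow runs in
a few minutes on one CPU; class counts are pro-rated when scaling.

## Known limitations

* The normal reference for Wald tests is slightly anti-conservative at
  n = 3 per cell for low counts; the stage-wise construction and the
  fold-change margin leave the realized OFDR far below nominal in practice
  (measured ≈0).
* Specificity recall is deliberately conservative: genes without power for
  equivalence at every shared timepoint stay unclassified.
* TMM reference selection follows the upper-quartile-closest-to-mean
  convention; pathological libraries (e.g. >50% zeros) may warrant manual
  reference choice.
* Between-dataset normalization is intentionally absent: the workflow
  integrates decisions, never pooled counts.
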