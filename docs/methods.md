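# Methods

This note records the model behind `ordimap`, the choices made where the
design was genuinely open, and what the synthetic studies do and do not
demonstrate.

## Association model

Pairwise association between gene expression vectors is measured by
Kendall tau-b, the tie-corrected rank correlation

    tau_b = (C − D) / sqrt((n0 − n1)(n0 − n2)),

with C/D the concordant/discordant sample-pair counts, n0 = n(n−1)/2 and
n1, n2 the pair counts tied in each variable. Rank correlation is used
because expression in severely diseased tissue is far from normally
distributed. The implementation counts concordances exactly over integer
sign vectors; the full matrix over all gene pairs is a single integer
matrix product (the sign-vector Gram matrix), which computes the
640 × 640 study case in well under a second and returns values identical
to the scalar definition. Constant genes make tau undefined; they abort
the computation with the list of offending genes (or are dropped on
request) — undefined values are never silently replaced by 0, which
would distort the downstream ordination.

For the diseased condition the tissue-damage covariate z (ordinal
necrosis grade) is removed by the first-order partial correlation

    tau_xy.z = (tau_xy − tau_xz · tau_yz) / sqrt((1 − tau_xz²)(1 − tau_yz²)).

One ordered covariate is the model's scope; higher-order schemes collapse
to this form here. The plug-in formula can overshoot |1| by floating
error, so results are clipped to [−1, 1]. A covariate rank-collinear with
a gene (|tau_xz| = 1) leaves the pair undefined and raises.

Distribution shape is summarized by Sarle's bimodality coefficient
(skew² + 1)/kurtosis with the plain (non-excess) kurtosis; the uniform
distribution scores exactly 5/9, which is used as the bimodality
benchmark. The coefficient is a pragmatic operationalization of a visual
claim; it flags the two-shouldered tau distributions produced by a strong
common covariate reliably at the study's pair counts (≥ ~5000 pairs).

## Ordination

Correlations become nonmetric distances by d = (−1)·tau — deliberately
zero-centered rather than the usual 1 − tau. Classical scaling is applied
to the recovered similarity S = −d: double-center B = JSJ with
J = I − (1/n)11ᵀ, factor B = UΣVᵀ by SVD, and take coordinates UΣ^{1/2}
truncated to k axes. Whether to double-center was an open choice; the
double-centered form is the unique classical-scaling reading consistent
with zero-centered input and an SVD factorization, and the iterative
nonmetric comparators provide the robustness check. Because −tau is not
Euclidean, B can have negative eigendirections: the SVD orders axes by
eigenvalue magnitude, and the sign of each retained eigenvalue is
reported (`axis_eigen_signs`) so heavily non-Euclidean structure is
visible. Axis orientation is fixed by flipping each axis so its
largest-magnitude loading is positive, making runs (and languages)
comparable.

Sammon's mapping minimizes E = (1/Σd) Σ (d_ij − δ_ij)²/d_ij by the
classic diagonal-Newton update (step factor 0.3) with step halving, so
stress never increases; it is initialized from the classical-scaling
configuration and is therefore deterministic. Kruskal's nonmetric MDS
(stress-1 with monotone regression) runs on the SMACOF implementation in
scikit-learn, same initialization. Both need positive dissimilarities:
when the minimum off-diagonal value falls below a small positive floor
(10⁻³ of the range), all values are shifted uniformly so the minimum
equals the floor. The shift is monotone — all a nonmetric method uses —
and inputs that are already positive pass through untouched, so
Euclidean-realizable inputs embed at stress ≈ 0. Configuration agreement
is the Procrustes correlation sqrt(1 − m²) after optimal
translation/rotation/reflection/scaling; on default synthetic studies the
three methods agree at > 0.95.

k = 3 retained dimensions are used for map-level statistics (maps are
read in 2–3 dimensions) and k = 50 for the mirSVR regression, matching
that regression's stated dimensionality; both are configurable.

## Differential expression

Per-gene one-way ANOVA F (two groups here, so F = t²), ties in the gene
ranking broken by gene id. Selection follows the
confidence-quantile-of-permuted-false-counts formulation: for the cut at
the r-th largest observed F, the number of permuted-null genes exceeding
that cut is tabulated over random label permutations; the cut is
acceptable when the confidence-quantile (inverted-CDF order statistic) of
that count, divided by r, is at or below the FDR target, and the largest
acceptable r wins. With FDR 1 % at 80 % confidence, under a global null
the procedure selects anything at all in ≈ 20 % of datasets — exactly
the advertised confidence, verified by simulation in the test suite. At
least 100 permutations are required (the quantile is unresolvable below
that); constant genes get F = 0 and are never selected. Signed fold
change is 2^(Δ log2 means), reported as r when r ≥ 1 and −1/r otherwise;
the fold-change filter is strict (|FC| > threshold excludes the
boundary).

## Covariate diagnostics

The |R| screen is Pearson on log2 values (the covariate relations are
modeled as straight lines; a Kendall variant is available). The
zero-covariate correction fits per-gene OLS of expression on the grade
and takes the intercept; the output records that grade 0 lies outside
the observed range, so intercepts are an extrapolation. The correction is
diagnostic only — the main ordination removes the covariate through
partial correlations, not by replacing the matrix with intercepts.

## Thematic statistics

* **Ellipses** — covariance ellipses at 1.6 standard deviations along the
  principal axes (the ordination-plot 'sd' convention), not a chi-square
  quantile. Requires k+1 points; degenerate (all-identical) groups raise.
* **Density fields** — isotropic Gaussian kernels with an absolute
  bandwidth on a regular grid (bounding box + 3 bandwidths, or a caller-
  supplied shared extent), renormalized to integrate to 1 on the grid.
  The miRNA/mRNA complementarity score is the Spearman correlation of the
  two fields across grid cells — an explicit operationalization of a
  qualitative "the maps look complementary" observation; negative values
  mean complementary occupancy.
* **Median shift** — per miRNA, the median tau against all mRNAs in each
  condition; classification by strict threshold on the difference
  (default ±0.15). Antisymmetric under condition swap by construction.
* **Target pairs** — Euclidean distances in the first 3 retained
  dimensions for the map-level report (the paper-style 2–3-D reading),
  50 for the regression; both configurable. The sign-flip control negates
  both miRNA-vs-mRNA blocks of the association matrix (preserving
  symmetry) and reruns the full classical ordination with identical
  settings — it does not merely re-sign coordinates. Background is the
  set of all miRNA–mRNA id pairs.
* **mirSVR regression** — OLS of the pair's mirSVR score on the per-
  dimension absolute coordinate differences |x_d(miRNA) − x_d(mRNA)|,
  d = 1..50 (the only per-dimension "distance" that is well defined),
  with intercept; reports multiple R² and the overall F-test p. Needs
  more pairs than predictors + 1; the pipeline reduces the
  dimensionality with a warning when a filtered study leaves too few
  pairs, while the standalone operation raises.
* **Seed groups** — exact string grouping after uppercasing and T→U
  normalization; singletons are counted but excluded from the groups.

## Synthetic studies: what they emulate

A diseased sample j with ordinal necrosis grade g_j (grades 1..4 assigned
cyclically — the true grading scale is study-specific and any monotone
numeric coding is equivalent for rank-based analyses) gives gene i

    x_ij = b_i + dir_i · a · g_j + s_b · f_{B(i),j} + couplings + N(0, σ²),

control samples lack the covariate term. Choices and rationale:

| parameter | default | units | why |
|---|---|---|---|
| n_mirna / n_mrna | 109 / 531 | genes | the emulated study's post-selection counts |
| samples | 13 + 17 | — | diseased + control group sizes |
| baseline b_i | Normal(8, 3) | log2 | RMA-scale log2 intensities span ~2–14 |
| covariate effect a | 1.2 | log2 per grade | strong histology confounding: a grade-1→4 swing moves a directional gene ~3.6 log2 units, putting a large minority of genes above the |R| > 0.9 screen, as in diseased-tissue data |
| direction split | 0.45 / 0.45 / 0.10 | hepatocyte / infiltrate / neutral | the analyzed genes are differentially expressed *by construction*, so nearly all carry a necrosis direction; the 10 % neutral fraction keeps a null slice for calibration |
| blocks | 9, s_b = 0.8 | log2 | nine functional classes; within-block correlation ~0.4 tau after covariate removal, enough to cluster without collapsing the map |
| couplings | 1.0 / 1.0 | log2 | planted pair tau ≈ ∓0.45, comparable to strong real co-expression; pairs alternate inhibitory/feed-forward; setting one strength to 0 makes the bundle single-type (so "feed-forward = 0" is an inhibitory-only study) |
| noise σ | 0.5 | log2 | typical residual array noise |
| target pairs | 100 | pairs | dense enough for a stable mean distance and the 50-dimension regression |
| seed groups | 8 | groups | pairs of miRNAs sharing a 7-base seed |

All randomness derives from one integer seed through a single numpy
`default_rng` (PCG64). Fixed-proportion label assignment (not Bernoulli)
keeps the planted composition exact in every replicate.

What the generator does **not** emulate: probe-level microarray
artifacts and normalization, heavy-tailed/outlier expression, correlated
noise beyond the block factors, hub miRNAs targeting many mRNAs, realistic
mirSVR score distributions (scores are uniform on [−2, −0.1]), or latent
covariates beyond the single necrosis grade. Passing tests therefore show
that the pipeline recovers the structures it is designed for under an
idealized generative model — not that real studies satisfy that model.

## Problem sizes and numerical conventions

Replicate-based properties are checked at a reduced study size
(100 genes × 13 + 17 samples, 20–200 replicates) and single-run
properties at the full 640-gene size; these sizes keep the whole suite
and the acceptance script in the tens of seconds while leaving every
statistic far from its decision boundary. Other conventions: the
permutation-count quantile uses the inverted-CDF (order-statistic)
method; partial correlations are clipped to [−1, 1]; the iterative MDS
floor is 10⁻³ of the dissimilarity range; ellipse membership uses the
Mahalanobis radius at the ellipse scale; F statistics of constant genes
are 0; expression files are written with 6 significant digits (the
documented read∘write precision).

## Known limitations

* The generator's single-covariate, linear-on-log2 structure is the
  simplest model producing the study's confounding signatures; real
  tissue has additional latent covariates.
* The 50-dimension mirSVR regression is calibrated (uniform null p) but
  with 100–200 pairs its power against weak signals is limited, matching
  the small effect sizes such regressions report in practice.
* Sarle's coefficient can miss bimodality with very unequal mode masses;
  it is a screen, not a test.
* Classical scaling of a nonmetric −tau matrix has no optimality
  guarantee in the embedded dimension; the Sammon/Kruskal comparators are
  the intended robustness check.
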