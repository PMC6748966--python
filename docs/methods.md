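# Methods

`omifuse` implements three integrative analyses for paired gene-expression
and copy-number (CNV) data on two related diseases (here bipolar disorder
and schizophrenia) plus a shared normal group, together with the synthetic
data designs and evaluation statistics used to validate them.

Notation: for group *k*, subject *i* carries an expression vector
x_i^(k) ∈ R^p, a CNV vector z_i^(k) ∈ R^p, and (for the disease contrasts)
a binary outcome y_i^(k) with 0 = control.

## 1. Vertical integration (A1) and comparators

The integrative outcome model for one disease contrast proceeds in three
steps:

1. **Sparse PCA of expression.** Rank-one penalized matrix decomposition:
   each component solves max uᵀAv subject to ‖u‖₂ ≤ 1, ‖v‖₂ ≤ 1, ‖v‖₁ ≤ c
   on the column-centered matrix, by alternating u ← Av/‖Av‖ and
   v ← soft-threshold(Aᵀu)/‖·‖ with the threshold found by bisection so the
   L1 bound binds; components are removed by rank-one deflation. With
   c = √p this is exactly classical PCA. The top K = 10 components (by
   singular value) are retained; K is fixed rather than selected because
   the goal is an outcome model, not component inference.
2. **Reversed regression and decomposition.** Each CNV column is regressed
   on the 10 expression PC scores by ordinary least squares (a ridge of
   1e-6 is applied only on rank deficiency). The fitted part of Z carries
   the CNV information that overlaps with expression; the residual
   R = Z − X_pc ω̂ carries the independent part. By least-squares geometry,
   X_pcᵀR = 0 to machine precision.
3. **Outcome model.** Sparse PCA of R (again K = 10), then unpenalized
   maximum-likelihood logistic regression of y on the 20 scores. On
   separation or non-convergence the fit falls back to a ridge-stabilized
   (1e-4) Newton iteration, flagged on the result object.

Comparators: A2 stacks sparse PCs of expression and of raw CNV (no
decomposition); A3 and A4 use one block only. Forcing ω̂ = 0 makes A1
coincide with A2 exactly, which is used as a structural test. New samples
are scored with the training centering, loadings and ω̂ (no refit), which
is what makes the resampled prediction evaluation honest.

Defaults and their reasons: sparsity bound c = √p/2 (the cited SPCA
routine's tuning is not disclosed; a convenience bisection from a target
nonzero count is provided); mean-centering without variance scaling
(minimal PCA convention; scaling is a flag); sign convention: each
loading's largest-magnitude entry is positive; alternation stops when the
singular value changes by < 1e-7 (max 200 alternations).

## 2. Horizontal marker identification (B1/B2) and baseline (B3)

Two penalized logistic regressions are coupled through a fusion penalty:

    min  Σ_k −l̄(β^(k), α_k) + λ₁ Σ_k ‖β^(k)‖₁ + (λ₂/2) ρ(β^(1), β^(2))

where l̄ is the per-sample mean log-likelihood (normalization makes λ
values comparable across contrasts of different size; a flag restores the
literal unnormalized form). Two fusions are implemented:

* **Magnitude penalty (B1):** Σ_j Σ_{k≠k'} (β_j^(k) − s_j β_j^(k'))² with
  s_j = 1 iff the two coefficients share their sign (Sgn(0) = 0). For a
  same-sign pair this shrinks the value difference; for a discordant pair
  it degenerates to a ridge on both coefficients.
* **Sign penalty (B2):** Σ_j Σ_{k≠k'} (Sgn β_j^(k) − Sgn β_j^(k'))²,
  optimized through the smooth surrogate Sgn(x) ≈ x/√(x² + τ), τ = 1e-2 on
  standardized predictors; reported penalty values use exact signs.

λ₂ = 0 reduces the problem to two independent Lasso-logistic fits; the
separate baseline (B3) is that special case.

**Solver.** Cyclic coordinate descent on a quadratic majorization of the
logistic loss with the 1/4 curvature bound (w = 1/4), which guarantees the
loss part decreases at every full sweep. The fusion indicator s (B1) or
surrogate denominators (B2) are frozen at each sweep start; coordinate
updates are closed-form soft-threshold steps:

* magnitude, same-sign: β ← S(q + 2λ₂β', λ₁)/(h + 2λ₂);
* magnitude, discordant: β ← S(q, λ₁)/(h + λ₂) — the coordinate appears
  once per ordered pair, so the discordant curvature is λ₂, not 2λ₂;
* sign surrogate: β ← S(q + 2λ₂β'/(dd'), λ₁)/(h + 2λ₂/d²).

Because refreshing s/d between sweeps can in principle raise the
objective, a sweep-level backtracking safeguard accepts a sweep only if
the exact objective did not increase (halving toward the previous iterate,
stopping when no decrease exists) — the recorded objective trace is
therefore non-increasing by construction. Fused fits additionally stop
when the per-sweep objective decrement falls below 1e-9 relative (the
frozen-surrogate step is a near-identity fixed point near its optimum and
otherwise crawls); unfused fits use the strict coefficient criterion
(1e-5, max 1000 sweeps), on which the exact reduction identities rely.
A final **zero-snap polish** sets a coefficient exactly to zero whenever
doing so does not increase the exact objective — a plain descent move that
removes coefficients stranded near zero by the stall.

Two structural consequences of the penalties are worth knowing:
(i) the magnitude penalty's discordant ridge shrinks a one-disease
coefficient toward, but never exactly to, zero, so minimizers can contain
"dust" coefficients of order 1e-3–1e-2 that count as selections under
exact-zero support reading; (ii) the sign surrogate actively pulls the
partner disease's coefficient across the L1 threshold, so sign-penalty
false positives tend to come in cross-disease pairs. Both effects tax the
fused estimators under any support-counting comparison; see §6.

The update order within the pair is sequential (the second group sees the
first's fresh value); to make the fit invariant to argument order, the two
datasets are ordered canonically by content before solving and the
solution is mirrored back, so swapping the inputs swaps the coefficient
vectors exactly. Predictors are standardized inside the solver;
coefficients are returned on the standardized scale with the scalers
attached (original-scale accessors are provided).

**Tuning.** Grid search with warm starts along a 16-point geometric λ₁
path from λ_max down to 0.05·λ_max (the path top is nudged up by 1e-8
relative so it is the exact null fit despite summation-order rounding) and
a fusion ladder λ₂ ∈ {2, 8, 32} — on the normalized-likelihood scale the
cross-disease quadratic dominates the per-coordinate loss curvature (1/4)
from about λ₂ = 2 upward. Two criteria:

* **Refit-BIC (default):** per-dataset BIC where each candidate support is
  refit by a ridge-stabilized (1e-2) unpenalized logistic regression. The
  refit matters: fusion deliberately biases coefficients, so the penalized
  fit's own likelihood makes any fused model look worse than its unfused
  counterpart. Ties go to the sparser fit within a λ₂ column and to the
  stronger coupling across columns (with a support-based score, equal
  scores mean equal supports, and the fused fit has the smaller effective
  complexity).
* **Cross-validated deviance:** 5-fold stratified out-of-fold deviance.
  Unlike support-based scores, this rewards the estimation gain of fusion,
  and it is the criterion under which matched diseases select a positive
  coupling in nearly all replicates.

## 3. Horizontal regulation estimation (C1/C2) and baseline (C3)

Per gene j and group k, expression is a sparse linear function of all
CNVs, x_j^(k) = Z^(k) η_j^(k) + δ. The fused objective

    Σ_k (1/2n_k) Σ_j ‖x_j^(k) − Z^(k) η_j^(k)‖² + λ₃ Σ_{k,j} ‖η_j^(k)‖₁
      + λ₄ Σ_j ρ(η_j^(1), η_j^(2))

uses the same two fusions (note: no ½ on the λ₄ term). The problem
decouples over genes; the solver is the same coordinate-descent core with
exact quadratic loss (no majorization needed), vectorized across genes,
with the per-gene safeguard keeping every per-gene objective — and hence
the total trace — non-increasing. Cis (diagonal) and trans entries are
penalized alike. Constant CNV columns have their coefficients fixed at
zero with a warning. λ₄ = 0 reduces to per-gene, per-group Lasso (C3,
also used for the normal group). Fused fits cold-start rather than warm
start along the λ₃ path: warm starts were observed to set the frozen-s
dynamics oscillating in 1000-sweep micro-steps.

**Tuning.** One global (λ₃, λ₄) shared by all genes (per-gene tuning is an
option), 16-point λ₃ path, λ₄ ∈ {0.1, 0.5, 2}. The default criterion is a
per-gene refit BIC summed over genes and groups — per-gene OLS on each
selected support, n·log(RSS/n) + log(n)·df — with two guards: supports
with df > n/2 are scored as buying nothing (the profile variance estimate
collapses as df approaches n, otherwise letting saturated refits win in
the per-gene p ≫ n regime), and an RSS floor of 1e-6 of the null RSS. An
out-of-fold squared-error criterion ('cv') is available and is the one
that sees fusion's estimation gain (§6).

**Distances.** Dist(A, B) = Σ_{j,l} (A_jl − B_jl)² and
SignDist(A, B) = Σ_{j,l} (Sgn A_jl − Sgn B_jl)², summed over genes to one
scalar per group pair (summation rather than averaging; rescaling is
trivial). Distances are computed on original-scale coefficients so groups
with different CNV scalings are comparable.

## 4. Synthetic-data designs

* **Marker scenarios I–IV.** Disease-k expression ~ N(μ_k, Σ), controls
  ~ N(0, Σ); n = 40 per group, p = 100. Σ is block-diagonal over the 8
  outcome-associated variables and the 92 null ones, each block AR with
  entry 0.3^|j−l|. μ₁ = (−1,−1,−1,−1,2,2,2,2,0,…,0) throughout;
  μ₂ equals μ₁ (I), (−1,−1,−4,−4,2,2,4,4,0,…) (II),
  (−2,−2,−0.5,−0.5,3,3,1,1,0,…) (III), (2,2,−0.5,−0.5,3,3,−1,−1,0,…) (IV)
  — from identical effects through same-sign magnitude differences to
  conflicting signs. One control draw per replicate is shared by both
  disease contrasts, matching the single normal group of the study design.
* **Regulation design.** Each expression is regulated by 10% of the CNV
  measurements; half the nonzero coefficients are Uniform(0.6, 1.2), half
  Uniform(−1.2, −0.6); the two diseases share six important CNVs per gene
  with matching signs (remaining support indices and all magnitudes are
  disease-specific; supports are re-drawn per gene); errors are N(0, 1).
  The study ran this design on its access-gated observed CNV matrix; here
  a synthetic surrogate stands in: AR(0.3)-correlated Gaussian columns,
  optionally cut at tertiles into copy-number-like levels {−1, 0, 1}. The
  surrogate's sample size defaults to n = 40 per group, the simulation
  chapter's stated group size. A loader path accepts a real CNV matrix
  when the user has access. Designs whose support (10% of p) cannot hold
  the six shared CNVs raise an error — note that a 40-gene pathway with
  40 CNVs is such a case.
* **Vertical test data.** No published design exists for the vertical
  pipeline, so a latent-factor construction is used: expression is driven
  by two sparse factors; CNV is an expression-driven component (weight =
  `overlap_strength`) plus an independent sparse factor; the outcome
  follows a logistic model on one expression factor and the independent
  CNV factor. This creates exactly the situation the decomposition is
  meant to exploit — predictive CNV signal orthogonal to expression.

What the generators do **not** emulate: array noise and batch structure,
copy-number segmentation, heavy-tailed expression distributions, realistic
linkage between CNV dosage and expression beyond linearity, and the
correlation structure of real pathways. Passing tests therefore establish
the estimators' claimed behavior under the stated generative models, not
performance on array data.

## 5. Evaluation

TPR/FPR score exact-nonzero supports against the known truth. Prediction
is scored by the corrected prediction ratio, implemented as balanced
accuracy — 0.5·(sensitivity + specificity) at threshold 0.5, ties
predicting class 0 — so a useless classifier scores 0.5 at any class
imbalance (the formula is printed in output headers; raw accuracy is a
flag). The resampling evaluation repeats stratified 75%/25% train/test
splits (200 by default), refitting the entire pipeline, including SPCA and
ω̂, on each training part.

## 6. Known limitations

* **Support-counting vs fusion.** Under exact-zero support reading, the
  fused estimators carry a structural handicap: magnitude-ridge dust and
  sign-drag pairs inflate their selected supports at any tuning (§2). In
  the simulation comparisons this shows up as fused false-positive rates
  that tie or slightly exceed the separate-Lasso baseline even where the
  fused true-positive rates are far higher; and it is why the default
  refit-BIC, which scores supports, rarely strictly prefers λ₂ > 0 on
  matched data while out-of-fold error robustly does.
* **Per-gene p ≫ n.** With 100 CNVs and 40 samples per gene, no RSS-based
  criterion can reliably separate dense candidate supports; the df > n/2
  guard is a blunt but honest boundary.
* The sign surrogate's frozen-denominator step converges at a slow linear
  rate; the objective-stall stop leaves an objective gap of order 1e-6,
  negligible for selection but visible in high-precision comparisons.
* Problem sizes in the test-suite simulations (20–30 replicates, 40 genes
  in the regulation design, 100 resampling splits) are the package's
  standing validation sizes; the generators accept larger values.
* High-dimensional inference (p-values for penalized fits) is out of
  scope, as is any penalty other than the Lasso for the sparsity term.
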