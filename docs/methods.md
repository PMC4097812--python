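# Methods

This note records the models, algorithmic choices, and study conditions
behind `kernelfuse`, and what the synthetic experiments do and do not
establish.

## Kernels and normalization

All kernels are linear: `K[i, j]` is the dot product of the two
subjects' feature vectors, so the kernel is symmetric PSD by
construction.  Modalities differ in feature count and physical scale, so
before any combination each kernel is normalized to unit diagonal,
`K_ij / sqrt(K_ii K_jj)` — equivalent to projecting every subject's
feature vector onto the unit sphere.  Normalization is undefined for a
subject with a zero feature vector; that is a hard error naming the
subject, never a silent drop.  No per-feature centering or
standardization is applied by default — the per-subject normalization is
the only rescaling — but both are available as opt-in flags on
`linear_kernel` for users whose features live on incommensurable scales.
Validation accepts a user-supplied kernel as PSD when its smallest
eigenvalue is ≥ −1e−8 × the largest, which tolerates the round-off
negatives of rank-deficient p ≫ n kernels.

Subjects are aligned across modality files by explicit ID match, never
by row position.

## The dual SVM solver

`KernelSVC` maximizes the soft-margin dual (box constraints `0 ≤ α_i ≤
C`, equality `Σ y_i α_i = 0`) with sequential minimal optimization using
first-order maximal-violating-pair selection, stopping when the KKT gap
falls below `tol` (default 1e−10; loose enough to be cheap at m ≲ 50,
tight enough that α agrees with a brute-force QP solve to ~1e−8).  The
bias is the mean of `y_i − Σ_j α_j y_j K_ij` over margin support vectors
(`tol < α < C − tol`); when every α sits on a box bound the midpoint of
the KKT-admissible interval is used.  `sign(0) = +1` everywhere a label
is taken from a decision value.  `C = 1` is the fixed default for
single-kernel, SK, AV and MV classifiers — the conventional choice for
p ≫ n neuroimaging kernels, where the margin term rather than the box is
what regularizes; only MKL exposes C to tuning.

The constraint formulation includes the bias term: the printed primal in
some sources omits `b` from the margin inequality, but the dual equality
constraint `Σ y_i α_i = 0` only arises when the bias is present, so the
implementation follows the standard (LIBSVM-style) biased form.

## Elastic-net multi-kernel learning

MKL learns non-negative per-kernel weights β jointly with the SVM.  The
penalty interpolates between the two classic regularizers on the
per-kernel weight-vector blocks `w_k`:

    penalty(w) = 1/2 [ (1 − λ)(Σ_k ‖w_k‖)² + λ Σ_k ‖w_k‖² ]

λ = 0 is the squared block-L1 norm — simplex MKL, which drives the
weights of uninformative kernels to zero — and λ = 1 is the block-L2
norm, which is algebraically identical to a plain SVM on the un-weighted
kernel sum, i.e. SK.  **Note the convention: λ = 0 sparse, λ = 1
uniform**, the opposite of part of the MKL literature.  Two properties
recommended this interpolation over a literal L1+L2 penalty on the β
vector itself: (i) at λ = 1 the learned weights are *exactly* uniform,
matching the stated uniform limit rather than merely approaching it, and
(ii) because the squared-L1 term is scale-free in the block norms, the
weight profile depends on the kernels' relative informativeness, not on
the absolute scale of the dual solution (a literal β-penalty switches
between all-uniform and all-zero as C crosses a data-dependent
threshold).

Optimization uses the variational identity `(Σ‖w_k‖)² = min_{γ ∈
simplex} Σ ‖w_k‖²/γ_k` and alternates two exact minimizations of the
jointly convex objective: an SVM dual solve on `Σ η_k K_k` with `η_k =
γ_k/((1−λ) + λγ_k)` (warm-started from the previous α), and the
closed-form update `γ_k = ‖w_k‖ / Σ_j ‖w_j‖` with `‖w_k‖² = η_k² ·
(αy)ᵀK_k(αy)`.  Both steps decrease the objective, so the per-iteration
objective path is monotone (asserted in tests).  Convergence is declared
at relative objective change < 1e−6; the iteration cap is 500 because
near the sparse regime the weight of a dying kernel decays geometrically
with a ratio close to 1 and a 200-iteration cap stops measurably short
of the 1e−6 criterion.  Non-convergence raises an error carrying the
trailing objective values.  Base kernels are normalized before MKL by
default, for comparability with SK.

Hyperparameters are tuned by `MKLGridSearchCV`: a nested grid search
over C (decade grid 0.001…1000; a six-value 0.001…100 variant is
provided because "six steps from 0.001 increasing by orders of
magnitude" is ambiguous) and λ (0.1…1.0 in steps of 0.1), scored by
inner-CV balanced accuracy on the training subjects only, ties broken
toward larger λ then smaller C (the more uniform, more regularized
model).  Inner CV is leave-one-out by default, stratified k-fold as a
faster option.  The regime sweeps below use fixed λ instead of the full
nested search: a nested LOO × 70-point grid inside an outer LOOCV is
~10⁵ MKL fits, which is out of desk-scale proportion to what the sweep
measures.  The fixed values are study conditions chosen from the
methods' intent: λ = 0.5 (neutral mixing) for the complementary and
redundant regimes, λ = 0.1 (sparse regime, the point of MKL when some
kernels are noise) for the one-noisy regime; C = 1 throughout.

## Prediction-level fusion

AV averages the base classifiers' real-valued decision values and takes
the sign — magnitudes carry confidence, so one confident classifier can
outvote two lukewarm ones.  MV keeps only the signs; for an even number
of voters ties are possible and must be broken by an a-priori rule:
`av-sign` (fall back to the sign of the summed decision values, the
default), `fixed-negative`, or `fixed-positive`.  The comparison
pipeline skips MV for even-size combinations unless a tie rule is
configured explicitly, since the tie heuristic rather than the data
would drive those classifications.  Voting ties that were broken are
counted and reported.

## Evaluation machinery

Leave-one-out CV trains on m−1 subjects and scores the held-out one; for
linear kernels, slicing rows/columns of the full-data kernel is exactly
the fold kernel (cross-checked in tests against per-fold refits on raw
features).  Accuracy is the exact fraction correct; balanced accuracy is
the mean of sensitivity and specificity and coincides with accuracy for
equal groups (asserted on every result).  A fold whose training labels
collapse to one class is an error naming the fold.

Permutation tests permute the label vector (count-preserving — the
conventional reading of "random reassignment" with fixed groups;
independent reassignment is available as an option), re-run the full
LOOCV per replicate, and report p = #{null ≥ true}/n_perm — the plain
count/n estimator, with the (count+1)/(n+1) variant as a flag.
Replicate r draws from a generator seeded `seed + r`, making the null
distribution bitwise reproducible.

McNemar's test compares two classifiers' correct/incorrect indicators
(the standard choice for accuracy comparison; raw labels would conflate
disagreement with error).  With b + c < 25 discordant pairs the exact
two-sided binomial p is used (2·P(X ≤ min(b,c)), capped at 1), otherwise
the continuity-corrected chi-square; b = c = 0 yields p = 1 with an
explicit "no discordant pairs" note.  Pooled comparisons concatenate the
indicators across contexts before testing.  Holm–Bonferroni correction
is the standard step-down procedure (via statsmodels).

BSMCA — the best single-modality classification accuracy within a
combination — is the maximum single-kernel LOOCV accuracy over exactly
the kernels in that combination; ties go to the first kernel in
canonical (configuration) order and are flagged.

## Synthetic data generator

For subject i (label y_i ∈ {−1, +1}) and modality k, an informative
feature j is

    x_ijk = y_i·d_k + g_ik + σ_k·ε_ijk,   g_ik = √ρ·z_i + √(1−ρ)·u_ik

with z_i shared across modalities, u_ik modality-specific, ε i.i.d.
feature noise (all standard normal).  The unit-variance subject factor
g is the nuisance that drives misclassification: at ρ = 1 all modalities
err on the same subjects (redundant), at ρ = 0 their errors are
independent (complementary) — which is precisely the quantity that
determines whether fusion can help.  Uninformative features are pure
noise; a modality with informative fraction 0 is all noise.  An optional
block-correlation flag (off by default) gives features crude spatial
correlation.

Defaults mirror a small clinical imaging study: 19 subjects per class,
three modalities, p ≫ n.  The preset effect sizes were calibrated once
by simulation (`scripts/calibrate_presets.py`) so that a single modality
reaches the ~65–75% solo-accuracy band typical of such studies: d = 0.70
for the p = 400 presets, d = 0.60 at paper scale (p in the thousands).
Presets: `complementary` (ρ = 0), `redundant` (ρ = 1), `one-noisy` (one
informative modality + two all-noise), `all-noise` (null), and
`paper-scale` (p ∈ {5000, 3000, 4000}, ρ = 0.5).

The MKL weight-recovery diagnostic uses a separate config — one
*clearly* informative kernel (d = 1.5, ~90% solo accuracy) plus two
pure-noise kernels — because the correct weighting is only unambiguous
when the informative kernel is unambiguous: at band-level signal
(solo ~70%) the convex MKL objective legitimately retains weight on
near-identity noise kernels, which reduce training hinge loss the way a
ridge term does.

What the generator does *not* emulate: spatial autocorrelation of real
voxel data (beyond the crude block option), site/scanner effects,
non-Gaussian tails, and group-size imbalance pathologies.  Passing the
regime tests therefore shows the methods behave as the complementarity
arithmetic predicts under clean Gaussian conditions — not that fusion
will help on any particular real dataset, where the degree of
complementary information is an empirical unknown.

## Numerical and reproducibility choices

* SMO tolerance 1e−10, iteration cap 5×10⁵; dual feasibility is held to
  1e−6 in tests.  Support vectors are α > 1e−8·C.
* Warm starts across MKL outer iterations clip the previous α to the
  box and repair the equality constraint coordinate-wise before
  iterating.
* Kernel symmetry is enforced exactly after construction
  ((K + Kᵀ)/2); PSD tolerance −1e−8 relative.
* All subset enumeration, tie-breaking and output ordering follow the
  canonical kernel order (order of appearance in the configuration), so
  outputs are deterministic; result CSVs embed the master seed in a
  header comment and rerunning with the same config and seed reproduces
  them byte-for-byte.
* Simulation scales in the shipped experiments (e.g. 20 null datasets ×
  100 permutations; 10 seeds per fusion regime) are chosen to keep the
  full suite in the tens of minutes on one CPU while leaving the
  binomial/median acceptance margins interpretable; the evaluation
  functions default to the conventional 1000 permutations.

## Known limitations

* Binary classification only; no multi-class schemes, no probability
  calibration, no ROC/AUC.
* Linear kernels only (no RBF/polynomial, no kernel products); no
  primal weight-map extraction for voxel visualization.
* MKL convergence in the deep-sparse regime (λ → 0 with several dying
  kernels) can require hundreds of outer iterations; the objective is
  convex so the endpoint is well-defined, but runtime grows.
* The LOOCV + small-m setting carries the usual caveats: accuracy
  estimates have ~8-point sampling noise at m = 38, and the BSMCA, as a
  maximum over noisy estimates, is upward-biased — deltas against it
  are conservative.
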