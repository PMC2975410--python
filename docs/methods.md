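# Methods

This note documents the models and procedures implemented in `genepu`,
the parameter defaults and why they hold, the numerical choices, what the
simulators do and do not emulate, and the package's known limitations.

## Setting and assumptions

Each functional class defines one binary task over a fixed gene universe
with a positive set *P* (curated annotations) and an unlabeled set *U*
(everything else; contains hidden positives). The method assumes a
max-margin classifier over a gene-by-gene kernel is appropriate, that
hidden positives are a minority of *U*, and that the geometry of the
positive class is locally convex enough that points between neighboring
positives are themselves plausible positives. The negative "class" is
assumed heterogeneous — "not annotated to this term" covers many
unrelated functions — which is why a *representative* negative subset is
preferable to either all of *U* or a random sample.

## Stage 1 — synthetic positive oversampling

For each positive **e**, the k nearest positives are found (k = 10;
distances from explicit features when available, else the kernel-induced
metric d(i,j) = √(Kᵢᵢ + Kⱼⱼ − 2Kᵢⱼ), which equals the feature-space
Euclidean distance for inner-product kernels; kNN ties break by ascending
index for determinism). n of the k neighbors are drawn uniformly without
replacement — n = round(amount/100) clamped to [0, k], so a 500%
enlargement uses 5 neighbors — and one synthetic point
ẽ = α·e + (1−α)·e′, α ~ U(0,1) rejecting exact endpoints, is created per
chosen neighbor; exactly n·|P| synthetics in total. The guarantee is
elementary: if wᵀx + b > 0 for both parents, then
wᵀẽ + b = α(wᵀe + b) + (1−α)(wᵀe′ + b) > 0, so the enlargement can never
introduce an example a separating hyperplane would call negative. The
enlargement amount per class follows the annotation-size schedule
(4×, 2×, 1×, 0× for <60, 60–100, 100–300, ≥300 positives); classes with
at least 300 positives get no synthesis.

Synthetic points need no explicit coordinates: for a PSD kernel,
K(s, x) = αK(e, x) + (1−α)K(e′, x) extends the kernel by bilinearity
(implemented as coefficient-matrix products; the synthetic–synthetic
block follows the same expansion). For prediction against the original,
unextended kernel, `collapse_synthetic_supports` folds each synthetic
support vector's dual weight back onto its parents — an exact
transformation by the same bilinearity.

## Stage 2 — representative negative extraction

10% of P̃ and 10% of *U* (ceil counts) are held out as validation V. A
one-class SVM with ν = 0.10 is fit on all training points; unlabeled
points it scores as outliers form N₁ (if it flags none, the fallback
takes the 10% of unlabeled genes with the smallest mean kernel similarity
to the positives, with a warning). Iteration i trains a two-class SVM on
P̃′ vs Nᵢ at fixed C = 1 (hyperparameter search is deliberately deferred
to stage 3), scores the remaining unlabeled pool U′, and forms
Nᵢ₊₁ = N_pred ∪ N_SVs where N_pred is the ≤ m·|P̃′| points with the most
negative decision values among those predicted negative (m = 3; decision
magnitude is the natural SVM confidence) and N_SVs are the negative
support vectors, the minimal summary of the previous negative set. N_pred
leaves U′, so |U′| strictly decreases. The loop runs while
|U′| ≥ 4·|P̃′| and also exits if no new negative is predicted. Each
iteration's classifier then labels V (held-out positives +1, held-out
unlabeled −1 — a biased but consistent selection signal, since hidden
positives in V penalize all iterations equally) and the negative set of
the best-F1 iteration is returned as RN, ties to the earliest iteration;
if every F1 is 0, the last set is returned with a warning.

The "boundary marches toward the positives" picture is quantified by the
mean geometric margin f(x)/‖w‖ of the positives, which shrinks from the
first to the last iteration in essentially all seeded 2-D runs (asserted
at ≥ 80% over 20 seeds). Note the raw decision values of hidden positives
typically *decrease* slightly across iterations in well-separated data:
they start deep inside the positive side, and a boundary moving closer
shrinks every margin. A criterion based on increasing hidden-positive
scores only makes sense when hidden positives start misclassified.

## Stage 3 — final classifier

The final SVM trains on P̃ ∪ RN. Precomputed-kernel mode grid-searches C
over {2⁻⁵, 2⁻³, …, 2¹⁵}; explicit-feature (RBF) mode additionally grids
g over {2⁻¹⁵, …, 2³}. Model selection is stratified 5-fold CV maximizing
F1, with the NaN→0 rule applied per fold and ties broken toward smaller C
then smaller g (making the search invariant to grid order).

**Leakage-aware folds.** Oversampling before cross-validation is the
classic way to fool model selection: a synthetic point lying between two
parents in the training folds makes memorizing hyperparameters look
perfect on the validation fold. Folds are therefore formed over the
original examples only; a synthetic joins a fold's training part only
when both its parents train there, and synthetics are never scored as
validation cases. Without this guard the RBF grid occasionally selected a
memorizing g (CV F1 = 1.0) whose holdout recall was 0.

## Kernel integration

Expression: missing entries are imputed by weighted k-nearest gene rows
(k = 10; squared distances over co-observed columns rescaled by the
inverse co-observed fraction; weights ∝ 1/distance, exact-duplicate
donors take over with equal weight; a column observed in no donor falls
back to the column mean; observed entries are never modified), then
K = exp(−γ‖xᵢ−xⱼ‖²) with γ = 2 (a flag standardizes columns first;
default is raw values). Interactions: K = exp(βH) with H = A − D and
β = 2, computed by dense symmetric eigendecomposition — exact at the
desk scale this package targets (n up to a few thousand); H annihilates
the all-ones vector, so rows sum to 1 and the kernel is a lazy-random-
walk similarity. Sequence or other precomputed similarities are read as
TSV with symmetry enforced by (K + Kᵀ)/2. Each source is double-centered
and then cosine-normalized (unit self-similarity; a 1e-10 ridge guards
diagonals in (0, 1e-10], and a nonpositive diagonal is an error naming
the gene) before the entrywise sum, so no source dominates by scale.
Center-then-normalize is chosen because normalizing after centering gives
every gene unit self-similarity in each source.

## Simulators: what they emulate, and what they don't

`simulate_pu_dataset` draws positives from one isotropic Gaussian at the
origin and negatives from an equal-weight mixture of three Gaussian
components at distance `separation` from the origin in random directions
— the multimodality exercises the representativeness logic, since a
random negative sample can miss a component. Labeled positives are a
uniform subset of the positives; the rest hide in *U*; row order is
shuffled. The standard benchmark suite is n_labeled_pos = 20,
n_hidden_pos = 80, n_neg = 900, d = 10, separation = 4, noise_sd = 1,
seeds 1–20, with 20% of *P* and of *U* held out per seed for evaluation.
Erdős–Rényi graphs and iid-Gaussian expression matrices with Bernoulli
missingness (fully-missing rows re-masked) cover the kernel-building
stages.

What passing these tests shows: the contracts hold (caps, termination,
disjointness, determinism), the guarantees are exact (convexity,
bilinearity), and catastrophic imbalance failure is avoided. What they do
not show: performance on real annotation data. Real similarity structure
is not Gaussian, hidden-positive rates vary per term, and class overlap
is far heavier. Two behaviors expected from the real-annotation regime do **not**
reproduce under these easy, well-separated conditions: the balanced
random-negative baseline does not overfit (|P| random negatives already
outline a separable negative class, so its mean F1 edges out the full
pipeline by ~0.01 here, and its seed variance is not elevated), and the
4× enlargement, by scaling the |U′| < 4·|P̃′| stopping threshold, halts
the boundary march after ~2 iterations, leaving near-boundary negatives
unclaimed and costing precision. Both are properties of the method's
published stopping rule interacting with the simulation geometry, and
they are reported as measured.

## Numerical choices and degenerate inputs

- All randomness flows from `numpy.random.default_rng` seeded per run; a
  single top-level seed makes whole-pipeline runs byte-identical.
- F1 uses the NaN→0 convention by default (0/0 precision or recall);
  group variance is the population variance (divide by n), with a flag
  for sample variance. ROC is the normalized Mann–Whitney rank statistic;
  ties count 1/2; single-class truth yields NaN.
- Kernel symmetry is enforced at 1e-8 and repaired by averaging; PSD
  checks warn at eigenvalues below −1e-6 but proceed (the bilinear
  extension is only *meaningful* for inner-product kernels).
- The one-class stage needs a kernel whose feature embedding lies in one
  orthant (RBF and similarity kernels qualify); on centered kernels it
  can degenerate, which the smallest-mean-similarity fallback covers.
- Group boundaries are half-open so every count maps to exactly one
  group; gene identifiers are opaque case-sensitive strings.
- `psol_lite` is a deliberately simplified two-step rendition of the
  dispersion-based selection idea (greedy max-min approximation of an
  NP-hard criterion, |P| initial negatives, growth capped at 3·|P| per
  round, stop below 4·|P|); it makes no claim of fidelity to the original
  PSoL algorithm.

## Limitations

Dense kernels cap the practical universe at a few thousand genes. The
reduction of an ontology to a working term list is taken as given — any
term list works, none is derived. GAF support is a thin two-column
extractor (no evidence-code filtering, no is_a/part_of distinction).
Kernel weights in the sum are uniform; learning them is out of scope.
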