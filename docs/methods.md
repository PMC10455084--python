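# Methods

## Problem setting

Open-set recognition: training data contain K known classes; test data
mix those classes with classes never seen in training. The system must
(a) detect whether a test sample belongs to any known class and (b) name
the species when it does. Stage 1 is a one-class decision over the pooled
known-class training set (a single hypersphere, not one per class — the
pipeline treats "known" as one concept and leaves species identity to
stage 2; a per-class-union mode exists behind `mode="per-class"` for
exploration). Stage 2 is an exchangeable multi-class backend.

## Weighted SVDD

The primal encloses the mapped training data in a minimal sphere with
weighted slack penalties; the dual is a box-constrained QP on the simplex

    max  Σ αᵢ Kᵢᵢ − ΣΣ αᵢ αⱼ Kᵢⱼ     s.t.  Σ αᵢ = 1,  0 ≤ αᵢ ≤ C·wᵢ.

Feasibility requires Σ C·wᵢ ≥ 1; this is checked explicitly and violated
instances raise with advice to increase C, since commonly quoted cost
values silently assume it.

**Weights.** The weighting scheme is a design choice of this package:
wᵢ = exp(−dᵢ²/(2·median dⱼ²)), rescaled to max 1, where dᵢ² is the
kernel-space squared distance of sample i to the empirical centroid
(computable from the gram matrix alone). It encodes "concentrated
samples weigh more, outliers less", reduces to near-uniform on clean
data, and degrades to exactly uniform when all points coincide.
User-supplied weights are accepted everywhere; uniform weights recover
standard SVDD exactly, which the tests assert bit-for-bit.

**Solver.** Deterministic SMO-style coordinate ascent on maximal
violating pairs: the equality constraint is preserved by moving mass
between the coordinate with the largest gradient (still below its box
cap) and the one with the smallest (still above 0); the step has a
closed-form unconstrained optimum, clipped to the box. Initialization is
uniform 1/n clipped to the bounds with the deficit spread over remaining
capacity; convergence when the maximal KKT violation drops below
tol = 1e−6. No randomness anywhere. Agreement with a dense
general-purpose QP solve is asserted to 1e−6 in objective on random
instances, and against minimal-enclosing-ball geometry in closed form.

**Radius.** R² is the mean squared center distance over unbounded
support vectors (tol < αᵢ < C·wᵢ − tol), which are equidistant from the
center in exact arithmetic; averaging damps floating-point spread. If no
unbounded SV exists, R² falls back to the largest squared distance among
samples strictly below their cap. Sub-tolerance alphas are zeroed and
the rest renormalized before the radius and center constant are
computed, so the stored support expansion is exactly the one used at
prediction time. The acceptance rule adds the solver tolerance to the
spec margin (d² ≤ R²(1+1e−9) + 1e−12 + tol) because boundary SVs agree
on d² only to within the solver tolerance; decisions at practical score
gaps are unaffected.

**Variants.** `svdd` = uniform weights; `wsvdd` = centroid weights;
`ocsvm` = uniform weights, relying on the standard result that for
unit-diagonal kernels (RBF) the one-class-SVM hyperplane and the SVDD
sphere induce identical accept/reject decisions — asserted in the tests
rather than re-derived by a second optimizer.

## Hyperparameter search

Only known-class data exist at tuning time. The default criterion is
**leave-one-class-out detection F1**: each known class in turn plays the
role of a surrogate unknown; stage 1 is fitted on a stratified 80 % of
the remaining classes and scored by the detection F1 over the held-out
20 % (as knowns) plus the surrogate class (as unknowns). This simulates
openness with the data at hand and trades coverage against tightness.
The earlier-considered criterion of maximizing held-out *acceptance*
alone is retained (`criterion="acceptance"`) but demoted to diagnostics:
acceptance is monotone in sphere looseness, so on unimodal synthetic
data it always selects the loosest grid point and yields a stage 1 with
poor unknown rejection. Ties prefer larger γ (the tightest sphere among
equals), then smaller C. The library default operating point when no
search is run is γ = 0.5, C = 7.5.

The grid used in the shipped benchmark spans γ ∈ {0.001, 0.005, 0.02,
0.05, 0.1, 0.5} — from below the median-pairwise-distance heuristic
(≈ 0.004 on the synthetic geometry) through the variance-matched 1/dim
= 0.02 up to 0.5 — and C ∈ {0.5, 2, 7.5}.

## Baselines

All baselines use raw Euclidean distance. OSNN-CV accepts with the
shared label of the two nearest training samples (ties broken by lowest
index). OSNN-NNDR accepts the nearest sample's class iff the ratio of
its distance to the distance of the nearest *other-class* sample is
below T (strict; T = 0.35 is the conventional operating point; the
"other" sample is excluded by class, not by identity). NCM accepts the
nearest class centroid's label iff the distance is strictly below T;
centroid ties resolve in label sort order. The tuned-T protocol for NCM
mirrors the framework's search: stratified 3-fold CV over a quantile
grid of distance-to-own-centroid values, maximizing held-out acceptance
with ties to the smallest T — no unknown-class information is used.

## Metrics

Detection counts score known-vs-unknown detection only: a known-class
sample is "right" when predicted as *any* known label. This is the only
reading under which a closed-set classifier has recall exactly 1 and
its F1 collapses to 2k/(2k+u) for a test set with k known and u unknown
samples — the analytic anchors 0.1667 (75/750) and 0.4444 (150/375).
Species-level correctness is scored by P₀ and Cohen's κ over the
(K+1)-class confusion matrix in which all unknown species collapse into
one UNKNOWN class; per-unknown-species predictions are impossible by
construction, so the collapsed convention is the default. A literal K+U
reading is available as `kappa_ku`: unknown species then have zero
predicted-count marginals, so they contribute nothing to Pₑ. All 0/0
ratios are defined as 0; Pₑ = 1 defines κ = 1 iff agreement is perfect.

## Synthetic data

The generator emulates the geometry of deep-embedding class clusters:
class centers drawn uniformly on a radius-`center_scale` hypersphere,
samples = center + isotropic Gaussian noise. Defaults — 5 known + 10
unknown classes, 75 samples per class, dim 50, center_scale 8, unit
noise — keep the 15×75 shape of a typical leaf benchmark at desk scale
(real CNN embeddings are 1000-D; the separation-to-noise geometry, not
the ambient dimension, drives the methods). Expected within-class
squared pair distance is 2·dim·σ² = 100 versus ≳ 164 between classes,
so clusters overlap in radius yet separate under high-dimensional
concentration — deliberately not trivially separable. What passing
tests show is that the pipeline orders correctly and detects reliably
under this geometry; they do not certify performance on real embedding
manifolds, which are anisotropic, curved and class-imbalanced.

The benchmark protocol is the 8:2 per-class hold-out (floor on the
train share; at 75 samples per class this is exactly 60/15): 5 known
classes give 300 train / 825 test, 10 give 600 / 525. Benchmarks
average seeds 1–10 with grid-searched (γ, C) per seed; 3 folds / LOCO
splits keep a full two-case, ten-seed comparison around a minute of CPU.

## LBP front end

Radius-1, 8-neighbor local binary pattern with raw 256-bin histograms:
bit b of a pixel's code is set iff the b-th neighbor — clockwise from
the top-left, first neighbor in the most significant bit — is ≥ the
center (ties count as inliers); border pixels are excluded and the
histogram is normalized to sum 1. The 59-bin uniform-pattern variant
(≤ 2 circular transitions; one catch-all bin) is available behind a
flag. The dialect (start corner, orientation, bit order, tie rule) is a
documented package convention; histograms from other LBP dialects are
bin permutations of this one.

## Known limitations

- Stage-1 rejection is a hard sphere test; no calibrated rejection
  scores or ROC sweeps are offered.
- The SMO solver is dense (O(n²) memory in the gram matrix); it is
  sized for the hundreds-to-thousands regime of the intended use, not
  for n ≫ 10⁴.
- The default backend (nearest class mean) is deliberately simple; for
  real embeddings a stronger backend should be plugged in through the
  fit/predict contract.
- Grid search assumes RBF kernels; linear kernels are kept for
  closed-form geometry tests rather than production use.
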