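# Methods

## Scope and data model

The package quantifies brain-tissue volumes from a co-registered pair
of intensity volumes — one anatomical (T1-MRI-like contrast: CSF dark,
WM bright) and one functional (FDG-PET-like contrast: GM bright) — and
classifies subject-level feature vectors with a one-class model. All
images are 2D slices or 3D grids of scalar intensities normalised to
[0, 1]; the three tissues are fixed in the canonical order (CSF, GM,
WM), which also fixes integer label ids. Skull stripping, registration
and N3-style retrospective bias correction are assumed done upstream;
the package's own bias handling (below) addresses the residual smooth
inhomogeneity.

## Tissue modelling

### Bias-corrected fuzzy c-means

BCFCM minimises the fuzzy objective with an additive per-voxel bias
field β and a neighbourhood regulariser (weight α, 3×3 or 3×3×3
window without the centre, periodic boundary handling so every voxel
has exactly N_R neighbours and the neighbourhood relation is
symmetric). Three design choices matter:

* **The bias field is restricted to an affine (degree-1 polynomial)
  function of the voxel coordinates.** An unconstrained per-voxel β
  can absorb the entire image — the corrected intensities collapse
  onto a weighted centroid average and the centroids coincide — and a
  quadratic basis can mimic compact, radially symmetric anatomy. An
  affine ramp is the smooth field that remains identifiable from
  anatomical structure; `ClusterConfig.bias_degree` raises the degree
  when the scanner profile is known to be more curved than the
  anatomy.
* **Every block update is an exact coordinate minimiser.** Memberships
  and centroids follow the standard constrained minimisation; the bias
  update is a weighted least-squares projection of the unconstrained
  per-voxel minimiser onto the affine subspace. Objective traces are
  therefore non-increasing by construction (asserted to 1e-9 per step
  in the tests), and iteration stops when |ΔJ| < ε.
* **The estimated bias is subtracted before the downstream stages.**
  Correcting intensity inhomogeneity is the purpose of this step; the
  genetic refinement and the possibilistic modelling all operate on
  the corrected intensities. Empirically this is where the hybrid's
  robustness comes from: at 20% noise with a 20% bias ramp the hybrid
  chain reaches mean per-tissue Tanimoto overlap ≈ 0.8 versus ≈ 0.6
  for plain FCM on the same filtered images (recomputed by
  `scripts/acceptance.py`).

### Genetic refinement

A population of Ω = 10 chromosomes (each the centroid set of one
seeded BCFCM run) evolves for 20 generations with fitness-proportional
selection on 1/(1+w), single elitism, one-point crossover at centroid
boundaries (P_c = 0.8) and per-gene Gaussian mutation (P_m = 0.01,
scale 5% of the feature range). The merit w assigns each voxel to its
nearest chromosome centre and sums weighted squared distances to the
per-cluster gravity centres; empty clusters contribute nothing and are
re-seeded from random data points during mutation. Best-so-far fitness
is monotone by elitism. Voxel weights default to 1.

### Possibilistic-fuzzy c-means

PFCM is initialised with the GA-best centroids and their induced fuzzy
partition, and iterates exact block updates of memberships (FCM form),
typicalities t = 1/(1+(b·d²/γ)^{1/(η−1)}) and centroids weighted by
a·uᵐ + b·tᵎ until |ΔJ| < ε. The per-cluster penalties γᵢ default to
the fuzzy intra-cluster spread of the initialising partition
(multiplier K = 1) and stay fixed during the fit. The typicality
matrix, reshaped per tissue, provides the possibility maps passed to
fusion — typicalities are absolute degrees, which is what a
possibility distribution requires; the relative memberships are kept
for inspection and drive hard labelling of a single modality.

Parameter defaults: C = 3 clusters, fuzzifier m = 2 (the customary
[1.5, 3] sweep's retained value), possibilistic exponent η = 4
(midpoint of the customary [3, 5] range), trade-offs a = b = 1,
neighbourhood weight α = 0.7 (raise for noisier images), convergence
ε = 0.005 with a 200-iteration safety cap. Tests that compare against
fixed points tighten ε.

### Numerical conventions

* Zero distance: a voxel exactly on a centroid takes membership (and
  typicality) 1 there, shared equally if several centroids coincide.
* Coincident centroids at convergence raise a `RuntimeWarning` (the
  known pure-possibilistic failure mode).
* Random initialisation draws spread data points k-means++-style from
  the seeded generator; plain uniform draws from a WM-dominated image
  frequently place all centroids in one intensity mode, which FCM
  escapes but possibilistic models do not.
* Distances are squared Euclidean throughout.

## Fusion

Per tissue, the agreement h = 1 − mean|π₁ − π₂| over the foreground
is computed, then one of four operators combines the two maps
voxel-wise. h is floored at 1e-6 before any division (h = 0 would be
undefined; at low h the cautious branch of FOP4 dominates anyway), and
operators 1, 3 and 4 — which can exceed 1 as renormalised T-norms when
min > h — are clamped back into [0, 1]; the partial-volume
normalisation later removes any residual scale effect. FOP4 is the
default operator. CSF is never fused: the anatomical CSF map passes
through verbatim, because the functional channel carries no reliable
CSF information.

## Decision

Labelling takes the per-voxel argmax of the fused maps; exact ties go
to the earlier tissue in the canonical order and are counted in
`LabelMap.n_ties`; voxels whose possibilities are all zero get the
background label (−1). Partial volumes renormalise the fused degrees
and sum to one on foreground by construction. The synthesis image is
the partial-volume-weighted sum of the functional-modality PFCM
centroids (mean functional activity per tissue), hence linear in the
centroid vector and bounded by its extremes. Volumetry reports both
soft volumes (integrated fractions × voxel volume) and hard volumes
(label counts). The default subject feature vector for classification
concatenates the three soft-volume fractions and the three per-tissue
mean synthesis intensities.

## SVDD

The dual QP (maximise Σα_i K(x_i,x_i) − ΣΣ α_i α_j K(x_i,x_j) subject
to Σα = 1, 0 ≤ α ≤ C) is solved by a deterministic most-violating-pair
coordinate ascent to KKT tolerance 1e-6. R² is the mean squared
distance of the unbounded support vectors (0 < α < C), falling back to
the farthest support vector when the solution leaves none unbounded
(e.g. N = 1). The RBF kernel is K(x,y) = exp(−‖x−y‖²/σ²); σ = 0 is
mapped to the linear kernel, since a zero-width RBF is meaningless.
The standard constraint ‖x−a‖² ≤ R² + ξ is used. Grid search scores
each (σ, C) cell by k-fold one-class cross-validation — mean of the
held-out-target accept rate and the outlier reject rate — with
deterministic ties toward smaller C, then smaller σ.

Divide-and-conquer training partitions the target set with seeded
k-means (10 restarts), solves a local SVDD per cell, and retrains on
the union of the local support vectors. The final stage reuses the
original C; local penalties are floored at 1/n_cell so the equality
constraint stays feasible in small cells. The model records the
k·O((N/k)³) work estimate and the pooled local support-vector count.
The continuous score R² − distance² is exposed for ROC construction,
since the raw decision is binary.

## Evaluation harness

Tanimoto and Jaccard overlap return 0 by convention when both masks
are empty (flagged in the docstring); sensitivity/specificity return
`None` rather than 0 when their denominators vanish. ROC curves sweep
all unique score thresholds; the trapezoid area equals the
Mann–Whitney concordance statistic with ties counting one half, which
the tests verify against a pairwise oracle. The cross-validation
harness implements the protocol actually described — 10 independent
stratified 70/30 resamples — with standard disjoint stratified k-fold
available via `scheme="kfold"`. Summaries report boxplot five-number
statistics with mild (1.5·IQR) and extreme (3·IQR) outlier counts.

## The phantom generator

Geometry is nested concentric regions — CSF core, GM ring, WM
exterior — with linear partial-volume mixing across a band of
`pv_width` voxels at each interface; ground-truth fractions sum to 1
and labels are their argmax. "SNR x%" noise is additive white Gaussian
noise with standard deviation x% of the intensity dynamic range (the
stated levels span 1–20%). The intensity-inhomogeneity surrogate is a
smooth diagonal linear ramp scaled so max|field| equals
`bias_amplitude` × dynamic range (default 20%), added to the
anatomical channel. Default tissue means are (0.10, 0.50, 0.90)
anatomical and (0.05, 0.90, 0.40) functional.

What the phantom does **not** emulate: realistic anatomy (no atlas
warping), MR physics or PET kinetics, spatially correlated noise,
multiplicative bias, or motion/registration error. Passing phantom
tests therefore demonstrates algorithmic correctness and the stated
robustness ordering under controlled corruption — not clinical
performance on real cohorts.

## Problem sizes

Validation runs use sizes chosen to keep the whole suite fast while
leaving every effect measurable: 64×64 phantoms for exact-limit
recovery (the "noiseless phantom" is the exact limit — zero noise,
zero bias, sharp boundaries — where ground truth is unambiguous),
48×48 phantoms over 10 seeds for the 20%-noise robustness comparison
(GA scaled to 6 chromosomes × 10 generations there), 500-point
two-blob sets for divide-and-conquer, and a 70/30 synthetic cohort of
6-feature subjects (target/outlier separation 3σ — discriminably
different but overlapping populations) for the classification
metrics.

## Known limitations

* PFCM centroids can drift toward heavier neighbouring clusters when
  classes are strongly imbalanced and overlapping; the bias-corrected
  initialisation mitigates but does not remove this.
* The affine bias subspace cannot represent strongly curved scanner
  profiles; raising `bias_degree` trades identifiability for
  flexibility.
* The SMO-style solver is quadratic-memory in the kernel matrix;
  divide-and-conquer is the intended route for large cohorts.
* Equal-error rate is interpolated linearly between bracketing ROC
  points and has no calibrated target value.
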