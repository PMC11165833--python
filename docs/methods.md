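# Methods

This note documents the models, defaults, numerical choices and limitations
of `conngrad`. It is written for users who want to understand what the
pipeline computes and what the synthetic validation does and does not show.

## Pipeline model

**Consensus connectome.** Individual structural connectomes over-represent
short edges (stronger and more reproducibly tracked), so a group matrix built
from globally most-consistent edges is biased short. The distance-dependent
procedure used here: pool every edge nonzero in at least one subject; split
the pool into `n_bins` (default 10) equal-count bins of Euclidean
inter-centroid distance; give each bin a quota equal to the rounded mean
per-subject nonzero-edge count in that bin; fill each quota in a fixed total
order — consistency (fraction of subjects with a nonzero weight) descending,
then mean nonzero weight descending, then lexicographic (i, j); a retained
edge's weight is the mean over the subjects in which it is nonzero. Two
commitments go beyond the published sketch of this family of methods and are
this package's own: the deterministic tie-break chain (reproducibility
requires a total order) and a connectivity guarantee — the
maximum-spanning-tree edges of the subject-mean matrix are always added
(logged), because an isolated parcel makes the affinity kernel undefined
downstream. `uniform_consensus` is the comparison baseline: same edge count,
globally most-consistent edges, no distance stratification. Consensus is
computed over all subjects by default (`subjects=` switches to a group).

**Affinity and diffusion map.** Each row of the input matrix is thresholded
at its own `sparsity` quantile (default 0.9, i.e. keep the strongest ~10% of
each connectivity profile); similarity between thresholded rows is the
normalized angle `1 − (2/π)·arccos(cos θ)`, clipped to [0, 1], unit diagonal.
The diffusion operator uses α = 0.5 (Fokker–Planck normalization):
`W' = W/(d^α dᵀ^α)`, `P = D'⁻¹W'`, eigendecomposed through the symmetric
conjugate `D_q^{1/2} P D_q^{-1/2}` for stability. The stationary eigenvector
(λ₀ = 1) is dropped; under the automatic diffusion-time rule the k-th
component is the unit-norm right eigenvector scaled by `λ_k/(1−λ_k)` (a fixed
`diffusion_time = t` gives `λ_k^t` instead). Eigenvector sign is fixed by
making the entry of largest magnitude positive. Variance explained is
`λ_k / Σ_{j≥1} max(λ_j, 0)` over the full nontrivial spectrum. A repeated
unit eigenvalue means the affinity graph is disconnected and raises an error
rather than returning an unbounded `λ/(1−λ)` scale; during cohort embedding
such subjects are excluded with a logged reason. K defaults to 3 gradients
and is configurable (sensitivity variants use 4, 7, 11).

**Alignment and eccentricity.** Individual embeddings (same kernel
parameters) are aligned to the template by orthogonal Procrustes over all K
components jointly — reflections allowed, no centering, and deliberately no
scaling, because a per-subject scale would absorb exactly the global
expansion/contraction signal eccentricity is meant to carry. Eccentricity of
region i in subject s is `‖g_i^{(s)} − c‖₂` over the first K components. The
center `c` defaults to the template-manifold centroid so all subjects are
measured against one reference; a subject-wise centroid is selectable
(`center="subject"`). Only cortical regions enter eccentricity; the
subcortex is analyzed through degree.

**Inference.** The effect measure is the t of the group coefficient
(patient = 1) in OLS of each region's feature on
[1, group, age, sex(F = 1)], residual df = n − 4 (for a single contrast
F = t², so this is the ANCOVA group effect; dropping covariates reduces it
to the classical pooled two-sample t, which the covariate-free variant
uses). The null distribution permutes group labels over subjects — one
shared permutation per draw for all regions, preserving their spatial
correlation, which is what makes BH-FDR behave across correlated regions —
and `p = #{|t_perm| > |t_obs|}/n_perm` (strictly-greater counting, so p = 0
is attainable; an optional (b+1)/(n+1) correction exists and is off by
default). Default 10,000 permutations; tests use 200–2,000. A numerically
zero standard error (constant feature) yields t = 0, flagged degenerate.
q-values are Benjamini–Hochberg (via statsmodels); significance is
q < 0.05. Freedman–Lane residual permutation is not implemented — simple
relabeling is the literal design here; the flag namespace leaves room for it.

**Classification.** Within each training fold only: per-feature OLS of the
feature on [1, age, sex] and residualization of train and test with the
training coefficients; standardization by training mean/SD; LASSO on the 0/1
label with the penalty chosen by inner 5-fold CV over a log-spaced grid
(1e-4…1, 30 points); ordinary least squares on the selected columns. The
linear (not logistic) model on the binary label is intentional; scores are
thresholded at 0.5 for precision/recall of the patient class and pooled
across the 5 test folds for one ROC/AUC per repeat. If LASSO selects
nothing the fold falls back to the training base rate (logged). A
whole-sample pre-residualization mode (`nested_residualization=False`)
exists for comparison with pipelines that regress covariates out before CV;
the nested default is the statistically valid one, and the permuted-label
test verifying chance-level AUC is the leakage check.

## Synthetic cohort generator

The generator is the package's test bed and defines the study conditions.
Each region carries a latent position in a `latent_dim = 3` Gaussian cloud:
axis k is `s_k·(c·z_k + √(1−c²)·ε)` with standardized centroid axis `z_k`,
independent standard normal `ε`, scales `s = (1.4, 1.05, 0.8)` and spatial
coupling `c = 0.5` — so the leading recovered gradients emulate left–right
and anterior–posterior organization while the cloud stays volumetric. The
volumetric (full-rank Gaussian) form matters: kernel eigenfunctions over a
Gaussian cloud are near-linear in the coordinates, which is what makes
diffusion-map recovery of the planted axes provable and testable. Centroids
sit on mirrored hemispheric shells (radius 60 length units) with seven
spatially contiguous network wedges per hemisphere; hierarchy labels derive
deterministically from networks (somatomotor→idiotypic, limbic→paralimbic,
visual/dorsal-attention→unimodal, rest→heteromodal) so the planted network
classes coincide with hierarchy classes. Subcortical structures use fixed
interior centroids.

Edge weights: `w_ij = exp(−‖g_i−g_j‖)·exp(−d_ij/λ_d)` with `λ_d = 150`,
multiplied by log-normal noise `exp(σ·z)` (σ = 0.2, symmetric z), then
sparsified to `density = 0.35` by keeping the largest edges plus the cortical
maximum-spanning-tree (so no subject's cortical graph disconnects). Subject
individuality is i.i.d. latent-position noise with sd 0.25, chosen so that
individual aligned gradients correlate ~0.85–0.9 with the template — the
realistic range for individual-to-template structural-gradient alignment;
smaller values produce an implausibly homogeneous cohort.

Planted effects (defaults are the study conditions): patients' limbic-network
latent positions displaced radially outward by (1 + δ_e), δ_e = 0.5;
somatomotor positions inward by (1 − δ_c), δ_c = 0.3, both about the cortical
latent centroid; caudate/amygdala/accumbens rows and columns scaled by 1.5
(edges between two affected structures get the factor twice). With all
effects off the two groups are exchangeable by construction, which the null
calibration tests exploit. Covariates emulate a migraine clinic cohort:
47 patients / 41 controls by default, ~75% female, ages 25–50, phase mix
interictal/peri-ictal/ictal ≈ 55/13/32%, ~15% with aura, ~17% depression or
anxiety flags.

What the generator does **not** emulate: anatomical geometry (regions are
labeled wedges on a shell, not real parcels), tractography biases beyond a
generic distance penalty, hub/rich-club structure, site or head-motion
effects, and any clinical-score correlation. Passing tests therefore show
that the pipeline recovers effects expressed through latent-geometry
displacement and degree scaling — not that it would detect any particular
real-world pathology.

## Numerical choices

- Symmetry tolerance on input matrices 1e-8; asymmetric inputs are
  symmetrized as (A + Aᵀ)/2 with a warning. NaNs and negative weights are
  errors, not warnings.
- Eigendecomposition is a dense symmetric solve (parcel counts here are a
  few hundred at most); the oracle tests compare against an independent
  dense eigensolve of the non-symmetric operator.
- The degenerate-t floor is `1e-10·(1 + max|y|)` on the standard error.
- Result tables round floats to 6 significant digits; region ordering (by
  0-based id) and subject ordering (subjects.tsv row order) are canonical.
- One root seed spawns all stage seeds via a seeded generator; every
  documented entry point is bit-reproducible under a fixed seed.

## Known limitations

- **Effect leakage in embedding space.** A planted displacement of ~28% of
  cortical regions changes every subject's whole embedding: the non-planted
  group-difference field is roughly 15–25% of the planted field in norm,
  about a third to a half of it attributable to systematic Procrustes
  rotation/scale mismatch between groups and the rest to the nonlinearity of
  the spectral embedding. At cohort sizes with high power this leakage
  becomes statistically significant outside the planted set; the pipeline
  localizes the *strongest* effects (the planted network is reliably the
  top-ranked class) but is not a surgical detector of effect boundaries.
- **Radial planting is radius-weighted.** The displacement rule moves a
  region in proportion to its distance from the latent centroid, so planted
  regions near the centroid carry intrinsically small effects and are the
  last to reach significance.
- **Third-axis identifiability.** With the default row-thresholded kernel,
  the third embedding component competes with harmonics of the first; exact
  per-axis recovery of a 3-axis latent geometry is only clean with a dense
  (unthresholded) kernel, which is how the recovery property is tested.
- The automatic `λ/(1−λ)` component scaling is sensitive when λ₁ → 1
  (near-disconnected affinity graphs); such subjects are excluded with a
  log message rather than silently embedded with an exploding scale.
- Spin-test or other spatial-autocorrelation-preserving nulls are out of
  scope; the permutation null is exchangeability of subjects, not of space.
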