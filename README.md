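# conngrad

Structural connectome gradient analysis for case–control cohort studies —
with episodic migraine as the motivating application — built as a tested,
reusable Python pipeline with scikit-learn-style estimators.

## The problem

Diffusion tractography yields, per subject, a weighted structural
connectivity matrix **W** over cortical parcels and subcortical structures.
Classical graph metrics summarize such matrices edge-by-edge or node-by-node;
*gradient* (manifold-learning) analysis instead asks how each region is
positioned along a few continuous axes of connectome organization, and how a
disease shifts those positions. `conngrad` implements that full workflow:

1. **Group-representative connectome** by *distance-dependent consensus
   thresholding*: pooled edges are binned by inter-centroid distance and each
   bin keeps its most consistent edges up to the average per-subject count,
   preserving long-range connections that uniform consistency thresholding
   discards.
2. **Gradients** by diffusion map embedding of a normalized-angle affinity
   kernel. With degrees `d_i`, the kernel is renormalized as
   `W'_ij = W_ij / (d_i^α d_j^α)` (α = 0.5) and the random-walk operator
   `P = D'⁻¹W'` is eigendecomposed; the k-th gradient is
   `ψ_k · λ_k/(1−λ_k)`. Individual embeddings are aligned to the template by
   orthogonal Procrustes (reflections allowed, no scaling).
3. **Manifold eccentricity**: per region and subject, the Euclidean distance
   `‖g_i − c‖₂` between the region's position over the first K gradients and
   the center of the template manifold. Expansion/contraction of this single
   scalar summarizes multivariate gradient reorganization.
4. **Group inference**: the t-statistic of the group term in
   `feature ~ 1 + group + age + sex`, with significance from permutation of
   group labels (one shared permutation across regions per draw;
   `p = #{|t_perm| > |t_obs|}/n_perm`) and Benjamini–Hochberg FDR across
   regions; results stratified by the seven functional networks and four
   cortical hierarchy levels.
5. **Subcortical degree**: the row sum of subcortico-cortical edge weights
   per structure (thalamus, caudate, putamen, pallidum, hippocampus,
   amygdala, accumbens), contrasted with the same permutation machinery.
6. **Classification**: LASSO feature selection (inner 5-fold CV over a
   log-spaced penalty grid) followed by a linear model on the selected
   eccentricity + degree features, evaluated by stratified 5-fold CV repeated
   100 times (precision, recall, AUC, per-feature selection probabilities).
7. **Sensitivity variants**: subject-subset reruns (aura exclusion, headache
   phase, depression/anxiety exclusion), gradient-count overrides, and a
   covariate-free rerun, each compared to the reference t-map by Pearson r.

Because patient MRI matrices of this kind are generally not shareable, the
package ships a first-class **synthetic cohort generator**: regions carry
latent positions in a low-dimensional Gaussian cloud, edge weights decay in
both latent and physical distance
(`w_ij ∝ exp(−‖g_i−g_j‖)·exp(−d_ij/λ_d)`), and group effects are planted as
radial expansion of limbic-network positions, contraction of somatomotor
positions, and a multiplicative degree factor on caudate/amygdala/accumbens
rows. Every downstream stage is validated end-to-end against this generator.

## Worked example

```python
import conngrad as cg

cfg = cg.SimulationConfig(n_patients=24, n_controls=24, seed=7)
cohort = cg.simulate_cohort(cfg)
out = cg.contrast_pipeline(cohort, n_perm=2000, seed=7)

print(f"variance explained by G1-G3: {out.template.variance_explained.sum():.1%}")
print(f"significant regions (FDR < 0.05): {int(out.result.significant.sum())} of 100")
print(f"strongest network: {out.network_summary.max_class()}")
```

prints

```
variance explained by G1-G3: 18.8%
significant regions (FDR < 0.05): 29 of 100
strongest network: limbic
```

The three template gradients explain 18.8% of the (synthetic) connectome's
affinity spectrum; 29 regions differ significantly between the simulated
patients and controls, and stratifying the t-map shows the limbic network —
where the expansion was planted — carrying the strongest effect. Continuing
with the subcortex and the classifier:

```python
kept = cohort.subjects["subject_id"].isin(out.gradients.subject_ids).to_numpy()
subjects = cohort.subjects.loc[kept]
degree = cg.subcortical_degree(cohort.subset(kept))
covariates = cg.encode_covariates(subjects["age"].to_numpy(), subjects["sex"].to_numpy())
deg_res = cg.subcortical_contrast(degree, subjects["group"].to_numpy(),
                                  covariates=covariates, n_perm=2000, seed=7)
features = cg.build_feature_table(out.eccentricity, degree)
report = cg.cross_validated_classify(features, subjects["group"].to_numpy(),
                                     covariates=covariates, n_repeats=20, seed=7)
```

reports the six planted structures (caudate, amygdala, accumbens bilaterally)
among the significant subcortical degrees and

```
classification: AUC 1.00 +/- 0.00, precision 0.98, recall 0.99
```

— planted effects at these magnitudes are fully separable; real cohorts sit
well below this ceiling.

A `conngrad` command-line interface mirrors the library
(`simulate`, `consensus`, `gradients`, `eccentricity`, `stats`,
`subcortical`, `classify`, `sensitivity`, `run-all`); `run-all` drives the
whole pipeline from one YAML config and a single root seed.

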