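# Methods

## The model

`subgrad` estimates **subcortical-to-cortical functional connectivity
gradients**: each subcortical voxel is assigned a position in a
low-dimensional embedding such that voxels with similar whole-cortex
connectivity profiles lie close together. The per-subject estimator is a
five-stage deterministic composition:

1. **Cortical PCA compression.** With far fewer timepoints than cortical
   voxels (`t << b`), the `[t x b]` cortical time-series matrix has rank at
   most `t - 1`, so its PC score series (`[t x min(t-1, b)]`) carry the
   complete row-space geometry. Correlating against PC scores instead of
   individual voxels loses nothing about voxel-voxel *similarity* (checked
   explicitly: the fingerprint-derived similarity matrix correlates r > 0.98
   with the brute-force voxelwise one on synthetic subjects). When
   `b > 2t` the scores are computed from the `[t x t]` Gram matrix
   (eigenvectors scaled by the square roots of the eigenvalues), which is
   algebraically identical to the thin SVD and much faster.
2. **Connectivity fingerprints.** Pearson correlation of every subcortical
   voxel with every PC score series, `[a x p]`, `p = min(t-1, b)`.
   Zero-variance voxels are a hard error, never silently dropped — dropping
   would desynchronize the voxel order that all downstream stages share.
3. **Row thresholding.** Each row keeps its top `ceil(density * p)` entries
   by *signed* value (default density 0.10); ties break toward the lowest
   column index. The discarded entries become structural zeros and the rows
   are subsequently compared over all `p` coordinates.
4. **Affinity.** Pairwise row similarity: Pearson (default), Spearman,
   cosine, normalized angle (`1 - arccos(cos)/pi`), or a self-tuning
   Gaussian kernel (`gamma` = 1 / median nonzero squared pairwise distance).
   The matrix is symmetrized by averaging with its transpose and the
   diagonal fixed at 1.
5. **Spectral embedding.** Diffusion maps by default (`alpha = 0.5`,
   `diffusion_time = 0`, i.e. the multi-scale `lambda / (1 - lambda)`
   coordinate scaling, with the non-trivial eigenvectors divided by the
   stationary one — the conventions of the widely used gradient toolboxes);
   Laplacian eigenmaps and PCA of the affinity rows as alternatives for the
   stability analysis. Negative affinities are clipped to zero before the
   diffusion/Laplacian embeddings (both require non-negative kernels); the
   PCA variant sees the signed matrix. A disconnected affinity graph is an
   error reported with its component count. Column signs follow a fixed
   rule (largest-magnitude coordinate positive) so repeated runs are
   byte-identical.

**Group template and alignment.** Spectral embeddings are defined only up
to component order, sign, and rotations of near-degenerate eigenspaces, so
per-subject gradients are not voxel-comparable. All subjects' gradients are
stacked side-by-side (`[a x k*n]`) and the first `k` left singular vectors
form the group template; each subject is then mapped onto it by closed-form
Procrustes (translation + isotropic scaling + rotation, reflections
allowed). Scaling is deliberate: the desk-scale diffusion amplitude
`lambda/(1-lambda)` is numerically volatile across subjects, and the full
similarity transform puts every subject on the template's scale so that the
downstream variance statistics compare gradient *shape*. At small voxel
counts individual subjects often split the main axis across two
near-degenerate components; the template concentrates the shared structure
into its leading column and the per-subject rotation recovers it, which is
why planted-axis recovery is assessed on aligned gradients.

**Harmonization.** A parametric empirical-Bayes location/scale batch model
(the ComBat family) is implemented in-package and applied per gradient
column with voxels as features and subjects as observations. Batch
location and scale parameters are estimated per voxel, shrunk toward
normal / inverse-gamma priors moment-matched across voxels, and removed;
the design covariates to preserve (two control-referenced group indicator
columns) are re-added. A single batch is a no-op; a batch with one subject
is rejected (its scale is inestimable).

## The statistical battery

- **ROI summaries**: per subject x ROI x gradient mean and unbiased
  (`n-1`) variance over member voxels; per-subject **global variance** of a
  gradient over all voxels. **Multivariate dispersion** (mean squared
  distance to the centroid) deliberately uses the `n` denominator so that
  its 1-D case is the population-variance form of univariate dispersion;
  both conventions are documented and tested.
- **Expansion test**: one-tailed Welch t-test of patient vs control global
  gradient-1 variance (expansion direction = patients larger), with
  Cohen's d on the pooled SD and an optional Bonferroni factor for the
  separate L/R patient-group tests. Welch is used because group variances
  are not assumed equal; the choice is a package decision.
- **Ipsi/contra flipping**: L-lateralized patients' left ROIs become
  ipsilateral, right ROIs contralateral; R-lateralized the reverse;
  controls keep L/R labels. The mapping is an involution.
- **Control-referenced z-scoring**: patient ROI statistics are z-scored
  against the side-matched control distribution (left to control-left,
  never to contralateral controls) *before* flipping; subject-space group
  contrasts are t-tests on these z-scores.
- **Permutation tests**: group labels are shuffled preserving group sizes;
  each pseudo-subject's ipsilateral side is re-derived from its assigned
  label, so the null absorbs any intrinsic hemispheric asymmetry. The
  two-tailed p centers exceedances at the null median and uses the
  `(k+1)/(n+1)` add-one convention (one-sided exceedance for non-negative
  distance statistics). Default 2000 permutations.
- **Bhattacharyya distances**: closed form for bivariate normal summaries
  of (gradient 1, gradient 2) ROI clouds,
  `D = (1/8) dmu' Sbar^-1 dmu + (1/2) ln(det Sbar / sqrt(det S1 det S2))`.
  Near-singular covariances receive a numerical ridge
  (`1e-10 x` mean eigenvalue). Inside the *permutation statistic* the
  Gaussian fits use 5% covariance shrinkage: voxel-wise group averaging
  shrinks residual scatter so strongly that the smallest covariance
  eigenvalue is noise, and the unshrunk distance fluctuates by an order of
  magnitude across realizations of the same effect. Shrinkage is applied
  identically to the observed and permuted statistics; null calibration
  after the change is 0.060 at alpha = 0.05 over 200 null cohorts.
- **Clinical model**: per-ROI OLS of a patient gradient statistic on
  laterality (R = 1), MTS, BTCS and disease duration, with Bonferroni
  correction across the four covariate terms.
- **Stability analysis**: all 5 kernels x 3 embeddings are run end-to-end
  (each variant aligned and harmonized within itself), patients' first two
  aligned gradients are cohort-averaged, and variants are compared by
  |Pearson r| (magnitude, because gradients are aligned within but not
  across variants). A failed variant yields NaN entries, never fabricated
  values.

## The synthetic cohort generator

The generator emulates the data regime the pipeline consumes, with a
planted scalar **connectopic axis**:

- Named ROIs (thalamus, caudate, putamen, pallidum, hippocampus, amygdala)
  occupy disjoint segments of an interior band `[0.15, 0.85]` of the
  cortical sheet coordinate; the axis is linear in voxel index within each
  block. Left/right homologs mirror each other (same segment) — homologous
  regions have near-identical connectivity in real data, and the mirror
  symmetry makes group labels exchangeable at null.
- `m = 5` latent network signals (i.i.d. standard normal over `t`
  timepoints) drive the cortical sheet through unit-norm Gaussian-bump
  loadings over the sheet coordinate (soft communities). Cortical
  observation noise is a field of *localized* random bump modes
  (width 0.03 of the sheet): real cortical signals are spatially smooth,
  and the local modes are what give connectivity fingerprints their high
  effective rank. Localized rather than stationary modes are deliberate —
  interval eigenmodes (cosines) peak coherently at both sheet ends and
  would spuriously couple the two ends of the axis into a horseshoe.
- Each subcortical voxel pools the cortical time-series around its
  (group-effective) axis position through a unit-norm Gaussian kernel
  (width 0.08) plus its own white noise (sd 0.8 against unit-variance
  pooled signal).
- The global mean signal is regressed out of the cortical sheet only,
  emulating confound-cleaned input. It is *not* regressed from the
  subcortical rows: removing a shared component from the rows being
  embedded induces the classic global-signal-regression artifact (mutual
  anticorrelation with the bulk), which couples the axis ends.
- **Planted effects.** Expansion: patients' generating axis is affinely
  stretched about its midpoint so its spread exceeds the controls' by
  exactly `expansion_factor` (default 1.5). Lateralized shift: the
  ipsilateral hippocampus of the configured patient groups (default R-TLE
  only, reproducing an asymmetric right-greater-than-left ipsilateral
  effect) is offset along the axis by `hippocampus_shift` (default 0.3).
  Batch effects: protocol 2 recordings get a multiplicative amplitude
  factor and an additive batch confound realized as a spatially
  heterogeneous shared time-course — a time-constant offset would be
  invisible to correlation-based connectivity, and a spatially flat one
  would vanish under the global-signal cleaning. An optional knob couples
  disease duration to per-subject expansion for model-recovery tests.
- Cohort shape defaults mirror a 71-participant two-protocol study
  (16 controls / 31 L-TLE / 24 R-TLE; protocol split about 46/55 for
  patients and 8/16 for controls), with MTS, BTCS and duration drawn from
  per-group distributions matching that cohort's demographics table.
- Everything planted is recorded in a `GroundTruth` manifest
  (axis, mixing weights, per-group effective axes and effect maps, batch
  parameters), so recovery tests never re-run the simulator. The axis
  layout and effect maps are configuration-determined; only noise and
  covariates depend on the seed.

**What the generator does not emulate**: hemodynamics, head motion,
physiological confounds, spatial 3-D structure (the sheet is 1-D), scanner
drift, or any causal disease biology. Passing tests show the *pipeline*
recovers what was planted under this idealized linear regime; they are not
evidence about real fMRI.

## Problem sizes and numerical choices

- Desk-scale default dimensions: `a = 300`, `b = 2000`, `t = 200`,
  `m = 5`; 20 embedding components are retained for cohort analyses (the
  proportional analog of keeping 250 of ~9000 voxels; `embed` itself
  returns up to 250 components when requested, and all retained columns are
  aligned and harmonized).
- Calibration runs use 200 label-exchangeable cohorts of 8/8/8 subjects at
  `a = 120, b = 500, t = 100` with 500 permutations. Expansion power runs
  use 50 replicate cohorts of 80 controls vs 40+40 patients; lateralized
  shift power runs use 50 replicates of the 16/31/24 default cohort. These
  sizes are the package's own simulation-design choices.
- Eigenvalues are reported both raw (native operator scale) and normalized
  by the total positive spectrum; Laplacian-eigenmap importances are
  reported as `1 - lambda` so every method orders gradients by descending
  importance.
- Degenerate inputs are rejected loudly with the stage name attached:
  zero-variance voxels, constant fingerprint rows under correlation
  kernels, non-symmetric or disconnected affinities, all-zero gradient
  sets, singleton batches, rank-deficient clinical designs.

## Known limitations

- Per-subject (unaligned) gradient 1 is an unreliable estimator of the
  planted axis at `a = 300` — the leading eigenspace is often
  near-degenerate and the axis splits across two components. All scientific
  claims are made on aligned gradients; this mirrors why the template-
  alignment stage exists at all.
- The subject-level gradient-1 variance responds to planted expansion with
  a cohort-level Cohen's d of roughly 0.4-1.2 at the default conditions;
  single-cohort effect sizes are noisy, and the acceptance summary averages
  d over five replicate cohorts.
- The label-permutation test for lateralized contrasts absorbs hemispheric
  asymmetry into its null by construction and is therefore less powerful
  than the control-referenced z-score t-test when the planted effect is
  itself a hemispheric asymmetry; both are reported.
- The parametric ComBat variant only; no non-parametric or longitudinal
  modes, and no more than the two-protocol batch structure is modeled.
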