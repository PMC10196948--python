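# subgrad

Subcortical-to-cortical **functional connectivity gradients**: per-subject
gradient estimation, group-template Procrustes alignment, batch
harmonization, and the gradient-space statistical battery used to compare
patient groups — plus a synthetic fMRI cohort generator with planted ground
truth for validating every stage.

## Who this is for

Neuroimaging researchers studying how the connectivity organization of
subcortical structures (thalamus, striatum, hippocampus, amygdala, ...)
differs between groups — for example between temporal lobe epilepsy (TLE)
patients with left- vs right-lateralized seizure onset and healthy
controls. The package consumes *already preprocessed* (confound-regressed)
4-D fMRI time-series plus label volumes and a covariate table; it performs
no registration, confound regression, or surface rendering.

## The method

For each subject with subcortical time-series `[t x a]` and cortical
gray-matter time-series `[t x b]`:

1. reduce the cortex by PCA to `[t x min(t-1, b)]` score series (lossless
   for voxel-voxel similarity since `t << b`);
2. correlate every subcortical voxel with every PC score — the `[a x p]`
   connectivity fingerprint;
3. keep the top 10% of connections in each row;
4. build the `[a x a]` affinity matrix (Pearson row correlation by
   default; Spearman / cosine / normalized-angle / Gaussian kernels for
   stability analysis);
5. embed with diffusion maps (`alpha = 0.5`, multi-scale
   `lambda/(1-lambda)` scaling; Laplacian eigenmaps and PCA as
   alternatives) — the embedding coordinates are the **gradients**, ordered
   by eigenvalue.

Subjects' gradients are aligned to a group PCA template by closed-form
Procrustes (translation + scaling + rotation) and harmonized across
acquisition protocols with a parametric empirical-Bayes location/scale
batch model that preserves group contrasts. The statistical layer provides
ROI mean/variance summaries, gradient-expansion tests (one-tailed Welch t
on per-subject global gradient-1 variance, Cohen's d), ipsi/contralateral
relabeling by seizure laterality, control-referenced z-scoring,
label-permutation nulls (2000 shuffles, two-tailed add-one p), closed-form
Bhattacharyya distances between bivariate-normal ROI clouds in
(gradient 1, gradient 2) space, per-ROI clinical covariate models
(laterality, MTS, BTCS, disease duration; Bonferroni x4), and a 15-variant
kernel-by-embedding stability analysis.

See `docs/methods.md` for the model, conventions, and the synthetic
generator's design.

## Worked example

```python
import numpy as np
from subgrad import (SimulationConfig, generate_cohort, GradientParams,
                     global_variance, expansion_test)
from subgrad.pipeline import compute_stack
from scipy.stats import spearmanr

cohort = generate_cohort(SimulationConfig(seed=1))       # 71 subjects
stack, sets = compute_stack(cohort.recordings, GradientParams(n_components=20))

# does gradient 1 recover the planted connectopic axis?
r = spearmanr(stack.tensor.mean(axis=0)[:, 0],
              cohort.ground_truth.connectopic_axis).statistic
print(f"axis recovery |rho| = {abs(r):.3f}")

# is the planted 1.5x gradient expansion detected?
g = np.asarray(stack.groups)
gv = global_variance(stack, 1).to_numpy()
res = expansion_test(gv[g != "control"], gv[g == "control"])
print(f"expansion: d = {res.cohens_d:.2f}, one-tailed p = {res.p_value:.4f}")
```

Output (seed 1):

```
axis recovery |rho| = 0.985
expansion: d = 1.25, one-tailed p = 0.0003
```

The cohort-average aligned gradient 1 orders the 300 subcortical voxels
along the planted axis almost perfectly, and the patients' gradient-1
spread is significantly larger than the controls', as planted.

## Command line

```bash
subgrad simulate --config sim.yaml --out cohort/ --seed 1
subgrad gradients --ts sub-000_bold.nii --subcortex parc.nii --cortex mask.nii \
        --labels parcellation_labels.tsv --out gradients.tsv
subgrad run --config run.yaml      # end-to-end: gradients -> align -> harmonize -> stats
subgrad stability --cohort cohort/ --out stability.tsv
```

Every output table carries a provenance sidecar (config hash + seed) that
regenerates it exactly.

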