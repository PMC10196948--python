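"""Gradient-space statistics: ROI summaries, expansion metrics, permutation
nulls with ipsilateral/contralateral flipping, control-referenced z-scoring,
Bhattacharyya distances, clinical covariate models and the kernel-by-method
stability analysis.

Two complementary comparison frames are supported, mirroring how group
differences are usually assessed in gradient space:

* **average gradient space** — gradients are voxel-wise averaged within each
  group first, and group statistics are computed on the average clouds;
* **subject space** — the statistic (ROI mean / variance) is computed per
  subject and the per-subject values are compared across groups, after
  z-scoring to side-matched controls to cancel inherent left/right
  asymmetries.

Significance for lateralized contrasts comes from group-label permutation:
shuffling the L/R-lateralization labels (and re-deriving each subject's
ipsilateral side from its shuffled label) builds a null that absorbs any
intrinsic hemispheric asymmetry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .alignment import AlignedGradientStack, align_cohort, harmonize
from .gradients import (
    EMBEDDING_METHODS,
    KERNELS,
    PATIENT_GROUPS,
    GradientParams,
    ParcellationMap,
    PipelineError,
    SubjectRecording,
    compute_affinity,
    compute_fingerprint,
    embed,
    reduce_cortex_pca,
    threshold_rows,
)

# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------


@dataclass
class PermutationTestResult:
    observed: float
    null_sample: np.ndarray
    p_value: float
    n_perm: int
    seed: int
    alternative: str = "two-sided"

    def __post_init__(self) -> None:
        self.null_sample = np.asarray(self.null_sample, dtype=float)
        assert self.null_sample.size == self.n_perm
        assert 0 < self.p_value <= 1


@dataclass
class ExpansionTestResult:
    t_statistic: float
    p_value: float
    p_corrected: float
    cohens_d: float
    n_patient: int
    n_control: int


@dataclass
class GaussianSummary:
    """Bivariate normal fit of a (gradient 1, gradient 2) voxel cloud."""

    mu: np.ndarray
    sigma: np.ndarray
    singular: bool = False

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float).reshape(-1)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        if np.min(np.linalg.eigvalsh(self.sigma)) < -1e-10:
            raise ValueError("covariance must be positive semi-definite")


@dataclass
class ClinicalModelFit:
    """OLS fit of y ~ laterality + MTS + BTCS + duration for one response."""

    coefficients: dict[str, float]
    stderr: dict[str, float]
    p_values: dict[str, float]
    p_corrected: dict[str, float]
    response: tuple = ()
    n: int = 0


CLINICAL_TERMS = ("laterality", "mts", "btcs", "duration")


# ---------------------------------------------------------------------------
# ROI summaries and expansion metrics
# ---------------------------------------------------------------------------


def roi_stats(
    stack: AlignedGradientStack,
    parcellation: ParcellationMap,
    gradients: Sequence[int] = (1, 2),
) -> pd.DataFrame:
    """Per subject x ROI x gradient sample mean and unbiased variance.

    ``gradients`` are 1-based column indices. Output is tidy with columns
    subject_id, group, roi, side, gradient, mean, variance.
    """
    if stack.a != parcellation.a:
        raise PipelineError("roi_stats", "stack and parcellation voxel counts differ")
    rows = []
    for roi in parcellation.roi_names:
        for side in ("L", "R"):
            ix = parcellation.indices(roi, side)
            if ix.size == 0:
                raise PipelineError("roi_stats", f"empty ROI ({roi}, {side})")
            for g in gradients:
                vals = stack.tensor[:, ix, g - 1]  # [n_subjects x v]
                means = vals.mean(axis=1)
                variances = vals.var(axis=1, ddof=1) if ix.size > 1 else np.zeros(len(vals))
                for s in range(stack.n_subjects):
                    rows.append(
                        {
                            "subject_id": stack.subject_ids[s],
                            "group": stack.groups[s],
                            "roi": roi,
                            "side": side,
                            "gradient": g,
                            "mean": means[s],
                            "variance": variances[s],
                        }
                    )
    return pd.DataFrame(rows)


def global_variance(stack: AlignedGradientStack, gradient: int = 1) -> pd.Series:
    """Per-subject variance of one gradient over all subcortical voxels."""
    if not 1 <= gradient <= stack.k:
        raise PipelineError("global_variance", f"gradient {gradient} out of range 1..{stack.k}")
    v = stack.tensor[:, :, gradient - 1].var(axis=1, ddof=1)
    return pd.Series(v, index=pd.Index(stack.subject_ids, name="subject_id"), name=f"g{gradient}_variance")


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Classic Cohen's d with the pooled standard deviation."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = x.size, y.size
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 == 0:
        return 0.0
    return float((x.mean() - y.mean()) / np.sqrt(sp2))


def expansion_test(
    patient_vars: np.ndarray,
    control_vars: np.ndarray,
    one_tailed: bool = True,
    bonferroni: int = 1,
) -> ExpansionTestResult:
    """Welch t-test of patient vs control global gradient variance.

    One-tailed in the expansion direction (patients > controls) by default;
    ``bonferroni`` multiplies the p-value for family-wise correction (e.g. 2
    for the separate L/R patient-group tests).
    """
    x = np.asarray(patient_vars, float)
    y = np.asarray(control_vars, float)
    if x.size < 2 or y.size < 2:
        raise PipelineError("expansion_test", "need at least 2 subjects per group")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        raise PipelineError("expansion_test", "zero pooled variance")
    res = sps.ttest_ind(x, y, equal_var=False, alternative="greater" if one_tailed else "two-sided")
    p = float(res.pvalue)
    return ExpansionTestResult(
        t_statistic=float(res.statistic),
        p_value=p,
        p_corrected=min(1.0, bonferroni * p),
        cohens_d=cohens_d(x, y),
        n_patient=x.size,
        n_control=y.size,
    )


def multivariate_dispersion(coords: np.ndarray) -> float:
    """Mean squared Euclidean distance of points to their centroid.

    For 1-D input this equals the biased (n-denominator) variance — the
    univariate-dispersion equivalence; note it deliberately differs from the
    unbiased (n-1) convention used by :func:`roi_stats` / :func:`global_variance`.
    """
    X = np.asarray(coords, float)
    if X.ndim == 1:
        X = X[:, None]
    centered = X - X.mean(axis=0, keepdims=True)
    return float(np.mean(np.sum(centered**2, axis=1)))


# ---------------------------------------------------------------------------
# Laterality bookkeeping
# ---------------------------------------------------------------------------

_FLIP = {
    "L": {"L": "ipsi", "R": "contra", "ipsi": "L", "contra": "R"},
    "R": {"R": "ipsi", "L": "contra", "ipsi": "R", "contra": "L"},
}


def flip_to_ipsi_contra(stats: pd.DataFrame, laterality: Mapping[str, str]) -> pd.DataFrame:
    """Relabel patient ROI sides to ipsi/contra given each subject's SOZ side.

    L-lateralized subjects: left -> ipsi, right -> contra; R-lateralized the
    reverse. Control rows pass through unchanged. The mapping is an
    involution: applying it twice restores the L/R labels.
    """
    out = stats.copy()
    sides = out["side"].to_numpy(dtype=object)
    for i, (sid, group) in enumerate(zip(out["subject_id"], out["group"])):
        if group == "control":
            continue
        if sid not in laterality:
            raise PipelineError("flip_to_ipsi_contra", f"missing laterality for patient {sid!r}")
        lat = laterality[sid]
        if lat not in _FLIP:
            raise PipelineError("flip_to_ipsi_contra", f"laterality must be L or R, got {lat!r}")
        sides[i] = _FLIP[lat][sides[i]]
    out["side"] = sides
    return out


def group_average_gradient(stack: AlignedGradientStack, members: Sequence[int | str]) -> np.ndarray:
    """Voxel-wise mean gradient ``[a x k]`` over the given subjects."""
    if len(members) == 0:
        raise PipelineError("group_average_gradient", "empty group")
    if all(isinstance(m, str) for m in members):
        index = {sid: i for i, sid in enumerate(stack.subject_ids)}
        idx = [index[m] for m in members]
    else:
        idx = list(members)
    return stack.tensor[idx].mean(axis=0)


def zscore_to_controls(
    patient_stats: pd.DataFrame, control_stats: pd.DataFrame, side_matched: bool = True
) -> pd.DataFrame:
    """Z-score patient ROI statistics against side-matched controls.

    Both frames must still carry L/R side labels (z-scoring happens *before*
    any ipsi/contra flip): a left-lateralized patient's left hippocampus is
    referenced to the controls' left hippocampus, never the right. Adds
    ``z_mean`` and ``z_variance`` columns.
    """
    keys = ["roi", "gradient"] + (["side"] if side_matched else [])
    ref = control_stats.groupby(keys)[["mean", "variance"]].agg(["mean", "std"])
    out = patient_stats.copy()
    z_cols = {stat: np.empty(len(out)) for stat in ("mean", "variance")}
    for i, row in enumerate(out.itertuples(index=False)):
        key = tuple(getattr(row, k) for k in keys)
        key = key if len(keys) > 1 else key[0]
        for stat in ("mean", "variance"):
            mu = ref.loc[key, (stat, "mean")]
            sd = ref.loc[key, (stat, "std")]
            if not np.isfinite(sd) or sd == 0:
                raise PipelineError(
                    "zscore_to_controls", f"zero/undefined control SD for {key} {stat}"
                )
            z_cols[stat][i] = (getattr(row, stat) - mu) / sd
    out["z_mean"] = z_cols["mean"]
    out["z_variance"] = z_cols["variance"]
    return out


# ---------------------------------------------------------------------------
# Permutation machinery
# ---------------------------------------------------------------------------


def _perm_p(observed: float, null: np.ndarray, alternative: str) -> float:
    n = null.size
    if alternative == "two-sided":
        # centered at the null median; add-one convention avoids p = 0
        med = np.median(null)
        k = int(np.sum(np.abs(null - med) >= np.abs(observed - med)))
    elif alternative == "greater":
        k = int(np.sum(null >= observed))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return (k + 1) / (n + 1)


def permutation_test(
    stat_fn: Callable[[list, list], float],
    group_a: Sequence,
    group_b: Sequence,
    n_perm: int = 2000,
    seed: int = 0,
    alternative: str = "two-sided",
) -> PermutationTestResult:
    """Group-label permutation test of an arbitrary two-group statistic.

    ``stat_fn(items_a, items_b)`` must be a pure function of the two groups;
    items carry whatever per-subject data the statistic needs (e.g. both
    hemispheres' voxel values, so that ipsi/contra flipping can follow the
    *assigned* label inside ``stat_fn``). The null shuffles subjects between
    groups preserving group sizes. The two-tailed p centers exceedances at
    the null median and uses the (k+1)/(n+1) convention.
    """
    items_a, items_b = list(group_a), list(group_b)
    if len(items_a) < 2 or len(items_b) < 2:
        raise PipelineError("permutation_test", "need at least 2 subjects per group")
    observed = float(stat_fn(items_a, items_b))
    pooled = items_a + items_b
    n_a = len(items_a)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(len(pooled))
        null[i] = stat_fn([pooled[j] for j in perm[:n_a]], [pooled[j] for j in perm[n_a:]])
    return PermutationTestResult(
        observed=observed,
        null_sample=null,
        p_value=_perm_p(observed, null, alternative),
        n_perm=n_perm,
        seed=seed,
        alternative=alternative,
    )


def subject_roi_clouds(
    stack: AlignedGradientStack,
    parcellation: ParcellationMap,
    roi: str,
    gradients: Sequence[int] = (1, 2),
    subjects: Optional[Sequence[int]] = None,
) -> list[dict[str, np.ndarray]]:
    """Per-subject {side -> [v x len(gradients)]} voxel clouds for one ROI."""
    cols = [g - 1 for g in gradients]
    idx = range(stack.n_subjects) if subjects is None else subjects
    out = []
    for s in idx:
        out.append(
            {
                side: stack.tensor[s][parcellation.indices(roi, side)][:, cols]
                for side in ("L", "R")
            }
        )
    return out


def avg_space_roi_mean_stat(
    side_a: str = "L", side_b: str = "R", gradient_col: int = 0
) -> Callable[[list, list], float]:
    """Average-gradient-space ROI contrast: difference of ROI means of the
    voxel-wise group-average gradients, group A read from ``side_a`` (its
    ipsilateral side) and group B from ``side_b``."""

    def stat(items_a: list, items_b: list) -> float:
        avg_a = np.mean([it[side_a] for it in items_a], axis=0)
        avg_b = np.mean([it[side_b] for it in items_b], axis=0)
        return float(avg_a[:, gradient_col].mean() - avg_b[:, gradient_col].mean())

    return stat


def subject_space_roi_mean_stat(
    side_a: str = "L", side_b: str = "R", gradient_col: int = 0
) -> Callable[[list, list], float]:
    """Subject-space ROI contrast: difference of group means of per-subject
    ROI mean gradient values."""

    def stat(items_a: list, items_b: list) -> float:
        mean_a = np.mean([it[side_a][:, gradient_col].mean() for it in items_a])
        mean_b = np.mean([it[side_b][:, gradient_col].mean() for it in items_b])
        return float(mean_a - mean_b)

    return stat


# ---------------------------------------------------------------------------
# Bivariate-normal summaries and Bhattacharyya distance
# ---------------------------------------------------------------------------


def fit_gaussian2d(
    g1_values: np.ndarray, g2_values: np.ndarray, shrinkage: float = 0.0
) -> GaussianSummary:
    """Sample mean and covariance of a (gradient 1, gradient 2) cloud.

    ``shrinkage`` adds a ridge of that fraction of the mean eigenvalue to
    the covariance — small voxel clouds (and especially voxel-wise group
    averages, whose residual scatter is strongly shrunk) yield
    ill-conditioned covariances whose near-null eigenvalues are pure noise.
    """
    x = np.asarray(g1_values, float)
    y = np.asarray(g2_values, float)
    if x.size != y.size or x.size < 2:
        raise PipelineError("fit_gaussian2d", "need >= 2 paired voxels")
    X = np.column_stack([x, y])
    mu = X.mean(axis=0)
    sigma = np.atleast_2d(np.cov(X.T, ddof=1))
    if shrinkage > 0:
        sigma = sigma + shrinkage * (np.trace(sigma) / sigma.shape[0]) * np.eye(sigma.shape[0])
    evals = np.linalg.eigvalsh(sigma)
    singular = bool(evals.min() <= 1e-12 * max(evals.max(), 1e-300))
    return GaussianSummary(mu=mu, sigma=sigma, singular=singular)


def _stabilized(sigma: np.ndarray) -> tuple[np.ndarray, bool]:
    evals = np.linalg.eigvalsh(sigma)
    if evals.min() > 1e-12 * max(evals.max(), 1e-300) and evals.min() > 0:
        return sigma, False
    eps = 1e-10 * np.trace(sigma) / sigma.shape[0]
    if eps <= 0:
        eps = 1e-300
    return sigma + eps * np.eye(sigma.shape[0]), True


def bhattacharyya_distance(p: GaussianSummary, q: GaussianSummary) -> float:
    """Closed-form Bhattacharyya distance between two multivariate normals.

    ``D = (1/8) dmu' S^-1 dmu + (1/2) ln( det S / sqrt(det S1 det S2) )``
    with ``S = (S1 + S2)/2``. Symmetric, non-negative, zero iff the
    distributions coincide. Near-singular covariances are ridge-stabilized
    (eps = 1e-10 * mean eigenvalue) before inversion.
    """
    s1, _ = _stabilized(p.sigma)
    s2, _ = _stabilized(q.sigma)
    sbar = (s1 + s2) / 2.0
    dmu = p.mu - q.mu
    sign, logdet_bar = np.linalg.slogdet(sbar)
    if sign <= 0:
        raise PipelineError("bhattacharyya_distance", "non-PSD pooled covariance")
    _, logdet1 = np.linalg.slogdet(s1)
    _, logdet2 = np.linalg.slogdet(s2)
    term_mu = 0.125 * dmu @ np.linalg.solve(sbar, dmu)
    term_cov = 0.5 * (logdet_bar - 0.5 * (logdet1 + logdet2))
    return float(term_mu + term_cov)


def bhattacharyya_permutation(
    clouds_a: Sequence[Mapping[str, np.ndarray]],
    clouds_b: Sequence[Mapping[str, np.ndarray]],
    side_a: str = "L",
    side_b: str = "R",
    n_perm: int = 2000,
    seed: int = 0,
    shrinkage: float = 0.05,
) -> PermutationTestResult:
    """Permutation test on the Bhattacharyya distance between group-average
    2-D ROI distributions.

    Each subject contributes both hemispheres' voxel clouds; group A reads
    ``side_a`` (its ipsilateral side) and group B reads ``side_b``, so the
    label shuffle re-derives each pseudo-subject's ipsilateral cloud from its
    assigned label exactly as the observed statistic does. One-sided
    exceedance p (the distance is non-negative). The Gaussian fits use 5%
    covariance shrinkage by default: voxel-wise averaging leaves the
    group-average clouds with near-singular covariances whose smallest
    eigenvalues are noise, and the unshrunk distance is dominated by them.
    """

    def stat(items_a: list, items_b: list) -> float:
        avg_a = np.mean([it[side_a] for it in items_a], axis=0)
        avg_b = np.mean([it[side_b] for it in items_b], axis=0)
        ga = fit_gaussian2d(avg_a[:, 0], avg_a[:, 1], shrinkage=shrinkage)
        gb = fit_gaussian2d(avg_b[:, 0], avg_b[:, 1], shrinkage=shrinkage)
        return bhattacharyya_distance(ga, gb)

    return permutation_test(
        stat, list(clouds_a), list(clouds_b), n_perm=n_perm, seed=seed, alternative="greater"
    )


# ---------------------------------------------------------------------------
# Clinical covariate model
# ---------------------------------------------------------------------------


def fit_clinical_model(
    y: np.ndarray, covariates: pd.DataFrame, response: tuple = ()
) -> ClinicalModelFit:
    """OLS of a per-patient gradient statistic on clinical covariates.

    ``y = b0 + b_lat X_lat + b_MTS X_MTS + b_BTCS X_BTCS + b_dur X_dur``
    with ``X_lat = 1`` for right-lateralized patients. Per-coefficient
    p-values are Bonferroni-corrected across the four covariate terms.
    """
    import statsmodels.api as sm

    y = np.asarray(y, float)
    if y.size < 6:
        raise PipelineError("fit_clinical_model", "need at least 6 patients")
    if "laterality" in covariates:
        lat = covariates["laterality"].map({"L": 0.0, "R": 1.0, 0: 0.0, 1: 1.0}).to_numpy()
    else:
        lat = covariates["group"].map({"L-TLE": 0.0, "R-TLE": 1.0}).to_numpy()
    X = pd.DataFrame(
        {
            "laterality": lat,
            "mts": covariates["mts"].astype(float).to_numpy(),
            "btcs": covariates["btcs"].astype(float).to_numpy(),
            "duration": covariates["duration_years"].astype(float).to_numpy(),
        }
    )
    Xd = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xd.to_numpy())
    if rank < Xd.shape[1]:
        sds = Xd.to_numpy().std(axis=0)
        const_cols = [c for c, s in zip(Xd.columns[1:], sds[1:]) if s == 0]
        raise PipelineError(
            "fit_clinical_model",
            f"rank-deficient design (rank {rank} of {Xd.shape[1]}); constant columns: {const_cols}",
        )
    fit = sm.OLS(y, Xd).fit()
    names = ["const"] + list(X.columns)
    coeff = dict(zip(names, np.asarray(fit.params, float)))
    stderr = dict(zip(names, np.asarray(fit.bse, float)))
    pvals = dict(zip(names, np.asarray(fit.pvalues, float)))
    pcorr = {k: min(1.0, 4.0 * pvals[k]) for k in CLINICAL_TERMS}
    return ClinicalModelFit(
        coefficients=coeff,
        stderr=stderr,
        p_values=pvals,
        p_corrected=pcorr,
        response=response,
        n=y.size,
    )


# ---------------------------------------------------------------------------
# Kernel x embedding stability analysis
# ---------------------------------------------------------------------------


@dataclass
class StabilityResult:
    """Cross-variant agreement of cohort-average gradients.

    ``matrices[g]`` is the |Pearson r| matrix between the 15 kernel-by-method
    variants for gradient ``g+1``; entries for failed variants are NaN.
    """

    variants: list[str]
    matrices: np.ndarray  # [n_keep x 15 x 15]
    failed: list[str] = field(default_factory=list)


def stability_analysis(
    recordings: Sequence[SubjectRecording],
    kernels: Sequence[str] = KERNELS,
    methods: Sequence[str] = EMBEDDING_METHODS,
    n_keep: int = 2,
    params: GradientParams = GradientParams(),
) -> StabilityResult:
    """Run every kernel x embedding variant end-to-end and cross-correlate.

    For each variant the whole cohort is embedded, aligned to its own
    template and harmonized across protocols; patients' first ``n_keep``
    aligned gradients are averaged and compared across variants by the
    magnitude of the Pearson correlation (gradients of different variants
    are aligned within, not across, variants, so the sign is arbitrary).
    """
    groups = [r.group for r in recordings]
    batches = [r.protocol for r in recordings]
    # kernel/method-independent front end, computed once per subject
    fps = []
    for rec in recordings:
        scores = reduce_cortex_pca(rec.cortical_ts)
        fps.append(threshold_rows(compute_fingerprint(rec.subcortical_ts, scores), params.density))

    patient_ix = [i for i, g in enumerate(groups) if g in PATIENT_GROUPS]
    if not patient_ix:
        patient_ix = list(range(len(recordings)))

    labels: list[str] = []
    averages: list[Optional[np.ndarray]] = []
    failed: list[str] = []
    for kernel in kernels:
        affs = None
        try:
            affs = [compute_affinity(fp, kernel) for fp in fps]
        except Exception:
            pass
        for method in methods:
            label = f"{kernel}:{method}"
            labels.append(label)
            if affs is None:
                averages.append(None)
                failed.append(label)
                continue
            try:
                sets = [
                    embed(
                        aff,
                        method=method,
                        n_components=params.n_components,
                        alpha=params.alpha,
                        diffusion_time=params.diffusion_time,
                    )
                    for aff in affs
                ]
                stack = align_cohort(sets, k=params.n_components, groups=groups, batches=batches)
                if len(set(batches)) > 1:
                    stack = harmonize(stack)
                avg = stack.tensor[patient_ix].mean(axis=0)[:, :n_keep]
                averages.append(avg)
            except Exception:
                averages.append(None)
                failed.append(label)

    n_var = len(labels)
    mats = np.full((n_keep, n_var, n_var), np.nan)
    for g in range(n_keep):
        for i in range(n_var):
            if averages[i] is None:
                continue
            for j in range(i, n_var):
                if averages[j] is None:
                    continue
                r = np.corrcoef(averages[i][:, g], averages[j][:, g])[0, 1]
                mats[g, i, j] = mats[g, j, i] = abs(r)
    return StabilityResult(variants=labels, matrices=mats, failed=failed)
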