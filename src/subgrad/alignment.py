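"""Group template construction, Procrustes alignment and batch harmonization.

Spectral embeddings are defined only up to component order and sign (and,
across subjects, arbitrary rotations of near-degenerate eigenspaces), so
per-subject gradients are not voxel-comparable until aligned to a common
template. The template is the PCA basis of all subjects' gradients stacked
side by side; each subject is then mapped onto it by a closed-form
Procrustes transform (translation + isotropic scaling + rotation, with
reflections permitted). Residual protocol/scanner differences are removed
afterwards with a parametric empirical-Bayes location/scale batch model
(the ComBat family) that preserves the modeled group contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .gradients import GradientSet, PipelineError


@dataclass
class GradientTemplate:
    """Orthonormal ``[a x k]`` group basis for gradient alignment."""

    coords: np.ndarray
    source: int  # number of subjects stacked

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        gram = self.coords.T @ self.coords
        if not np.allclose(gram, np.eye(gram.shape[0]), atol=1e-10):
            raise ValueError("template columns must be orthonormal")


@dataclass
class AlignedGradientStack:
    """``[n_subjects x a x k]`` aligned (optionally harmonized) gradients."""

    tensor: np.ndarray
    subject_ids: list[str]
    groups: list[str]
    batches: list[str]
    harmonized: bool = False

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=float)
        if self.tensor.ndim != 3:
            raise ValueError("stack tensor must be [n x a x k]")
        n = self.tensor.shape[0]
        if not (len(self.subject_ids) == len(self.groups) == len(self.batches) == n):
            raise ValueError("subject metadata length must match tensor")

    @property
    def n_subjects(self) -> int:
        return self.tensor.shape[0]

    @property
    def a(self) -> int:
        return self.tensor.shape[1]

    @property
    def k(self) -> int:
        return self.tensor.shape[2]


def build_template(gradient_sets: Sequence[GradientSet], k: int = 250) -> GradientTemplate:
    """PCA basis of the horizontally stacked ``[a x (k_sub * n)]`` gradients.

    Each stacked column (one gradient of one subject) is treated as an
    observation in voxel space; the template is the first ``k`` left singular
    vectors. The stack is not re-centered: gradient coordinates are already
    centered near zero by construction, and omitting the centering keeps the
    template exactly inside the span of the subjects' gradients.
    """
    if not gradient_sets:
        raise PipelineError("build_template", "need at least one gradient set")
    a = gradient_sets[0].a
    k_sub = gradient_sets[0].k
    for gs in gradient_sets:
        if gs.a != a or gs.k != k_sub:
            raise PipelineError(
                "build_template",
                f"inconsistent gradient shapes: expected [{a} x {k_sub}], got [{gs.a} x {gs.k}]",
            )
    X = np.hstack([gs.coords for gs in gradient_sets])
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    k_eff = min(k, U.shape[1], a)
    return GradientTemplate(coords=U[:, :k_eff], source=len(gradient_sets))


def procrustes_align(
    source: GradientSet | np.ndarray,
    template: GradientTemplate,
    center: bool = True,
    scale: bool = True,
) -> np.ndarray:
    """Map source gradients onto the template by the optimal Procrustes transform.

    Closed form: (optionally) center both point sets, take the SVD of the
    cross-covariance ``Sc.T @ Tc = U S V.T``, rotate by ``R = U V.T``
    (reflections allowed), and (optionally) scale by
    ``trace(S) / ||Sc||_F^2`` and translate onto the template centroid. With
    ``center`` and ``scale`` on, this is the global minimizer of the
    Frobenius distance over all translation + isotropic scaling + orthogonal
    transformations, so aligning can never increase the distance to the
    template; with them off it is the classic orthogonal (rotation-only)
    Procrustes solution.
    """
    S = source.coords if isinstance(source, GradientSet) else np.asarray(source, dtype=float)
    T = template.coords
    if S.shape != T.shape:
        raise PipelineError(
            "procrustes_align", f"shape mismatch: source {S.shape} vs template {T.shape}"
        )
    mu_s = S.mean(axis=0) if center else np.zeros(S.shape[1])
    mu_t = T.mean(axis=0) if center else np.zeros(T.shape[1])
    Sc = S - mu_s
    Tc = T - mu_t
    norm_s = np.linalg.norm(Sc)
    if norm_s == 0:
        raise PipelineError("procrustes_align", "degenerate (constant) source gradients")
    U, sig, Vt = np.linalg.svd(Sc.T @ Tc, full_matrices=False)
    R = U @ Vt
    s = sig.sum() / norm_s**2 if scale else 1.0
    return s * (Sc @ R) + mu_t


def align_cohort(
    gradient_sets: Sequence[GradientSet],
    template: Optional[GradientTemplate] = None,
    k: int = 250,
    groups: Optional[Sequence[str]] = None,
    batches: Optional[Sequence[str]] = None,
    center: bool = True,
    scale: bool = True,
) -> AlignedGradientStack:
    """Build (or reuse) a template and Procrustes-align every subject to it.

    The full similarity transform (translation + isotropic scaling +
    rotation) is applied per subject, which puts all subjects' gradients on
    the template's scale; downstream variance comparisons therefore measure
    differences in gradient *shape*, not in per-subject embedding amplitude
    (the diffusion amplitude ``lambda/(1-lambda)`` is numerically volatile
    at small voxel counts). Pass ``center=False, scale=False`` for classic
    rotation-only alignment.
    """
    if template is None:
        template = build_template(gradient_sets, k=k)
    n = len(gradient_sets)
    aligned = np.stack(
        [procrustes_align(gs, template, center=center, scale=scale) for gs in gradient_sets]
    )
    ids = [str(gs.params.get("subject_id", i)) for i, gs in enumerate(gradient_sets)]
    return AlignedGradientStack(
        tensor=aligned,
        subject_ids=ids,
        groups=list(groups) if groups is not None else ["control"] * n,
        batches=list(batches) if batches is not None else ["batch-0"] * n,
        harmonized=False,
    )


# ---------------------------------------------------------------------------
# ComBat-style batch harmonization
# ---------------------------------------------------------------------------


def _combat_fit_transform(
    dat: np.ndarray, batch_idx: list[np.ndarray], design: np.ndarray, n_batch_cols: int
) -> np.ndarray:
    """Parametric empirical-Bayes location/scale adjustment of one data block.

    ``dat`` is ``[features x samples]``; ``design`` holds the batch one-hot
    columns first, then the covariates to preserve. Batch location (gamma)
    and scale (delta^2) are estimated per feature, shrunk toward
    batch-level normal / inverse-gamma priors fitted by moments, and removed
    from the standardized data; covariate effects and the pooled scale are
    then restored.
    """
    n_features, n_samples = dat.shape
    batch_sizes = np.array([len(ix) for ix in batch_idx])

    beta = np.linalg.lstsq(design, dat.T, rcond=None)[0]  # [n_design x features]
    grand_mean = (batch_sizes / n_samples) @ beta[:n_batch_cols]
    resid = dat - (design @ beta).T
    var_pooled = (resid**2).mean(axis=1)
    var_pooled = np.where(var_pooled == 0, 1e-24, var_pooled)

    stand_mean = grand_mean[:, None] + (design[:, n_batch_cols:] @ beta[n_batch_cols:]).T
    sd = np.sqrt(var_pooled)[:, None]
    s_data = (dat - stand_mean) / sd

    gamma_star = np.empty((len(batch_idx), n_features))
    delta_star = np.empty((len(batch_idx), n_features))
    for i, ix in enumerate(batch_idx):
        block = s_data[:, ix]
        g_hat = block.mean(axis=1)
        d_hat = block.var(axis=1, ddof=1)
        # moment-matched hyperpriors across features
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        m, s2 = d_hat.mean(), d_hat.var(ddof=1)
        if s2 == 0 or t2 == 0:
            gamma_star[i], delta_star[i] = g_hat, d_hat
            continue
        a_prior = (2 * s2 + m**2) / s2
        b_prior = (m * s2 + m**3) / s2
        n_b = len(ix)
        g_new, d_new = g_hat.copy(), d_hat.copy()
        for _ in range(200):
            g_old, d_old = g_new, d_new
            g_new = (t2 * n_b * g_hat + d_old * g_bar) / (t2 * n_b + d_old)
            sum2 = ((block - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (0.5 * sum2 + b_prior) / (n_b / 2.0 + a_prior - 1.0)
            if max(
                np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
                np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
            ) < 1e-6:
                break
        gamma_star[i], delta_star[i] = g_new, d_new

    out = np.empty_like(dat)
    for i, ix in enumerate(batch_idx):
        out[:, ix] = (s_data[:, ix] - gamma_star[i][:, None]) / np.sqrt(delta_star[i])[:, None]
    return out * sd + stand_mean


def harmonize(
    stack: AlignedGradientStack,
    batch_labels: Optional[Sequence[str]] = None,
    preserve_design: Optional[np.ndarray] = None,
) -> AlignedGradientStack:
    """Remove batch effects from an aligned stack, preserving group contrasts.

    Harmonization runs separately per gradient column with voxels as features
    and subjects as observations. ``preserve_design`` defaults to the two
    control-referenced group indicator columns derived from ``stack.groups``
    (patient-laterality and control status are re-added after batch removal).
    A single batch is a no-op; a batch with one subject is rejected because
    its scale parameter is inestimable.
    """
    batches = list(batch_labels) if batch_labels is not None else list(stack.batches)
    if len(batches) != stack.n_subjects:
        raise PipelineError("harmonize", "one batch label per subject required")
    levels = sorted(set(batches))
    if len(levels) == 1:
        return AlignedGradientStack(
            tensor=stack.tensor.copy(),
            subject_ids=list(stack.subject_ids),
            groups=list(stack.groups),
            batches=batches,
            harmonized=True,
        )
    batch_idx = [np.flatnonzero(np.asarray(batches, dtype=object) == lv) for lv in levels]
    for lv, ix in zip(levels, batch_idx):
        if len(ix) < 2:
            raise PipelineError("harmonize", f"batch {lv!r} has fewer than 2 subjects")

    onehot = np.zeros((stack.n_subjects, len(levels)))
    for j, ix in enumerate(batch_idx):
        onehot[ix, j] = 1.0
    if preserve_design is None:
        group_levels = [g for g in ("L-TLE", "R-TLE") if g in stack.groups]
        preserve_design = np.column_stack(
            [np.asarray([g == lv for g in stack.groups], dtype=float) for lv in group_levels]
        ) if group_levels else np.empty((stack.n_subjects, 0))
    design = np.hstack([onehot, np.atleast_2d(preserve_design).reshape(stack.n_subjects, -1)])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise PipelineError("harmonize", "design matrix is rank deficient")

    out = np.empty_like(stack.tensor)
    for j in range(stack.k):
        dat = stack.tensor[:, :, j].T  # [voxels x subjects]
        out[:, :, j] = _combat_fit_transform(dat, batch_idx, design, len(levels)).T
    return AlignedGradientStack(
        tensor=out,
        subject_ids=list(stack.subject_ids),
        groups=list(stack.groups),
        batches=batches,
        harmonized=True,
    )
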