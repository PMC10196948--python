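"""Per-subject functional connectivity gradient estimation.

The pipeline maps every subcortical voxel to a point in a low-dimensional
"gradient" space in which voxels with similar whole-cortex connectivity
profiles lie close together:

1. the cortical gray-matter time-series ``[t x b]`` is compressed by PCA to
   at most ``t - 1`` component score series (``t << b`` makes the voxelwise
   connectivity matrix redundant — its row geometry is fully determined by
   the PC scores);
2. every subcortical voxel's time-series is correlated with every cortical
   PC score, giving an ``[a x p]`` connectivity fingerprint;
3. each fingerprint row is sparsified to its top-``density`` fraction of
   connections;
4. pairwise row similarity yields an ``[a x a]`` affinity matrix
   (Pearson by default; Spearman, cosine, normalized-angle and Gaussian
   kernels are available for stability analyses);
5. a spectral embedding of the affinity matrix (diffusion maps by default;
   Laplacian eigenmaps and PCA as alternatives) produces the gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

Kernel = Literal["pearson", "spearman", "cosine", "normalized_angle", "gaussian"]
EmbeddingMethod = Literal["diffusion", "laplacian_eigenmaps", "pca"]

KERNELS: tuple[str, ...] = (
    "pearson",
    "spearman",
    "cosine",
    "normalized_angle",
    "gaussian",
)
EMBEDDING_METHODS: tuple[str, ...] = ("diffusion", "laplacian_eigenmaps", "pca")

GROUPS: tuple[str, ...] = ("control", "L-TLE", "R-TLE")
PATIENT_GROUPS: tuple[str, ...] = ("L-TLE", "R-TLE")


class PipelineError(ValueError):
    """Raised when a pipeline stage rejects its input; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class SubjectRecording:
    """One subject's extracted time-series plus labels.

    ``subcortical_ts`` is ``[t x a]`` and ``cortical_ts`` is ``[t x b]``;
    voxel column order is fixed by the shared :class:`ParcellationMap`.
    """

    subject_id: str
    subcortical_ts: np.ndarray
    cortical_ts: np.ndarray
    group: str = "control"
    protocol: str = "protocol-1"
    mts: bool = False
    btcs: bool = False
    duration_years: float = float("nan")

    def __post_init__(self) -> None:
        self.subcortical_ts = np.asarray(self.subcortical_ts, dtype=float)
        self.cortical_ts = np.asarray(self.cortical_ts, dtype=float)
        if self.subcortical_ts.ndim != 2 or self.cortical_ts.ndim != 2:
            raise PipelineError("recording", "time-series must be 2-D [t x voxels]")
        if self.subcortical_ts.shape[0] != self.cortical_ts.shape[0]:
            raise PipelineError(
                "recording",
                f"timepoint mismatch: subcortical t={self.subcortical_ts.shape[0]} "
                f"vs cortical t={self.cortical_ts.shape[0]}",
            )
        if self.t < 3:
            raise PipelineError("recording", f"need at least 3 timepoints, got {self.t}")
        if self.group not in GROUPS:
            raise PipelineError("recording", f"unknown group label {self.group!r}")
        for name, ts in (("subcortical", self.subcortical_ts), ("cortical", self.cortical_ts)):
            bad = np.flatnonzero(np.std(ts, axis=0) == 0)
            if bad.size:
                raise PipelineError(
                    "recording",
                    f"{name} time-series has {bad.size} zero-variance voxel(s), "
                    f"first at column {bad[0]}",
                )

    @property
    def t(self) -> int:
        return self.subcortical_ts.shape[0]

    @property
    def a(self) -> int:
        return self.subcortical_ts.shape[1]

    @property
    def b(self) -> int:
        return self.cortical_ts.shape[1]


@dataclass
class ParcellationMap:
    """Per-voxel (roi, hemisphere) labels; voxel order shared by all subjects."""

    roi: np.ndarray  # [a] str
    hemisphere: np.ndarray  # [a] "L" | "R"

    def __post_init__(self) -> None:
        self.roi = np.asarray(self.roi, dtype=object)
        self.hemisphere = np.asarray(self.hemisphere, dtype=object)
        if self.roi.shape != self.hemisphere.shape:
            raise ValueError("roi and hemisphere label arrays must have equal length")
        bad = set(self.hemisphere) - {"L", "R"}
        if bad:
            raise ValueError(f"hemisphere labels must be L or R, got {sorted(bad)}")

    @property
    def a(self) -> int:
        return self.roi.size

    @property
    def roi_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.roi:
            seen.setdefault(r)
        return list(seen)

    def indices(self, roi: str, hemisphere: str) -> np.ndarray:
        return np.flatnonzero((self.roi == roi) & (self.hemisphere == hemisphere))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"voxel_id": np.arange(self.a), "roi": self.roi, "hemisphere": self.hemisphere}
        )


@dataclass
class ConnectivityFingerprint:
    """``[a x p]`` correlations of subcortical voxels to cortical PCs."""

    matrix: np.ndarray
    density: Optional[float] = None  # retained row fraction after thresholding

    @property
    def a(self) -> int:
        return self.matrix.shape[0]

    @property
    def p(self) -> int:
        return self.matrix.shape[1]


@dataclass
class AffinityMatrix:
    """Symmetric ``[a x a]`` voxel-voxel similarity."""

    matrix: np.ndarray
    kernel: str

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("affinity must be square")
        self.matrix = m

    @property
    def a(self) -> int:
        return self.matrix.shape[0]


@dataclass
class GradientSet:
    """``[a x k]`` embedding coordinates, columns ordered by importance.

    ``eigenvalues`` are the component importances on the embedding method's
    native scale (diffusion-operator eigenvalues, random-walk eigenvalues
    ``1 - lambda_Laplacian``, or PCA explained variances), always
    non-increasing. ``eigenvalues_normalized`` sums to the retained fraction
    of total importance.
    """

    coords: np.ndarray
    eigenvalues: np.ndarray
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.coords.shape[1] != self.eigenvalues.size:
            raise ValueError("one eigenvalue per gradient column required")
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("eigenvalues must be non-increasing")

    @property
    def a(self) -> int:
        return self.coords.shape[0]

    @property
    def k(self) -> int:
        return self.coords.shape[1]

    @property
    def eigenvalues_normalized(self) -> np.ndarray:
        total = self.params.get("eigenvalue_total", float(np.sum(self.eigenvalues)))
        return self.eigenvalues / total if total > 0 else self.eigenvalues


@dataclass(frozen=True)
class GradientParams:
    """Tunable knobs of the per-subject pipeline with the study defaults."""

    density: float = 0.10
    kernel: str = "pearson"
    method: str = "diffusion"
    n_components: int = 250
    alpha: float = 0.5
    diffusion_time: float = 0

    def as_dict(self) -> dict:
        return {
            "density": self.density,
            "kernel": self.kernel,
            "method": self.method,
            "n_components": self.n_components,
            "alpha": self.alpha,
            "diffusion_time": self.diffusion_time,
        }


# ---------------------------------------------------------------------------
# Stage 1: cortical PCA compression
# ---------------------------------------------------------------------------


def reduce_cortex_pca(cortical_ts: np.ndarray) -> np.ndarray:
    """Compress ``[t x b]`` cortical time-series to PC scores ``[t x min(t-1, b)]``.

    Columns are mean-centered internally; the returned score columns are
    ordered by decreasing explained variance and mutually orthogonal. The
    Gram matrix (row-space geometry) of the centered data is preserved up to
    rank truncation, which is the property the fingerprint step relies on.
    """
    X = np.asarray(cortical_ts, dtype=float)
    if X.ndim != 2:
        raise PipelineError("reduce_cortex_pca", "input must be 2-D [t x b]")
    t, b = X.shape
    if t < 3:
        raise PipelineError("reduce_cortex_pca", f"need t >= 3 timepoints, got {t}")
    Xc = X - X.mean(axis=0, keepdims=True)
    if not np.any(Xc):
        raise PipelineError("reduce_cortex_pca", "all-constant input: no variance to decompose")
    n_comp = min(t - 1, b)
    if b > 2 * t:
        # Gram route: eigendecompose the [t x t] matrix Xc Xc.T; scores are
        # U * sqrt(eigenvalue), identical to the SVD route for b >> t
        G = Xc @ Xc.T
        evals, evecs = eigh(G)
        order = np.argsort(evals)[::-1][:n_comp]
        scores = evecs[:, order] * np.sqrt(np.clip(evals[order], 0.0, None))
    else:
        # scores = U * S from the thin SVD of the centered data
        U, s, _ = np.linalg.svd(Xc, full_matrices=False)
        scores = U[:, :n_comp] * s[:n_comp]
    return scores


# ---------------------------------------------------------------------------
# Stage 2: connectivity fingerprints
# ---------------------------------------------------------------------------


def compute_fingerprint(
    subcortical_ts: np.ndarray, pc_scores: np.ndarray
) -> ConnectivityFingerprint:
    """Pearson-correlate every subcortical voxel with every cortical PC.

    Entry ``(i, j)`` is the correlation of voxel ``i``'s time-series with PC
    score series ``j``. Zero-variance voxels are a hard error (dropping them
    would desynchronize voxel order across subjects); zero-variance trailing
    PC columns (rank deficiency) correlate with nothing and get entry 0.
    """
    Y = np.asarray(subcortical_ts, dtype=float)
    P = np.asarray(pc_scores, dtype=float)
    if Y.shape[0] != P.shape[0]:
        raise PipelineError(
            "compute_fingerprint",
            f"timepoint mismatch: ts t={Y.shape[0]} vs scores t={P.shape[0]}",
        )
    Yc = Y - Y.mean(axis=0, keepdims=True)
    Pc = P - P.mean(axis=0, keepdims=True)
    y_norm = np.linalg.norm(Yc, axis=0)
    p_norm = np.linalg.norm(Pc, axis=0)
    bad = np.flatnonzero(y_norm == 0)
    if bad.size:
        raise PipelineError(
            "compute_fingerprint",
            f"zero-variance subcortical voxel(s) at indices {bad[:5].tolist()}",
        )
    p_norm_safe = np.where(p_norm == 0, 1.0, p_norm)
    F = (Yc.T @ Pc) / np.outer(y_norm, p_norm_safe)
    F[:, p_norm == 0] = 0.0
    np.clip(F, -1.0, 1.0, out=F)
    return ConnectivityFingerprint(matrix=F, density=None)


def threshold_rows(
    fingerprint: ConnectivityFingerprint, density: float = 0.10
) -> ConnectivityFingerprint:
    """Keep the top ``ceil(density * p)`` entries of each row by signed value.

    Survivors retain their values, everything else becomes 0. Ties are broken
    toward the lowest column index; the input is not modified.
    """
    if not 0 < density <= 1:
        raise PipelineError("threshold_rows", f"density must be in (0, 1], got {density}")
    F = fingerprint.matrix
    a, p = F.shape
    keep = int(np.ceil(density * p))
    out = np.zeros_like(F)
    # stable argsort of -row: equal values keep ascending column order
    order = np.argsort(-F, axis=1, kind="stable")[:, :keep]
    rows = np.repeat(np.arange(a), keep)
    cols = order.ravel()
    out[rows, cols] = F[rows, cols]
    return ConnectivityFingerprint(matrix=out, density=density)


# ---------------------------------------------------------------------------
# Stage 3: affinity kernels
# ---------------------------------------------------------------------------


def _row_correlation(X: np.ndarray, stage: str) -> np.ndarray:
    sd = np.std(X, axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise PipelineError(stage, f"constant fingerprint row(s) at voxel indices {bad[:5].tolist()}")
    return np.corrcoef(X)


def compute_affinity(fingerprint: ConnectivityFingerprint, kernel: str = "pearson") -> AffinityMatrix:
    """Pairwise row similarity of the (thresholded) fingerprint.

    Post-threshold zeros are treated as structural zeros: rows are compared
    over all ``p`` coordinates. The Gaussian kernel is self-tuning,
    ``exp(-gamma * ||xi - xj||^2)`` with ``gamma`` = 1 / median nonzero
    squared pairwise distance.
    """
    X = fingerprint.matrix
    if kernel == "pearson":
        A = _row_correlation(X, "compute_affinity")
    elif kernel == "spearman":
        R = rankdata(X, axis=1)
        A = _row_correlation(R, "compute_affinity")
    elif kernel == "cosine":
        norms = np.linalg.norm(X, axis=1)
        bad = np.flatnonzero(norms == 0)
        if bad.size:
            raise PipelineError(
                "compute_affinity", f"zero fingerprint row(s) at voxel indices {bad[:5].tolist()}"
            )
        Xn = X / norms[:, None]
        A = Xn @ Xn.T
    elif kernel == "normalized_angle":
        inner = compute_affinity(fingerprint, "cosine").matrix
        A = 1.0 - np.arccos(np.clip(inner, -1.0, 1.0)) / np.pi
    elif kernel == "gaussian":
        d2 = pdist(X, metric="sqeuclidean")
        nonzero = d2[d2 > 0]
        gamma = 1.0 / np.median(nonzero) if nonzero.size else 1.0
        A = np.exp(-gamma * squareform(d2))
    else:
        raise PipelineError("compute_affinity", f"unknown kernel {kernel!r}")
    A = (A + A.T) / 2.0
    if kernel in ("pearson", "spearman", "cosine", "normalized_angle", "gaussian"):
        np.fill_diagonal(A, 1.0)
    return AffinityMatrix(matrix=A, kernel=kernel)


# ---------------------------------------------------------------------------
# Stage 4: spectral embeddings
# ---------------------------------------------------------------------------


def _fix_column_signs(coords: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|coordinate| entry positive."""
    if coords.size == 0:
        return coords
    idx = np.argmax(np.abs(coords), axis=0)
    signs = np.sign(coords[idx, np.arange(coords.shape[1])])
    signs[signs == 0] = 1.0
    return coords * signs


def _check_connected(W: np.ndarray, stage: str) -> None:
    n_comp, _ = connected_components(sparse.csr_matrix(W > 0), directed=False)
    if n_comp > 1:
        raise PipelineError(stage, f"affinity graph is disconnected ({n_comp} components)")


def _diffusion_embedding(
    W: np.ndarray, n_components: int, alpha: float, diffusion_time: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """Diffusion map of a non-negative affinity.

    Standard anisotropic normalization: ``W_a = W / (d^alpha d^alpha^T)``
    followed by row normalization to a Markov operator, solved through the
    conjugate symmetric matrix. Coordinates are the non-trivial eigenvectors
    divided by the stationary (first) eigenvector and scaled by
    ``lambda / (1 - lambda)`` at ``diffusion_time == 0`` (multi-scale map)
    or ``lambda ** diffusion_time`` otherwise.
    """
    d = W.sum(axis=1)
    if np.any(d <= 0):
        raise PipelineError("embed", "affinity has a zero-degree voxel")
    d_alpha = d**alpha
    Wa = W / np.outer(d_alpha, d_alpha)
    da = Wa.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(da)
    S = Wa * np.outer(inv_sqrt, inv_sqrt)
    S = (S + S.T) / 2.0
    evals, evecs = eigh(S)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    # eigenvectors of the Markov operator; psi normalized by the stationary one
    phi = evecs * inv_sqrt[:, None]
    psi = phi / phi[:, [0]]
    lam = evals[1 : n_components + 1]
    if diffusion_time == 0:
        scale = lam / (1.0 - lam)
    else:
        scale = lam**diffusion_time
    coords = psi[:, 1 : n_components + 1] * scale
    return coords, lam, float(np.sum(evals[1:][evals[1:] > 0]))


def _laplacian_embedding(W: np.ndarray, n_components: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Laplacian eigenmaps: smallest non-trivial solutions of ``L v = lam D v``.

    Importance is reported as the random-walk eigenvalue ``1 - lam`` so the
    leading gradient has the largest value, matching the other methods.
    """
    d = W.sum(axis=1)
    if np.any(d <= 0):
        raise PipelineError("embed", "affinity has a zero-degree voxel")
    L = np.diag(d) - W
    evals, evecs = eigh(L, np.diag(d))
    lam = 1.0 - evals[1 : n_components + 1]
    coords = evecs[:, 1 : n_components + 1]
    return coords, lam, float(np.sum(np.abs(1.0 - evals[1:])))


def _pca_embedding(A: np.ndarray, n_components: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Principal components of the affinity rows (works on signed affinities)."""
    Ac = A - A.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(Ac, full_matrices=False)
    var = s**2 / (A.shape[0] - 1)
    coords = U[:, :n_components] * s[:n_components]
    return coords, var[:n_components], float(np.sum(var))


def embed(
    affinity: AffinityMatrix,
    method: str = "diffusion",
    n_components: int = 250,
    alpha: float = 0.5,
    diffusion_time: float = 0,
) -> GradientSet:
    """Spectral embedding of an affinity matrix into ``min(n_components, a-1)`` gradients.

    Negative affinity entries are clipped to 0 before the diffusion and
    Laplacian embeddings (both require a non-negative kernel); the PCA
    variant uses the signed matrix unchanged. Column signs follow a fixed
    deterministic rule so repeated runs are identical.
    """
    A = affinity.matrix
    if not np.all(np.isfinite(A)):
        raise PipelineError("embed", "affinity contains non-finite entries")
    if not np.allclose(A, A.T, atol=1e-10):
        raise PipelineError("embed", "affinity is not symmetric")
    a = A.shape[0]
    k = min(n_components, a - 1)
    if method in ("diffusion", "laplacian_eigenmaps"):
        W = np.clip(A, 0.0, None)
        _check_connected(W, "embed")
        if method == "diffusion":
            coords, evals, total = _diffusion_embedding(W, k, alpha, diffusion_time)
        else:
            coords, evals, total = _laplacian_embedding(W, k)
    elif method == "pca":
        coords, evals, total = _pca_embedding(A, k)
    else:
        raise PipelineError("embed", f"unknown embedding method {method!r}")
    coords = _fix_column_signs(coords)
    return GradientSet(
        coords=coords,
        eigenvalues=evals,
        method=method,
        params={
            "alpha": alpha,
            "diffusion_time": diffusion_time,
            "n_components": n_components,
            "eigenvalue_total": total,
        },
    )


# ---------------------------------------------------------------------------
# Stage 5: full per-subject composition
# ---------------------------------------------------------------------------


def subject_gradients(
    recording: SubjectRecording, params: GradientParams = GradientParams()
) -> GradientSet:
    """Run the full deterministic per-subject pipeline.

    ``reduce_cortex_pca -> compute_fingerprint -> threshold_rows ->
    compute_affinity -> embed``, with provenance (all parameters plus the
    subject id) recorded on the result.
    """
    scores = reduce_cortex_pca(recording.cortical_ts)
    fp = compute_fingerprint(recording.subcortical_ts, scores)
    fp = threshold_rows(fp, params.density)
    aff = compute_affinity(fp, params.kernel)
    gs = embed(
        aff,
        method=params.method,
        n_components=params.n_components,
        alpha=params.alpha,
        diffusion_time=params.diffusion_time,
    )
    gs.params.update(params.as_dict())
    gs.params["subject_id"] = recording.subject_id
    return gs
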