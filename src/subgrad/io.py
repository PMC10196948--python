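"""Readers/writers for the pipeline's on-disk formats and run configuration.

Formats: NIfTI-1 for 4-D time-series and 3-D integer-label masks, TSV for
covariates, gradients, ground-truth manifests and results tables, YAML for
run configuration. The voxel ordering contract shared by every module is
ascending linear (C-order ravel) index within each mask; any reordering is
an error, never silent.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .alignment import AlignedGradientStack
from .gradients import GradientSet, ParcellationMap, PipelineError, SubjectRecording


# ---------------------------------------------------------------------------
# NIfTI packing of synthetic cohorts
# ---------------------------------------------------------------------------


def _grid_shape(n_voxels: int) -> tuple[int, int, int]:
    side = int(np.ceil(n_voxels ** (1 / 3)))
    while side**3 < n_voxels:
        side += 1
    return (side, side, side)


def _pack(values: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Place a flat voxel vector (or [voxels x t] block) onto a 3-D grid."""
    extra = values.shape[1:] if values.ndim > 1 else ()
    grid = np.zeros((int(np.prod(shape)),) + extra, dtype=float)
    grid[: values.shape[0]] = values
    return grid.reshape(shape + extra)


def write_recording(
    rec: SubjectRecording, parcellation: ParcellationMap, out_dir: Path
) -> dict[str, Path]:
    """Write one subject as 4-D NIfTI plus the shared mask volumes.

    Subcortical voxels occupy the first ``a`` linear grid indices and
    cortical voxels the next ``b``, so ascending-linear-index extraction
    reproduces the in-memory column order exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    a, b, t = rec.a, rec.b, rec.t
    shape = _grid_shape(a + b)
    affine = np.eye(4)

    combined = np.vstack([rec.subcortical_ts.T, rec.cortical_ts.T])  # [(a+b) x t]
    img = nib.Nifti1Image(_pack(combined, shape).astype(np.float32), affine)
    ts_path = out_dir / f"{rec.subject_id}_bold.nii"
    nib.save(img, ts_path)

    roi_names = parcellation.roi_names
    label_of = {(roi, hemi): i + 1 for i, (roi, hemi) in enumerate(
        (r, h) for r in roi_names for h in ("L", "R")
    )}
    sub_labels = np.array(
        [label_of[(r, h)] for r, h in zip(parcellation.roi, parcellation.hemisphere)], dtype=float
    )
    sub_mask = _pack(sub_labels, shape)
    cort_mask = _pack(
        np.concatenate([np.zeros(a), np.ones(b)]), shape
    )
    sub_path = out_dir / "subcortex_parcellation.nii"
    cort_path = out_dir / "cortex_mask.nii"
    nib.save(nib.Nifti1Image(sub_mask.astype(np.int16), affine), sub_path)
    nib.save(nib.Nifti1Image(cort_mask.astype(np.int16), affine), cort_path)
    lookup = pd.DataFrame(
        [{"label": v, "roi": k[0], "hemisphere": k[1]} for k, v in label_of.items()]
    )
    lookup_path = out_dir / "parcellation_labels.tsv"
    lookup.to_csv(lookup_path, sep="\t", index=False)
    return {"ts": ts_path, "subcortex": sub_path, "cortex": cort_path, "labels": lookup_path}


def load_recording(
    ts_path: Path,
    subcortex_mask_path: Path,
    cortex_mask_path: Path,
    covariate_row: Optional[dict] = None,
    label_lookup: Optional[pd.DataFrame] = None,
) -> tuple[SubjectRecording, ParcellationMap]:
    """Extract a subject recording from NIfTI volumes.

    Grids and affines of the time-series and both masks must match; voxels
    are extracted in ascending linear index order within each mask, and the
    two masks must not overlap.
    """
    ts_img = nib.load(str(ts_path))
    sub_img = nib.load(str(subcortex_mask_path))
    cort_img = nib.load(str(cortex_mask_path))
    if ts_img.shape[:3] != sub_img.shape or ts_img.shape[:3] != cort_img.shape:
        raise PipelineError(
            "load_recording",
            f"grid mismatch: ts {ts_img.shape[:3]}, subcortex {sub_img.shape}, "
            f"cortex {cort_img.shape}",
        )
    for other in (sub_img, cort_img):
        if not np.allclose(ts_img.affine, other.affine, atol=1e-6):
            raise PipelineError("load_recording", "affine mismatch between time-series and mask")
    data = np.asarray(ts_img.dataobj, dtype=float)
    if data.ndim != 4:
        raise PipelineError("load_recording", "time-series image must be 4-D")
    flat = data.reshape(-1, data.shape[3])
    sub_lab = np.asarray(sub_img.dataobj).reshape(-1)
    cort_lab = np.asarray(cort_img.dataobj).reshape(-1)
    overlap = int(np.sum((sub_lab > 0) & (cort_lab > 0)))
    if overlap:
        raise PipelineError("load_recording", f"masks overlap at {overlap} voxel(s)")
    sub_ix = np.flatnonzero(sub_lab > 0)
    cort_ix = np.flatnonzero(cort_lab > 0)
    if sub_ix.size == 0 or cort_ix.size == 0:
        raise PipelineError("load_recording", "empty mask")

    if label_lookup is not None:
        lut = {int(r.label): (r.roi, r.hemisphere) for r in label_lookup.itertuples(index=False)}
    else:
        lut = {int(v): (f"roi-{int(v)}", "L") for v in np.unique(sub_lab[sub_ix])}
    roi = np.array([lut[int(v)][0] for v in sub_lab[sub_ix]], dtype=object)
    hemi = np.array([lut[int(v)][1] for v in sub_lab[sub_ix]], dtype=object)
    parc = ParcellationMap(roi=roi, hemisphere=hemi)

    cov = covariate_row or {}
    rec = SubjectRecording(
        subject_id=str(cov.get("subject_id", Path(ts_path).stem)),
        subcortical_ts=flat[sub_ix].T,
        cortical_ts=flat[cort_ix].T,
        group=str(cov.get("group", "control")),
        protocol=str(cov.get("protocol", "protocol-1")),
        mts=bool(cov.get("mts", False)),
        btcs=bool(cov.get("btcs", False)),
        duration_years=float(cov.get("duration_years", float("nan"))),
    )
    return rec, parc


# ---------------------------------------------------------------------------
# TSV formats
# ---------------------------------------------------------------------------


def write_ground_truth(manifest_axis: np.ndarray, parc: ParcellationMap, path: Path) -> None:
    df = parc.to_frame()
    df["axis_position"] = manifest_axis
    df.to_csv(path, sep="\t", index=False)


def write_gradients(gs: GradientSet, parc: ParcellationMap, path: Path) -> None:
    """Gradient TSV: voxel_id, roi, hemisphere, g1..gk (+ eigenvalue sidecar)."""
    df = parc.to_frame()
    for j in range(gs.k):
        df[f"g{j + 1}"] = gs.coords[:, j]
    df.to_csv(path, sep="\t", index=False)
    ev = pd.DataFrame(
        {
            "gradient": np.arange(1, gs.k + 1),
            "eigenvalue": gs.eigenvalues,
            "eigenvalue_normalized": gs.eigenvalues_normalized,
        }
    )
    ev.to_csv(Path(str(path).replace(".tsv", "") + "_eigenvalues.tsv"), sep="\t", index=False)


def read_gradients(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_stack(stack: AlignedGradientStack, out_dir: Path) -> None:
    """One wide TSV per gradient (rows voxels, columns subjects) + sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for j in range(stack.k):
        pd.DataFrame(stack.tensor[:, :, j].T, columns=stack.subject_ids).to_csv(
            out_dir / f"gradient_{j + 1:03d}.tsv", sep="\t", index=False
        )
    sidecar = {
        "subject_ids": stack.subject_ids,
        "groups": stack.groups,
        "batches": stack.batches,
        "harmonized": stack.harmonized,
        "n_subjects": stack.n_subjects,
        "a": stack.a,
        "k": stack.k,
    }
    (out_dir / "stack.json").write_text(json.dumps(sidecar, indent=2))


def read_stack(out_dir: Path) -> AlignedGradientStack:
    out_dir = Path(out_dir)
    meta = json.loads((out_dir / "stack.json").read_text())
    tensor = np.empty((meta["n_subjects"], meta["a"], meta["k"]))
    for j in range(meta["k"]):
        df = pd.read_csv(out_dir / f"gradient_{j + 1:03d}.tsv", sep="\t")
        tensor[:, :, j] = df[meta["subject_ids"]].to_numpy().T
    return AlignedGradientStack(
        tensor=tensor,
        subject_ids=meta["subject_ids"],
        groups=meta["groups"],
        batches=meta["batches"],
        harmonized=meta["harmonized"],
    )


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Serializable parameters of an end-to-end run.

    Every stochastic stage takes its seed from ``seed``; a configuration
    without an explicit seed is rejected at validation rather than silently
    defaulted.
    """

    seed: Optional[int] = None
    out_dir: str = "subgrad-results"
    density: float = 0.10
    kernel: str = "pearson"
    method: str = "diffusion"
    n_components: int = 250
    alpha: float = 0.5
    diffusion_time: float = 0.0
    n_perm: int = 2000
    gradients_of_interest: tuple[int, ...] = (1, 2)
    simulation: Optional[dict] = None  # SimulationConfig overrides; None = load inputs
    input_dir: Optional[str] = None
    covariates_tsv: Optional[str] = None
    batch_column: str = "protocol"

    def validate(self) -> "RunConfig":
        if self.seed is None:
            raise PipelineError("config", "an explicit seed is required")
        if not 0 < self.density <= 1:
            raise PipelineError("config", f"density must be in (0, 1], got {self.density}")
        if self.simulation is None and self.input_dir is None:
            raise PipelineError("config", "either simulation parameters or an input_dir required")
        return self

    def to_yaml(self, path: Path) -> None:
        d = asdict(self)
        d["gradients_of_interest"] = list(self.gradients_of_interest)
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "gradients_of_interest" in d:
            d["gradients_of_interest"] = tuple(d["gradients_of_interest"])
        return cls(**d).validate()

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
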