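"""Synthetic multi-subject fMRI cohort with a planted connectopic axis.

The generator emulates the data regime the gradient pipeline consumes:
per-subject subcortical and cortical time-series in which every subcortical
voxel mixes ``m`` latent cortical network signals with weights that vary
smoothly along a planted scalar axis (the ground-truth "gradient position").
Group effects are planted directly on that generating axis:

* patients' axis values are spread around the axis midpoint by
  ``expansion_factor`` (gradient expansion);
* the ipsilateral hippocampus of the configured patient group(s) receives an
  additive axis offset (a lateralized connectivity shift);
* acquisition protocols differ by a multiplicative amplitude factor and an
  additive batch-shared nuisance time-course (a time-constant offset would
  be invisible to correlation-based connectivity, so the additive batch
  effect is realized as a confound signal common to all voxels of the
  recording).

Everything planted is recorded in a :class:`GroundTruth` manifest so that
recovery tests never need to re-run the simulator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .gradients import (
    GROUPS,
    PATIENT_GROUPS,
    ParcellationMap,
    PipelineError,
    SubjectRecording,
)

DEFAULT_ROIS: tuple[str, ...] = (
    "thalamus",
    "caudate",
    "putamen",
    "pallidum",
    "hippocampus",
    "amygdala",
)


def default_roi_layout(a: int = 300, rois: Sequence[str] = DEFAULT_ROIS) -> list[tuple[str, str, int]]:
    """Bilateral layout splitting ``a`` voxels near-evenly over the named ROIs.

    Any remainder after even division is spread one voxel at a time over the
    leading blocks, so every (roi, hemisphere) block differs in size by at
    most one voxel.
    """
    n_units = 2 * len(rois)
    if a < n_units:
        raise ValueError(f"a={a} too small for {n_units} bilateral ROI blocks")
    per, rem = divmod(a, n_units)
    blocks = [(roi, hemi) for roi in rois for hemi in ("L", "R")]
    return [(roi, hemi, per + (1 if i < rem else 0)) for i, (roi, hemi) in enumerate(blocks)]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Cohort shape defaults mirror a 71-participant two-protocol TLE study
    (16 controls, 31 left-lateralized and 24 right-lateralized patients);
    matrix dimensions are desk-scale: ``a=300`` subcortical voxels,
    ``b=2000`` cortical voxels, ``t=200`` timepoints, ``m=5`` latent
    cortical networks.
    """

    n_control: int = 16
    n_ltle: int = 31
    n_rtle: int = 24
    t: int = 200
    a: int = 300
    b: int = 2000
    m: int = 5
    roi_layout: Optional[list[tuple[str, str, int]]] = None
    noise_sd: float = 0.8
    expansion_factor: float = 1.5
    hippocampus_shift: float = 0.3
    shifted_groups: tuple[str, ...] = ("R-TLE",)
    shifted_roi: str = "hippocampus"
    mixing_width: float = 0.15
    pool_width: float = 0.08
    cortical_noise_span: float = 0.03
    axis_margin: float = 0.15
    batch_assignment: Optional[Mapping[str, str]] = None
    batch_offset: float = 0.5
    batch_scale: float = 1.1
    duration_expansion_coupling: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.roi_layout is None:
            self.roi_layout = default_roi_layout(self.a)
        total = sum(c for _, _, c in self.roi_layout)
        if total != self.a:
            raise ValueError(f"roi_layout voxel counts sum to {total}, expected a={self.a}")
        seen = set()
        for roi, hemi, _ in self.roi_layout:
            if (roi, hemi) in seen:
                raise ValueError(f"duplicate ROI block ({roi}, {hemi})")
            seen.add((roi, hemi))
        rois = {roi for roi, _, _ in self.roi_layout}
        for roi in rois:
            if {h for r, h, _ in self.roi_layout if r == roi} != {"L", "R"}:
                raise ValueError(f"ROI {roi!r} must appear once per hemisphere")
        if self.t <= self.m + 1:
            raise ValueError(f"t={self.t} must exceed m+1={self.m + 1} (latents unrecoverable)")
        if self.expansion_factor < 1:
            raise ValueError("expansion_factor must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for g in self.shifted_groups:
            if g not in PATIENT_GROUPS:
                raise ValueError(f"shifted_groups entries must be patient groups, got {g!r}")

    @property
    def n_total(self) -> int:
        return self.n_control + self.n_ltle + self.n_rtle

    def group_sequence(self) -> list[str]:
        return (
            ["control"] * self.n_control
            + ["L-TLE"] * self.n_ltle
            + ["R-TLE"] * self.n_rtle
        )


@dataclass
class GroundTruth:
    """Manifest of everything the simulator planted.

    ``connectopic_axis`` is the neutral per-voxel axis position in [0, 1];
    ``effective_axis[group]`` is the axis actually used to generate that
    group (after expansion/shift); ``group_effect_map[group]`` is their
    difference, identically zero for controls. ``network_loadings`` are the
    neutral mixing weights.
    """

    connectopic_axis: np.ndarray
    network_loadings: np.ndarray
    effective_axis: dict[str, np.ndarray]
    group_effect_map: dict[str, np.ndarray]
    batch_effect_map: dict[str, dict[str, float]]
    parcellation: ParcellationMap

    def axis_spread(self, group: str) -> float:
        """Standard deviation of the generating axis for a group."""
        return float(np.std(self.effective_axis[group]))


@dataclass
class SyntheticCohort:
    recordings: list[SubjectRecording]
    parcellation: ParcellationMap
    ground_truth: GroundTruth
    covariates: pd.DataFrame
    config: SimulationConfig


# ---------------------------------------------------------------------------
# Axis layout and mixing weights
# ---------------------------------------------------------------------------


def _axis_layout(config: SimulationConfig) -> tuple[np.ndarray, ParcellationMap]:
    """Planted axis: named ROIs occupy disjoint [0, 1] segments, linear in
    voxel index within each block; left/right homologs mirror each other
    (same segment), matching the near-identical gradient distributions of
    hemispheric homologs in real data."""
    rois: list[str] = []
    for roi, _, _ in config.roi_layout:
        if roi not in rois:
            rois.append(roi)
    counts = {roi: sum(c for r, _, c in config.roi_layout if r == roi) for roi in rois}
    total = sum(counts.values())
    edges: dict[str, tuple[float, float]] = {}
    # the axis occupies an interior band of the cortical sheet so that
    # patient-group expansion keeps every voxel's pooled cortical target
    # on-sheet instead of saturating at the edges
    lo = config.axis_margin
    span = 1.0 - 2 * config.axis_margin
    for roi in rois:
        hi = lo + span * counts[roi] / total
        edges[roi] = (lo, hi)
        lo = hi
    axis = np.empty(config.a)
    roi_lab = np.empty(config.a, dtype=object)
    hemi_lab = np.empty(config.a, dtype=object)
    pos = 0
    for roi, hemi, count in config.roi_layout:
        seg_lo, seg_hi = edges[roi]
        # interior grid so adjacent ROI segments do not touch
        axis[pos : pos + count] = np.linspace(seg_lo, seg_hi, count + 2)[1:-1]
        roi_lab[pos : pos + count] = roi
        hemi_lab[pos : pos + count] = hemi
        pos += count
    return axis, ParcellationMap(roi=roi_lab, hemisphere=hemi_lab)


def mixing_weights(axis: np.ndarray, m: int, width: float) -> np.ndarray:
    """Unit-norm Gaussian-bump mixing weights at each axis position.

    Network ``j`` is centered at ``(j + 0.5) / m``; a voxel's weight on it
    decays with squared axis distance, so nearby voxels share connectivity
    profiles and the axis is recoverable from connectivity alone.
    """
    centers = (np.arange(m) + 0.5) / m
    W = np.exp(-((axis[:, None] - centers[None, :]) ** 2) / (2 * width**2))
    norms = np.linalg.norm(W, axis=1, keepdims=True)
    return W / norms


def _effective_axes(config: SimulationConfig, axis: np.ndarray, parc: ParcellationMap) -> dict[str, np.ndarray]:
    """Planted group effects on the generating axis.

    Expansion is an affine stretch of the whole axis about its midpoint, so
    the spread of patients' generating axis positions (and hence of their
    mixing-weight profiles) exceeds the controls' by exactly
    ``expansion_factor``; the lateralized shift additively displaces the
    ipsilateral target ROI of the configured group(s).
    """
    eff = {"control": axis.copy()}
    for group in PATIENT_GROUPS:
        if config.expansion_factor == 1.0:
            ax = axis.copy()  # exact null: keeps labels exchangeable bit-for-bit
        else:
            ax = 0.5 + config.expansion_factor * (axis - 0.5)
        if group in config.shifted_groups and config.hippocampus_shift:
            ipsi = "L" if group == "L-TLE" else "R"
            ix = parc.indices(config.shifted_roi, ipsi)
            ax[ix] = ax[ix] + config.hippocampus_shift
        eff[group] = ax
    return eff


# ---------------------------------------------------------------------------
# Signal generation
# ---------------------------------------------------------------------------


def simulate_cortical_signals(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``[t x m]`` latent network signals and the ``[t x b]`` cortical sheet.

    Latents are i.i.d. standard normal (zero mean, mutually near-orthogonal
    in expectation). Cortical voxels sit on a uniform grid of their own
    [0, 1] coordinate and load onto the latent networks through the same
    Gaussian-bump profile as the subcortex, forming ``m`` soft communities.
    Observation noise is spatially autocorrelated along the sheet through a
    field of localized random bump modes of width ``cortical_noise_span``
    (unit marginal variance): real cortical signals are smooth fields, and
    the resulting local noise modes are what give connectivity fingerprints
    their high effective rank. Localized (rather than stationary-Fourier)
    modes are deliberate — interval eigenmodes peak coherently at both sheet
    ends and would spuriously couple the two ends of the planted axis.
    """
    if config.t <= config.m:
        raise PipelineError("simulate_cortical_signals", "t must exceed m")
    latents = rng.standard_normal((config.t, config.m))
    u = (np.arange(config.b) + 0.5) / config.b
    loadings = mixing_weights(u, config.m, config.mixing_width)  # [b x m]
    w = config.cortical_noise_span
    if w > 0:
        q = int(np.ceil(4.0 / w))
        centers = rng.uniform(-2 * w, 1 + 2 * w, size=q)
        bumps = np.exp(-((u[None, :] - centers[:, None]) ** 2) / (2 * w**2))  # [q x b]
        bumps /= np.sqrt(np.sum(bumps**2, axis=0, keepdims=True))  # unit voxel variance
        noise = rng.standard_normal((config.t, q)) @ bumps
    else:
        noise = rng.standard_normal((config.t, config.b))
    cortical = latents @ loadings.T + config.noise_sd * noise
    return latents, cortical


def _protocol_for(config: SimulationConfig, subject_id: str, group: str, idx_in_group: int) -> str:
    if config.batch_assignment is not None:
        return config.batch_assignment[subject_id]
    # two-protocol split echoing a 46/55-patient, 8/16-control first-protocol share
    if group == "control":
        frac = 0.5
        n = config.n_control
    else:
        frac = 46 / 55
        n = config.n_ltle if group == "L-TLE" else config.n_rtle
    return "protocol-1" if idx_in_group < round(frac * n) else "protocol-2"


def simulate_subject(
    config: SimulationConfig,
    group_label: str,
    latents: np.ndarray,
    cortical_ts: np.ndarray,
    ground_truth: GroundTruth,
    rng: np.random.Generator,
    subject_id: str = "sub-0",
    protocol: str = "protocol-1",
) -> SubjectRecording:
    """Generate one subject's recording from shared ground truth.

    Subcortical voxel ``i`` pools the cortical time-series of voxels whose
    grid position is near its (group-effective) axis position, through a
    unit-norm Gaussian pooling kernel of width ``pool_width``, plus its own
    Gaussian observation noise. Pooling the observed cortical signals (noise
    included) rather than the latents alone gives every subcortical voxel a
    full-rank connectivity fingerprint that varies smoothly along the axis —
    in expectation it still mixes the latent networks with the bump weights
    interpolated at its axis position. The protocol batch effect (amplitude
    scale and additive confound time-course) is applied to both tissue
    blocks.
    """
    if group_label not in GROUPS:
        raise PipelineError("simulate_subject", f"unknown group label {group_label!r}")
    axis = ground_truth.effective_axis[group_label]
    u = (np.arange(config.b) + 0.5) / config.b
    K = np.exp(-((axis[:, None] - u[None, :]) ** 2) / (2 * config.pool_width**2))
    K /= np.linalg.norm(K, axis=1, keepdims=True)
    sub = cortical_ts @ K.T + config.noise_sd * rng.standard_normal((config.t, config.a))
    cort = cortical_ts
    batch = ground_truth.batch_effect_map[protocol]
    if batch["scale"] != 1.0 or batch["offset"] != 0.0:
        # spatially heterogeneous confound: scanner effects are not uniform,
        # and a spatially flat component would vanish under the global-signal
        # cleaning emulated below
        confound = rng.standard_normal(config.t)
        prof_sub = 1.0 + 0.5 * rng.standard_normal(config.a)
        prof_cort = 1.0 + 0.5 * rng.standard_normal(config.b)
        sub = batch["scale"] * sub + batch["offset"] * np.outer(confound, prof_sub)
        cort = batch["scale"] * cort + batch["offset"] * np.outer(confound, prof_cort)
    # emulate confound-regressed input: project the global mean signal out of
    # the cortical sheet (the pipeline consumes already-cleaned time-series).
    # The subcortical block is left untouched: removing a shared component
    # from the rows being embedded would induce the classic global-signal-
    # regression artifact (mutual anticorrelation with the bulk couples the
    # two ends of the axis), whereas cleaning the cortical side only removes
    # the degenerate shared principal component from the fingerprint columns.
    g = cort.mean(axis=1)
    g = g - g.mean()
    denom = g @ g
    if denom > 0:
        cort = cort - np.outer(g, (g @ cort) / denom)
    return SubjectRecording(
        subject_id=subject_id,
        subcortical_ts=sub,
        cortical_ts=cort,
        group=group_label,
        protocol=protocol,
    )


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

# per-group clinical covariate distributions (probabilities / normal params)
_MTS_P = {"L-TLE": 6 / 31, "R-TLE": 9 / 24}
_BTCS_P = {"L-TLE": 23 / 31, "R-TLE": 16 / 24}
_DURATION = {"L-TLE": (16.0, 13.0), "R-TLE": (17.0, 15.0)}


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate the full cohort plus ground-truth manifest and covariates.

    The axis layout and planted effect maps are configuration-determined;
    only noise realizations and clinical covariates depend on the seed.
    Optionally couple disease duration to per-subject expansion through
    ``duration_expansion_coupling`` for clinical-model recovery tests.
    """
    for name, n in (("control", config.n_control), ("L-TLE", config.n_ltle), ("R-TLE", config.n_rtle)):
        if n == 0:
            warnings.warn(f"group {name!r} has zero subjects; contrasts involving it will fail")

    axis, parc = _axis_layout(config)
    loadings = mixing_weights(axis, config.m, config.mixing_width)
    batch_map = {
        "protocol-1": {"offset": 0.0, "scale": 1.0},
        "protocol-2": {"offset": config.batch_offset, "scale": config.batch_scale},
    }
    eff = _effective_axes(config, axis, parc)
    gt = GroundTruth(
        connectopic_axis=axis,
        network_loadings=loadings,
        effective_axis=eff,
        group_effect_map={g: eff[g] - axis for g in eff},
        batch_effect_map=batch_map,
        parcellation=parc,
    )

    ss = np.random.SeedSequence(config.seed)
    cov_rng = np.random.default_rng(ss.spawn(1)[0])
    subject_streams = ss.spawn(config.n_total)

    recordings: list[SubjectRecording] = []
    rows = []
    group_counter: dict[str, int] = {}
    for i, group in enumerate(config.group_sequence()):
        idx_in_group = group_counter.get(group, 0)
        group_counter[group] = idx_in_group + 1
        sid = f"sub-{i:03d}"
        protocol = _protocol_for(config, sid, group, idx_in_group)
        rng = np.random.default_rng(subject_streams[i])

        if group == "control":
            mts, btcs, duration = False, False, float("nan")
            subj_gt = gt
        else:
            mts = bool(cov_rng.random() < _MTS_P[group])
            btcs = bool(cov_rng.random() < _BTCS_P[group])
            mu_d, sd_d = _DURATION[group]
            duration = float(max(1.0, cov_rng.normal(mu_d, sd_d)))
            subj_gt = gt
            if config.duration_expansion_coupling:
                # per-subject expansion grows with disease duration
                extra = 1.0 + config.duration_expansion_coupling * duration
                ax = 0.5 + extra * (gt.effective_axis[group] - 0.5)
                subj_gt = GroundTruth(
                    connectopic_axis=gt.connectopic_axis,
                    network_loadings=gt.network_loadings,
                    effective_axis={**gt.effective_axis, group: ax},
                    group_effect_map=gt.group_effect_map,
                    batch_effect_map=gt.batch_effect_map,
                    parcellation=parc,
                )

        latents, cortical = simulate_cortical_signals(config, rng)
        rec = simulate_subject(
            config, group, latents, cortical, subj_gt, rng, subject_id=sid, protocol=protocol
        )
        rec.mts = mts
        rec.btcs = btcs
        rec.duration_years = duration
        recordings.append(rec)
        rows.append(
            {
                "subject_id": sid,
                "group": group,
                "protocol": protocol,
                "mts": int(mts),
                "btcs": int(btcs),
                "duration_years": duration,
            }
        )
    return SyntheticCohort(
        recordings=recordings,
        parcellation=parc,
        ground_truth=gt,
        covariates=pd.DataFrame(rows),
        config=config,
    )


def null_config(**overrides) -> SimulationConfig:
    """A label-exchangeable configuration: no expansion, no shift, keeps batches."""
    base = dict(expansion_factor=1.0, hippocampus_shift=0.0)
    base.update(overrides)
    return SimulationConfig(**base)
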