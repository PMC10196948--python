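"""End-to-end orchestration: cohort -> gradients -> template -> alignment ->
harmonization -> gradient-space statistics, with provenance on every output."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as sgio
from .alignment import AlignedGradientStack, align_cohort, build_template, harmonize
from .gradients import (
    PATIENT_GROUPS,
    GradientParams,
    ParcellationMap,
    PipelineError,
    SubjectRecording,
    subject_gradients,
)
from .stats import (
    avg_space_roi_mean_stat,
    bhattacharyya_permutation,
    cohens_d,
    expansion_test,
    fit_clinical_model,
    flip_to_ipsi_contra,
    global_variance,
    permutation_test,
    roi_stats,
    subject_roi_clouds,
    subject_space_roi_mean_stat,
    zscore_to_controls,
)
from .synthetic import SimulationConfig, SyntheticCohort, generate_cohort

log = logging.getLogger("subgrad")


@dataclass
class PipelineResult:
    stack: AlignedGradientStack
    parcellation: ParcellationMap
    covariates: pd.DataFrame
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    eigenvalues: Optional[pd.DataFrame] = None
    provenance: dict = field(default_factory=dict)


def _load_cohort(config: sgio.RunConfig) -> tuple[list[SubjectRecording], ParcellationMap, pd.DataFrame]:
    input_dir = Path(config.input_dir)
    cov_path = Path(config.covariates_tsv) if config.covariates_tsv else input_dir / "covariates.tsv"
    covariates = pd.read_csv(cov_path, sep="\t")
    lookup = pd.read_csv(input_dir / "parcellation_labels.tsv", sep="\t")
    recordings = []
    parc = None
    for row in covariates.to_dict("records"):
        rec, parc = sgio.load_recording(
            input_dir / f"{row['subject_id']}_bold.nii",
            input_dir / "subcortex_parcellation.nii",
            input_dir / "cortex_mask.nii",
            covariate_row=row,
            label_lookup=lookup,
        )
        recordings.append(rec)
    return recordings, parc, covariates


def compute_stack(
    recordings: list[SubjectRecording],
    params: GradientParams,
    do_harmonize: bool = True,
) -> tuple[AlignedGradientStack, list]:
    """Per-subject gradients, template alignment and (optional) harmonization."""
    sets = [subject_gradients(rec, params) for rec in recordings]
    groups = [r.group for r in recordings]
    batches = [r.protocol for r in recordings]
    stack = align_cohort(sets, k=params.n_components, groups=groups, batches=batches)
    if do_harmonize and len(set(batches)) > 1:
        stack = harmonize(stack)
    return stack, sets


def analyze_stack(
    stack: AlignedGradientStack,
    parcellation: ParcellationMap,
    covariates: pd.DataFrame,
    n_perm: int = 2000,
    seed: int = 0,
    gradients: tuple[int, ...] = (1, 2),
) -> dict[str, pd.DataFrame]:
    """The full gradient-space statistical battery on an aligned stack."""
    tables: dict[str, pd.DataFrame] = {}
    groups = np.asarray(stack.groups, dtype=object)
    ctrl_ix = np.flatnonzero(groups == "control")
    l_ix = np.flatnonzero(groups == "L-TLE")
    r_ix = np.flatnonzero(groups == "R-TLE")
    pat_ix = np.concatenate([l_ix, r_ix])
    laterality = {
        sid: ("L" if g == "L-TLE" else "R")
        for sid, g in zip(stack.subject_ids, stack.groups)
        if g in PATIENT_GROUPS
    }

    # --- global gradient-1 expansion -------------------------------------
    gvar = global_variance(stack, gradient=1).to_numpy()
    expansion_rows = []
    for name, ix, bonf in (
        ("TLE_vs_control", pat_ix, 1),
        ("L-TLE_vs_control", l_ix, 2),
        ("R-TLE_vs_control", r_ix, 2),
    ):
        if ix.size >= 2 and ctrl_ix.size >= 2:
            res = expansion_test(gvar[ix], gvar[ctrl_ix], one_tailed=True, bonferroni=bonf)
            expansion_rows.append(
                {
                    "contrast": name,
                    "gradient": 1,
                    "statistic": "global_variance",
                    "t": res.t_statistic,
                    "p": res.p_value,
                    "p_corrected": res.p_corrected,
                    "cohens_d": res.cohens_d,
                    "n_patient": res.n_patient,
                    "n_control": res.n_control,
                }
            )
    tables["expansion"] = pd.DataFrame(expansion_rows)

    # --- ROI statistics, z-scoring, flipping ------------------------------
    stats_df = roi_stats(stack, parcellation, gradients=gradients)
    ctrl_stats = stats_df[stats_df["group"] == "control"]
    pat_stats = stats_df[stats_df["group"] != "control"]
    if len(ctrl_ix) >= 2 and len(pat_stats):
        pat_z = zscore_to_controls(pat_stats, ctrl_stats)
        stats_flipped = flip_to_ipsi_contra(pat_z, laterality)
    else:
        stats_flipped = flip_to_ipsi_contra(pat_stats, laterality)
    tables["roi_stats"] = stats_df
    tables["roi_stats_flipped"] = stats_flipped

    # --- lateralized ipsi contrasts (L-TLE vs R-TLE) ----------------------
    contrast_rows = []
    rois = parcellation.roi_names
    n_rois = len(rois)
    if l_ix.size >= 2 and r_ix.size >= 2:
        for gi, g in enumerate(gradients):
            for roi in rois:
                clouds_l = subject_roi_clouds(stack, parcellation, roi, gradients, subjects=l_ix)
                clouds_r = subject_roi_clouds(stack, parcellation, roi, gradients, subjects=r_ix)
                seed_roi = seed + 7919 * (gi * n_rois + rois.index(roi))
                avg_res = permutation_test(
                    avg_space_roi_mean_stat("L", "R", gradient_col=gi),
                    clouds_l,
                    clouds_r,
                    n_perm=n_perm,
                    seed=seed_roi,
                )
                sub_res = permutation_test(
                    subject_space_roi_mean_stat("L", "R", gradient_col=gi),
                    clouds_l,
                    clouds_r,
                    n_perm=n_perm,
                    seed=seed_roi + 1,
                )
                d_sub = cohens_d(
                    [c["L"][:, gi].mean() for c in clouds_l],
                    [c["R"][:, gi].mean() for c in clouds_r],
                )
                for frame, res, d in (
                    ("average_space", avg_res, np.nan),
                    ("subject_space", sub_res, d_sub),
                ):
                    contrast_rows.append(
                        {
                            "contrast": "LTLE_vs_RTLE_ipsi",
                            "frame": frame,
                            "roi": roi,
                            "side": "ipsi",
                            "gradient": g,
                            "statistic": "mean",
                            "observed": res.observed,
                            "p_perm": res.p_value,
                            "p_corrected": min(1.0, n_rois * res.p_value),
                            "cohens_d": d,
                            "n_perm": n_perm,
                            "seed": res.seed,
                        }
                    )
                if gi == 0 and len(gradients) >= 2:
                    bres = bhattacharyya_permutation(
                        clouds_l, clouds_r, side_a="L", side_b="R", n_perm=n_perm, seed=seed_roi + 2
                    )
                    contrast_rows.append(
                        {
                            "contrast": "LTLE_vs_RTLE_ipsi",
                            "frame": "average_space",
                            "roi": roi,
                            "side": "ipsi",
                            "gradient": 0,
                            "statistic": "bhattacharyya",
                            "observed": bres.observed,
                            "p_perm": bres.p_value,
                            "p_corrected": min(1.0, n_rois * bres.p_value),
                            "cohens_d": np.nan,
                            "n_perm": n_perm,
                            "seed": bres.seed,
                        }
                    )
    tables["roi_contrasts"] = pd.DataFrame(contrast_rows)

    # --- clinical covariate models ----------------------------------------
    clinical_rows = []
    pat_cov = covariates[covariates["group"] != "control"].reset_index(drop=True)
    if len(pat_cov) >= 6 and l_ix.size and r_ix.size and len(stats_flipped):
        flipped = stats_flipped.set_index(["subject_id", "roi", "side", "gradient"]).sort_index()
        for roi in rois:
            for stat in ("mean", "variance"):
                try:
                    y = np.array(
                        [
                            flipped.loc[(sid, roi, "ipsi", 1), stat]
                            for sid in pat_cov["subject_id"]
                        ]
                    )
                    fit = fit_clinical_model(y, pat_cov, response=(roi, 1, stat))
                except PipelineError:
                    continue
                for term in ("laterality", "mts", "btcs", "duration"):
                    clinical_rows.append(
                        {
                            "roi": roi,
                            "gradient": 1,
                            "statistic": stat,
                            "term": term,
                            "beta": fit.coefficients[term],
                            "stderr": fit.stderr[term],
                            "p": fit.p_values[term],
                            "p_corrected": fit.p_corrected[term],
                            "n": fit.n,
                        }
                    )
    tables["clinical"] = pd.DataFrame(clinical_rows)
    return tables


def run_pipeline(config: sgio.RunConfig) -> PipelineResult:
    """Execute the configured pipeline and write all result tables.

    Any stage error halts the run with the stage name attached; every output
    carries the config hash and seed needed to regenerate it exactly.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    if config.simulation is not None:
        sim_kwargs = dict(config.simulation)
        sim_kwargs.setdefault("seed", config.seed)
        cohort = generate_cohort(SimulationConfig(**sim_kwargs))
        recordings, parc, covariates = cohort.recordings, cohort.parcellation, cohort.covariates
        sgio.write_ground_truth(
            cohort.ground_truth.connectopic_axis, parc, out_dir / "ground_truth.tsv"
        )
    else:
        recordings, parc, covariates = _load_cohort(config)
    timings["cohort"] = time.perf_counter() - t0
    log.info("cohort: %d subjects, a=%d, b=%d, t=%d", len(recordings),
             recordings[0].a, recordings[0].b, recordings[0].t)

    params = GradientParams(
        density=config.density,
        kernel=config.kernel,
        method=config.method,
        n_components=config.n_components,
        alpha=config.alpha,
        diffusion_time=config.diffusion_time,
    )
    t1 = time.perf_counter()
    stack, sets = compute_stack(recordings, params)
    timings["gradients_alignment"] = time.perf_counter() - t1
    log.info("stack: n=%d, a=%d, k=%d, harmonized=%s",
             stack.n_subjects, stack.a, stack.k, stack.harmonized)

    ev = pd.DataFrame(
        {
            "gradient": np.arange(1, min(5, sets[0].k) + 1),
            "eigenvalue_normalized_mean": np.mean(
                [gs.eigenvalues_normalized[: min(5, gs.k)] for gs in sets], axis=0
            ),
            "eigenvalue_normalized_sd": np.std(
                [gs.eigenvalues_normalized[: min(5, gs.k)] for gs in sets], axis=0
            ),
            "eigenvalue_raw_mean": np.mean([gs.eigenvalues[: min(5, gs.k)] for gs in sets], axis=0),
        }
    )

    t2 = time.perf_counter()
    tables = analyze_stack(
        stack, parc, covariates,
        n_perm=config.n_perm, seed=config.seed, gradients=config.gradients_of_interest,
    )
    timings["statistics"] = time.perf_counter() - t2

    sgio.write_stack(stack, out_dir / "stack")
    covariates.to_csv(out_dir / "covariates.tsv", sep="\t", index=False)
    ev.to_csv(out_dir / "eigenvalues.tsv", sep="\t", index=False)
    for name, df in tables.items():
        df.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
    provenance = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "n_subjects": len(recordings),
        "a": recordings[0].a,
        "b": recordings[0].b,
        "t": recordings[0].t,
        "k": stack.k,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return PipelineResult(
        stack=stack,
        parcellation=parc,
        covariates=covariates,
        tables=tables,
        eigenvalues=ev,
        provenance=provenance,
    )
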