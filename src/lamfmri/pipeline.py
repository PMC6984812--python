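"""End-to-end orchestration: simulate -> first-level -> profiles -> group
-> mvpa -> raster -> report.

Every stage reads its inputs from the output directory (so any stage can
be re-run in isolation from persisted intermediates), derives its own
sub-seed from the config seed with a counter-based scheme, and writes
TSV/JSON outputs plus a provenance log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .design import ExperimentParams, build_run_design, schedule_targets
from .glm import build_design_matrix, fit_glm_ar1
from .group import make_group_table, stepdown_test
from .laminar import CONTRASTS, blockwise_contrast, fit_laminar_glm, roi_depth_profile
from .mvpa import (ATTENTION_PAIRS, STIMULUS_PAIRS, decode_per_depth,
                   exact_sign_permutation, fit_accuracy_shape,
                   make_pattern_dataset, pattern_similarity)
from .raster import dataset_shape_regression, group_slope_test
from .synth import (DEFAULT_ROI_SIZES, VertexBetaDataset, default_ground_truth,
                    make_cortical_patch, simulate_vertex_betas,
                    simulate_voxel_timeseries)

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

log = logging.getLogger("lamfmri")

STAGES = ("simulate", "firstlevel", "profiles", "group", "mvpa", "raster", "report")

#: Contrast families analysed at group level: (contrast, ROI pair, a-priori
#: sidedness for the step-down).  Primary ROI first in each pair.
GROUP_ANALYSES = (
    ("V-Fix", ("A1", "PT"), {"C": "less"}),
    ("A-Fix", ("V1", "V23"), {"C": "less"}),
    ("AV-A", ("A1", "PT"), {}),
    ("AV-V", ("V1", "V23"), {}),
    ("AttA-AttV", ("A1", "PT"), {}),
    ("AttV-AttA", ("V1", "V23"), {}),
)

DECODING_ANALYSES = (
    (("AV", "A"), "stim", ("A1", "PT")),
    (("AV", "V"), "stim", ("V1", "V23")),
    (("AttA", "AttV"), "att", ("A1", "PT")),
    (("AttA", "AttV"), "att", ("V1", "V23")),
)


@dataclass
class PipelineConfig:
    """Fully serialisable run configuration.

    Defaults reproduce the study's design constants (33 s blocks, 16 s
    fixation, 660 ms SOA, 125 ms annulus spacing, 16 targets per
    condition...) with desk-scale ROI sizes and 11 subjects.
    """

    seed: int = 0
    n_subjects: int = 11
    roi_sizes: dict = field(default_factory=lambda: dict(DEFAULT_ROI_SIZES))
    noise_overrides: dict = field(default_factory=dict)   # GroundTruth kwargs
    roi_overrides: dict = field(default_factory=dict)     # per-ROI ROITruth kwargs
    blockwise_group_input: bool = False   # enter 12 blockwise shapes, not their mean
    similarity_depth: int | None = None   # None = pool depths
    firstlevel_voxels: int = 8            # demo-scale voxel count for GLM check
    out_dir: str = "lamfmri_out"

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))

    def stage_seed(self, stage: str) -> int:
        """Counter-based sub-seed (< 2**31) so stages re-run in isolation."""
        idx = STAGES.index(stage)
        return int(np.random.SeedSequence([self.seed, idx]).generate_state(1)[0]
                   % 2**31)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def _ground_truth(config: PipelineConfig):
    from .synth import ROITruth

    roi_overrides = {name: ROITruth(**kw) if isinstance(kw, dict) else kw
                     for name, kw in config.roi_overrides.items()}
    return default_ground_truth(rois=roi_overrides, **config.noise_overrides)


def _load_datasets(out: Path) -> list[VertexBetaDataset]:
    paths = sorted((out / "datasets").glob("sub-*.h5"))
    if not paths:
        raise FileNotFoundError("no simulated datasets found; run 'simulate' first")
    return [VertexBetaDataset.load(p) for p in paths]


# --------------------------------------------------------------------------
# Stages
# --------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, out: Path) -> dict:
    seed = config.stage_seed("simulate")
    design = build_run_design(ExperimentParams(), rng_seed=seed)
    schedule = schedule_targets(design, rng_seed=seed + 1)
    patch = make_cortical_patch(config.roi_sizes, rng_seed=seed)
    truth = _ground_truth(config)
    datasets = simulate_vertex_betas(patch, truth, design,
                                     config.n_subjects, rng_seed=seed)
    (out / "datasets").mkdir(parents=True, exist_ok=True)
    for ds in datasets:
        ds.save(out / "datasets" / f"{ds.subject_id}.h5")
    schedule.to_frame().to_csv(out / "target_schedule.tsv", sep="\t", index=False)
    n_targets = schedule.to_frame().groupby(["condition", "modality"]).size()
    return {"n_subjects": len(datasets),
            "betas_per_subject": int(datasets[0].betas.shape[2]),
            "n_vertices": int(datasets[0].n_vertices),
            "blocks_per_run": len(design.run_blocks(1)),
            "stimuli_per_block": design.params.stimuli_per_block,
            "targets_per_condition_per_modality":
                sorted(set(int(v) for v in n_targets))}


def stage_firstlevel(config: PipelineConfig, out: Path) -> dict:
    """Demonstration-scale AR(1) GLS check on simulated voxel time series."""
    seed = config.stage_seed("firstlevel")
    rng = np.random.default_rng(seed)
    design = build_run_design(ExperimentParams(), rng_seed=seed)
    nvox = config.firstlevel_voxels
    true_betas = rng.normal(0.0, 1.0, size=(18, nvox))
    series, dm = simulate_voxel_timeseries(
        design, true_betas, run=1, ar1_rho=0.3, noise_sd=0.5, rng_seed=seed)
    fit = fit_glm_ar1(series, dm)
    est = fit.block_betas(dm.block_hrf_columns)
    err = est - true_betas
    result = {"rho_hat": fit.rho,
              "beta_rmse": float(np.sqrt(np.mean(err**2))),
              "beta_bias": float(np.mean(err)),
              "n_voxels": nvox}
    (out / "firstlevel.json").write_text(json.dumps(result, indent=2))
    return result


def stage_profiles(config: PipelineConfig, out: Path) -> dict:
    datasets = _load_datasets(out)
    rows = []
    for ds in datasets:
        rois = sorted(set(ds.roi_labels))
        for roi in rois:
            betas = ds.roi_betas(roi)
            for cname, spec in CONTRASTS.items():
                profiles = roi_depth_profile(betas)        # (6 depths, 72)
                con, cells = blockwise_contrast(profiles, ds.labels, spec)
                shapes = fit_laminar_glm(con.T)   # per blockwise profile
                for k in range(con.shape[-1]):
                    rows.append({
                        "subject": ds.subject_id, "roi": roi, "contrast": cname,
                        "block": int(cells.at[k, "block"]),
                        "run": int(cells.at[k, "run"]),
                        "day": int(cells.at[k, "day"]),
                        "C": float(np.atleast_1d(shapes.C)[k]),
                        "L": float(np.atleast_1d(shapes.L)[k]),
                    })
    table = pd.DataFrame(rows)
    table.to_csv(out / "shape_params.tsv", sep="\t", index=False)
    return {"n_rows": len(table),
            "contrast_estimates_per_cell":
                int(table.groupby(["subject", "roi", "contrast"]).size().iloc[0])}


def stage_group(config: PipelineConfig, out: Path) -> dict:
    table = pd.read_csv(out / "shape_params.tsv", sep="\t")
    frames, summary = [], {}
    for contrast, (primary, nonprimary), sided in GROUP_ANALYSES:
        sub = table[(table["contrast"] == contrast)
                    & (table["roi"].isin([primary, nonprimary]))]
        if sub.empty:
            continue
        group_cols = ["subject", "roi"]
        agg = (sub.groupby(group_cols)[["C", "L"]].mean().reset_index()
               if not config.blockwise_group_input else
               sub[group_cols + ["C", "L"]])
        gt = make_group_table(agg, contrast=contrast,
                              roi_map={primary: "primary",
                                       nonprimary: "nonprimary"})
        res = stepdown_test(gt, sided=sided)
        frames.append(res.to_frame())
        summary[contrast] = {"stage1_F": res.stage1.statistic,
                             "stage1_p": res.stage1.p,
                             "stages_run": res.stages_run}
    result = pd.concat(frames, ignore_index=True)
    result.to_csv(out / "group_stepdown.tsv", sep="\t", index=False)
    (out / "group_summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def stage_mvpa(config: PipelineConfig, out: Path) -> dict:
    datasets = _load_datasets(out)
    rows = []
    for ds in datasets:
        for comparison, by, rois in DECODING_ANALYSES:
            for roi in rois:
                pdata = make_pattern_dataset(ds, roi, comparison, by=by)
                prof = decode_per_depth(pdata)
                shape = fit_accuracy_shape(prof)
                rows.append({"subject": ds.subject_id, "roi": roi,
                             "comparison": prof.comparison,
                             **{f"acc_d{d}": float(a)
                                for d, a in enumerate(prof.accuracies)},
                             "C": float(shape.C), "L": float(shape.L)})
    acc = pd.DataFrame(rows)
    acc.to_csv(out / "decoding.tsv", sep="\t", index=False)

    # Pattern-similarity contrast in A1 + exact sign permutation.
    contrasts = [pattern_similarity(ds, "A1", ATTENTION_PAIRS, STIMULUS_PAIRS,
                                    depth=config.similarity_depth).contrast
                 for ds in datasets]
    p = exact_sign_permutation(contrasts, two_sided=True)
    sim = {"subject_contrasts": [float(c) for c in contrasts],
           "mean_contrast": float(np.mean(contrasts)),
           "permutation_p": p}
    (out / "similarity.json").write_text(json.dumps(sim, indent=2))
    return {"mean_accuracy": {c: float(acc[acc["comparison"] == c]
                                       [[f"acc_d{d}" for d in range(6)]]
                                       .to_numpy().mean())
                              for c in acc["comparison"].unique()},
            "similarity_contrast": sim["mean_contrast"],
            "similarity_p": p}


RASTER_ANALYSES = (
    ("A1", "V-Fix", "AV-A", "L"),
    ("PT", "V-Fix", "AV-A", "C"),
    ("A1", "V-Fix", "A-Fix", "C"),   # control pair
)


def stage_raster(config: PipelineConfig, out: Path) -> dict:
    datasets = _load_datasets(out)
    rows, summary = [], {}
    for roi, sorting, predicted, shape in RASTER_ANALYSES:
        slopes = []
        for ds in datasets:
            res = dataset_shape_regression(ds, roi, CONTRASTS[sorting],
                                           CONTRASTS[predicted], shape)
            slopes.append(res.slope)
            rows.append({"subject": ds.subject_id, "roi": roi,
                         "sorting": sorting, "predicted": predicted,
                         "shape": shape, "slope": res.slope})
        test = group_slope_test(slopes)
        summary[f"{roi}:{sorting}->{predicted}:{shape}"] = test
    pd.DataFrame(rows).to_csv(out / "raster_slopes.tsv", sep="\t", index=False)
    (out / "raster_summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def stage_report(config: PipelineConfig, out: Path) -> dict:
    report = {"config": asdict(config),
              "config_sha256": hashlib.sha256(
                  config.to_json().encode()).hexdigest(),
              "version": __version__}
    for name in ("firstlevel", "group_summary", "similarity", "raster_summary"):
        path = out / f"{name}.json"
        if path.exists():
            report[name] = json.loads(path.read_text())
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "firstlevel": stage_firstlevel,
    "profiles": stage_profiles,
    "group": stage_group,
    "mvpa": stage_mvpa,
    "raster": stage_raster,
    "report": stage_report,
}


def run_pipeline(config: PipelineConfig, stages=None) -> dict:
    """Run the requested stages (default: all) and return the run report.

    A stage failure aborts with the stage name; outputs of completed
    stages persist, so a fixed configuration can be resumed stage by
    stage.  Deterministic given ``config.seed``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())
    results = {}
    for stage in (stages or STAGES):
        if stage not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage '{stage}' (choose from {STAGES})")
        log.info("running stage %s", stage)
        try:
            results[stage] = _STAGE_FUNCS[stage](config, out)
        except Exception as exc:          # noqa: BLE001 - stage name context
            raise StageError(stage, exc) from exc
    return results
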