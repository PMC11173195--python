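"""Pipeline orchestration: config validation, end-to-end runs, provenance.

A single declarative YAML/JSON config drives the whole chain
synth -> dataprep -> searchlight -> groupstats -> rsa -> encoding -> behav.
All randomness fans out from one master seed per stage; the results
directory carries a provenance manifest (config, seeds, package version)
and every map a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from . import behav, dataprep, encoding, groupstats, rsa, searchlight, synth
from .volume import BoldRun, StatMap, VolumeGrid, default_grid

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "nifti_roundtrip"]


class ExperimentBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_subjects: int = Field(4, ge=2)
    n_runs: int = Field(2, ge=1)
    grid_size: int = Field(12, ge=8)
    voxel_mm: float = Field(2.4, gt=0)
    tr: float = Field(0.85, gt=0)
    n_volumes: int | None = Field(None, description="auto-sized from the schedule if null")
    n_trim: int = Field(10, ge=0)
    effect_scale: float = Field(1.0, ge=0)
    noise_sd: float = Field(1.0, ge=0)
    roi_radius_mm: float = Field(6.0, gt=0)
    embedding_max_tokens: int = Field(21, ge=1)
    embedding_width: int = Field(768, ge=1)
    embedding_class_effect: float = Field(1.0, ge=0)


class AnalysisBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    dimensions: list[str] = ["affect", "desirability"]
    scheme: str = "leave_one_run_out"
    radius_mm: float = Field(4.0, gt=0)
    n_reps: int = Field(100, ge=1)
    n_perm: int = Field(10_000, ge=1)
    alpha: float = Field(0.05, gt=0, lt=1)
    n_shuffles: int = Field(100, ge=1)
    restrict_centers_to_rois: bool = Field(
        True, description="evaluate searchlights only at ground-truth ROI + control centers"
    )

    @field_validator("dimensions")
    @classmethod
    def _dims(cls, v: list[str]) -> list[str]:
        bad = set(v) - {"affect", "desirability"}
        if bad:
            raise ValueError(f"unknown dimensions {sorted(bad)}")
        return v

    @field_validator("scheme")
    @classmethod
    def _scheme(cls, v: str) -> str:
        if v not in searchlight.SCHEMES:
            raise ValueError(f"scheme must be one of {searchlight.SCHEMES}")
        return v


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    experiment: ExperimentBlock = ExperimentBlock()
    analysis: AnalysisBlock = AnalysisBlock()
    seed: int = 0

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=True)


def validate_config(path_or_dict: str | Path | dict) -> PipelineConfig:
    """Parse + validate a YAML/JSON config; unknown keys are rejected."""
    if isinstance(path_or_dict, dict):
        raw = path_or_dict
    else:
        text = Path(path_or_dict).read_text()
        raw = yaml.safe_load(text) or {}
    return PipelineConfig.model_validate(raw)


def _stage_seed(master: int, stage: str) -> int:
    h = np.random.SeedSequence([master, abs(hash(stage)) % (2**31)])
    return int(h.generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute the full synthetic study and write all results.

    Layout: sub-XX/ per-subject searchlight maps, group/ TFCE results,
    rsa/ and encoding/ maps, behavioral.json, manifest.json.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    exp, ana = config.experiment, config.analysis
    grid = default_grid(exp.grid_size, exp.voxel_mm)
    concepts = synth.make_concept_set()
    emb = synth.simulate_embeddings(
        concepts,
        max_tokens=exp.embedding_max_tokens,
        width=exp.embedding_width,
        class_effect=exp.embedding_class_effect,
        seed=_stage_seed(config.seed, "embeddings"),
    )
    model_rdm = rsa.model_rdm_from_embeddings(emb.matrix)

    # shared mapping across subjects: one spec seed for ROI placement/patterns
    spec = synth.make_signal_spec(
        grid,
        concepts,
        seed=_stage_seed(config.seed, "signal"),
        effect_scale=exp.effect_scale,
        noise_sd=exp.noise_sd,
        roi_radius_mm=exp.roi_radius_mm,
        embeddings=emb,
    )
    spec.save_manifest(out / "manifest_ground_truth.json")

    centers = None
    if ana.restrict_centers_to_rois:
        centers = np.vstack([r.voxel_ijk for r in spec.rois])

    subj_maps: dict[str, list[StatMap]] = {d: [] for d in ana.dimensions}
    subj_patterns = []
    for s in range(exp.n_subjects):
        sdir = out / f"sub-{s:02d}"
        sdir.mkdir(exist_ok=True)
        runs, schedule = synth.simulate_subject(
            concepts,
            grid=grid,
            spec=spec,
            n_runs=exp.n_runs,
            n_volumes=exp.n_volumes,
            tr=exp.tr,
            seed=_stage_seed(config.seed, f"subject-{s}"),
        )
        for ev, run in zip(schedule, runs):
            synth.write_events_tsv(ev, sdir / f"run-{run.run_id}_events.tsv")
        examples = dataprep.prepare_examples(runs, schedule, n_trim=exp.n_trim)
        subj_patterns.append(rsa.average_per_concept(examples))
        for dim in ana.dimensions:
            m = searchlight.run_searchlight(
                examples,
                dim,
                scheme=ana.scheme,
                radius_mm=ana.radius_mm,
                seed=_stage_seed(config.seed, f"searchlight-{s}-{dim}"),
                n_reps=ana.n_reps,
                centers=centers,
            )
            m.to_nifti(sdir / f"searchlight_{dim}.nii")
            subj_maps[dim].append(m)

    gdir = out / "group"
    gdir.mkdir(exist_ok=True)
    report: dict = {"version": __version__}
    for dim in ana.dimensions:
        res = groupstats.one_sample_signflip(
            subj_maps[dim],
            n_perm=ana.n_perm,
            alpha=ana.alpha,
            seed=_stage_seed(config.seed, f"group-{dim}"),
        )
        res.p_map.to_nifti(gdir / f"{dim}_corrected_p.nii")
        res.tfce_map.to_nifti(gdir / f"{dim}_tfce.nii")
        report[f"group_{dim}_clusters"] = res.cluster_table()
    if set(ana.dimensions) == {"affect", "desirability"}:
        res = groupstats.paired_difference_inference(
            subj_maps["desirability"],
            subj_maps["affect"],
            n_perm=ana.n_perm,
            alpha=ana.alpha,
            seed=_stage_seed(config.seed, "group-contrast"),
        )
        res.p_map.to_nifti(gdir / "desirability_gt_affect_p.nii")
        report["group_contrast_clusters"] = res.cluster_table()

    rdir = out / "rsa"
    rdir.mkdir(exist_ok=True)
    rsa_diffs = []
    for s, pat in enumerate(subj_patterns):
        obs = rsa.searchlight_rsa(pat, model_rdm, radius_mm=ana.radius_mm, centers=centers)
        cha = rsa.rsa_chance(
            pat,
            model_rdm,
            n_shuffles=ana.n_shuffles,
            seed=_stage_seed(config.seed, f"rsa-chance-{s}"),
            radius_mm=ana.radius_mm,
            centers=centers,
        )
        diff = StatMap(data=obs.data - cha.data, grid=grid, tag="z_minus_chance")
        diff.to_nifti(rdir / f"sub-{s:02d}_z_minus_chance.nii")
        rsa_diffs.append(diff)
    if len(subj_patterns) >= 3:
        nc = rsa.noise_ceiling(subj_patterns, radius_mm=ana.radius_mm, centers=centers)
        nc.lower.to_nifti(rdir / "noise_ceiling_lower.nii")
        nc.upper.to_nifti(rdir / "noise_ceiling_upper.nii")

    ratings = synth.simulate_ratings(
        concepts, n_subjects=exp.n_subjects, seed=_stage_seed(config.seed, "ratings")
    )
    report["behavioral"] = behav.affect_desirability_report(ratings, concepts)

    manifest = {
        "config": config.model_dump(),
        "version": __version__,
        "stages": [
            "synth", "dataprep", "searchlight", "groupstats", "rsa", "behav",
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
    return out


def nifti_roundtrip(obj: StatMap | BoldRun, path: str | Path) -> StatMap | BoldRun:
    """Write then re-read a map or run; values/affine/shape survive."""
    obj.to_nifti(path)
    if isinstance(obj, BoldRun):
        return BoldRun.from_nifti(path, tr=obj.tr, grid=obj.grid, run_id=obj.run_id)
    return StatMap.from_nifti(path, grid=obj.grid, tag=obj.tag)
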