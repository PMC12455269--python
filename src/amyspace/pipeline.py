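"""End-to-end orchestration of the three analysis aims.

Aim 1 correlates amyloid SUVR maps voxel-wise with a shared expression
atlas; Aim 2 correlates ROI-mean amyloid load with clinical variables;
Aim 3 correlates SUVR voxel-wise with the MRI metric maps and compares
each metric's clinical-association profile with amyloid's.  Sign-flip
effect-size tests (Aims 1/3) and permutation correlation tests (Aim 2)
feed Storey FDR batches, one batch per aim.  The default parameters are
the analysis plan's: r0 = 0.3, mask threshold 0.9, 10000 permutations,
alpha = 0.05, fALFF band 0.01-0.1 Hz, wDeCe sparsity 0.1.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._seeds import rng_for, seed_for
from .association import (ATLAS_MODALITY, association_frame, clinical_matrix,
                          cohort_association, roi_mean_table)
from .inference import (group_difference, permutation_corr_test,
                        signflip_effect_size_test, similarity_of_profiles,
                        storey_fdr)
from .map_metrics import motion_screen
from .roi_masks import DEFAULT_ROIS
from .synthgen import (CLINICAL_VARIABLES, CohortConfig, SyntheticCohort,
                       generate_cohort)

__all__ = ["RunConfig", "RunReport", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run; defaults are the analysis plan's."""

    input_mode: str = "synthetic"  # "synthetic" | "user"
    n_subjects: int = 35
    cohort_mode: str = "exact"  # synthetic generation mode
    r0: float = 0.3
    tau: float = 0.9
    n_perm: int = 10000
    alpha: float = 0.05
    falff_band: tuple[float, float] = (0.01, 0.1)
    wdece_sparsity: float = 0.1
    motion_threshold_voxels: float = 2.0
    seed: int = 0
    out_dir: str = "amyspace-run"
    include_timeseries: bool = True
    clinical_variables: tuple[str, ...] = tuple(CLINICAL_VARIABLES)

    def validate(self) -> None:
        if self.input_mode not in ("synthetic", "user"):
            raise ValueError("input_mode must be 'synthetic' or 'user'")
        if not 0.0 < self.tau <= 1.0:
            raise ValueError(f"mask threshold tau must lie in (0, 1], got {self.tau}")
        if not 0.0 < self.r0 < 1.0:
            raise ValueError("r0 must lie in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        lo, hi = self.falff_band
        if not 0 < lo < hi:
            raise ValueError("invalid fALFF band")
        if not 0 < self.wdece_sparsity <= 1:
            raise ValueError("wdece_sparsity must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("falff_band", "clinical_variables"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["falff_band"] = list(self.falff_band)
        d["clinical_variables"] = list(self.clinical_variables)
        return d


@dataclass
class RunReport:
    """All tables and logs of one run, plus the provenance manifest."""

    aim1: pd.DataFrame
    aim2_r: pd.DataFrame
    aim2_q: pd.DataFrame
    aim2_n: pd.DataFrame
    aim3_mean_r: pd.DataFrame
    aim3_q: pd.DataFrame
    similarity: pd.DataFrame
    group_differences: pd.DataFrame
    exclusions: pd.DataFrame
    associations: pd.DataFrame
    manifest: dict

    def write(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tables = {
            "aim1_atlas.tsv": self.aim1,
            "aim2_clinical_r.tsv": self.aim2_r,
            "aim2_clinical_q.tsv": self.aim2_q,
            "aim2_clinical_n.tsv": self.aim2_n,
            "aim3_metrics_r.tsv": self.aim3_mean_r,
            "aim3_metrics_q.tsv": self.aim3_q,
            "aim3_similarity.tsv": self.similarity,
            "group_differences.tsv": self.group_differences,
            "exclusions.tsv": self.exclusions,
            "associations.tsv": self.associations,
        }
        for name, frame in tables.items():
            frame.to_csv(out / name, sep="\t", float_format="%.10g")
        (out / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True))
        return out


def _screen_motion(cohort: SyntheticCohort, config: RunConfig) -> tuple[SyntheticCohort, list[dict]]:
    exclusions = []
    kept = []
    for s in cohort.subjects:
        if s.displacement is not None and s.bold is not None:
            res = motion_screen(s.displacement, s.bold.voxel_size[0],
                                config.motion_threshold_voxels)
            if not res.passed:
                exclusions.append({
                    "subject_id": s.subject_id, "reason": "motion",
                    "detail": f"{len(res.offending_frames)} frames > "
                              f"{res.threshold_mm:g} mm"})
                continue
        kept.append(s)
    if len(kept) < len(cohort.subjects):
        cohort = dataclasses.replace(cohort, subjects=kept)
    return cohort, exclusions


def run_pipeline(config: RunConfig,
                 cohort: SyntheticCohort | None = None) -> RunReport:
    """Execute simulate -> SUVR -> masks -> screening -> association ->
    inference and assemble the per-aim tables.

    A pre-built cohort may be supplied (user data adapted into the cohort
    container, or a cohort generated elsewhere); otherwise a synthetic
    cohort is generated from the config.  Deterministic given config and
    seed.
    """
    config.validate()
    root = config.seed
    if cohort is None:
        if config.input_mode != "synthetic":
            raise ValueError("user input mode requires a pre-built cohort "
                             "(see synthgen.write_cohort / cli simulate)")
        cc = CohortConfig(n_subjects=config.n_subjects, mode=config.cohort_mode,
                          include_timeseries=config.include_timeseries)
        cohort = generate_cohort(cc, seed=root)

    cohort, exclusions = _screen_motion(cohort, config)
    for mod, count in getattr(cohort.config, "missing_counts", {}).items():
        if count:
            exclusions.append({"subject_id": "", "reason": f"missing_modality:{mod}",
                               "detail": f"{count} subjects lack {mod}"})

    records = cohort_association(cohort, DEFAULT_ROIS, tau=config.tau)
    assoc = association_frame(records)
    rois = [r.roi_id for r in DEFAULT_ROIS if r.roi_id in set(assoc["roi_id"])]
    metric_mods = [m for m in cohort.config.modalities
                   if m in set(assoc["modality_id"])]

    # ---- Aim 1: atlas arm --------------------------------------------------
    aim1_rows = []
    atlas = assoc[assoc["modality_id"] == ATLAS_MODALITY]
    for roi in rois:
        sub = atlas[atlas["roi_id"] == roi]
        if sub.empty:
            continue
        res = signflip_effect_size_test(
            sub["z"].to_numpy(), roi_id=roi, modality_id=ATLAS_MODALITY,
            r0=config.r0, n_perm=config.n_perm,
            seed=seed_for(root, "aim1", roi))
        aim1_rows.append({"roi_id": roi, "n": res.n,
                          "mean_r": float(sub["r"].mean()),
                          "mean_abs_r": res.mean_abs_r, "t": res.t_stat,
                          "p": res.p})
    aim1 = pd.DataFrame(aim1_rows).set_index("roi_id")
    aim1["q"] = storey_fdr(aim1["p"].to_numpy())
    aim1["significant"] = aim1["q"] < config.alpha

    # ---- Aim 2: clinical arm ----------------------------------------------
    suvr_means = roi_mean_table(cohort, modality=None, tau=config.tau)
    variables = [v for v in config.clinical_variables
                 if v in cohort.clinical.columns]
    amyloid_cm = clinical_matrix(cohort.clinical, suvr_means, variables,
                                 modality_id="suvr")
    aim2_r = amyloid_cm.r.copy()
    aim2_n = amyloid_cm.n.copy()
    aim2_p = pd.DataFrame(index=aim2_r.index, columns=aim2_r.columns, dtype=float)
    for roi in aim2_r.index:
        for var in aim2_r.columns:
            if not np.isfinite(aim2_r.loc[roi, var]):
                continue
            _, p = permutation_corr_test(
                suvr_means[roi].to_numpy(),
                cohort.clinical[var].to_numpy(dtype=np.float64),
                n_perm=config.n_perm, seed=seed_for(root, "aim2", roi, var))
            aim2_p.loc[roi, var] = p
    flat_p = aim2_p.to_numpy().ravel()
    finite = np.isfinite(flat_p)
    flat_q = np.full_like(flat_p, np.nan)
    flat_q[finite] = storey_fdr(flat_p[finite])
    aim2_q = pd.DataFrame(flat_q.reshape(aim2_p.shape), index=aim2_p.index,
                          columns=aim2_p.columns)

    # ---- Aim 3: MRI metric arm --------------------------------------------
    aim3_results = {}
    for mod in metric_mods:
        msub = assoc[assoc["modality_id"] == mod]
        for roi in rois:
            cell = msub[msub["roi_id"] == roi]
            if len(cell) < 3:
                continue
            aim3_results[(roi, mod)] = signflip_effect_size_test(
                cell["z"].to_numpy(), roi_id=roi, modality_id=mod,
                r0=config.r0, n_perm=config.n_perm,
                seed=seed_for(root, "aim3", roi, mod))
    aim3_mean_r = pd.DataFrame(index=rois, columns=metric_mods, dtype=float)
    aim3_p = pd.DataFrame(index=rois, columns=metric_mods, dtype=float)
    for (roi, mod), res in aim3_results.items():
        cell = assoc[(assoc["roi_id"] == roi) & (assoc["modality_id"] == mod)]
        aim3_mean_r.loc[roi, mod] = float(cell["r"].mean())
        aim3_p.loc[roi, mod] = res.p

    sim_rows = []
    for mod in metric_mods:
        metric_means = roi_mean_table(cohort, modality=mod, tau=config.tau)
        metric_cm = clinical_matrix(cohort.clinical, metric_means, variables,
                                    modality_id=mod)
        sim = similarity_of_profiles(
            metric_cm, amyloid_cm, n_perm=config.n_perm,
            seed=seed_for(root, "aim3-similarity", mod),
            amyloid_roi_means=suvr_means, clinical=cohort.clinical)
        sim_rows.append({"modality_id": mod, "r_sim": sim.r_sim, "p": sim.p,
                         "n_cells": sim.n_cells})
    similarity = pd.DataFrame(sim_rows).set_index("modality_id")

    # one FDR batch over the whole aim: voxel-wise tests + similarity tests
    aim3_flat = aim3_p.to_numpy().ravel()
    finite3 = np.isfinite(aim3_flat)
    batch = np.concatenate([aim3_flat[finite3], similarity["p"].to_numpy()])
    q_batch = storey_fdr(batch)
    q3 = np.full_like(aim3_flat, np.nan)
    q3[finite3] = q_batch[:finite3.sum()]
    aim3_q = pd.DataFrame(q3.reshape(aim3_p.shape), index=aim3_p.index,
                          columns=aim3_p.columns)
    similarity["q"] = q_batch[finite3.sum():]
    similarity["significant"] = similarity["q"] < config.alpha

    group_diff = group_difference(
        cohort.clinical, "amyloid_positive",
        variables=[v for v in variables if v in cohort.clinical.columns])

    manifest = {
        "software": {"name": "amyspace", "version": __version__},
        "config": config.to_dict(),
        "seed": root,
        "n_subjects_analyzed": len(cohort.subjects),
        "n_association_records": int(len(assoc)),
        "rois": rois,
        "modalities": metric_mods + [ATLAS_MODALITY],
    }
    return RunReport(
        aim1=aim1, aim2_r=aim2_r, aim2_q=aim2_q, aim2_n=aim2_n,
        aim3_mean_r=aim3_mean_r, aim3_q=aim3_q, similarity=similarity,
        group_differences=group_diff,
        exclusions=pd.DataFrame(exclusions,
                                columns=["subject_id", "reason", "detail"]),
        associations=assoc, manifest=manifest)
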