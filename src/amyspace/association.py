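"""Per-subject voxel-wise spatial correlation and cohort-level assembly.

The central quantity: for one subject, one ROI and one target modality,
the Pearson correlation across ROI voxels between the subject's amyloid
SUVR map and the target map, Fisher-transformed to z = atanh(r).  The
cohort-level structures gather these per (subject, ROI, modality), plus
subject-level correlations of ROI-mean values with clinical variables.

Missing voxel values (non-finite in either map) are excluded pairwise;
missing clinical values are handled pairwise-complete per cell, matching
per-variable availability in real cohorts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pet_suvr import compute_suvr
from .roi_masks import (DEFAULT_ROIS, ROIDefinition, downsample_mask_fraction,
                        extract_roi_values, threshold_mask)
from .volumes import MaskVolume, ScalarVolume

__all__ = [
    "SubjectROICorrelation",
    "ClinicalAssociationMatrix",
    "voxelwise_pearson",
    "fisher_transform",
    "cohort_association",
    "clinical_matrix",
    "analysis_masks",
    "roi_mean_table",
]

log = logging.getLogger(__name__)

ATLAS_MODALITY = "atlas"


@dataclass
class SubjectROICorrelation:
    """One subject's voxel-wise r (and Fisher z) for one (ROI, modality)."""

    subject_id: str
    roi_id: str
    modality_id: str
    n_voxels: int
    r: float
    z: float


@dataclass
class ClinicalAssociationMatrix:
    """Pearson r of per-ROI mean values with clinical variables over subjects.

    ``r`` is a (ROI x variable) frame; ``n`` holds the pairwise-complete
    subject count per cell.  Cells with fewer than 3 complete pairs are
    missing (NaN), never zero.
    """

    modality_id: str
    r: pd.DataFrame
    n: pd.DataFrame


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xm = x - x.mean()
    ym = y - y.mean()
    denom = np.sqrt((xm @ xm) * (ym @ ym))
    return float((xm @ ym) / denom)


def voxelwise_pearson(map_a: ScalarVolume, map_b: ScalarVolume,
                      mask: MaskVolume) -> float:
    """Pearson r between two maps over the mask, pairwise-complete on
    finite voxels.  Raises if fewer than 3 finite pairs remain or either
    map is constant over the mask."""
    map_a.require_same_grid(map_b, "second map")
    map_a.require_same_grid(mask, "mask")
    sel = mask.as_bool()
    a = map_a.data[sel]
    b = map_b.data[sel]
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 3:
        raise ValueError("fewer than 3 finite paired voxels in ROI")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in ROI")
    return _pearson(a, b)


def fisher_transform(r):
    """Fisher variance-stabilizing transform z = atanh(r).

    |r| within 1e-12 of 1 is clamped to +/-(1 - 1e-12) with a warning so z
    stays finite; |r| > 1 raises.
    """
    arr = np.asarray(r, dtype=np.float64)
    if np.any(np.abs(arr) > 1):
        raise ValueError("|r| > 1 has no Fisher transform")
    clip = np.abs(arr) >= 1.0 - 1e-12
    if np.any(clip):
        warnings.warn("|r| at or above 1 - 1e-12 clamped before atanh",
                      RuntimeWarning, stacklevel=2)
        arr = np.clip(arr, -(1.0 - 1e-12), 1.0 - 1e-12)
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) or out.ndim == 0 else out


def analysis_masks(cohort, tau: float = 0.9) -> dict[str, MaskVolume]:
    """Decimate the cohort's fine-grid ROI masks to the analysis grid and
    binarize at inclusion probability >= tau."""
    out = {}
    for name, fine in cohort.roi_masks_fine.items():
        prob = downsample_mask_fraction(fine, cohort.factor)
        out[name] = threshold_mask(prob, tau)
    return out


def _subject_suvr(subject, reference_coarse: MaskVolume) -> ScalarVolume:
    return compute_suvr(subject.amyloid_pet, reference_coarse).values


def reference_analysis_mask(cohort, tau: float = 0.9) -> MaskVolume:
    prob = downsample_mask_fraction(cohort.reference_mask_fine, cohort.factor)
    return threshold_mask(prob, tau)


def cohort_association(cohort, rois: tuple[ROIDefinition, ...] | None = None,
                       modalities: tuple[str, ...] | None = None,
                       tau: float = 0.9) -> list[SubjectROICorrelation]:
    """All per-(subject, ROI, modality) voxel-wise correlations of a cohort.

    The amyloid map is SUVR-normalized per subject; masks are decimated
    and thresholded at tau.  The atlas modality pairs each subject's SUVR
    map with the single shared atlas map and skips ROIs flagged out of the
    atlas comparison (white matter).  Subjects missing a modality are
    skipped for that modality with a log entry.
    """
    masks = analysis_masks(cohort, tau)
    ref = reference_analysis_mask(cohort, tau)
    if rois is None:
        # every mask the cohort carries, with the standard ROI metadata
        # where the name matches and plain definitions otherwise
        known = {r.roi_id: r for r in DEFAULT_ROIS}
        roi_defs = {name: known.get(name, ROIDefinition(name)) for name in masks}
    else:
        roi_defs = {r.roi_id: r for r in rois if r.roi_id in masks}
    if modalities is None:
        modalities = tuple(cohort.config.modalities) + (ATLAS_MODALITY,)
    records: list[SubjectROICorrelation] = []
    for subject in cohort.subjects:
        suvr = _subject_suvr(subject, ref)
        for roi_id, roi in roi_defs.items():
            mask = masks[roi_id]
            n_vox = mask.count()
            for mod in modalities:
                if mod == ATLAS_MODALITY:
                    if not roi.include_in_atlas_comparison:
                        continue
                    target = cohort.atlas
                else:
                    target = subject.metric_maps.get(mod)
                    if target is None:
                        log.info("cohort_association: %s missing modality %s; "
                                 "record skipped", subject.subject_id, mod)
                        continue
                r = voxelwise_pearson(suvr, target, mask)
                records.append(SubjectROICorrelation(
                    subject_id=subject.subject_id, roi_id=roi_id,
                    modality_id=mod, n_voxels=n_vox, r=r,
                    z=fisher_transform(r)))
    return records


def association_frame(records: list[SubjectROICorrelation]) -> pd.DataFrame:
    return pd.DataFrame([vars(rec) for rec in records])


def roi_mean_table(cohort, modality: str | None = None,
                   tau: float = 0.9) -> pd.DataFrame:
    """Per-subject ROI-mean values (subjects x ROIs) for one modality.

    ``modality=None`` gives ROI-mean amyloid SUVR; otherwise the named
    metric map.  Subjects missing the modality get NaN rows.
    """
    masks = analysis_masks(cohort, tau)
    ref = reference_analysis_mask(cohort, tau)
    rows = {}
    for subject in cohort.subjects:
        if modality is None:
            vol = _subject_suvr(subject, ref)
        else:
            vol = subject.metric_maps.get(modality)
        if vol is None:
            rows[subject.subject_id] = {roi: np.nan for roi in masks}
            continue
        rows[subject.subject_id] = {
            roi: extract_roi_values(vol, mask, roi).mean
            for roi, mask in masks.items()}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "subject_id"
    return out


def clinical_matrix(cohort_table: pd.DataFrame, roi_means: pd.DataFrame,
                    variables: list[str] | None = None,
                    modality_id: str = "suvr") -> ClinicalAssociationMatrix:
    """Correlate per-subject ROI means with clinical variables.

    Each cell is the Pearson r over pairwise-complete subjects (recorded
    per cell in ``n``); cells with fewer than 3 complete pairs are NaN.
    """
    if variables is None:
        variables = [c for c in cohort_table.columns
                     if pd.api.types.is_numeric_dtype(cohort_table[c])
                     and cohort_table[c].nunique() > 2]
    common = roi_means.index.intersection(cohort_table.index)
    r = pd.DataFrame(index=roi_means.columns, columns=variables, dtype=float)
    n = pd.DataFrame(0, index=roi_means.columns, columns=variables, dtype=int)
    for roi in roi_means.columns:
        x_all = roi_means.loc[common, roi].to_numpy(dtype=np.float64)
        for var in variables:
            y_all = cohort_table.loc[common, var].to_numpy(dtype=np.float64)
            ok = np.isfinite(x_all) & np.isfinite(y_all)
            n.loc[roi, var] = int(ok.sum())
            if ok.sum() < 3:
                r.loc[roi, var] = np.nan  # flagged missing, never zero
                continue
            x, y = x_all[ok], y_all[ok]
            if x.std() == 0 or y.std() == 0:
                r.loc[roi, var] = np.nan
                continue
            r.loc[roi, var] = _pearson(x, y)
    return ClinicalAssociationMatrix(modality_id=modality_id, r=r, n=n)
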