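"""ROI mask resampling, thresholding and value extraction.

High-resolution anatomical ROI masks are brought to the analysis grid by
integer-factor decimation: the value of each coarse voxel is the exact
fraction of its fine-grid children inside the mask ("probability of
inclusion").  The coarse mask is then binarized by keeping voxels whose
inclusion probability is at least a threshold (default 0.9), which
mitigates partial-volume effects in the lower-resolution space.

Voxel vectors extracted over a mask follow a fixed ordering: row-major
(C-order) over the (x, y, z) voxel indices, i.e. lexicographic with the
z index varying fastest.  The same ordering is used everywhere, so voxels
stay paired across modalities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .volumes import MaskVolume, ScalarVolume

__all__ = [
    "ROIDefinition",
    "DEFAULT_ROIS",
    "downsample_mask_fraction",
    "threshold_mask",
    "extract_roi_values",
    "ROIValues",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ROIDefinition:
    """A named region of interest and whether it enters the atlas comparison.

    The white-matter ROI is excluded from the transcriptome-atlas arm:
    off-target tracer binding in white matter is of dubious significance
    and the expression atlas carries no white-matter data.
    """

    roi_id: str
    name: str = ""
    include_in_atlas_comparison: bool = True

    def __post_init__(self):
        if not self.name:
            object.__setattr__(self, "name", self.roi_id)


#: The study's bilateral FreeSurfer-derived ROI set, spanning small
#: (entorhinal, ~50 analysis voxels) to large (whole cortex, ~4000).
DEFAULT_ROIS: tuple[ROIDefinition, ...] = (
    ROIDefinition("entorhinal"),
    ROIDefinition("limbic-subcortical"),
    ROIDefinition("temporal"),
    ROIDefinition("anterior-cingulate"),
    ROIDefinition("precuneus-posterior-cingulate"),
    ROIDefinition("whole-cortex"),
    ROIDefinition("white-matter", include_in_atlas_comparison=False),
    ROIDefinition("basal-ganglia"),
)


def downsample_mask_fraction(mask: MaskVolume, factor) -> MaskVolume:
    """Decimate a boolean fine-grid mask to coarse-grid inclusion fractions.

    ``factor`` is a positive integer (or per-axis triple); each coarse
    voxel's value is ``children_in_mask / factor**3``, computed from exact
    integer counts.  Fine-grid dimensions must be divisible by the factor;
    no implicit padding is performed.
    """
    if not mask.is_boolean:
        raise ValueError("downsample_mask_fraction expects a boolean mask")
    f = np.broadcast_to(np.asarray(factor, dtype=int), (3,)).copy()
    if np.any(f < 1):
        raise ValueError("decimation factor must be a positive integer")
    shape = np.asarray(mask.shape)
    if np.any(shape % f != 0):
        raise ValueError(
            f"fine-grid dims {tuple(shape)} not divisible by factor {tuple(f)}"
        )
    coarse = shape // f
    counts = (
        mask.data.astype(np.int64)
        .reshape(coarse[0], f[0], coarse[1], f[1], coarse[2], f[2])
        .sum(axis=(1, 3, 5))
    )
    frac = counts / float(f.prod())
    vs = tuple(v * k for v, k in zip(mask.voxel_size, f))
    aff = np.asarray(mask.affine).copy()
    aff[:3, :3] = aff[:3, :3] * f[np.newaxis, :]
    # shift origin so coarse voxel centres sit at the centroid of their children
    aff[:3, 3] = aff[:3, 3] + np.asarray(mask.affine)[:3, :3] @ ((f - 1) / 2.0)
    return MaskVolume(frac, voxel_size=vs, affine=aff)


def threshold_mask(prob: MaskVolume, tau: float = 0.9) -> MaskVolume:
    """Binarize an inclusion-probability mask: keep voxels with prob >= tau."""
    if not (0.0 < tau <= 1.0):
        raise ValueError(f"threshold tau must lie in (0, 1], got {tau}")
    data = prob.data.astype(np.float64) if prob.is_boolean else prob.data
    return MaskVolume(data >= tau, voxel_size=prob.voxel_size, affine=prob.affine)


@dataclass
class ROIValues:
    """Voxel values of one map over one ROI, in the fixed voxel ordering."""

    roi_id: str
    values: np.ndarray
    mean: float
    n_excluded_nonfinite: int = 0

    def __len__(self) -> int:
        return len(self.values)


def extract_roi_values(map: ScalarVolume, mask: MaskVolume,
                       roi_id: str = "roi") -> ROIValues:
    """Extract the map's voxel values over a boolean mask, plus their mean.

    Non-finite map voxels are dropped (with a logged count); the mean is
    the arithmetic mean of the remaining finite values.  Raises if the
    effective mask is empty.
    """
    map.require_same_grid(mask, f"mask for {roi_id}")
    sel = mask.as_bool()
    vals = map.data[sel]  # C-order: lexicographic in (x, y, z), z fastest
    finite = np.isfinite(vals)
    n_excluded = int(vals.size - finite.sum())
    if n_excluded:
        log.info("extract_roi_values[%s]: excluded %d non-finite voxels",
                 roi_id, n_excluded)
    vals = vals[finite]
    if vals.size == 0:
        raise ValueError(f"empty effective mask for ROI '{roi_id}'")
    return ROIValues(roi_id=roi_id, values=vals, mean=float(vals.mean()),
                     n_excluded_nonfinite=n_excluded)
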