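"""Standardized uptake value ratio (SUVR) computation.

Amyloid PET uptake is expressed as a dimensionless ratio to the mean
uptake over a reference region (here, a cerebellar-like mask), so that
the reference region's mean SUVR is exactly 1.  The reference mask may
be boolean (each voxel counts equally) or a probability-of-inclusion
volume (probability-weighted mean), as resampled masks arrive fractional.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .volumes import MaskVolume, ScalarVolume

__all__ = ["SUVRMap", "compute_suvr"]

log = logging.getLogger(__name__)


@dataclass
class SUVRMap:
    """An SUVR volume together with the reference mean it was scaled by."""

    values: ScalarVolume
    reference_mean: float


def compute_suvr(pet: ScalarVolume, reference: MaskVolume) -> SUVRMap:
    """Divide a PET uptake volume by its mean over the reference mask.

    Non-finite PET voxels propagate as non-finite SUVR; voxels inside the
    reference mask must be finite.  Raises on an empty reference mask, a
    non-positive reference mean, or a grid mismatch.
    """
    pet.require_same_grid(reference, "reference mask")
    if reference.is_boolean:
        weights = reference.data.astype(np.float64)
    else:
        weights = reference.data
    wsum = float(weights.sum())
    if wsum == 0.0:
        raise ValueError("empty reference mask")
    ref_values = pet.data[weights > 0]
    if not np.all(np.isfinite(ref_values)):
        raise ValueError("non-finite PET values inside the reference mask")
    ref_mean = float((weights * np.where(weights > 0, pet.data, 0.0)).sum() / wsum)
    if ref_mean <= 0.0:
        raise ValueError("invalid reference intensity: non-positive reference mean")
    n_nonfinite = int(np.count_nonzero(~np.isfinite(pet.data)))
    if n_nonfinite:
        log.info("compute_suvr: %d non-finite PET voxels propagate to SUVR", n_nonfinite)
    values = ScalarVolume(pet.data / ref_mean, pet.voxel_size, pet.affine)
    return SUVRMap(values=values, reference_mean=ref_mean)
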