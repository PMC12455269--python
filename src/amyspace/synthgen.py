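"""Synthetic multimodal cohorts with exactly known ground truth.

Real amyloid-PET/MRI cohorts of the kind this pipeline analyses are not
redistributable per subject, so every downstream stage is exercised on
synthetic cohorts whose statistical structure is imposed by construction:

* within-ROI voxel-wise correlation between each subject's amyloid map and
  each target map (atlas or MRI metric) is set to a requested rho — exactly
  in "exact" mode (sample moments forced), or in distribution in "sampling"
  mode (population moments);
* subject-level correlations among clinical variables and a latent amyloid
  burden (which sets every ROI's mean SUVR by an affine map) follow a
  requested positive-semidefinite correlation matrix, again exactly or in
  distribution;
* BOLD-like series have a controllable fraction of spectral amplitude in
  the 0.01–0.1 Hz band and controllable neighbourhood coupling;
* DWI signals follow the monoexponential tensor model
  ``S = S0 * exp(-b g^T D g)`` from a known tensor field.

Geometry: a high-resolution grid (default 64^3 at 1 mm) carries boolean ROI
masks built from axis-aligned boxes that are unions of full coarse cells, so
integer-factor decimation to the analysis grid (default 32^3 at 2 mm) is
exact.  ROI sizes span ~50 to ~4000 analysis voxels.  All randomness flows
from one root seed via documented per-subject/per-map sub-streams.

The shared atlas map is generated first; each subject's within-ROI amyloid
pattern is then forced against the atlas pattern (realizing the atlas-arm
rho per subject), and each metric map is forced against that subject's own
amyloid pattern.  In exact mode every subject's correlations equal the
targets to rounding, so cross-subject variance of the per-cell r is zero by
construction; sampling mode restores realistic between-subject variation.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seeds import rng_for
from .map_metrics import GradientTable
from .volumes import MaskVolume, ScalarVolume, SeriesVolume

__all__ = [
    "GroundTruth",
    "CohortConfig",
    "SubjectData",
    "SyntheticCohort",
    "forced_correlation_field",
    "generate_bold_volume",
    "generate_dwi_signals",
    "generate_cohort",
    "default_ground_truth",
    "default_gradient_table",
    "random_tensor_field",
    "write_cohort",
    "CLINICAL_VARIABLES",
    "DEFAULT_MODALITIES",
]

log = logging.getLogger(__name__)

#: Clinical/demographic variables carried by the cohort table, with the
#: cohort-level mean and SD used to put them on realistic scales
#: (age-corrected standard scores for grip strength and cognition).
CLINICAL_VARIABLES: dict[str, tuple[float, float]] = {
    "age": (73.17, 9.07),
    "bmi": (26.56, 4.45),
    "grip_strength": (101.81, 15.49),
    "fluid_cognition": (112.71, 15.28),
    "crystallised_cognition": (109.85, 11.54),
}

#: Default MRI-metric modalities attached to each subject.
DEFAULT_MODALITIES: tuple[str, ...] = (
    "t1t2_ratio", "fa", "md", "odi", "ivf", "wvf", "cbf",
    "wdece", "reho", "falff",
)

#: Default per-modality target voxel-wise correlation with amyloid load,
#: applied to every ROI unless overridden per (roi, modality).  Signs and
#: magnitudes mirror the qualitative pattern the pipeline is meant to
#: resolve: microstructural metrics couple strongly, diffusivity/dispersion
#: metrics negatively, functional metrics weakly.
_DEFAULT_MODALITY_RHO: dict[str, float] = {
    "t1t2_ratio": 0.50, "fa": 0.55, "md": -0.35, "odi": -0.30,
    "ivf": 0.30, "wvf": -0.30, "cbf": 0.35,
    "wdece": 0.10, "reho": 0.10, "falff": 0.05,
}

#: Atlas arm: positive coupling in the entorhinal cortex only, a clear
#: anti-correlation in the basal ganglia, weak elsewhere.
_DEFAULT_ATLAS_RHO: dict[str, float] = {
    "entorhinal": 0.50,
    "limbic-subcortical": -0.10,
    "temporal": 0.05,
    "anterior-cingulate": -0.05,
    "precuneus-posterior-cingulate": 0.10,
    "whole-cortex": 0.05,
    "basal-ganglia": -0.35,
}

#: ROI boxes on the analysis (coarse) grid: name -> (origin, shape), chosen
#: disjoint and spanning ~50 to ~4000 analysis voxels.
_DEFAULT_ROI_BOXES: dict[str, tuple[tuple[int, int, int], tuple[int, int, int]]] = {
    "entorhinal": ((1, 1, 1), (5, 5, 2)),
    "limbic-subcortical": ((8, 1, 1), (5, 5, 6)),
    "anterior-cingulate": ((15, 1, 1), (5, 5, 4)),
    "precuneus-posterior-cingulate": ((22, 1, 1), (5, 8, 5)),
    "temporal": ((1, 11, 1), (10, 10, 6)),
    "basal-ganglia": ((13, 11, 1), (5, 10, 5)),
    "whole-cortex": ((1, 1, 9), (20, 20, 10)),
    "white-matter": ((1, 1, 21), (10, 10, 10)),
}

#: Cerebellar-like reference region (disjoint from every ROI).
_REFERENCE_BOX: tuple[tuple[int, int, int], tuple[int, int, int]] = ((24, 24, 24), (6, 6, 6))


# --------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruth:
    """The exactly known statistical structure a synthetic cohort realizes."""

    target_voxel_rho: dict[tuple[str, str], float]
    clinical_corr: pd.DataFrame  # symmetric, unit diagonal, PSD; includes "amyloid_burden"
    band_fraction: float
    seed: int
    tensor_field: np.ndarray | None = None  # (X, Y, Z, 3, 3), mm^2/s

    def __post_init__(self) -> None:
        for key, rho in self.target_voxel_rho.items():
            if not -1.0 < rho < 1.0:
                raise ValueError(f"target rho for {key} must lie strictly in (-1, 1)")
        c = self.clinical_corr.to_numpy(dtype=np.float64)
        if not np.allclose(c, c.T, atol=1e-12):
            raise ValueError("clinical_corr must be symmetric")
        if not np.allclose(np.diag(c), 1.0, atol=1e-12):
            raise ValueError("clinical_corr must have unit diagonal")
        if np.linalg.eigvalsh(c).min() < -1e-10:
            raise ValueError("clinical_corr must be positive semidefinite")
        if not 0.0 <= self.band_fraction <= 1.0:
            raise ValueError("band_fraction must lie in [0, 1]")


def default_ground_truth(seed: int = 0,
                         rois: tuple[str, ...] | None = None,
                         modalities: tuple[str, ...] = DEFAULT_MODALITIES,
                         ) -> GroundTruth:
    """The default study conditions: per-cell voxel rho and clinical structure."""
    rois = tuple(_DEFAULT_ROI_BOXES) if rois is None else rois
    rho: dict[tuple[str, str], float] = {}
    for roi in rois:
        if roi in _DEFAULT_ATLAS_RHO:
            rho[(roi, "atlas")] = _DEFAULT_ATLAS_RHO[roi]
        for mod in modalities:
            rho[(roi, mod)] = _DEFAULT_MODALITY_RHO.get(mod, 0.1)
    labels = ["amyloid_burden"] + list(CLINICAL_VARIABLES)
    c = np.eye(len(labels))
    # amyloid burden vs clinical: mildly positive across the board, strongest
    # for BMI and grip strength; plausible inter-clinical structure.
    pairs = {
        ("amyloid_burden", "age"): 0.15,
        ("amyloid_burden", "bmi"): 0.35,
        ("amyloid_burden", "grip_strength"): 0.30,
        ("amyloid_burden", "fluid_cognition"): 0.10,
        ("amyloid_burden", "crystallised_cognition"): 0.10,
        ("age", "grip_strength"): -0.20,
        ("age", "fluid_cognition"): -0.15,
        ("bmi", "grip_strength"): 0.10,
        ("fluid_cognition", "crystallised_cognition"): 0.30,
    }
    idx = {name: i for i, name in enumerate(labels)}
    for (a, b), v in pairs.items():
        c[idx[a], idx[b]] = c[idx[b], idx[a]] = v
    clinical_corr = pd.DataFrame(c, index=labels, columns=labels)
    return GroundTruth(target_voxel_rho=rho, clinical_corr=clinical_corr,
                       band_fraction=0.8, seed=seed)


# --------------------------------------------------------------------------
# primitive generators


def forced_correlation_field(base: np.ndarray, rho: float,
                             seed: int | np.random.Generator) -> np.ndarray:
    """A vector whose *sample* Pearson correlation with ``base`` equals rho.

    Construction: standardize base; draw Gaussian noise; residualize the
    noise against base (and the constant); standardize the residual; mix
    with weights rho and sqrt(1 - rho^2).  The output is standardized
    (sample mean 0, unit sample SD), so r(out, base) = rho to ~1e-8.
    """
    base = np.asarray(base, dtype=np.float64).ravel()
    if base.size < 3:
        raise ValueError("base must have at least 3 voxels")
    if not -1.0 < rho < 1.0:
        raise ValueError(f"rho must lie strictly in (-1, 1), got {rho}")
    sd = base.std()
    if sd == 0:
        raise ValueError("zero-variance base")
    b = (base - base.mean()) / sd
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for _ in range(16):
        noise = rng.standard_normal(base.size)
        pre_sd = noise.std()
        noise = noise - noise.mean()
        noise = noise - (noise @ b) / (b @ b) * b  # exact sample orthogonality
        nsd = noise.std()
        # a draw (nearly) collinear with the base leaves only rounding error
        # behind; its direction is meaningless, so resample
        if nsd > 1e-8 * pre_sd:
            break
    else:
        raise RuntimeError("could not draw noise independent of the base")
    e = noise / nsd
    return rho * b + math.sqrt(1.0 - rho * rho) * e


def generate_bold_volume(shape: tuple[int, int, int], n_vols: int, tr: float,
                         band_fraction: float, coupling: float,
                         seed: int, band: tuple[float, float] = (0.01, 0.1),
                         ) -> SeriesVolume:
    """A BOLD-like 4D series with controlled in-band spectral fraction.

    Each voxel's series is synthesized in the frequency domain with random
    phases and Rayleigh-distributed bin amplitudes, rescaled so the expected
    fraction of spectral amplitude inside ``band`` equals ``band_fraction``.
    ``coupling`` in [0, 1] mixes in one shared series common to the whole
    volume, so neighbouring voxels' concordance (ReHo) grows with coupling.
    """
    if not 0.0 <= band_fraction <= 1.0:
        raise ValueError("band_fraction must lie in [0, 1]")
    if not 0.0 <= coupling <= 1.0:
        raise ValueError("coupling must lie in [0, 1]")
    if n_vols < 16:
        raise ValueError("n_vols must be >= 16")
    if tr <= 0:
        raise ValueError("tr must be positive")
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n_vols, d=tr)
    # synthesis bins stay 2 bins clear of the band edges so that the
    # spectral leakage of a tapered/windowed analysis cannot move amplitude
    # across the boundary
    df = freqs[1] if freqs.size > 1 else 0.0
    margin = 2 * df
    in_band = (freqs >= band[0] + margin) & (freqs <= band[1] - margin)
    out_band = (freqs < band[0] - margin) | (freqs > band[1] + margin)
    in_band[0] = out_band[0] = False
    if band_fraction > 0 and not in_band.any():
        raise ValueError("band contains no frequency bins at this length/TR")
    if band_fraction < 1 and not out_band.any():
        raise ValueError("no out-of-band bins at this length/TR")

    def one_series(r: np.random.Generator, n: int) -> np.ndarray:
        nf = freqs.size
        amp = np.abs(r.standard_normal((n, nf)) + 1j * r.standard_normal((n, nf)))
        phase = r.uniform(0, 2 * np.pi, (n, nf))
        amp[:, ~(in_band | out_band)] = 0.0  # DC and edge-margin bins carry nothing
        a_in = amp[:, in_band].sum(axis=1, keepdims=True)
        a_out = amp[:, out_band].sum(axis=1, keepdims=True)
        amp[:, in_band] *= np.where(a_in > 0, band_fraction / np.maximum(a_in, 1e-300), 0.0)
        amp[:, out_band] *= np.where(a_out > 0, (1 - band_fraction) / np.maximum(a_out, 1e-300), 0.0)
        spec = amp * np.exp(1j * phase)
        ts = np.fft.irfft(spec, n=n_vols, axis=1)
        sd = ts.std(axis=1, keepdims=True)
        return ts / np.where(sd > 0, sd, 1.0)

    n_vox = int(np.prod(shape))
    private = one_series(rng, n_vox)
    shared = one_series(rng, 1)
    mixed = math.sqrt(coupling) * shared + math.sqrt(1.0 - coupling) * private
    data = mixed.reshape(shape + (n_vols,))
    return SeriesVolume(data=data, tr=tr)


def generate_dwi_signals(tensor_field: np.ndarray, gradients: GradientTable,
                         s0: float = 1000.0, seed: int = 0,
                         noise_sd: float = 0.0) -> SeriesVolume:
    """DWI signals from a known tensor field under the monoexponential model.

    ``S = S0 * exp(-b g^T D g)`` per voxel and gradient, plus optional
    additive Gaussian noise of SD ``noise_sd``.  Tensors must be symmetric
    positive semidefinite; at ``noise_sd = 0`` the signals are exactly the
    model prediction.
    """
    tf = np.asarray(tensor_field, dtype=np.float64)
    if tf.ndim != 5 or tf.shape[3:] != (3, 3):
        raise ValueError("tensor_field must have shape (X, Y, Z, 3, 3)")
    if not np.allclose(tf, np.swapaxes(tf, 3, 4), atol=1e-12):
        raise ValueError("tensors must be symmetric")
    if np.linalg.eigvalsh(tf.reshape(-1, 3, 3)).min() < -1e-12:
        raise ValueError("tensors must be positive semidefinite")
    if np.any(gradients.bvals < 0):
        raise ValueError("negative b-value")
    b = gradients.bvals
    g = gradients.bvecs
    quad = np.einsum("mi,vij,mj->vm", g, tf.reshape(-1, 3, 3), g)  # g^T D g
    sig = s0 * np.exp(-b[np.newaxis, :] * quad)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sig = sig + rng.normal(0.0, noise_sd, sig.shape)
    data = sig.reshape(tf.shape[:3] + (len(gradients),))
    return SeriesVolume(data=data, tr=1.0)


def default_gradient_table(seed: int = 0) -> GradientTable:
    """The study-style scheme: 7 b0 volumes plus 93 directions split across
    b = 1500 and 3000 s/mm^2.  Directions are pseudo-random unit vectors."""
    rng = np.random.default_rng(seed)
    dirs = rng.standard_normal((93, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    bvals = np.concatenate([np.zeros(7), np.full(46, 1500.0), np.full(47, 3000.0)])
    bvecs = np.vstack([np.zeros((7, 3)), dirs])
    return GradientTable(bvals=bvals, bvecs=bvecs)


def random_tensor_field(shape: tuple[int, int, int], seed: int = 0) -> np.ndarray:
    """Random PSD tensors with eigenvalues in a physiological 0.2–2.0e-3 mm^2/s."""
    rng = np.random.default_rng(seed)
    n = int(np.prod(shape))
    lam = rng.uniform(0.2e-3, 2.0e-3, (n, 3))
    a = rng.standard_normal((n, 3, 3))
    q, _ = np.linalg.qr(a)
    d = np.einsum("nij,nj,nkj->nik", q, lam, q)
    d = 0.5 * (d + np.swapaxes(d, 1, 2))  # kill rounding asymmetry
    return d.reshape(shape + (3, 3))


# --------------------------------------------------------------------------
# cohort assembly


@dataclass
class CohortConfig:
    """Geometry and size of a synthetic cohort.

    Defaults match the study conditions: 35 subjects, a 2x decimation from
    a 64^3 1-mm grid to a 32^3 2-mm analysis grid, ROI boxes spanning ~50
    to ~4000 analysis voxels, 488-volume TR 0.8 s BOLD, and a 100-volume
    DWI scheme (7 b0 + 93 directions at b = 1500/3000 s/mm^2).  Subject
    counts missing a modality mirror the study's data availability
    (DWI-derived metrics missing for 2 subjects, CBF for 1).
    """

    n_subjects: int = 35
    fine_shape: tuple[int, int, int] = (64, 64, 64)
    fine_voxel_mm: float = 1.0
    factor: int = 2
    mode: str = "exact"  # "exact" (sample moments forced) | "sampling"
    modalities: tuple[str, ...] = DEFAULT_MODALITIES
    roi_boxes: dict[str, tuple[tuple[int, int, int], tuple[int, int, int]]] = field(
        default_factory=lambda: dict(_DEFAULT_ROI_BOXES))
    reference_box: tuple[tuple[int, int, int], tuple[int, int, int]] = _REFERENCE_BOX
    missing_counts: dict[str, int] = field(
        default_factory=lambda: {"fa": 2, "md": 2, "odi": 2, "ivf": 2, "wvf": 2,
                                 "cbf": 1})
    include_timeseries: bool = True
    bold_shape: tuple[int, int, int] = (8, 8, 8)
    bold_n_vols: int = 488
    bold_tr: float = 0.8
    bold_coupling: float = 0.5
    dwi_shape: tuple[int, int, int] = (6, 6, 6)
    dwi_s0: float = 1000.0
    dwi_noise_sd: float = 0.0

    @property
    def coarse_shape(self) -> tuple[int, int, int]:
        return tuple(s // self.factor for s in self.fine_shape)

    @property
    def coarse_voxel_mm(self) -> float:
        return self.fine_voxel_mm * self.factor

    def validate(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")
        if self.mode not in ("exact", "sampling"):
            raise ValueError("mode must be 'exact' or 'sampling'")
        if any(s % self.factor for s in self.fine_shape):
            raise ValueError("fine_shape must be divisible by the decimation factor")
        occupancy = np.zeros(self.coarse_shape, dtype=np.int8)
        for name, (origin, size) in list(self.roi_boxes.items()) + [
                ("__reference__", self.reference_box)]:
            if any(o < 0 or o + s > dim for o, s, dim in
                   zip(origin, size, self.coarse_shape)):
                raise ValueError(f"ROI '{name}' does not fit in the analysis grid")
            sl = tuple(slice(o, o + s) for o, s in zip(origin, size))
            occupancy[sl] += 1
        if occupancy.max() > 1:
            raise ValueError("ROI/reference boxes overlap; masks must be disjoint")


@dataclass
class SubjectData:
    """One subject's co-registered bundle of synthetic acquisitions."""

    subject_id: str
    amyloid_pet: ScalarVolume  # analysis grid, pre-SUVR units
    metric_maps: dict[str, ScalarVolume]
    bold: SeriesVolume | None = None
    dwi: SeriesVolume | None = None
    gradients: GradientTable | None = None
    displacement: np.ndarray | None = None  # framewise RMS displacement, mm


@dataclass
class SyntheticCohort:
    """A full synthetic cohort plus its generating ground truth.

    ROI and reference masks share one geometry across subjects (the
    synthetic analogue of coregistered per-subject masks), stored once:
    boolean masks on the fine grid, whose decimation to the analysis grid
    is exact because every box is a union of full coarse cells.
    """

    subjects: list[SubjectData]
    roi_masks_fine: dict[str, MaskVolume]
    reference_mask_fine: MaskVolume
    atlas: ScalarVolume  # shared expression-like map on the analysis grid
    clinical: pd.DataFrame  # index subject_id; includes group label
    truth: GroundTruth
    config: CohortConfig

    @property
    def factor(self) -> int:
        return self.config.factor


def _box_mask_fine(config: CohortConfig, origin, size) -> MaskVolume:
    data = np.zeros(config.fine_shape, dtype=bool)
    f = config.factor
    sl = tuple(slice(o * f, (o + s) * f) for o, s in zip(origin, size))
    data[sl] = True
    return MaskVolume(data, voxel_size=(config.fine_voxel_mm,) * 3)


def _coarse_box_sel(origin, size) -> tuple[slice, slice, slice]:
    return tuple(slice(o, o + s) for o, s in zip(origin, size))


def _coarse_affine(config: CohortConfig) -> np.ndarray:
    """Affine of the analysis grid as produced by exact decimation of the
    fine grid (coarse voxel centres at the centroid of their children)."""
    aff = np.eye(4)
    np.fill_diagonal(aff[:3, :3], config.coarse_voxel_mm)
    aff[:3, 3] = config.fine_voxel_mm * (config.factor - 1) / 2.0
    return aff


def _forced_clinical(n: int, corr: np.ndarray, rng: np.random.Generator,
                     exact: bool) -> np.ndarray:
    """(n, p) columns with sample (exact) or population correlation ``corr``."""
    p = corr.shape[0]
    if exact and n <= p:
        raise ValueError(
            f"exact clinical forcing needs n_subjects > {p} (the number of "
            "clinical variables incl. the latent burden); use sampling mode "
            "or a larger cohort")
    z = rng.standard_normal((n, p))
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(p))
    if exact:
        z = z - z.mean(axis=0)
        s = np.cov(z, rowvar=False, bias=False)
        z = z @ np.linalg.inv(np.linalg.cholesky(s)).T  # sample-whiten
    return z @ chol.T


def generate_cohort(config: CohortConfig | None = None,
                    truth: GroundTruth | None = None,
                    seed: int | None = None) -> SyntheticCohort:
    """Generate a synthetic cohort realizing the requested ground truth.

    In ``exact`` mode, per-subject within-ROI sample correlations between
    the amyloid map and each target map equal ``truth.target_voxel_rho``
    to ~1e-8, and clinical sample correlations equal ``truth.clinical_corr``
    to the same tolerance; in ``sampling`` mode the same values hold in
    expectation with sampling noise ~ (1 - rho^2)/sqrt(V).  Identical
    (config, truth, seed) yield bit-identical cohorts.
    """
    config = config or CohortConfig()
    config.validate()
    if truth is None:
        truth = default_ground_truth(seed=0 if seed is None else seed,
                                     rois=tuple(config.roi_boxes),
                                     modalities=config.modalities)
    root = truth.seed if seed is None else seed
    exact = config.mode == "exact"
    n = config.n_subjects
    cshape = config.coarse_shape
    cvox = (config.coarse_voxel_mm,) * 3
    caff = _coarse_affine(config)

    # --- clinical table with a latent amyloid burden column
    labels = list(truth.clinical_corr.index)
    y = _forced_clinical(n, truth.clinical_corr.to_numpy(dtype=np.float64),
                         rng_for(root, "clinical"), exact)
    subj_ids = [f"sub-{i:03d}" for i in range(n)]
    clinical = pd.DataFrame(index=pd.Index(subj_ids, name="subject_id"))
    burden_std = (y[:, 0] - y[:, 0].mean()) / y[:, 0].std(ddof=0)
    for j, name in enumerate(labels):
        if name == "amyloid_burden":
            continue
        mu, sd = CLINICAL_VARIABLES.get(name, (0.0, 1.0))
        clinical[name] = mu + sd * y[:, j]
    # binary amyloid reading: highest-burden ~11/35 of subjects flagged
    # positive, mirroring the study's 24/11 negative/positive split
    n_pos = max(1, round(n * 11 / 35))
    order = np.argsort(-burden_std, kind="stable")
    reading = np.zeros(n, dtype=int)
    reading[order[:n_pos]] = 1
    clinical["amyloid_positive"] = reading

    # target mean SUVR per subject: affine in the latent burden
    target_suvr = 1.2 + 0.25 * burden_std

    roi_masks_fine = {name: _box_mask_fine(config, *box)
                      for name, box in config.roi_boxes.items()}
    reference_mask_fine = _box_mask_fine(config, *config.reference_box)

    # the atlas carries one standardized pattern per ROI; each subject's
    # amyloid ROI voxels are then forced against it, so the atlas arm gets
    # its target rho with genuinely per-subject amyloid patterns
    pattern_rng = rng_for(root, "atlas-roi-pattern")
    atlas_pattern: dict[str, np.ndarray] = {}
    for name, (origin, size) in config.roi_boxes.items():
        pat = pattern_rng.standard_normal(size)
        atlas_pattern[name] = (pat - pat.mean()) / pat.std()

    # subject-level modality couplings: each metric's per-subject ROI-mean
    # offset tracks the latent burden with the modality's default strength,
    # giving the similarity arm non-degenerate clinical profiles
    mod_offset: dict[str, np.ndarray] = {}
    for mod in config.modalities:
        c = float(np.clip(_DEFAULT_MODALITY_RHO.get(mod, 0.1), -0.99, 0.99))
        eps = rng_for(root, "modality-offset", mod).standard_normal(n)
        mod_offset[mod] = c * burden_std + math.sqrt(1 - c * c) * eps

    grads = default_gradient_table(seed=rng_for(root, "gradients").integers(2**31))
    tensor_field = truth.tensor_field
    if tensor_field is None and config.include_timeseries:
        tensor_field = random_tensor_field(
            config.dwi_shape, seed=int(rng_for(root, "tensors").integers(2**31)))

    ref_sel = _coarse_box_sel(*config.reference_box)
    missing_of: dict[str, set[int]] = {
        mod: set(range(n - k, n)) for mod, k in config.missing_counts.items()}
    subjects: list[SubjectData] = []

    for i in range(n):
        srng = rng_for(root, "subject", i)
        pet = srng.normal(1.0, 0.1, cshape)
        pet[ref_sel] = srng.normal(1.0, 0.02, pet[ref_sel].shape)
        ref_mean = pet[ref_sel].mean()
        # ROI voxels: a per-subject pattern carrying the atlas-arm target
        # rho, scaled and shifted so the ROI-mean SUVR equals the
        # latent-burden target exactly (affine, so rho is untouched)
        for name, (origin, size) in config.roi_boxes.items():
            sl = _coarse_box_sel(origin, size)
            base = atlas_pattern[name].ravel()
            rho_a = truth.target_voxel_rho.get((name, "atlas"))
            if rho_a is None:
                pat = srng.standard_normal(base.size)
                pat = (pat - pat.mean()) / pat.std()
            elif exact:
                pat = forced_correlation_field(base, rho_a, srng)
            else:
                pat = (rho_a * base
                       + math.sqrt(1 - rho_a * rho_a) * srng.standard_normal(base.size))
            pet[sl] = (target_suvr[i] * ref_mean
                       + 0.1 * ref_mean * pat.reshape(size))
        amyloid = ScalarVolume(pet, voxel_size=cvox, affine=caff)

        metric_maps: dict[str, ScalarVolume] = {}
        for mod in config.modalities:
            if i in missing_of.get(mod, ()):
                continue
            mrng = rng_for(root, "subject", i, "metric", mod)
            data = mrng.standard_normal(cshape)
            for name, (origin, size) in config.roi_boxes.items():
                rho = truth.target_voxel_rho.get((name, mod))
                if rho is None:
                    continue
                sl = _coarse_box_sel(origin, size)
                base = pet[sl].ravel()
                if exact:
                    vals = forced_correlation_field(base, rho, mrng)
                else:
                    b = (base - base.mean()) / base.std()
                    noise = mrng.standard_normal(base.size)
                    vals = rho * b + math.sqrt(1 - rho * rho) * noise
                data[sl] = vals.reshape(size) + mod_offset[mod][i]
            metric_maps[mod] = ScalarVolume(data, voxel_size=cvox, affine=caff)

        bold = dwi = None
        displacement = None
        if config.include_timeseries:
            bold = generate_bold_volume(
                config.bold_shape, config.bold_n_vols, config.bold_tr,
                truth.band_fraction, config.bold_coupling,
                seed=int(rng_for(root, "subject", i, "bold").integers(2**31)))
            dwi = generate_dwi_signals(
                tensor_field, grads, s0=config.dwi_s0,
                seed=int(rng_for(root, "subject", i, "dwi").integers(2**31)),
                noise_sd=config.dwi_noise_sd)
            displacement = np.abs(
                rng_for(root, "subject", i, "motion").normal(
                    0.0, 0.05, config.bold_n_vols))
        subjects.append(SubjectData(
            subject_id=subj_ids[i], amyloid_pet=amyloid, metric_maps=metric_maps,
            bold=bold, dwi=dwi, gradients=grads if config.include_timeseries else None,
            displacement=displacement))

    # assemble the shared atlas map: background noise plus the per-ROI
    # patterns every subject's amyloid map was forced against
    atlas_data = rng_for(root, "atlas").standard_normal(cshape)
    for name, (origin, size) in config.roi_boxes.items():
        atlas_data[_coarse_box_sel(origin, size)] = atlas_pattern[name]
    atlas = ScalarVolume(atlas_data, voxel_size=cvox, affine=caff)

    return SyntheticCohort(subjects=subjects, roi_masks_fine=roi_masks_fine,
                           reference_mask_fine=reference_mask_fine, atlas=atlas,
                           clinical=clinical, truth=truth, config=config)


# --------------------------------------------------------------------------
# on-disk export


def write_cohort(cohort: SyntheticCohort, out_dir) -> Path:
    """Write a cohort to disk: NIfTI volumes, FSL bval/bvec, TSV clinical
    table and a JSON ground-truth manifest.  Returns the output directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)
    for name, m in cohort.roi_masks_fine.items():
        m.to_nifti(out / "masks" / f"roi-{name}.nii")
    cohort.reference_mask_fine.to_nifti(out / "masks" / "reference.nii")
    cohort.atlas.to_nifti(out / "atlas.nii")
    for s in cohort.subjects:
        sdir = out / s.subject_id
        sdir.mkdir(exist_ok=True)
        s.amyloid_pet.to_nifti(sdir / "amyloid_pet.nii")
        for mod, vol in s.metric_maps.items():
            vol.to_nifti(sdir / f"metric-{mod}.nii")
        if s.bold is not None:
            s.bold.to_nifti(sdir / "bold.nii")
        if s.dwi is not None:
            s.dwi.to_nifti(sdir / "dwi.nii")
            s.gradients.to_fsl(sdir / "dwi.bval", sdir / "dwi.bvec")
        if s.displacement is not None:
            np.savetxt(sdir / "displacement.txt", s.displacement, fmt="%.8g")
    cohort.clinical.to_csv(out / "clinical.tsv", sep="\t")
    manifest = {
        "seed": int(cohort.truth.seed),
        "mode": cohort.config.mode,
        "n_subjects": cohort.config.n_subjects,
        "band_fraction": cohort.truth.band_fraction,
        "target_voxel_rho": {f"{roi}|{mod}": v for (roi, mod), v
                             in cohort.truth.target_voxel_rho.items()},
        "clinical_corr": {
            "labels": list(cohort.truth.clinical_corr.index),
            "matrix": cohort.truth.clinical_corr.to_numpy().tolist(),
        },
    }
    (out / "ground_truth.json").write_text(json.dumps(manifest, indent=2))
    return out
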