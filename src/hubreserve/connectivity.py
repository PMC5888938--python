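"""Global hub-connectivity scores from denoised resting-state runs.

The processing chain implemented here takes a spatially normalized 4D run and
produces, per subject and seed, a single *global connectivity* score: the mean
of the positive Fisher-z Pearson correlations between an 8 mm spherical seed
(e.g. the left frontal cortex hub at MNI −42, 6, 28) and every grey-matter
voxel outside the seed. This is a weighted degree-centrality hub measure.

Steps (in the order the pipeline applies them):

1. :func:`smooth_volumes` — 8 mm FWHM Gaussian smoothing honouring the affine.
2. :func:`denoise_run` — linear detrend, 0.01–0.08 Hz zero-phase band-pass,
   then residualization against the six motion parameters and the mean white
   matter / CSF signals (confounds filtered identically first).
3. :func:`compute_framewise_displacement` / :func:`build_censor_mask` —
   motion scrubbing: volumes with FD > 0.5 mm are censored together with one
   preceding and two subsequent volumes; subjects with > 30 % of volumes
   censored are excluded.
4. :func:`global_connectivity` — the score itself, on retained volumes only.

All geometry runs through the image affine in world millimetres; there is no
voxel-index arithmetic across grids.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage, signal

from ._types import (
    BoldRun,
    CensorMask,
    ConnectivityResult,
    FdSeries,
    GmMask,
    MotionTrace,
    RoiSpec,
)

__all__ = [
    "compute_framewise_displacement",
    "build_censor_mask",
    "make_sphere_roi",
    "build_group_gm_mask",
    "smooth_volumes",
    "denoise_run",
    "global_connectivity",
    "bandpass_filter",
]

#: FWHM of a Gaussian equals sigma * 2*sqrt(2*ln 2).
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

# Clip bound applied to correlations before the Fisher z-transform so that
# r = +/-1 stays finite.
R_CLIP = 1.0 - 1e-7


def compute_framewise_displacement(
    motion: MotionTrace, sphere_radius_mm: float = 50.0
) -> FdSeries:
    """Framewise displacement: summed absolute parameter change per volume.

    Rotations are converted to millimetres of arc on a sphere of
    ``sphere_radius_mm`` (50 mm, the convention under which the 0.5 mm
    scrubbing threshold is calibrated). The first volume has no predecessor
    and is fixed at 0.
    """
    if len(motion) < 2:
        raise ValueError("motion trace needs at least 2 volumes to difference")
    params = motion.as_matrix()
    deltas = np.abs(np.diff(params, axis=0))
    fd_tail = deltas[:, :3].sum(axis=1) + sphere_radius_mm * deltas[:, 3:].sum(axis=1)
    return FdSeries(np.concatenate([[0.0], fd_tail]))


def build_censor_mask(
    fd: FdSeries | np.ndarray,
    threshold_mm: float = 0.5,
    n_pre: int = 1,
    n_post: int = 2,
    exclusion_fraction: float = 0.30,
) -> CensorMask:
    """Scrub volumes around motion spikes and decide subject exclusion.

    Every volume with FD strictly above ``threshold_mm`` is censored together
    with ``n_pre`` preceding and ``n_post`` subsequent volumes (windows are
    clipped at run boundaries; overlapping windows union). A subject is
    excluded when the censored fraction strictly exceeds
    ``exclusion_fraction``. ``fd`` may be an :class:`FdSeries` or any
    per-volume displacement array.
    """
    fd_values = fd.fd if isinstance(fd, FdSeries) else np.asarray(fd, dtype=float).ravel()
    if fd_values.size == 0:
        raise ValueError("framewise displacement series is empty")
    n = fd_values.size
    censored = np.zeros(n, dtype=bool)
    for t in np.flatnonzero(fd_values > threshold_mm):
        censored[max(0, t - n_pre) : min(n, t + n_post + 1)] = True
    retained = ~censored
    frac = float(censored.mean())
    return CensorMask(retained=retained, censored_fraction=frac, excluded=frac > exclusion_fraction)


def _world_coordinates(affine: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """World (mm) coordinates of every voxel centre; shape (*shape, 3)."""
    ii, jj, kk = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]), indexing="ij"
    )
    ijk = np.stack([ii, jj, kk], axis=-1).astype(float)
    return ijk @ affine[:3, :3].T + affine[:3, 3]


def make_sphere_roi(
    spec: RoiSpec, affine: np.ndarray, shape: tuple[int, int, int]
) -> np.ndarray:
    """Binary mask of voxels within ``spec.radius`` mm of the seed centre.

    Membership is decided in world space: a voxel belongs to the sphere iff
    the Euclidean distance from its centre to ``spec.center_mni`` is at most
    the radius.
    """
    affine = np.asarray(affine, dtype=float)
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("grid affine is singular")
    world = _world_coordinates(affine, tuple(shape))
    dist2 = ((world - np.asarray(spec.center_mni)) ** 2).sum(axis=-1)
    mask = dist2 <= spec.radius**2
    if not mask.any():
        raise ValueError(
            f"seed sphere '{spec.name}' (centre {spec.center_mni}, radius "
            f"{spec.radius} mm) lies entirely outside the image grid"
        )
    return mask


def build_group_gm_mask(
    gm_probability_maps: list[np.ndarray], threshold: float = 0.3
) -> GmMask:
    """Average per-subject grey-matter probability maps and binarize.

    A voxel enters the mask iff its mean probability across subjects is
    *strictly* greater than ``threshold``.
    """
    if len(gm_probability_maps) == 0:
        raise ValueError("need at least one grey-matter probability map")
    maps = [np.asarray(m, dtype=float) for m in gm_probability_maps]
    shape = maps[0].shape
    for i, m in enumerate(maps):
        if m.shape != shape:
            raise ValueError(f"probability map {i} has shape {m.shape}, expected {shape}")
        if m.min() < 0 or m.max() > 1:
            raise ValueError(f"probability map {i} has values outside [0, 1]")
    mean_map = np.mean(maps, axis=0)
    return GmMask(mask=mean_map > threshold, threshold=threshold)


def smooth_volumes(run: BoldRun, fwhm_mm: float = 8.0) -> BoldRun:
    """Gaussian-smooth each volume with an isotropic world-space kernel.

    The kernel width is specified as full-width at half-maximum in
    millimetres; the per-axis sigma in voxel units is derived from the voxel
    edge lengths implied by the affine, so anisotropic grids are handled.
    ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm_mm == 0:
        return BoldRun(run.data.copy(), run.tr, run.affine.copy(), run.run_id)
    sigma_vox = (fwhm_mm * _FWHM_TO_SIGMA) / run.voxel_sizes()
    smoothed = ndimage.gaussian_filter(run.data, sigma=(*sigma_vox, 0.0))
    return BoldRun(smoothed, run.tr, run.affine.copy(), run.run_id)


def bandpass_filter(
    series: np.ndarray, tr: float, band_hz: tuple[float, float] = (0.01, 0.08), order: int = 2
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass along the last axis."""
    low, high = band_hz
    nyquist = 1.0 / (2.0 * tr)
    if not (0 < low < high < nyquist):
        raise ValueError(
            f"band edges must satisfy 0 < low < high < Nyquist ({nyquist:.4f} Hz); "
            f"got ({low}, {high})"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=1.0 / tr, output="sos")
    return signal.sosfiltfilt(sos, series, axis=-1)


def denoise_run(
    run: BoldRun,
    motion: MotionTrace,
    wm_mask: np.ndarray,
    csf_mask: np.ndarray,
    band_hz: tuple[float, float] = (0.01, 0.08),
) -> np.ndarray:
    """Detrend, band-pass and nuisance-regress a run; returns voxels x time.

    Rows are voxels in C (row-major) raveled order over the 3D grid. Per
    voxel, in order: linear detrend; zero-phase band-pass at ``band_hz``;
    residualization against the six motion parameters and the mean white
    matter and CSF signals. The confound regressors are detrended and
    filtered identically before the regression so that frequencies removed
    from the data cannot be reintroduced.
    """
    if len(motion) != run.n_volumes:
        raise ValueError(
            f"motion trace length {len(motion)} does not match run volumes {run.n_volumes}"
        )
    wm_mask = np.asarray(wm_mask, dtype=bool)
    csf_mask = np.asarray(csf_mask, dtype=bool)
    for name, m in (("white-matter", wm_mask), ("CSF", csf_mask)):
        if m.shape != run.shape3d:
            raise ValueError(f"{name} mask shape {m.shape} does not match run grid {run.shape3d}")

    n_vox = int(np.prod(run.shape3d))
    mat = run.data.reshape(n_vox, run.n_volumes)

    cleaned = signal.detrend(mat, axis=-1, type="linear")
    cleaned = bandpass_filter(cleaned, run.tr, band_hz)

    confounds = np.column_stack(
        [
            motion.as_matrix(),
            mat[wm_mask.ravel()].mean(axis=0),
            mat[csf_mask.ravel()].mean(axis=0),
        ]
    )
    confounds = signal.detrend(confounds, axis=0, type="linear")
    confounds = bandpass_filter(confounds.T, run.tr, band_hz).T

    design = np.column_stack([np.ones(run.n_volumes), confounds])
    beta, *_ = np.linalg.lstsq(design, cleaned.T, rcond=None)
    return cleaned - (design @ beta).T


def _pearson_to_seed(seed_ts: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Pearson r between one series and each row; zero-variance rows get r=0."""
    s = seed_ts - seed_ts.mean()
    t = targets - targets.mean(axis=1, keepdims=True)
    s_norm = np.sqrt((s**2).sum())
    t_norm = np.sqrt((t**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (t @ s) / (t_norm * s_norm)
    return np.where(t_norm > 0, r, 0.0)


def global_connectivity(
    cleaned: np.ndarray,
    seed_mask: np.ndarray,
    gm: GmMask,
    censor: CensorMask,
    subject_id: str = "",
    seed_name: str = "",
    min_retained: int = 10,
) -> ConnectivityResult:
    """Mean positive Fisher-z correlation of the seed with grey matter.

    ``cleaned`` is the voxels x time matrix from :func:`denoise_run` (rows in
    C raveled grid order). Censored volumes are dropped; the seed time series
    is the mean over seed-and-grey-matter voxels; Pearson correlations are
    computed against every grey-matter voxel *outside* the seed; correlations
    are clipped to +/-(1 - 1e-7) and Fisher z-transformed; the score averages
    the z values of voxels with r > 0 only (negative and zero correlations
    drop out of numerator and denominator alike). If no voxel correlates
    positively the score is 0 and a warning flag is set.
    """
    if censor.excluded:
        raise ValueError(
            f"subject '{subject_id}' is excluded by the scrubbing QC "
            f"({censor.censored_fraction:.1%} of volumes censored); refusing to score"
        )
    seed_mask = np.asarray(seed_mask, dtype=bool)
    if seed_mask.shape != gm.mask.shape:
        raise ValueError("seed mask and grey-matter mask are on different grids")
    retained = censor.retained
    if retained.size != cleaned.shape[1]:
        raise ValueError("censor mask length does not match the time dimension")
    if int(retained.sum()) < min_retained:
        raise ValueError(
            f"only {int(retained.sum())} retained volumes (< {min_retained}); too few to correlate"
        )

    seed_flat = seed_mask.ravel()
    gm_flat = gm.mask.ravel()
    seed_gm = seed_flat & gm_flat
    if not seed_gm.any():
        raise ValueError(f"seed '{seed_name}' contains no grey-matter voxels")
    target_flat = gm_flat & ~seed_flat

    seed_ts = cleaned[seed_gm][:, retained].mean(axis=0)
    if np.std(seed_ts) == 0:
        raise ValueError(f"seed '{seed_name}' time series has zero variance")

    r = _pearson_to_seed(seed_ts, cleaned[target_flat][:, retained])
    z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    positive = r > 0
    n_pos = int(positive.sum())
    no_positive = n_pos == 0
    if no_positive:
        warnings.warn(
            f"no positively correlated grey-matter voxel for seed '{seed_name}'; score set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        score = 0.0
    else:
        score = float(z[positive].mean())

    return ConnectivityResult(
        subject_id=subject_id,
        seed_name=seed_name,
        score=score,
        n_positive_voxels=n_pos,
        n_gm_voxels=int(target_flat.sum()),
        censored_fraction=censor.censored_fraction,
        excluded=False,
        no_positive_warning=no_positive,
    )
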