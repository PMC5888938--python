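"""Core value types shared across the pipeline.

These are thin, validated containers: a 4D BOLD run with its geometry, the
per-volume motion/displacement/censoring state used by scrubbing, seed-sphere
definitions, and the per-subject connectivity score record that the
statistical modules consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "BoldRun",
    "MotionTrace",
    "FdSeries",
    "CensorMask",
    "RoiSpec",
    "GmMask",
    "ConnectivityResult",
    "SEED_SPECS",
]


@dataclass
class BoldRun:
    """A 4D resting-state run: intensities, repetition time and geometry.

    ``data`` is indexed (x, y, z, t); ``affine`` maps voxel indices to world
    (RAS+) millimetre coordinates.
    """

    data: np.ndarray
    tr: float
    affine: np.ndarray
    run_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D (x,y,z,t), got ndim={self.data.ndim}")
        if self.data.shape[3] < 2:
            raise ValueError("BOLD run needs at least 2 volumes")
        if not self.tr > 0:
            raise ValueError(f"repetition time must be positive, got {self.tr}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def voxel_sizes(self) -> np.ndarray:
        """World-space edge length of one voxel step along each array axis."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


@dataclass
class MotionTrace:
    """Rigid-body realignment parameters per volume.

    ``translations`` in mm and ``rotations`` in radians, each of shape
    (n_volumes, 3).
    """

    translations: np.ndarray
    rotations: np.ndarray

    def __post_init__(self) -> None:
        self.translations = np.atleast_2d(np.asarray(self.translations, dtype=float))
        self.rotations = np.atleast_2d(np.asarray(self.rotations, dtype=float))
        if self.translations.shape[1] != 3 or self.rotations.shape[1] != 3:
            raise ValueError("motion trace needs 3 translation and 3 rotation columns")
        if self.translations.shape[0] != self.rotations.shape[0]:
            raise ValueError("translation and rotation traces differ in length")

    def __len__(self) -> int:
        return self.translations.shape[0]

    def as_matrix(self) -> np.ndarray:
        """(n_volumes, 6) matrix in column order trans_x..z, rot_x..z."""
        return np.hstack([self.translations, self.rotations])


@dataclass
class FdSeries:
    """Framewise displacement per volume, mm; the first volume is fixed at 0."""

    fd: np.ndarray

    def __post_init__(self) -> None:
        self.fd = np.asarray(self.fd, dtype=float).ravel()
        if self.fd.size == 0:
            raise ValueError("framewise displacement series is empty")
        if self.fd[0] != 0:
            raise ValueError("fd[0] must be 0 by convention")
        if np.any(self.fd < 0):
            raise ValueError("framewise displacement cannot be negative")

    def __len__(self) -> int:
        return self.fd.size


@dataclass
class CensorMask:
    """Volume retention state after scrubbing, plus the exclusion verdict."""

    retained: np.ndarray
    censored_fraction: float
    excluded: bool

    def __post_init__(self) -> None:
        self.retained = np.asarray(self.retained, dtype=bool).ravel()
        expected = 1.0 - float(np.mean(self.retained))
        if abs(expected - self.censored_fraction) > 1e-12:
            raise ValueError("censored_fraction inconsistent with retained mask")

    def __len__(self) -> int:
        return self.retained.size


@dataclass(frozen=True)
class RoiSpec:
    """A spherical seed region in world (MNI) coordinates."""

    name: str
    center_mni: tuple[float, float, float]
    radius: float = 8.0

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("sphere radius must be positive")


#: The left-frontal hub seed and its three control seeds (right homotope,
#: occipital-pole and primary-motor null regions), 8 mm radius each.
SEED_SPECS: Mapping[str, RoiSpec] = {
    "LFC": RoiSpec("LFC", (-42.0, 6.0, 28.0)),
    "RFC": RoiSpec("RFC", (42.0, 6.0, 28.0)),
    "OCC": RoiSpec("OCC", (-19.0, -102.0, -3.0)),
    "M1": RoiSpec("M1", (-38.0, -22.0, 56.0)),
}


@dataclass
class GmMask:
    """Binary grey-matter mask on the run grid.

    Built by averaging per-subject grey-matter probability maps and keeping
    voxels whose mean probability is strictly above ``threshold``.
    """

    mask: np.ndarray
    threshold: float = 0.3

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("grey-matter mask must be 3D")
        if not self.mask.any():
            raise ValueError("grey-matter mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class ConnectivityResult:
    """Per-subject, per-seed global connectivity score with QC fields.

    ``score`` is the mean of the positive Fisher-z correlations between the
    seed time series and every grey-matter voxel outside the seed;
    ``n_gm_voxels`` counts those candidate target voxels. ``score`` is None
    for excluded subjects.
    """

    subject_id: str
    seed_name: str
    score: float | None
    n_positive_voxels: int
    n_gm_voxels: int
    censored_fraction: float
    excluded: bool
    no_positive_warning: bool = False

    def __post_init__(self) -> None:
        if self.excluded:
            if self.score is not None:
                raise ValueError("excluded subjects carry no score")
        else:
            if self.score is None or self.score < 0:
                raise ValueError("score must be a non-negative number")
            if not (0 <= self.n_positive_voxels <= self.n_gm_voxels):
                raise ValueError("0 <= n_positive_voxels <= n_gm_voxels violated")
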