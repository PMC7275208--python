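"""Multi-radius spherical label masks encoding the five landmarks.

Each landmark is rendered as a filled sphere of class-coded voxels
(LCC=1, NCC=2, RCC=3, LCO=4, RCO=5) on a shared grid; masks at radii
3, 5 and 7 mm are the training / evaluation targets of the three
detection models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .volumetric_io import (
    CLASS_CODES,
    LANDMARK_NAMES,
    GridSpec,
    LandmarkSet,
    Volume3D,
    voxel_to_world,
    world_to_voxel,
)

__all__ = ["LabelMask", "generate_sphere_mask", "mask_to_landmarks", "LandmarkSet"]

logger = logging.getLogger(__name__)

DEFAULT_RADII = (3.0, 5.0, 7.0)


@dataclass
class LabelMask:
    """A label volume of class-coded landmark spheres at one radius (mm)."""

    volume: Volume3D
    radius: float

    def __post_init__(self):
        if self.volume.unit != "label":
            raise ValueError("LabelMask requires a label-unit volume")
        if self.radius <= 0:
            raise ValueError("radius must be positive")

    def class_count(self, code: int) -> int:
        return int(np.count_nonzero(self.volume.values == code))


def generate_sphere_mask(landmarks: LandmarkSet, grid: GridSpec, radius: float) -> LabelMask:
    """Render the five landmarks as class-coded spheres on ``grid``.

    A voxel belongs to class ``c`` when its center lies within ``radius`` mm
    (boundary inclusive) of landmark ``c``; where spheres overlap, the voxel
    takes the class of the *nearest* landmark center (ties -> lower class
    code). A landmark outside the grid simply leaves its class absent, with
    a logged warning.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    shape = np.array(grid.shape)
    labels = np.zeros(grid.shape, dtype=np.int16)
    best_d2 = np.full(grid.shape, np.inf)

    for name in LANDMARK_NAMES:  # ascending class code: ties keep the lower code
        code = CLASS_CODES[name]
        center_vox = world_to_voxel(grid, landmarks[name])
        if np.any(center_vox < -0.5) or np.any(center_vox > shape - 0.5):
            logger.warning("landmark %s lies outside the grid; class %d absent", name, code)
            continue
        # bounding box of the sphere in voxel space (direction is orthonormal,
        # so voxel-space distances are spacing-scaled world distances)
        margin = radius / grid.spacing
        lo = np.maximum(np.floor(center_vox - margin).astype(int), 0)
        hi = np.minimum(np.ceil(center_vox + margin).astype(int) + 1, shape)
        if np.any(lo >= hi):
            logger.warning("landmark %s sphere misses every voxel center", name)
            continue
        axes = [
            (grid.spacing[a] * (np.arange(lo[a], hi[a]) - center_vox[a])) ** 2
            for a in range(3)
        ]
        d2 = axes[0][:, None, None] + axes[1][None, :, None] + axes[2][None, None, :]
        box = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
        hit = (d2 <= radius * radius) & (d2 < best_d2[box])
        labels[box][hit] = code
        best_d2[box][hit] = d2[hit]

    vol = Volume3D(labels, grid.spacing, grid.origin, grid.direction, unit="label")
    return LabelMask(vol, float(radius))


def mask_to_landmarks(mask: LabelMask) -> LandmarkSet:
    """Recover landmark positions as per-class centroids of labeled voxels.

    The unweighted centroid of each class's voxel centers (world mm). For an
    isolated landmark on a voxel center the discretized ball is symmetric and
    the centroid is exact; off-center landmarks are recovered to within the
    discretization error (a fraction of a voxel).
    """
    labels = mask.volume.values
    grid = mask.volume.grid
    points = {}
    for name in LANDMARK_NAMES:
        idx = np.argwhere(labels == CLASS_CODES[name])
        if idx.size == 0:
            raise ValueError(f"class {name} is absent from the mask")
        points[name] = voxel_to_world(grid, idx.astype(float)).mean(axis=0)
    return LandmarkSet(points)
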