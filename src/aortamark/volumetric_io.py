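"""Volumetric image containers, NIfTI I/O, and grid geometry.

All world coordinates are RAS+ millimetres, as in the NIfTI standard.
Voxel indices are 0-based and *fractional indices are allowed*; the world
position of voxel ``(0, 0, 0)`` refers to the **center** of that voxel, so

    world = origin + direction @ (spacing * index)

is an exact affine round-trip with :func:`world_to_voxel`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

#: canonical class ordering of the five aortic-root landmarks:
#: the three leaflet hinge (basal attachment) points and the two coronary ostia.
LANDMARK_NAMES = ("LCC", "NCC", "RCC", "LCO", "RCO")

#: integer label codes used in sphere masks and probability-map channels.
CLASS_CODES = {"LCC": 1, "NCC": 2, "RCC": 3, "LCO": 4, "RCO": 5}

VALID_UNITS = ("HU", "probability", "label")

_ORTHO_TOL = 1e-6


def _as_vec3(x, name="value") -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {v.shape}")
    return v


def _check_direction(direction: np.ndarray) -> np.ndarray:
    d = np.asarray(direction, dtype=float)
    if d.shape != (3, 3):
        raise ValueError(f"direction must be 3x3, got {d.shape}")
    if np.linalg.norm(d.T @ d - np.eye(3)) >= _ORTHO_TOL:
        raise ValueError("direction matrix is not orthonormal")
    return d


@dataclass(frozen=True)
class GridSpec:
    """Shared voxel-grid geometry of a volume, mask, or probability map."""

    shape: tuple[int, int, int]
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError(f"shape must be three counts >= 1, got {self.shape}")
        sp = _as_vec3(self.spacing, "spacing")
        if np.any(sp <= 0):
            raise ValueError(f"spacing must be positive, got {sp}")
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "origin", _as_vec3(self.origin, "origin"))
        object.__setattr__(self, "direction", _check_direction(self.direction))

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine (NIfTI convention)."""
        a = np.eye(4)
        a[:3, :3] = self.direction @ np.diag(self.spacing)
        a[:3, 3] = self.origin
        return a

    def same_geometry(self, other: "GridSpec", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.direction, other.direction, atol=tol)
        )


@dataclass
class Volume3D:
    """A 3D scalar grid with physical geometry.

    ``unit`` is one of ``"HU"`` (CT attenuation), ``"probability"``
    (values in [0, 1]) or ``"label"`` (integer class codes 0-5).
    """

    values: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))
    unit: str = "HU"

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D, got ndim={self.values.ndim}")
        self.spacing = _as_vec3(self.spacing, "spacing")
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.origin = _as_vec3(self.origin, "origin")
        self.direction = _check_direction(self.direction)
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unit must be one of {VALID_UNITS}, got {self.unit!r}")
        if self.unit == "probability":
            if self.values.size and (self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9):
                raise ValueError("probability volume has values outside [0, 1]")
        if self.unit == "label":
            v = self.values
            if not np.issubdtype(v.dtype, np.integer):
                raise ValueError("label volume must have an integer dtype")
            if v.size and (v.min() < 0 or v.max() > 5):
                raise ValueError("label codes must lie in 0..5")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.values.shape, self.spacing, self.origin, self.direction)

    @property
    def is_isotropic(self) -> bool:
        return bool(np.allclose(self.spacing, self.spacing[0], atol=1e-9))


@dataclass
class LandmarkSet:
    """The five named aortic-root landmarks in world coordinates (mm).

    Exactly the classes LCC, NCC, RCC (hinge points) and LCO, RCO
    (coronary ostia) must be present, each as a finite 3D point.
    """

    points: Mapping[str, np.ndarray]

    def __post_init__(self):
        pts = {}
        if set(self.points) != set(LANDMARK_NAMES):
            raise ValueError(
                f"landmark set must contain exactly {LANDMARK_NAMES}, got {sorted(self.points)}"
            )
        for name in LANDMARK_NAMES:
            p = _as_vec3(self.points[name], name)
            if not np.all(np.isfinite(p)):
                raise ValueError(f"landmark {name} has non-finite coordinates: {p}")
            pts[name] = p
        self.points = pts

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def as_array(self) -> np.ndarray:
        """(5, 3) array in canonical class order LCC, NCC, RCC, LCO, RCO."""
        return np.stack([self.points[n] for n in LANDMARK_NAMES])

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "LandmarkSet":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (5, 3):
            raise ValueError(f"expected (5, 3) array, got {arr.shape}")
        return cls({n: arr[i] for i, n in enumerate(LANDMARK_NAMES)})

    def transformed(self, matrix: np.ndarray, translation: np.ndarray) -> "LandmarkSet":
        """Apply ``x -> matrix @ x + translation`` to every landmark."""
        m = np.asarray(matrix, float)
        t = _as_vec3(translation, "translation")
        return LandmarkSet({n: m @ p + t for n, p in self.points.items()})


def read_landmarks(path) -> LandmarkSet:
    """Read a landmark JSON file ``{"LCC": [x,y,z], ...}`` (mm, RAS+)."""
    with open(path) as fh:
        data = json.load(fh)
    return LandmarkSet({k: np.asarray(v, dtype=float) for k, v in data.items()})


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    with open(path, "w") as fh:
        json.dump({n: list(landmarks[n]) for n in LANDMARK_NAMES}, fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# coordinate transforms
# ---------------------------------------------------------------------------

def voxel_to_world(grid: GridSpec, index) -> np.ndarray:
    """World position (mm) of a fractional voxel index (or (N, 3) of them)."""
    idx = np.asarray(index, dtype=float)
    return grid.origin + (grid.direction @ (grid.spacing * idx).reshape(-1, 3).T).T.reshape(idx.shape)


def world_to_voxel(grid: GridSpec, point) -> np.ndarray:
    """Fractional voxel index of a world point (mm); exact inverse of voxel_to_world."""
    p = np.asarray(point, dtype=float)
    rel = (grid.direction.T @ (p - grid.origin).reshape(-1, 3).T).T
    return (rel / grid.spacing).reshape(p.shape)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def read_volume(path) -> Volume3D:
    """Read a NIfTI (.nii/.nii.gz) file into a :class:`Volume3D`.

    The stored affine is decomposed into spacing (column norms), an
    orthonormal direction matrix, and the origin. Images whose direction
    is not orthonormal (sheared affines) are rejected. The unit defaults
    to HU; volumes written by :func:`write_volume` carry their unit in
    the header description field.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(f"expected a 3D image, got shape {img.shape}: {path}")
    affine = img.affine
    mat = affine[:3, :3]
    spacing = np.linalg.norm(mat, axis=0)
    if np.any(spacing <= 0):
        raise ValueError(f"degenerate affine in {path}")
    direction = mat / spacing
    if np.linalg.norm(direction.T @ direction - np.eye(3)) >= _ORTHO_TOL:
        raise ValueError(f"non-orthonormal direction matrix in {path}")
    values = np.asanyarray(img.dataobj)
    unit = "HU"
    descrip = str(np.asarray(img.header.get("descrip", b"")).astype(str))
    for u in VALID_UNITS:
        if f"unit={u}" in descrip:
            unit = u
    if unit == "label":
        values = np.asarray(np.rint(values), dtype=np.int16)
    return Volume3D(values, spacing, affine[:3, 3], direction, unit)


def write_volume(volume: Volume3D, path) -> None:
    """Write a :class:`Volume3D` as NIfTI, preserving geometry and unit."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    values = volume.values
    if volume.unit == "label":
        values = np.asarray(values, dtype=np.int16)
    img = nib.Nifti1Image(values, volume.grid.affine)
    img.header["descrip"] = f"unit={volume.unit}".encode()
    img.header.set_slope_inter(1.0, 0.0)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# resampling / cropping / augmentation
# ---------------------------------------------------------------------------

def resample_isotropic(volume: Volume3D, target_spacing: float = 1.0) -> Volume3D:
    """Resample to isotropic ``target_spacing`` mm with cubic spline interpolation.

    The output covers the input's physical extent with shape
    ``ceil(shape * spacing / target_spacing)`` per axis, shares the input's
    origin and direction, and preserves the HU scale (no intensity rescaling).
    Interpolation uses an order-3 spline with mirror boundary handling.
    """
    if target_spacing <= 0:
        raise ValueError(f"target spacing must be positive, got {target_spacing}")
    if volume.unit not in ("HU", "probability"):
        raise ValueError(f"cannot spline-resample a {volume.unit} volume")
    t = float(target_spacing)
    in_shape = np.array(volume.values.shape)
    out_shape = np.ceil(in_shape * volume.spacing / t).astype(int)
    # output voxel j and input voxel i share origin/direction, so i = (t / spacing) * j
    matrix = np.diag(t / volume.spacing)
    out = ndimage.affine_transform(
        np.asarray(volume.values, dtype=float),
        matrix,
        output_shape=tuple(out_shape),
        order=3,
        mode="mirror",
    )
    if volume.unit == "probability":
        out = np.clip(out, 0.0, 1.0)  # cubic splines can overshoot
    return Volume3D(out, np.full(3, t), volume.origin, volume.direction, volume.unit)


def crop_centered(
    volume: Volume3D,
    center_world,
    size: int = 128,
    fill: float = -1024.0,
) -> Volume3D:
    """Extract a ``size``^3 sub-volume centered (in voxels) on ``center_world``.

    The voxel at index ``size // 2`` along each axis is the grid voxel whose
    center lies nearest ``center_world``. Voxels outside the source volume are
    filled with ``fill`` (default -1024 HU, air). The origin is updated so that
    retained voxels keep their world coordinates exactly.
    """
    if not volume.is_isotropic:
        raise ValueError("crop_centered requires an isotropic volume; resample first")
    center_idx = np.rint(world_to_voxel(volume.grid, _as_vec3(center_world, "center_world")))
    start = center_idx.astype(int) - size // 2
    in_shape = np.array(volume.values.shape)

    out = np.full((size, size, size), fill, dtype=float)
    src_lo = np.maximum(start, 0)
    src_hi = np.minimum(start + size, in_shape)
    if np.any(src_lo >= src_hi):
        logger.warning("crop window lies entirely outside the volume; output is all fill")
    else:
        dst_lo = src_lo - start
        dst_hi = src_hi - start
        out[dst_lo[0]:dst_hi[0], dst_lo[1]:dst_hi[1], dst_lo[2]:dst_hi[2]] = (
            volume.values[src_lo[0]:src_hi[0], src_lo[1]:src_hi[1], src_lo[2]:src_hi[2]]
        )
        if np.any(src_lo > start) or np.any(start + size > in_shape):
            logger.warning("crop window extends outside the volume; padding with %s", fill)
    new_origin = voxel_to_world(volume.grid, start.astype(float))
    return Volume3D(out, volume.spacing, new_origin, volume.direction, volume.unit)


def _rotation_matrix(angles_deg: np.ndarray) -> np.ndarray:
    """Composed rotation R = Rz @ Ry @ Rx from per-axis angles in degrees."""
    ax, ay, az = np.deg2rad(angles_deg)
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def random_similarity_transform(
    volume: Volume3D,
    landmarks: LandmarkSet,
    seed: int,
    limit: float = 3.0,
) -> tuple[Volume3D, LandmarkSet]:
    """Apply a random small similarity transform to image and landmarks jointly.

    A scale factor ``s = 1 + u/100`` and three per-axis rotation angles (deg)
    are each drawn from Uniform(-limit, limit) using a seeded generator, the
    data-augmentation regime used when training the detection networks. The
    transform acts about the volume's physical center; rotations compose as
    R = Rz @ Ry @ Rx. Image resampling is cubic; landmark points are mapped
    analytically, so the pair stays geometrically consistent.
    """
    if limit < 0:
        raise ValueError("limit must be >= 0")
    rng = np.random.default_rng(seed)
    u = rng.uniform(-limit, limit, size=4)
    s = 1.0 + u[0] / 100.0
    rot = _rotation_matrix(u[1:])

    grid = volume.grid
    center = voxel_to_world(grid, (np.array(volume.values.shape, float) - 1) / 2)

    if s == 1.0 and np.array_equal(rot, np.eye(3)):
        new_lm = LandmarkSet(dict(landmarks.points))
    else:
        new_lm = landmarks.transformed(s * rot, center - s * rot @ center)

    # output voxel v -> world w -> T^{-1}(w) -> input voxel index
    spdiag_inv = np.diag(1.0 / volume.spacing)
    spdiag = np.diag(volume.spacing)
    m_world = (1.0 / s) * rot.T
    matrix = spdiag_inv @ grid.direction.T @ m_world @ grid.direction @ spdiag
    offset = spdiag_inv @ grid.direction.T @ (
        (center - grid.origin) + m_world @ (grid.origin - center)
    )
    out = ndimage.affine_transform(
        np.asarray(volume.values, dtype=float), matrix, offset=offset, order=3, mode="mirror"
    )
    if volume.unit == "probability":
        out = np.clip(out, 0.0, 1.0)
    new_vol = replace(volume, values=out)
    return new_vol, new_lm
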