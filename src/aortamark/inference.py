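"""Detector backends, sliding-window prediction, and probability-map fusion.

The detection strategy runs three models — one per sphere radius (3, 5,
7 mm) — over a normalised CT sub-volume and averages their per-class
probability outputs into a single fused map. The trained networks are
abstracted behind :class:`DetectorBackend`; :class:`SurrogateBackend`
emulates a converged model analytically (a Gaussian confidence bump of
width tied to the sphere radius, centered at a jittered landmark
position) so the full detection chain is testable without a trained CNN.
"""

from __future__ import annotations

import abc
from dataclasses import dataclass, replace

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

N_CLASSES = 6  # background + 5 landmark classes

#: Training hyperparameters of the published three-model ensemble, recorded
#: for a future trainable backend; the surrogate backend does not use them.
TRAINED_BACKEND_DEFAULTS = {
    "iterations": 860_000,
    "epochs": 2500,
    "optimizer": "adam",
    "learning_rate": 1e-4,
    "loss": "dice",
    "l2_decay": 1e-4,
    "init": "orthogonal",
    "init_gain": 2.0,
    "activation": "relu",
    "input_size": 64,
}

HU_WINDOW = (-1024.0, 2048.0)


@dataclass
class ProbabilityMaps:
    """Per-class probability grids (channel 0 = background, 1-5 = landmarks).

    ``maps`` has shape ``(6, *grid.shape)``; values lie in [0, 1] and sum
    to 1 across channels at every voxel (within 1e-6).
    """

    grid: GridSpec
    maps: np.ndarray

    def __post_init__(self):
        self.maps = np.asarray(self.maps)
        expected = (N_CLASSES,) + self.grid.shape
        if self.maps.shape != expected:
            raise ValueError(f"maps shape {self.maps.shape} != {expected}")

    def class_map(self, code: int) -> np.ndarray:
        return self.maps[code]

    def validate(self, tol: float = 1e-6) -> None:
        if self.maps.min() < -tol or self.maps.max() > 1 + tol:
            raise ValueError("probabilities outside [0, 1]")
        sums = self.maps.sum(axis=0)
        if np.abs(sums - 1.0).max() > tol:
            raise ValueError("per-voxel class probabilities do not sum to 1")


def normalize_volume(volume: Volume3D) -> Volume3D:
    """Clip HU to [-1024, 2048] and map linearly onto [0, 1].

    A fixed window keeps air, soft tissue, contrast-enhanced blood and
    calcium on a stable scale across patients (512 HU maps to 0.5).
    """
    if volume.unit != "HU":
        raise ValueError("normalize_volume expects an HU volume")
    lo, hi = HU_WINDOW
    vals = (np.clip(np.asarray(volume.values, dtype=float), lo, hi) - lo) / (hi - lo)
    return replace(volume, values=vals, unit="probability")


class DetectorBackend(abc.ABC):
    """Contract for a landmark detector emulating one sphere-radius model.

    ``predict`` maps a normalised sub-volume (values in [0, 1]) and its grid
    geometry to per-class probabilities of shape ``(6, *values.shape)`` that
    sum to 1 at every voxel.
    """

    radius_tag: float

    @abc.abstractmethod
    def predict(self, values: np.ndarray, grid: GridSpec) -> np.ndarray:
        ...


class SurrogateBackend(DetectorBackend):
    """Analytic stand-in for a trained sphere-radius model.

    Emits, for each landmark class, an unnormalised Gaussian score
    ``exp(-||x - c~||^2 / (2 sigma^2))`` with ``sigma = radius_tag / 2``,
    centered at the true landmark perturbed once by isotropic Gaussian
    jitter of ``jitter_sd`` mm (independent per class and per radius model).
    A constant background score completes the softmax-style normalisation.
    The jitter is drawn at construction from a generator seeded by
    (seed, radius_tag, class code), so predictions are deterministic and
    consistent across sliding windows.
    """

    def __init__(
        self,
        true_landmarks: LandmarkSet,
        radius_tag: float,
        jitter_sd: float = 0.5,
        background_score: float = 0.05,
        seed: int = 0,
    ):
        if jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        self.radius_tag = float(radius_tag)
        self.jitter_sd = float(jitter_sd)
        self.background_score = float(background_score)
        self.seed = int(seed)
        self.sigma = self.radius_tag / 2.0
        self.centers = {}
        for name in LANDMARK_NAMES:
            rng = np.random.default_rng([self.seed, int(round(radius_tag)), CLASS_CODES[name]])
            eps = rng.normal(0.0, jitter_sd, size=3) if jitter_sd > 0 else np.zeros(3)
            self.centers[name] = true_landmarks[name] + eps

    def predict(self, values: np.ndarray, grid: GridSpec) -> np.ndarray:
        shape = values.shape
        scores = np.empty((N_CLASSES,) + shape, dtype=np.float64)
        scores[0] = self.background_score
        inv = 1.0 / (2.0 * self.sigma**2)
        for name in LANDMARK_NAMES:
            # direction is orthonormal, so world distance separates over axes
            # in spacing-scaled voxel coordinates
            c_vox = world_to_voxel(grid, self.centers[name])
            ax = [
                (grid.spacing[a] * (np.arange(shape[a]) - c_vox[a])) ** 2 for a in range(3)
            ]
            arg = -(ax[0][:, None, None] + ax[1][None, :, None] + ax[2][None, None, :]) * inv
            # exp underflows to (slow) denormals far from the bump; anything
            # below e^-60 is indistinguishable from 0 next to the background
            s = np.zeros(shape)
            near = arg > -60.0
            s[near] = np.exp(arg[near])
            scores[CLASS_CODES[name]] = s
        scores /= scores.sum(axis=0)
        return scores


def surrogate_predict(
    grid: GridSpec,
    true_landmarks: LandmarkSet,
    radius_tag: float,
    jitter_sd: float = 0.5,
    background_score: float = 0.05,
    seed: int = 0,
) -> ProbabilityMaps:
    """Whole-grid prediction of one surrogate sphere-radius model."""
    backend = SurrogateBackend(true_landmarks, radius_tag, jitter_sd, background_score, seed)
    dummy = np.empty(grid.shape, dtype=np.float32)
    return ProbabilityMaps(grid, backend.predict(dummy, grid))


def _window_starts(extent: int, window: int, stride: int) -> list[int]:
    if extent <= window:
        return [0]
    starts = list(range(0, extent - window + 1, stride))
    if starts[-1] != extent - window:
        starts.append(extent - window)  # shift the last window to touch the border
    return starts


def sliding_window_predict(
    volume: Volume3D,
    backend: DetectorBackend,
    window: int = 64,
    stride: int = 32,
) -> ProbabilityMaps:
    """Tile the volume with ``window``^3 patches and average the predictions.

    Windows are placed every ``stride`` voxels per axis, with the final
    window shifted to touch the border; overlapping predictions are
    averaged uniformly per voxel per class and renormalised. A volume
    smaller than the window is zero-padded to a single window.
    """
    if not volume.is_isotropic:
        raise ValueError("sliding_window_predict expects an isotropic volume")
    vals = np.asarray(volume.values, dtype=float)
    if vals.min() < -1e-9 or vals.max() > 1 + 1e-9:
        raise ValueError("volume must be normalised to [0, 1] first")
    grid = volume.grid
    shape = np.array(vals.shape)

    pad = np.maximum(window - shape, 0)
    if np.any(pad > 0):
        vals = np.pad(vals, [(0, int(p)) for p in pad])

    acc = np.zeros((N_CLASSES,) + vals.shape)
    cnt = np.zeros(vals.shape)
    starts = [_window_starts(s, window, stride) for s in vals.shape]
    for i in starts[0]:
        for j in starts[1]:
            for k in starts[2]:
                sl = (slice(i, i + window), slice(j, j + window), slice(k, k + window))
                sub_origin = voxel_to_world(grid, np.array([i, j, k], float))
                sub_grid = GridSpec((window,) * 3, grid.spacing, sub_origin, grid.direction)
                pred = backend.predict(vals[sl], sub_grid)
                acc[(slice(None),) + sl] += pred
                cnt[sl] += 1.0
    acc /= cnt
    acc = acc[:, : shape[0], : shape[1], : shape[2]]
    acc /= acc.sum(axis=0)
    return ProbabilityMaps(grid, acc)


def fuse_probability_maps(maps3) -> ProbabilityMaps:
    """Average the three per-radius probability maps and renormalise.

    Per class, the arithmetic mean of the three maps; the per-voxel class
    sums are then renormalised to 1 (they already are when each input is
    normalised, but renormalisation makes the contract explicit).
    """
    maps3 = list(maps3)
    if len(maps3) != 3:
        raise ValueError(f"expected three probability maps, got {len(maps3)}")
    grid = maps3[0].grid
    for m in maps3[1:]:
        if not grid.same_geometry(m.grid):
            raise ValueError("probability maps do not share one grid")
    mean = (maps3[0].maps + maps3[1].maps + maps3[2].maps) / 3.0
    mean /= mean.sum(axis=0)
    return ProbabilityMaps(grid, mean)
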