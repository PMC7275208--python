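"""Synthetic contrast-enhanced aortic-root CT phantoms with known landmarks.

Each phantom renders a tubular aortic root (contrast-enhanced lumen
around 300-500 HU inside soft tissue around 40 HU) whose valve geometry
is drawn from clinically plausible ranges: three hinge points on a
circle of 10-14 mm radius in a tilted annular plane, jittered around the
nominal 120-degree spacing, and the two coronary ostia at exactly known
perpendicular heights (10-20 mm) above that plane. Calcific deposits
near the hinge points, additive Gaussian noise, and optional directional
(motion-like) blur emulate the artefact mix of clinical TAVI CT. The
returned landmark set is the exact pre-noise geometry, so every
downstream stage can be validated against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .anatomy_geometry import derive_measurements
from .volumetric_io import (
    GridSpec,
    LandmarkSet,
    Volume3D,
    voxel_to_world,
    write_landmarks,
    write_volume,
)

__all__ = ["PhantomSpec", "generate_phantom", "cohort_specs", "generate_cohort"]

#: nominal hinge-point angles (deg) in the annular plane: LCC, NCC, RCC
HINGE_ANGLES = {"LCC": 90.0, "NCC": 210.0, "RCC": 330.0}
#: nominal ostium angles: each ostium sits above its own coronary cusp
OSTIUM_ANGLES = {"LCO": 90.0, "RCO": 330.0}

#: artefact fractions of the emulated clinical cohort
MOTION_FRACTION = 0.4
NOISE_HEAVY_FRACTION = 0.4


@dataclass(frozen=True)
class PhantomSpec:
    """Seeded parameter record controlling synthetic CT generation.

    Scalar fields are fixed values; ``*_range`` / ``*_sd`` fields
    parameterise the seeded draws made by :func:`generate_phantom`.
    All lengths in mm, intensities in HU, angles in degrees.
    """

    shape: tuple[int, int, int] = (160, 160, 160)
    spacing: tuple[float, float, float] = (0.7, 0.7, 0.7)
    annulus_radius_range: tuple[float, float] = (10.0, 14.0)
    plane_tilt_max: float = 20.0
    hinge_angle_jitter: float = 10.0
    lco_height_range: tuple[float, float] = (10.0, 20.0)
    rco_height_range: tuple[float, float] = (10.0, 20.0)
    lumen_hu_mean: float = 350.0
    lumen_hu_sd: float = 30.0
    tissue_hu_mean: float = 40.0
    tissue_hu_sd: float = 10.0
    calcium_rate: float = 3.0
    calcium_hu_range: tuple[float, float] = (700.0, 1500.0)
    noise_sd: float = 20.0
    motion_blur_sd: float = 0.0
    seed: int = 0


def _draw_geometry(spec: PhantomSpec, rng: np.random.Generator) -> dict:
    """Draw every randomised phantom parameter, in a fixed order."""
    d = {}
    d["annulus_radius"] = rng.uniform(*spec.annulus_radius_range)
    d["plane_tilt"] = rng.uniform(0.0, spec.plane_tilt_max)
    d["plane_azimuth"] = rng.uniform(0.0, 360.0)
    d["hinge_jitter"] = {
        k: rng.uniform(-spec.hinge_angle_jitter, spec.hinge_angle_jitter) for k in HINGE_ANGLES
    }
    d["lco_height"] = rng.uniform(*spec.lco_height_range)
    d["rco_height"] = rng.uniform(*spec.rco_height_range)
    d["ostium_angle_jitter"] = {k: rng.uniform(-15.0, 15.0) for k in OSTIUM_ANGLES}
    d["ostium_radius_frac"] = {k: rng.uniform(0.5, 0.75) for k in OSTIUM_ANGLES}
    d["lumen_hu"] = rng.normal(spec.lumen_hu_mean, spec.lumen_hu_sd)
    d["tissue_hu"] = rng.normal(spec.tissue_hu_mean, spec.tissue_hu_sd)
    d["n_calcium"] = int(rng.poisson(spec.calcium_rate))
    d["calcium"] = [
        {
            "hinge": rng.integers(0, 3),
            "offset": rng.uniform(-2.0, 2.0, size=3),
            "radius": rng.uniform(1.0, 2.5),
            "hu": rng.uniform(*spec.calcium_hu_range),
        }
        for _ in range(d["n_calcium"])
    ]
    return d


def _plane_frame(tilt_deg: float, azimuth_deg: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal (e1, e2, n) with n the annular-plane normal tilted from +z."""
    t, a = np.deg2rad(tilt_deg), np.deg2rad(azimuth_deg)
    ry = np.array([[np.cos(t), 0, np.sin(t)], [0, 1, 0], [-np.sin(t), 0, np.cos(t)]])
    rz = np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])
    frame = rz @ ry
    return frame[:, 0], frame[:, 1], frame[:, 2]


def generate_phantom(spec: PhantomSpec, return_draws: bool = False):
    """Render one phantom volume and its exact landmark set.

    Deterministic per ``spec.seed``: the same spec yields bit-identical
    volumes and landmarks. The landmark set reflects the exact analytic
    geometry (pre-noise), so ``derive_measurements`` on it recovers the
    drawn ostium heights to machine precision.
    """
    rng = np.random.default_rng(spec.seed)
    draws = _draw_geometry(spec, rng)

    shape = np.array(spec.shape, dtype=int)
    spacing = np.array(spec.spacing, dtype=float)
    grid = GridSpec(tuple(shape), spacing)
    center = voxel_to_world(grid, (shape - 1) / 2.0)

    e1, e2, n = _plane_frame(draws["plane_tilt"], draws["plane_azimuth"])
    r_ann = draws["annulus_radius"]

    points = {}
    for name, nominal in HINGE_ANGLES.items():
        theta = np.deg2rad(nominal + draws["hinge_jitter"][name])
        points[name] = center + r_ann * (np.cos(theta) * e1 + np.sin(theta) * e2)
    for name, nominal in OSTIUM_ANGLES.items():
        theta = np.deg2rad(nominal + draws["ostium_angle_jitter"][name])
        radial = draws["ostium_radius_frac"][name] * r_ann
        height = draws["lco_height"] if name == "LCO" else draws["rco_height"]
        points[name] = (
            center + radial * (np.cos(theta) * e1 + np.sin(theta) * e2) + height * n
        )
    landmarks = LandmarkSet(points)

    upper = spacing * (shape - 1)
    for name, p in landmarks.points.items():
        if np.any(p < 0) or np.any(p > upper):
            raise ValueError(f"phantom landmark {name} falls outside the grid: {p}")

    # axial (u, along the plane normal) and radial offsets of every voxel
    # center relative to the annulus center; identity direction, origin 0
    off = [spacing[a] * np.arange(shape[a]) - center[a] for a in range(3)]
    u = (
        off[0][:, None, None] * n[0]
        + off[1][None, :, None] * n[1]
        + off[2][None, None, :] * n[2]
    )
    r2 = (
        off[0][:, None, None] ** 2
        + off[1][None, :, None] ** 2
        + off[2][None, None, :] ** 2
    )
    rho2 = np.maximum(r2 - u**2, 0.0)

    # tubular root: a wider sinus segment just above the annulus, narrower
    # tube elsewhere, spanning ventricle side to ascending aorta
    r_tube = np.where((u >= 0.0) & (u <= 15.0), r_ann + 4.0, r_ann + 2.0)
    lumen = (u >= -15.0) & (u <= 45.0) & (rho2 <= r_tube**2)

    values = np.full(tuple(shape), draws["tissue_hu"], dtype=float)
    values[lumen] = draws["lumen_hu"]

    hinge_names = list(HINGE_ANGLES)
    for blob in draws["calcium"]:
        c = landmarks[hinge_names[int(blob["hinge"])]] + blob["offset"]
        r = blob["radius"]
        lo = np.maximum(np.floor((c - r) / spacing).astype(int), 0)
        hi = np.minimum(np.ceil((c + r) / spacing).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        bx = [spacing[a] * np.arange(lo[a], hi[a]) - c[a] for a in range(3)]
        d2 = (
            bx[0][:, None, None] ** 2
            + bx[1][None, :, None] ** 2
            + bx[2][None, None, :] ** 2
        )
        box = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
        values[box][d2 <= r * r] = blob["hu"]

    if spec.motion_blur_sd > 0:
        axis = int(rng.integers(0, 3))
        values = ndimage.gaussian_filter1d(
            values, sigma=spec.motion_blur_sd / spacing[axis], axis=axis
        )
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=tuple(shape))

    volume = Volume3D(values, spacing, np.zeros(3), np.eye(3), unit="HU")
    if return_draws:
        return volume, landmarks, draws
    return volume, landmarks


def cohort_specs(base_spec: PhantomSpec, n: int, seed: int) -> list[dict]:
    """Resolve per-case specs and artefact flags for a reproducible cohort.

    Per-case seeds derive from the master seed; 40% of cases receive
    motion-like blur and 40% elevated noise (the artefact mix reported for
    clinical TAVI cohorts), assigned by seeded permutation so the counts
    are exact and the assignment deterministic.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    rng = np.random.default_rng(seed)
    item_seeds = rng.integers(0, 2**31 - 1, size=n)
    motion = np.zeros(n, dtype=bool)
    motion[rng.permutation(n)[: round(MOTION_FRACTION * n)]] = True
    noisy = np.zeros(n, dtype=bool)
    noisy[rng.permutation(n)[: round(NOISE_HEAVY_FRACTION * n)]] = True

    cases = []
    for i in range(n):
        spec = replace(
            base_spec,
            seed=int(item_seeds[i]),
            motion_blur_sd=1.5 if motion[i] else base_spec.motion_blur_sd,
            noise_sd=2.0 * base_spec.noise_sd if noisy[i] else base_spec.noise_sd,
        )
        cases.append(
            {"id": f"case{i:04d}", "spec": spec, "motion": bool(motion[i]), "noise_heavy": bool(noisy[i])}
        )
    return cases


def generate_cohort(base_spec: PhantomSpec, n: int, seed: int, out_dir=None):
    """Generate a seeded phantom cohort; optionally persist it to disk.

    With ``out_dir`` set, writes one NIfTI volume and landmark JSON per case
    plus a ``manifest.csv`` (id, seed, artefact flags, true ostium heights,
    paths) and returns the manifest DataFrame. With ``out_dir=None`` the
    same phantoms are returned in memory as ``(manifest, items)`` where
    ``items`` maps case id to ``(Volume3D, LandmarkSet)``.
    """
    cases = cohort_specs(base_spec, n, seed)
    if out_dir is not None:
        out_dir = Path(out_dir)
        if not out_dir.exists():
            raise FileNotFoundError(f"output directory does not exist: {out_dir}")

    rows = []
    items = {}
    for case in cases:
        volume, landmarks = generate_phantom(case["spec"])
        meas = derive_measurements(landmarks)
        row = {
            "id": case["id"],
            "seed": case["spec"].seed,
            "motion": case["motion"],
            "noise_heavy": case["noise_heavy"],
            "lco_height_mm": meas.lco_height,
            "rco_height_mm": meas.rco_height,
        }
        if out_dir is not None:
            vol_path = out_dir / f"{case['id']}.nii.gz"
            lm_path = out_dir / f"{case['id']}_landmarks.json"
            write_volume(volume, vol_path)
            write_landmarks(landmarks, lm_path)
            row["volume_path"] = str(vol_path)
            row["landmarks_path"] = str(lm_path)
        else:
            items[case["id"]] = (volume, landmarks)
        rows.append(row)

    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(out_dir / "manifest.csv", index=False)
        return manifest
    return manifest, items
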