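"""Aortic annular plane reconstruction and coronary ostium heights.

The aortic annular plane (AAP) is the plane through the three basal
attachment (hinge) points of the valve leaflets — LCC, NCC, RCC. The
clinically relevant coronary heights are the perpendicular distances
from this plane to the left and right coronary ostia; low heights flag
a risk of coronary obstruction during valve implantation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumetric_io import LandmarkSet

__all__ = ["Plane", "Measurements", "fit_annular_plane", "coronary_height", "derive_measurements"]

_MIN_AREA = 1e-6  # mm^2; below this the hinge triangle is degenerate


@dataclass
class Plane:
    """A plane as point + unit normal, oriented toward the ostia side."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        self.point = np.asarray(self.point, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if not np.isfinite(norm) or abs(norm - 1.0) > 1e-9:
            raise ValueError("plane normal must be a unit vector")
        self.normal = n


@dataclass
class Measurements:
    """Coronary ostium heights above the annular plane (mm)."""

    lco_height: float
    rco_height: float

    def rounded(self) -> tuple[float, float]:
        """Heights at the clinically reported 0.1 mm resolution."""
        return round(self.lco_height, 1), round(self.rco_height, 1)


def fit_annular_plane(lcc, ncc, rcc, ostia) -> Plane:
    """Fit the annular plane through the three hinge points.

    The normal is the normalised cross product of two triangle edges, with
    its sign chosen so that the midpoint of the two coronary ostia has
    non-negative signed distance — heights come out positive for normal
    anatomy. Collinear or coincident hinge points are rejected.
    """
    lcc, ncc, rcc = (np.asarray(p, dtype=float) for p in (lcc, ncc, rcc))
    cross = np.cross(ncc - lcc, rcc - lcc)
    area = 0.5 * np.linalg.norm(cross)
    if area <= _MIN_AREA:
        raise ValueError(f"hinge points are (nearly) collinear: triangle area {area:.2e} mm^2")
    normal = cross / np.linalg.norm(cross)
    centroid = (lcc + ncc + rcc) / 3.0
    ostia = np.asarray(ostia, dtype=float).reshape(-1, 3)
    midpoint = ostia.mean(axis=0)
    if np.dot(midpoint - centroid, normal) < 0:
        normal = -normal
    return Plane(centroid, normal)


def coronary_height(plane: Plane, ostium) -> float:
    """Signed perpendicular distance (mm) from the plane to an ostium."""
    return float(np.dot(np.asarray(ostium, dtype=float) - plane.point, plane.normal))


def derive_measurements(landmarks: LandmarkSet) -> Measurements:
    """Annular plane from the hinge points, then both coronary heights."""
    plane = fit_annular_plane(
        landmarks["LCC"], landmarks["NCC"], landmarks["RCC"],
        ostia=[landmarks["LCO"], landmarks["RCO"]],
    )
    return Measurements(
        lco_height=coronary_height(plane, landmarks["LCO"]),
        rco_height=coronary_height(plane, landmarks["RCO"]),
    )
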