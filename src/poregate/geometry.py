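"""Pore geometry: diameter profiles along the axis, region means, helix
axes and tilt/bend angles, and the statistics linking geometry to hydration.

The diameter algorithm is slice-based minimal radial clearance: at each grid
z the pore diameter is twice the smallest (center distance from the axis
minus van der Waals radius) over atoms in an axial slab, floored at zero.
The pore axis is the laboratory z axis through the gate backbone center of
mass; frames must be pre-aligned to that convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .hydration import RegionSpec
from .regression import LinearModel, fit_line

__all__ = [
    "BONDI_RADII_NM", "PoreProfile", "HelixGeometry", "LinearModel",
    "diameter_profile", "mean_region_diameter",
    "diameter_hydration_regression", "helix_axis", "tilt_angles",
    "bend_angle", "pearson",
]

#: Bondi-style van der Waals radii (nm) by element.
BONDI_RADII_NM = {"H": 0.120, "C": 0.170, "N": 0.155, "O": 0.152,
                  "S": 0.180, "P": 0.180}


@dataclass
class PoreProfile:
    """Pore diameter versus axial coordinate."""

    z: np.ndarray
    d_pore: np.ndarray
    filled_from_neighbor: list = field(default_factory=list)

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.d_pore = np.asarray(self.d_pore, dtype=float)
        if np.any(np.diff(self.z) <= 0):
            raise ValueError("z grid must be strictly increasing")
        if np.any(self.d_pore < 0):
            raise ValueError("diameters must be non-negative")


@dataclass
class HelixGeometry:
    """Per-helix orientation metrics (angles in degrees, distances in nm)."""

    axis: np.ndarray
    centroid: np.ndarray
    radial_tilt: float = float("nan")
    lateral_tilt: float = float("nan")
    center_distance: float = float("nan")
    bend_angle: float = float("nan")
    domain_distance: float = float("nan")


def diameter_profile(coords, radii, z_grid,
                     slab_half_width: float = 0.1) -> PoreProfile:
    """Slice-clearance pore diameter at each grid z.

    ``coords`` is an (N, 3) array (nm) aligned so the pore axis is z;
    ``radii`` the per-atom van der Waals radii.  Grid points whose axial
    slab contains no atoms inherit the diameter of the nearest non-empty
    slab and are listed in ``filled_from_neighbor``.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    radii = np.asarray(radii, dtype=float)
    z_grid = np.asarray(z_grid, dtype=float)
    if radii.shape[0] != coords.shape[0]:
        raise ValueError("radii must match atoms")
    clearance_r = np.hypot(coords[:, 0], coords[:, 1]) - radii
    d = np.full(z_grid.size, np.nan)
    for i, z in enumerate(z_grid):
        in_slab = np.abs(coords[:, 2] - z) <= slab_half_width
        if np.any(in_slab):
            d[i] = max(0.0, 2.0 * float(clearance_r[in_slab].min()))
    empty = np.flatnonzero(np.isnan(d))
    filled = np.flatnonzero(~np.isnan(d))
    if filled.size == 0:
        raise ValueError("no grid slab contains any atom")
    for i in empty:
        d[i] = d[filled[np.argmin(np.abs(z_grid[filled] - z_grid[i]))]]
    return PoreProfile(z=z_grid, d_pore=d,
                       filled_from_neighbor=list(empty))


def mean_region_diameter(profile: PoreProfile, region: RegionSpec) -> float:
    """Unweighted mean diameter over the grid points inside a region."""
    mask = (profile.z >= region.z_lo) & (profile.z <= region.z_hi)
    if not np.any(mask):
        raise ValueError(f"no grid points inside region {region.name!r}")
    return float(profile.d_pore[mask].mean())


def diameter_hydration_regression(n_wat, d_mean) -> LinearModel:
    """OLS fit of mean gate diameter on water count (slope in nm/water)."""
    return fit_line(n_wat, d_mean)


def helix_axis(ca_coords):
    """Principal axis of a run of C-alpha positions.

    Returns ``(axis, centroid)`` with the unit axis oriented toward positive
    z (cytosol -> periplasm).  Needs at least four positions; the result is
    invariant under point-order reversal.
    """
    x = np.asarray(ca_coords, dtype=float).reshape(-1, 3)
    if x.shape[0] < 4:
        raise ValueError("need at least four C-alpha positions")
    centroid = x.mean(axis=0)
    _, _, vt = np.linalg.svd(x - centroid)
    axis = vt[0]
    # orient: positive z, falling back to first nonzero component
    for comp in (axis[2], axis[0], axis[1]):
        if abs(comp) > 1e-12:
            if comp < 0:
                axis = -axis
            break
    return axis / np.linalg.norm(axis), centroid


def tilt_angles(axis, centroid, pore_axis=(0.0, 0.0, 1.0),
                pore_point=(0.0, 0.0, 0.0)):
    """Radial and lateral tilt of a helix axis relative to the pore axis.

    The helix axis is decomposed in the local frame of the helix centroid:
    the radial plane contains the pore axis and the centroid's outward
    radial direction; the tangential plane contains the pore axis and the
    tangential direction.  The radial tilt is the angle (degrees) between
    the pore axis and the projection of the helix axis onto the radial
    plane, signed positive for outward lean; the lateral tilt is the same
    construction in the tangential plane, signed by the right-handed
    tangential direction (counter-clockwise seen from +z).

    A centroid on the pore axis leaves the radial direction undefined and
    is rejected.
    """
    h = np.asarray(axis, dtype=float)
    h = h / np.linalg.norm(h)
    zhat = np.asarray(pore_axis, dtype=float)
    zhat = zhat / np.linalg.norm(zhat)
    if np.dot(h, zhat) < 0:
        # orient the helix axis along the pore direction so tilts are
        # frame-independent
        h = -h
    rel = np.asarray(centroid, dtype=float) - np.asarray(pore_point, dtype=float)
    radial = rel - np.dot(rel, zhat) * zhat
    rnorm = np.linalg.norm(radial)
    if rnorm < 1e-9:
        raise ValueError("centroid lies on the pore axis; "
                         "radial direction undefined")
    u_r = radial / rnorm
    u_t = np.cross(zhat, u_r)

    p_rad = h - np.dot(h, u_t) * u_t          # projection into radial plane
    theta_rad = np.degrees(np.arctan2(np.dot(p_rad, u_r), np.dot(p_rad, zhat)))
    p_lat = h - np.dot(h, u_r) * u_r          # projection into tangential plane
    theta_lat = np.degrees(np.arctan2(np.dot(p_lat, u_t), np.dot(p_lat, zhat)))
    return float(theta_rad), float(theta_lat)


def bend_angle(p_a, p_b, p_c) -> float:
    """Angle at ``p_b`` between the directions to ``p_a`` and ``p_c``,
    in degrees (collinear points give 180)."""
    a = np.asarray(p_a, dtype=float) - np.asarray(p_b, dtype=float)
    c = np.asarray(p_c, dtype=float) - np.asarray(p_b, dtype=float)
    na, nc = np.linalg.norm(a), np.linalg.norm(c)
    if na < 1e-12 or nc < 1e-12:
        raise ValueError("bend angle undefined for coincident points")
    cosang = np.clip(np.dot(a, c) / (na * nc), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def pearson(series_a, series_b) -> float:
    """Sample Pearson correlation of two equal-length series."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    if a.size < 3:
        raise ValueError("need at least three points")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero-variance series: correlation undefined")
    return float(stats.pearsonr(a, b).statistic)
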