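"""Idealised liver-lobule geometry and the porto-central zonal coordinate.

A lobule is modelled as a regular hexagon: the central vein at the centre,
portal triads at the six vertices.  Each in-lobule pixel gets a zonal
coordinate ``u = d_vertex / (d_vertex + d_center)`` where ``d_vertex`` is the
distance to the nearest vertex (portal triad) and ``d_center`` the distance
to the central vein.  ``u`` runs from 0 at a portal triad to 1 at the central
vein; thresholding it yields the periportal (Z1), midzone (Z2) and
pericentral (Z3) bands.  The default thresholds (1/3, 1/2) are the empirical
terciles of ``u`` over the hexagon, so the three zones cover comparable
areas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ZONES = ("Z1", "Z2", "Z3")

#: Integer codes used in zone masks; 0 denotes out-of-lobule background.
BACKGROUND = 0
ZONE_CODES = {"Z1": 1, "Z2": 2, "Z3": 3}
ZONE_NAMES = {v: k for k, v in ZONE_CODES.items()}


class InvalidGeometryError(ValueError):
    """Raised for degenerate lobule geometries."""


def _hexagon_vertices(center: tuple[float, float], radius: float,
                      ) -> np.ndarray:
    angles = np.deg2rad(np.arange(6) * 60.0)
    return np.stack([center[0] + radius * np.cos(angles),
                     center[1] + radius * np.sin(angles)], axis=1)


@dataclass
class LobuleGeometry:
    """Grid layout of one idealised lobule.

    Parameters
    ----------
    grid_shape
        (rows, cols) of the imaging raster.
    pixel_size
        Edge length of a pixel in micrometres (spatial metadata only).
    hexagon_center
        Grid coordinates (row, col) of the central vein.
    vertices
        Six (row, col) portal-triad coordinates.  If omitted, a regular
        hexagon inscribed in the grid (radius 0.48 × min dimension) is used.
    zone_thresholds
        Two increasing cut points on the zonal coordinate ``u`` in (0, 1)
        separating Z1|Z2 and Z2|Z3.
    """

    grid_shape: tuple[int, int] = (40, 40)
    pixel_size: float = 50.0
    hexagon_center: tuple[float, float] | None = None
    vertices: np.ndarray | None = None
    zone_thresholds: tuple[float, float] = (1.0 / 3.0, 0.5)

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if rows < 1 or cols < 1:
            raise InvalidGeometryError("grid must be nonempty")
        if self.hexagon_center is None:
            self.hexagon_center = ((rows - 1) / 2.0, (cols - 1) / 2.0)
        if self.vertices is None:
            radius = 0.48 * min(rows, cols)
            self.vertices = _hexagon_vertices(self.hexagon_center, radius)
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.shape != (6, 2):
            raise InvalidGeometryError("expected 6 portal-triad vertices")
        t1, t2 = self.zone_thresholds
        if not (0.0 < t1 < t2 < 1.0):
            raise InvalidGeometryError(
                "zone thresholds must be strictly increasing within (0, 1)")
        center = np.asarray(self.hexagon_center, dtype=float)
        if np.min(np.linalg.norm(self.vertices - center, axis=1)) < 1e-9:
            raise InvalidGeometryError(
                "central vein coincides with a portal triad vertex")
        if not _point_in_hexagon(center[None, :], self.vertices)[0]:
            raise InvalidGeometryError("center must lie inside the hexagon")


def _point_in_hexagon(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Vectorised convex-polygon membership test (boundary counts inside)."""
    # orientation sign of the polygon
    area2 = 0.0
    for i in range(6):
        a, b = vertices[i], vertices[(i + 1) % 6]
        area2 += a[0] * b[1] - b[0] * a[1]
    sign = 1.0 if area2 > 0 else -1.0
    inside = np.ones(len(points), dtype=bool)
    for i in range(6):
        a, b = vertices[i], vertices[(i + 1) % 6]
        cross = ((b[0] - a[0]) * (points[:, 1] - a[1])
                 - (b[1] - a[1]) * (points[:, 0] - a[0]))
        inside &= sign * cross >= -1e-12
    return inside


def zonal_coordinate(points: np.ndarray, geometry: LobuleGeometry,
                     ) -> np.ndarray:
    """Porto-central coordinate u in [0, 1] for an (n, 2) array of points."""
    points = np.asarray(points, dtype=float)
    center = np.asarray(geometry.hexagon_center, dtype=float)
    d_center = np.linalg.norm(points - center, axis=1)
    d_vertex = np.min(
        np.linalg.norm(points[:, None, :] - geometry.vertices[None, :, :],
                       axis=2), axis=1)
    denom = d_vertex + d_center
    # at the exact centre denom = d_vertex > 0 (non-degenerate geometry)
    return np.where(denom > 0, d_vertex / np.where(denom > 0, denom, 1.0), 0.0)


def lobule_zone_map(geometry: LobuleGeometry) -> np.ndarray:
    """Zone mask for every grid pixel.

    Returns an int array of ``grid_shape``: 0 background (outside the
    hexagon), 1/2/3 for Z1/Z2/Z3.  Zone labels are assigned by thresholding
    the zonal coordinate at ``geometry.zone_thresholds`` (Z1: u < t1,
    Z2: t1 <= u < t2, Z3: u >= t2).
    """
    rows, cols = geometry.grid_shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    pts = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    inside = _point_in_hexagon(pts, geometry.vertices)
    u = zonal_coordinate(pts, geometry)
    t1, t2 = geometry.zone_thresholds
    codes = np.where(u < t1, ZONE_CODES["Z1"],
                     np.where(u < t2, ZONE_CODES["Z2"], ZONE_CODES["Z3"]))
    mask = np.where(inside, codes, BACKGROUND)
    return mask.reshape(rows, cols).astype(np.int8)
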