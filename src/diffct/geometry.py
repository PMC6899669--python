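"""Scan geometries and trajectories.

World frame
-----------
Millimetres, right-handed, isocenter at the origin.  The circular orbit lies
in the ``z = 0`` plane around the ``z`` axis.  The view angle ``beta`` is the
rotation of the acquisition frame, counterclockwise, with the convention that
at ``beta = 0`` rays travel along ``+y`` and the detector axis points along
``+x``:

* central ray direction   ``d(beta) = (-sin b,  cos b)``
* detector axis           ``u(beta) = ( cos b,  sin b)``
* fan/cone source         ``s(beta) = -SID * d(beta)``

Volume arrays are C-ordered with the x axis fastest: 2D arrays are indexed
``[iy, ix]`` and 3D arrays ``[iz, iy, ix]``; ``shape``/``spacing``/``origin``
are stored in that same (array-axis) order.  The world coordinate of voxel
``(i0, .., ik)`` is ``origin + index * spacing`` axis by axis.

Detector pixels are centred: pixel ``i`` of an ``n``-pixel row sits at the
physical coordinate ``s = (i - (n-1)/2) * spacing + offset`` so continuous
pixel coordinates are 0-based with pixel (0, 0) a pixel centre.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "VolumeGeometry",
    "DetectorGeometry",
    "ScanGeometry",
    "ProjectionMatrix",
    "circular_trajectory_2d",
    "cone_projection_matrices",
    "short_scan_range",
    "fan_angles",
    "project_world_point",
    "parallel_beam",
    "fan_beam",
    "cone_beam",
]

BeamType = Literal["parallel2d", "fan2d", "cone3d"]


def _as_tuple(x, n: int, dtype=float) -> tuple:
    arr = np.broadcast_to(np.asarray(x, dtype=dtype), (n,))
    return tuple(arr.tolist())


@dataclass(frozen=True)
class VolumeGeometry:
    """Regular attenuation grid with world-coordinate metadata.

    ``origin`` is the world coordinate of the *centre* of voxel index
    (0, ..., 0); by default the grid centre coincides with the isocenter.
    """

    shape: tuple[int, ...]
    spacing: tuple[float, ...]
    origin: tuple[float, ...] | None = None

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        ndim = len(shape)
        spacing = _as_tuple(self.spacing, ndim)
        if ndim not in (2, 3):
            raise ValueError(f"volume must be 2D or 3D, got shape {shape}")
        if any(s < 1 for s in shape):
            raise ValueError(f"all shape entries must be >= 1, got {shape}")
        if any(sp <= 0 for sp in spacing):
            raise ValueError(f"all spacings must be > 0, got {spacing}")
        if self.origin is None:
            origin = tuple(-(n - 1) / 2.0 * sp for n, sp in zip(shape, spacing))
        else:
            origin = _as_tuple(self.origin, ndim)
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def extent(self) -> tuple[float, ...]:
        """Physical size of the grid (mm) along each array axis."""
        return tuple(n * sp for n, sp in zip(self.shape, self.spacing))

    def axis_coordinates(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centres along one array axis."""
        n = self.shape[axis]
        return self.origin[axis] + np.arange(n) * self.spacing[axis]

    def world_grids(self) -> tuple[np.ndarray, ...]:
        """Meshgrids of world coordinates in (x, y[, z]) order."""
        coords = [self.axis_coordinates(a) for a in range(self.ndim)]
        mesh = np.meshgrid(*coords, indexing="ij")
        # array axes are (y, x) or (z, y, x); return world order (x, y[, z])
        return tuple(mesh[::-1])


@dataclass(frozen=True)
class DetectorGeometry:
    """Flat detector sampling: pixel counts, spacing and centre offset (mm).

    1D (single row) for the 2D beams; 2D ``(n_v, n_u)`` for cone beam with
    ``v`` along ``z`` and ``u`` along the in-plane detector axis.
    """

    shape: tuple[int, ...]
    spacing: tuple[float, ...]
    offset: tuple[float, ...] = (0.0,)

    def __post_init__(self):
        shape = tuple(int(s) for s in np.atleast_1d(self.shape))
        ndim = len(shape)
        spacing = _as_tuple(self.spacing, ndim)
        offset = _as_tuple(self.offset, ndim)
        if ndim not in (1, 2):
            raise ValueError(f"detector must be 1D or 2D, got shape {shape}")
        if any(s < 1 for s in shape):
            raise ValueError(f"pixel counts must be >= 1, got {shape}")
        if any(sp <= 0 for sp in spacing):
            raise ValueError(f"pixel spacings must be > 0, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "offset", offset)

    @property
    def ndim(self) -> int:
        return len(self.shape)

    def coordinates(self, axis: int = -1) -> np.ndarray:
        """Physical coordinates (mm) of the pixel centres along one axis."""
        axis = axis % self.ndim
        n = self.shape[axis]
        return (np.arange(n) - (n - 1) / 2.0) * self.spacing[axis] + self.offset[axis]

    def width(self, axis: int = -1) -> float:
        """Full physical width n * spacing (mm) along one axis."""
        axis = axis % self.ndim
        return self.shape[axis] * self.spacing[axis]


@dataclass(frozen=True)
class ProjectionMatrix:
    """3x4 homogeneous map from world mm to cone-beam detector pixels.

    ``P @ (x, y, z, 1)`` yields ``(u*w, v*w, w)``; ``w > 0`` for points in
    front of the camera (between source and detector).
    """

    entries: np.ndarray

    def __post_init__(self):
        entries = np.asarray(self.entries, dtype=float)
        if entries.shape != (3, 4):
            raise ValueError(f"projection matrix must be 3x4, got {entries.shape}")
        if np.linalg.matrix_rank(entries[:, :3]) < 3:
            raise ValueError("left 3x3 block of a projection matrix must have full rank")
        object.__setattr__(self, "entries", entries)

    @property
    def camera_center(self) -> np.ndarray:
        """World position of the source (null space of the matrix)."""
        M = self.entries[:, :3]
        return -np.linalg.solve(M, self.entries[:, 3])

    def ray_direction(self, u: float, v: float) -> np.ndarray:
        """Unit world direction of the ray through pixel (u, v)."""
        M = self.entries[:, :3]
        d = np.linalg.solve(M, np.array([u, v, 1.0]))
        n = np.linalg.norm(d)
        # orient away from the camera: depth row must grow along the ray
        if np.dot(self.entries[2, :3], d) < 0:
            n = -n
        return d / n


@dataclass(frozen=True)
class ScanGeometry:
    """Everything defining the implicit system matrix A for one scan."""

    beam: BeamType
    volume: VolumeGeometry
    detector: DetectorGeometry
    angles: np.ndarray
    source_isocenter_distance: float | None = None
    source_detector_distance: float | None = None
    projection_matrices: tuple[ProjectionMatrix, ...] | None = None

    def __post_init__(self):
        if self.beam not in ("parallel2d", "fan2d", "cone3d"):
            raise ValueError(f"unknown beam type {self.beam!r}")
        angles = np.asarray(self.angles, dtype=float)
        if angles.ndim != 1 or angles.size < 1:
            raise ValueError("angles must be a non-empty 1D array")
        if angles.size > 1:
            d = np.diff(angles)
            if np.any(d <= 0):
                raise ValueError("angles must be strictly increasing")
            if np.max(np.abs(d - d[0])) > 1e-9:
                raise ValueError("angles must be uniformly spaced")
        object.__setattr__(self, "angles", angles)
        if self.beam in ("fan2d", "cone3d"):
            sid, sdd = self.source_isocenter_distance, self.source_detector_distance
            if sid is None or sdd is None:
                raise ValueError(f"{self.beam} requires source_isocenter_distance "
                                 "and source_detector_distance")
            if not (0 < sid < sdd):
                raise ValueError("need 0 < SID < SDD")
        expected_det = 2 if self.beam == "cone3d" else 1
        if self.detector.ndim != expected_det:
            raise ValueError(f"{self.beam} needs a {expected_det}D detector")
        expected_vol = 3 if self.beam == "cone3d" else 2
        if self.volume.ndim != expected_vol:
            raise ValueError(f"{self.beam} needs a {expected_vol}D volume")
        if self.projection_matrices is not None:
            mats = tuple(self.projection_matrices)
            if len(mats) != self.n_views:
                raise ValueError("need one projection matrix per view")
            object.__setattr__(self, "projection_matrices", mats)

    @property
    def n_views(self) -> int:
        return int(self.angles.size)

    @property
    def angle_increment(self) -> float:
        """Uniform view spacing (rad); half-open convention, so this equals
        angular_range / n_views."""
        if self.n_views > 1:
            return float(self.angles[1] - self.angles[0])
        return float(2 * np.pi)

    @property
    def angular_range(self) -> float:
        return self.angle_increment * self.n_views

    @property
    def stack_shape(self) -> tuple[int, ...]:
        return (self.n_views, *self.detector.shape)

    def with_matrices(self) -> "ScanGeometry":
        """Return self with circular-orbit projection matrices attached."""
        if self.beam != "cone3d" or self.projection_matrices is not None:
            return self
        return replace(self, projection_matrices=tuple(cone_projection_matrices(self)))


# ---------------------------------------------------------------------------
# trajectories

def circular_trajectory_2d(n_views: int, start_angle: float = 0.0,
                           angular_range: float = np.pi
                           ) -> tuple[np.ndarray, np.ndarray]:
    """View angles and unit central-ray vectors of a circular 2D trajectory.

    Angles are ``beta_i = start + i * range/n_views`` covering the half-open
    interval ``[start, start + range)``; the central ray direction for view
    ``beta`` is ``(-sin beta, cos beta)``.
    """
    if n_views < 1:
        raise ValueError(f"n_views must be >= 1, got {n_views}")
    if angular_range <= 0:
        raise ValueError(f"angular_range must be > 0, got {angular_range}")
    angles = start_angle + np.arange(n_views) * (angular_range / n_views)
    rays = np.stack([-np.sin(angles), np.cos(angles)], axis=1)
    return angles, rays


def _frame(beta: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(ray direction d, detector axis u, detector axis v) at view angle beta."""
    d = np.array([-np.sin(beta), np.cos(beta), 0.0])
    u = np.array([np.cos(beta), np.sin(beta), 0.0])
    v = np.array([0.0, 0.0, 1.0])
    return d, u, v


def cone_projection_matrices(geom: ScanGeometry) -> list[ProjectionMatrix]:
    """Circular-orbit 3x4 projection matrices for every view of a cone scan.

    Each matrix is K [R | t]: the source orbits at SID in the z = 0 plane, the
    detector sits at SDD from the source perpendicular to the central ray, and
    the intrinsics map mm to 0-based pixel units with the principal point at
    the location implied by the centred detector convention.  The third row is
    left unnormalised so that the homogeneous depth ``w`` is the metric
    distance of the point from the source along the central ray (``w = SID``
    at the isocenter), which the FDK distance weight relies on.
    """
    if geom.beam != "cone3d":
        raise ValueError("projection matrices are defined for cone3d geometry")
    sid = geom.source_isocenter_distance
    sdd = geom.source_detector_distance
    (n_v, n_u) = geom.detector.shape
    (sp_v, sp_u) = geom.detector.spacing
    (off_v, off_u) = geom.detector.offset
    cu = (n_u - 1) / 2.0 - off_u / sp_u
    cv = (n_v - 1) / 2.0 - off_v / sp_v
    mats = []
    for beta in geom.angles:
        d, u, v = _frame(beta)
        src = -sid * d
        p2 = np.append(d, -d @ src)            # depth row: w = d . (x - src)
        p0 = (sdd / sp_u) * np.append(u, -u @ src) + cu * p2
        p1 = (sdd / sp_v) * np.append(v, -v @ src) + cv * p2
        mats.append(ProjectionMatrix(np.stack([p0, p1, p2])))
    return mats


def project_world_point(P: ProjectionMatrix, point: Sequence[float]
                        ) -> tuple[float, float]:
    """Map a world point (mm) to continuous detector pixel coordinates (u, v)."""
    x = np.append(np.asarray(point, dtype=float), 1.0)
    uw, vw, w = P.entries @ x
    if w <= 0:
        raise ValueError(f"degenerate projection: point has non-positive depth w={w:g}")
    return float(uw / w), float(vw / w)


# ---------------------------------------------------------------------------
# fan-angle helpers

def fan_angles(geom: ScanGeometry) -> np.ndarray:
    """Per-pixel fan angle gamma = atan(s / SDD) along the in-plane detector axis."""
    if geom.beam == "parallel2d":
        raise ValueError("fan angles are undefined for a parallel beam")
    s = geom.detector.coordinates(-1)
    return np.arctan2(s, geom.source_detector_distance)


def half_fan_angle(geom: ScanGeometry) -> float:
    """gamma_max from the full detector half-width."""
    if geom.beam == "parallel2d":
        raise ValueError("fan angle is undefined for a parallel beam")
    half_width = geom.detector.width(-1) / 2.0
    return float(np.arctan(half_width / geom.source_detector_distance))


def short_scan_range(geom: ScanGeometry) -> float:
    """Minimal complete angular range pi + 2*gamma_max for a divergent beam."""
    if geom.beam == "parallel2d":
        raise ValueError("short scan is undefined for a parallel beam (pi suffices)")
    return float(np.pi + 2.0 * half_fan_angle(geom))


# ---------------------------------------------------------------------------
# constructors

def _angles(n_views, start_angle, angular_range):
    angles, _ = circular_trajectory_2d(n_views, start_angle, angular_range)
    return angles


def parallel_beam(volume: VolumeGeometry, detector: DetectorGeometry,
                  n_views: int, angular_range: float = np.pi,
                  start_angle: float = 0.0) -> ScanGeometry:
    return ScanGeometry("parallel2d", volume, detector,
                        _angles(n_views, start_angle, angular_range))


def fan_beam(volume: VolumeGeometry, detector: DetectorGeometry, n_views: int,
             sid: float, sdd: float, angular_range: float | None = None,
             start_angle: float = 0.0) -> ScanGeometry:
    """Fan-beam scan; angular_range defaults to the short-scan range."""
    geom = ScanGeometry("fan2d", volume, detector, np.array([0.0]),
                        source_isocenter_distance=sid,
                        source_detector_distance=sdd)
    if angular_range is None:
        angular_range = short_scan_range(geom)
    return replace(geom, angles=_angles(n_views, start_angle, angular_range))


def cone_beam(volume: VolumeGeometry, detector: DetectorGeometry, n_views: int,
              sid: float, sdd: float, angular_range: float | None = None,
              start_angle: float = 0.0,
              matrices: Sequence[ProjectionMatrix] | None = None) -> ScanGeometry:
    """Cone-beam scan; angular_range defaults to the short-scan range and the
    circular-orbit projection matrices are generated unless supplied."""
    geom = ScanGeometry("cone3d", volume, detector, np.array([0.0]),
                        source_isocenter_distance=sid,
                        source_detector_distance=sdd)
    if angular_range is None:
        angular_range = short_scan_range(geom)
    geom = replace(geom, angles=_angles(n_views, start_angle, angular_range),
                   projection_matrices=tuple(matrices) if matrices else None)
    return geom.with_matrices()
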