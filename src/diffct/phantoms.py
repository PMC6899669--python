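"""Analytic test objects: geometric primitives, Shepp-Logan, and the
closed-form ellipse sinogram used as a projector oracle.

Primitives are *additive*: overlapping objects sum their attenuation values,
which is exactly how the Shepp-Logan head phantom encodes nested contrast
(the skull ellipse carries the full background value and interior structures
add small positive or negative increments).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .geometry import ScanGeometry, VolumeGeometry

__all__ = [
    "EllipsePrimitive",
    "BoxPrimitive",
    "VolumeGrid",
    "rasterize",
    "shepp_logan",
    "shepp_logan_ellipses",
    "analytic_sinogram",
]


@dataclass(frozen=True)
class EllipsePrimitive:
    """Ellipse (2D) or ellipsoid (3D), rotated about the z axis.

    center and semi_axes are world mm in (x, y[, z]) order; value is the
    additive attenuation contributed inside the primitive.
    """

    center: tuple[float, ...]
    semi_axes: tuple[float, ...]
    rotation: float = 0.0
    value: float = 1.0

    def __post_init__(self):
        center = tuple(float(c) for c in self.center)
        axes = tuple(float(a) for a in self.semi_axes)
        if len(center) != len(axes) or len(center) not in (2, 3):
            raise ValueError("center and semi_axes must both be 2- or 3-vectors")
        if any(a <= 0 for a in axes):
            raise ValueError(f"semi_axes must be > 0, got {axes}")
        object.__setattr__(self, "center", center)
        object.__setattr__(self, "semi_axes", axes)

    def contains(self, *coords: np.ndarray) -> np.ndarray:
        """Boolean membership for world coordinates given in (x, y[, z]) order."""
        x = coords[0] - self.center[0]
        y = coords[1] - self.center[1]
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        xr = c * x + s * y
        yr = -s * x + c * y
        q = (xr / self.semi_axes[0]) ** 2 + (yr / self.semi_axes[1]) ** 2
        if len(self.center) == 3:
            q = q + ((coords[2] - self.center[2]) / self.semi_axes[2]) ** 2
        return q <= 1.0


@dataclass(frozen=True)
class BoxPrimitive:
    """Axis-aligned rectangle / cuboid with additive attenuation."""

    center: tuple[float, ...]
    half_widths: tuple[float, ...]
    value: float = 1.0

    def __post_init__(self):
        center = tuple(float(c) for c in self.center)
        hw = tuple(float(h) for h in self.half_widths)
        if len(center) != len(hw) or len(center) not in (2, 3):
            raise ValueError("center and half_widths must both be 2- or 3-vectors")
        if any(h <= 0 for h in hw):
            raise ValueError(f"half_widths must be > 0, got {hw}")
        object.__setattr__(self, "center", center)
        object.__setattr__(self, "half_widths", hw)

    def contains(self, *coords: np.ndarray) -> np.ndarray:
        inside = np.ones(np.broadcast(*coords).shape, dtype=bool)
        for c, ctr, hw in zip(coords, self.center, self.half_widths):
            inside &= np.abs(c - ctr) <= hw
        return inside


@dataclass
class VolumeGrid:
    """Attenuation values on a regular grid plus its world metadata."""

    values: np.ndarray
    geometry: VolumeGeometry

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.shape:
            raise ValueError(f"array shape {self.values.shape} does not match "
                             f"geometry shape {self.geometry.shape}")


def rasterize(primitives: Sequence, geom: VolumeGeometry,
              supersampling: int = 1) -> VolumeGrid:
    """Rasterize additive primitives onto a grid.

    With supersampling ``k`` each voxel is sampled on a centred k^ndim
    sub-grid and receives ``value * inside_fraction`` from each primitive;
    partial-volume voxels converge to the exact coverage fraction as k grows.
    """
    if supersampling < 1:
        raise ValueError(f"supersampling must be >= 1, got {supersampling}")
    values = np.zeros(geom.shape)
    if not primitives:
        return VolumeGrid(values, geom)
    k = int(supersampling)
    # sub-sample offsets within one voxel, in units of spacing
    sub = (np.arange(k) + 0.5) / k - 0.5
    axes = [geom.axis_coordinates(a) for a in range(geom.ndim)]
    offsets = np.meshgrid(*([sub] * geom.ndim), indexing="ij")
    offsets = np.stack([o.ravel() for o in offsets], axis=1)  # (k^ndim, ndim)
    for off in offsets:
        coords = [ax + o * sp for ax, o, sp in zip(axes, off, geom.spacing)]
        mesh = np.meshgrid(*coords, indexing="ij")
        world = mesh[::-1]  # (x, y[, z]) order
        for prim in primitives:
            values += prim.value * prim.contains(*world)
    values /= len(offsets)
    return VolumeGrid(values, geom)


# ---------------------------------------------------------------------------
# Shepp-Logan parameter tables
#
# Columns: value, a, b, x0, y0, phi_deg  (2D, unit half-extent coordinates).
# The classic low-contrast table; the "modified" variant replaces the additive
# intensities with the widely used high-contrast set.
_SL2D = np.array([
    #  value      a       b       x0      y0     phi
    [2.00,   0.6900, 0.9200,  0.000,  0.0000,   0.0],
    [-0.98,  0.6624, 0.8740,  0.000, -0.0184,   0.0],
    [-0.02,  0.1100, 0.3100,  0.220,  0.0000, -18.0],
    [-0.02,  0.1600, 0.4100, -0.220,  0.0000,  18.0],
    [0.01,   0.2100, 0.2500,  0.000,  0.3500,   0.0],
    [0.01,   0.0460, 0.0460,  0.000,  0.1000,   0.0],
    [0.01,   0.0460, 0.0460,  0.000, -0.1000,   0.0],
    [0.01,   0.0460, 0.0230, -0.080, -0.6050,   0.0],
    [0.01,   0.0230, 0.0230,  0.000, -0.6060,   0.0],
    [0.01,   0.0230, 0.0460,  0.060, -0.6050,   0.0],
])
_MODIFIED_VALUES = np.array([1.0, -0.8, -0.2, -0.2, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1])

# 3D extension: z semi-axis and z centre per ellipsoid.  These two columns are
# a convention (the classic CONRAD/Matlab-style ellipsoid extension), not
# derivable from the 2D table.
_SL3D_C = np.array([0.810, 0.780, 0.220, 0.280, 0.410,
                    0.050, 0.050, 0.050, 0.020, 0.020])
_SL3D_Z0 = np.array([0.000, 0.000, 0.000, 0.000, -0.150,
                     0.250, 0.250, 0.000, 0.000, 0.000])


def shepp_logan_ellipses(dims: int = 2, variant: str = "modified",
                         scale: float = 1.0) -> list[EllipsePrimitive]:
    """The ten Shepp-Logan ellipses, scaled by ``scale`` mm per unit length."""
    if dims not in (2, 3):
        raise ValueError(f"dims must be 2 or 3, got {dims}")
    if variant not in ("standard", "modified"):
        raise ValueError(f"variant must be 'standard' or 'modified', got {variant!r}")
    vals = _MODIFIED_VALUES if variant == "modified" else _SL2D[:, 0]
    prims = []
    for i, (_, a, b, x0, y0, phi) in enumerate(_SL2D):
        rot = np.deg2rad(phi)
        if dims == 2:
            prims.append(EllipsePrimitive((x0 * scale, y0 * scale),
                                          (a * scale, b * scale), rot, vals[i]))
        else:
            prims.append(EllipsePrimitive(
                (x0 * scale, y0 * scale, _SL3D_Z0[i] * scale),
                (a * scale, b * scale, _SL3D_C[i] * scale), rot, vals[i]))
    return prims


def shepp_logan(geom: VolumeGeometry, dims: int | None = None,
                variant: str = "modified", supersampling: int = 2) -> VolumeGrid:
    """Rasterized Shepp-Logan head phantom scaled to the grid's field of view.

    The unit-circle parameter table is scaled isotropically by the smallest
    half-extent of the grid so the skull ellipse always fits inside the
    volume regardless of voxel counts.
    """
    if dims is None:
        dims = geom.ndim
    if dims != geom.ndim:
        raise ValueError(f"dims={dims} does not match a {geom.ndim}D grid")
    scale = min(geom.extent) / 2.0
    return rasterize(shepp_logan_ellipses(dims, variant, scale), geom,
                     supersampling=supersampling)


# ---------------------------------------------------------------------------
# analytic Radon transform of ellipses (parallel beam only)

def analytic_sinogram(ellipses: Sequence[EllipsePrimitive],
                      geom: ScanGeometry):
    """Exact parallel-beam sinogram of a set of 2D ellipses.

    The line at view angle ``theta`` and detector coordinate ``s`` is
    ``{x : u(theta).x = s}``; its intersection with an ellipse of semi-axes
    (a, b), rotation phi, centred at c has chord length
    ``2ab sqrt(r^2 - t^2) / r^2`` with ``r^2 = a^2 cos^2(theta-phi) +
    b^2 sin^2(theta-phi)`` and ``t = s - u.c``.  Units are value*mm.
    """
    from .projectors import ProjectionStack  # local import; no cycle at runtime

    if geom.beam != "parallel2d":
        raise ValueError("the analytic sinogram oracle supports parallel2d only")
    s = geom.detector.coordinates()
    out = np.zeros((geom.n_views, s.size))
    for iv, theta in enumerate(geom.angles):
        ux, uy = np.cos(theta), np.sin(theta)
        for e in ellipses:
            if len(e.center) != 2:
                raise ValueError("analytic sinogram needs 2D ellipses")
            a, b = e.semi_axes
            r2 = (a * np.cos(theta - e.rotation)) ** 2 \
                + (b * np.sin(theta - e.rotation)) ** 2
            t = s - (ux * e.center[0] + uy * e.center[1])
            inside = r2 - t ** 2
            chord = np.where(inside > 0, 2.0 * a * b * np.sqrt(np.maximum(inside, 0)) / r2, 0.0)
            out[iv] += e.value * chord
    return ProjectionStack(out, geom)
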