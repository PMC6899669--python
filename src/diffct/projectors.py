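"""Ray-driven forward projection and voxel-driven back projection.

The system matrix A of ``A x = p`` is never materialised in normal use; both
operators are computed on the fly:

* **forward** (ray-driven): one ray per detector pixel, marched from volume
  entry to exit in fixed steps of ``step_fraction * min(voxel spacing)``,
  sampling the volume with bi/trilinear interpolation and weighting each
  sample by the step length, so projections are true line integrals in
  value*mm.  Samples outside the grid contribute zero.
* **back** (voxel-driven): one detector lookup per voxel per view
  (orthogonal projection for parallel beam, perspective division for
  fan/cone), linear interpolation of the projection row/image, accumulated
  and scaled by the angular increment.  With ``fbp_weighting`` enabled the
  fan/cone contribution is multiplied by the FDK distance weight 1/U^2,
  U = depth/SID.

The two are an *unmatched* pair: the voxel-driven operator is close to, but
not exactly, the transpose of the ray-driven one.  For gradient computation
each operator therefore also exposes its exact algebraic transpose
(:func:`forward_project_transpose`, :func:`back_project_transpose`),
implemented by running the same traversal in scatter mode, so the same
interpolation weights are accumulated on the other side of the operator.
:func:`explicit_system_matrix` materialises A for tiny problems and serves as
the definition-level oracle for all of the above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .geometry import ScanGeometry
from .phantoms import VolumeGrid

__all__ = [
    "ProjectionStack",
    "ProjectorConfig",
    "forward_project",
    "back_project",
    "forward_project_transpose",
    "back_project_transpose",
    "explicit_system_matrix",
]


@dataclass
class ProjectionStack:
    """Per-view detector samples (line integrals, value*mm) plus geometry."""

    values: np.ndarray
    geometry: ScanGeometry

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.stack_shape:
            raise ValueError(f"stack shape {self.values.shape} does not match "
                             f"geometry stack shape {self.geometry.stack_shape}")


@dataclass(frozen=True)
class ProjectorConfig:
    """step_fraction: ray-march step as a fraction of the smallest voxel
    spacing; fbp_weighting: apply the 1/U^2 distance weight in fan/cone back
    projection (FBP/FDK use), off for plain adjoint-like use."""

    step_fraction: float = 0.5
    fbp_weighting: bool = False

    def __post_init__(self):
        if not (0 < self.step_fraction <= 1):
            raise ValueError(f"step_fraction must be in (0, 1], got {self.step_fraction}")


# ---------------------------------------------------------------------------
# numba kernels.  Each kernel runs in gather mode (adjoint=0: read `vol`,
# write `sino` for forward kernels; read `sino`, write `vol` for backproj
# kernels) or scatter mode (adjoint=1: identical traversal and weights, data
# flowing the other way), which makes the scatter kernel the exact transpose
# of the gather kernel.


@njit(cache=True, inline="always")
def _gather2(vol, fy, fx):
    ny, nx = vol.shape
    iy = int(math.floor(fy))
    ix = int(math.floor(fx))
    wy = fy - iy
    wx = fx - ix
    v = 0.0
    for dy in range(2):
        yy = iy + dy
        if 0 <= yy < ny:
            ay = wy if dy == 1 else 1.0 - wy
            for dx in range(2):
                xx = ix + dx
                if 0 <= xx < nx:
                    ax = wx if dx == 1 else 1.0 - wx
                    v += vol[yy, xx] * ay * ax
    return v


@njit(cache=True, inline="always")
def _scatter2(vol, fy, fx, val):
    ny, nx = vol.shape
    iy = int(math.floor(fy))
    ix = int(math.floor(fx))
    wy = fy - iy
    wx = fx - ix
    for dy in range(2):
        yy = iy + dy
        if 0 <= yy < ny:
            ay = wy if dy == 1 else 1.0 - wy
            for dx in range(2):
                xx = ix + dx
                if 0 <= xx < nx:
                    ax = wx if dx == 1 else 1.0 - wx
                    vol[yy, xx] += val * ay * ax


@njit(cache=True, inline="always")
def _gather3(vol, fz, fy, fx):
    nz, ny, nx = vol.shape
    iz = int(math.floor(fz))
    iy = int(math.floor(fy))
    ix = int(math.floor(fx))
    wz = fz - iz
    wy = fy - iy
    wx = fx - ix
    v = 0.0
    for dz in range(2):
        zz = iz + dz
        if 0 <= zz < nz:
            az = wz if dz == 1 else 1.0 - wz
            for dy in range(2):
                yy = iy + dy
                if 0 <= yy < ny:
                    ay = wy if dy == 1 else 1.0 - wy
                    for dx in range(2):
                        xx = ix + dx
                        if 0 <= xx < nx:
                            ax = wx if dx == 1 else 1.0 - wx
                            v += vol[zz, yy, xx] * az * ay * ax
    return v


@njit(cache=True, inline="always")
def _scatter3(vol, fz, fy, fx, val):
    nz, ny, nx = vol.shape
    iz = int(math.floor(fz))
    iy = int(math.floor(fy))
    ix = int(math.floor(fx))
    wz = fz - iz
    wy = fy - iy
    wx = fx - ix
    for dz in range(2):
        zz = iz + dz
        if 0 <= zz < nz:
            az = wz if dz == 1 else 1.0 - wz
            for dy in range(2):
                yy = iy + dy
                if 0 <= yy < ny:
                    ay = wy if dy == 1 else 1.0 - wy
                    for dx in range(2):
                        xx = ix + dx
                        if 0 <= xx < nx:
                            ax = wx if dx == 1 else 1.0 - wx
                            vol[zz, yy, xx] += val * az * ay * ax


@njit(cache=True, inline="always")
def _slab(p, d, lo, hi, t0, t1):
    """Intersect the running parameter interval with one axis slab."""
    if abs(d) < 1e-12:
        if p < lo or p > hi:
            return 1.0, 0.0
        return t0, t1
    ta = (lo - p) / d
    tb = (hi - p) / d
    if ta > tb:
        ta, tb = tb, ta
    return max(t0, ta), min(t1, tb)


@njit(cache=True)
def _k_par(vol, sino, oy, ox, sy, sx, angles, det_sp, det_off, step, adjoint):
    ny, nx = vol.shape
    n_det = sino.shape[1]
    xlo, xhi = ox - sx, ox + nx * sx
    ylo, yhi = oy - sy, oy + ny * sy
    reach = math.hypot(xhi - xlo, yhi - ylo)
    c = (n_det - 1) / 2.0
    for iv in range(angles.shape[0]):
        b = angles[iv]
        dx, dy = -math.sin(b), math.cos(b)
        ux, uy = math.cos(b), math.sin(b)
        for ip in range(n_det):
            s = (ip - c) * det_sp + det_off
            px, py = s * ux, s * uy
            t0, t1 = -reach, reach
            t0, t1 = _slab(px, dx, xlo, xhi, t0, t1)
            t0, t1 = _slab(py, dy, ylo, yhi, t0, t1)
            if t1 <= t0:
                continue
            n_steps = int(math.ceil((t1 - t0) / step))
            h = (t1 - t0) / n_steps
            acc = 0.0
            for k in range(n_steps):
                t = t0 + (k + 0.5) * h
                fx = (px + t * dx - ox) / sx
                fy = (py + t * dy - oy) / sy
                if adjoint:
                    _scatter2(vol, fy, fx, sino[iv, ip] * h)
                else:
                    acc += _gather2(vol, fy, fx)
            if not adjoint:
                sino[iv, ip] = acc * h


@njit(cache=True)
def _k_fan(vol, sino, oy, ox, sy, sx, angles, det_sp, det_off,
           sid, sdd, step, adjoint):
    ny, nx = vol.shape
    n_det = sino.shape[1]
    xlo, xhi = ox - sx, ox + nx * sx
    ylo, yhi = oy - sy, oy + ny * sy
    reach = sid + sdd + math.hypot(xhi - xlo, yhi - ylo)
    c = (n_det - 1) / 2.0
    for iv in range(angles.shape[0]):
        b = angles[iv]
        dx, dy = -math.sin(b), math.cos(b)
        ux, uy = math.cos(b), math.sin(b)
        srcx, srcy = -sid * dx, -sid * dy
        for ip in range(n_det):
            s = (ip - c) * det_sp + det_off
            ex = srcx + sdd * dx + s * ux
            ey = srcy + sdd * dy + s * uy
            rx, ry = ex - srcx, ey - srcy
            rn = math.hypot(rx, ry)
            rx, ry = rx / rn, ry / rn
            t0, t1 = 0.0, reach
            t0, t1 = _slab(srcx, rx, xlo, xhi, t0, t1)
            t0, t1 = _slab(srcy, ry, ylo, yhi, t0, t1)
            if t1 <= t0:
                continue
            n_steps = int(math.ceil((t1 - t0) / step))
            h = (t1 - t0) / n_steps
            acc = 0.0
            for k in range(n_steps):
                t = t0 + (k + 0.5) * h
                fx = (srcx + t * rx - ox) / sx
                fy = (srcy + t * ry - oy) / sy
                if adjoint:
                    _scatter2(vol, fy, fx, sino[iv, ip] * h)
                else:
                    acc += _gather2(vol, fy, fx)
            if not adjoint:
                sino[iv, ip] = acc * h


@njit(cache=True)
def _k_cone(vol, sino, oz, oy, ox, sz, sy, sx, srcs, minvs, step, adjoint):
    nz, ny, nx = vol.shape
    n_views, n_v, n_u = sino.shape
    xlo, xhi = ox - sx, ox + nx * sx
    ylo, yhi = oy - sy, oy + ny * sy
    zlo, zhi = oz - sz, oz + nz * sz
    diag = math.sqrt((xhi - xlo) ** 2 + (yhi - ylo) ** 2 + (zhi - zlo) ** 2)
    for iv in range(n_views):
        scx, scy, scz = srcs[iv, 0], srcs[iv, 1], srcs[iv, 2]
        reach = math.sqrt(scx * scx + scy * scy + scz * scz) * 3.0 + diag
        for ivv in range(n_v):
            for iu in range(n_u):
                # world ray direction of pixel (u, v): Minv @ (u, v, 1)
                rx = minvs[iv, 0, 0] * iu + minvs[iv, 0, 1] * ivv + minvs[iv, 0, 2]
                ry = minvs[iv, 1, 0] * iu + minvs[iv, 1, 1] * ivv + minvs[iv, 1, 2]
                rz = minvs[iv, 2, 0] * iu + minvs[iv, 2, 1] * ivv + minvs[iv, 2, 2]
                rn = math.sqrt(rx * rx + ry * ry + rz * rz)
                rx, ry, rz = rx / rn, ry / rn, rz / rn
                t0, t1 = 0.0, reach
                t0, t1 = _slab(scx, rx, xlo, xhi, t0, t1)
                t0, t1 = _slab(scy, ry, ylo, yhi, t0, t1)
                t0, t1 = _slab(scz, rz, zlo, zhi, t0, t1)
                if t1 <= t0:
                    continue
                n_steps = int(math.ceil((t1 - t0) / step))
                h = (t1 - t0) / n_steps
                acc = 0.0
                for k in range(n_steps):
                    t = t0 + (k + 0.5) * h
                    fx = (scx + t * rx - ox) / sx
                    fy = (scy + t * ry - oy) / sy
                    fz = (scz + t * rz - oz) / sz
                    if adjoint:
                        _scatter3(vol, fz, fy, fx, sino[iv, ivv, iu] * h)
                    else:
                        acc += _gather3(vol, fz, fy, fx)
                if not adjoint:
                    sino[iv, ivv, iu] = acc * h


@njit(cache=True, inline="always")
def _row_gather(row, fp):
    n = row.shape[0]
    i0 = int(math.floor(fp))
    w = fp - i0
    v = 0.0
    if 0 <= i0 < n:
        v += row[i0] * (1.0 - w)
    if 0 <= i0 + 1 < n:
        v += row[i0 + 1] * w
    return v


@njit(cache=True, inline="always")
def _row_scatter(row, fp, val):
    n = row.shape[0]
    i0 = int(math.floor(fp))
    w = fp - i0
    if 0 <= i0 < n:
        row[i0] += val * (1.0 - w)
    if 0 <= i0 + 1 < n:
        row[i0 + 1] += val * w


@njit(cache=True)
def _k_bp_par(vol, sino, oy, ox, sy, sx, angles, det_sp, det_off, dbeta, adjoint):
    ny, nx = vol.shape
    n_det = sino.shape[1]
    c = (n_det - 1) / 2.0
    for iv in range(angles.shape[0]):
        b = angles[iv]
        ux, uy = math.cos(b), math.sin(b)
        for iy in range(ny):
            y = oy + iy * sy
            for ix in range(nx):
                x = ox + ix * sx
                fp = (ux * x + uy * y - det_off) / det_sp + c
                if adjoint:
                    _row_scatter(sino[iv], fp, vol[iy, ix] * dbeta)
                else:
                    vol[iy, ix] += _row_gather(sino[iv], fp) * dbeta


@njit(cache=True)
def _k_bp_fan(vol, sino, oy, ox, sy, sx, angles, det_sp, det_off,
              sid, sdd, dbeta, weighted, adjoint):
    ny, nx = vol.shape
    n_det = sino.shape[1]
    c = (n_det - 1) / 2.0
    for iv in range(angles.shape[0]):
        b = angles[iv]
        dx, dy = -math.sin(b), math.cos(b)
        ux, uy = math.cos(b), math.sin(b)
        srcx, srcy = -sid * dx, -sid * dy
        for iy in range(ny):
            y = oy + iy * sy
            for ix in range(nx):
                x = ox + ix * sx
                relx, rely = x - srcx, y - srcy
                depth = dx * relx + dy * rely
                if depth <= 1e-9:
                    continue
                s_det = sdd * (ux * relx + uy * rely) / depth
                fp = (s_det - det_off) / det_sp + c
                w = dbeta
                if weighted:
                    w *= (sid / depth) * (sid / depth)
                if adjoint:
                    _row_scatter(sino[iv], fp, vol[iy, ix] * w)
                else:
                    vol[iy, ix] += _row_gather(sino[iv], fp) * w


@njit(cache=True)
def _k_bp_cone(vol, sino, oz, oy, ox, sz, sy, sx, mats, sid, dbeta,
               weighted, adjoint):
    nz, ny, nx = vol.shape
    n_views = sino.shape[0]
    for iv in range(n_views):
        m = mats[iv]
        for iz in range(nz):
            z = oz + iz * sz
            for iy in range(ny):
                y = oy + iy * sy
                for ix in range(nx):
                    x = ox + ix * sx
                    w_h = m[2, 0] * x + m[2, 1] * y + m[2, 2] * z + m[2, 3]
                    if w_h <= 1e-9:
                        continue
                    fu = (m[0, 0] * x + m[0, 1] * y + m[0, 2] * z + m[0, 3]) / w_h
                    fv = (m[1, 0] * x + m[1, 1] * y + m[1, 2] * z + m[1, 3]) / w_h
                    w = dbeta
                    if weighted:
                        w *= (sid / w_h) * (sid / w_h)
                    if adjoint:
                        _scatter2(sino[iv], fv, fu, vol[iz, iy, ix] * w)
                    else:
                        vol[iz, iy, ix] += _gather2(sino[iv], fv, fu) * w


# ---------------------------------------------------------------------------
# dispatchers


def _check_volume(vol: VolumeGrid, geom: ScanGeometry):
    if vol.geometry != geom.volume:
        raise ValueError("volume geometry does not match the scan geometry")


def _cone_arrays(geom: ScanGeometry):
    if geom.projection_matrices is None:
        raise ValueError("cone3d projection requires projection matrices "
                         "(use geometry.with_matrices())")
    mats = np.stack([m.entries for m in geom.projection_matrices])
    srcs = np.stack([m.camera_center for m in geom.projection_matrices])
    minvs = np.stack([np.linalg.inv(m.entries[:, :3])
                      for m in geom.projection_matrices])
    return mats, srcs, minvs


def _run_forward(vol_values: np.ndarray, geom: ScanGeometry,
                 cfg: ProjectorConfig, adjoint: bool) -> np.ndarray:
    step = cfg.step_fraction * min(geom.volume.spacing)
    g = geom
    if g.beam == "parallel2d":
        oy, ox = g.volume.origin
        sy, sx = g.volume.spacing
        if adjoint:
            vol = np.zeros(g.volume.shape)
            _k_par(vol, vol_values, oy, ox, sy, sx, g.angles,
                   g.detector.spacing[0], g.detector.offset[0], step, True)
            return vol
        sino = np.zeros(g.stack_shape)
        _k_par(vol_values, sino, oy, ox, sy, sx, g.angles,
               g.detector.spacing[0], g.detector.offset[0], step, False)
        return sino
    if g.beam == "fan2d":
        oy, ox = g.volume.origin
        sy, sx = g.volume.spacing
        args = (oy, ox, sy, sx, g.angles, g.detector.spacing[0],
                g.detector.offset[0], g.source_isocenter_distance,
                g.source_detector_distance, step)
        if adjoint:
            vol = np.zeros(g.volume.shape)
            _k_fan(vol, vol_values, *args, True)
            return vol
        sino = np.zeros(g.stack_shape)
        _k_fan(vol_values, sino, *args, False)
        return sino
    # cone3d
    _, srcs, minvs = _cone_arrays(g)
    oz, oy, ox = g.volume.origin
    sz, sy, sx = g.volume.spacing
    if adjoint:
        vol = np.zeros(g.volume.shape)
        _k_cone(vol, vol_values, oz, oy, ox, sz, sy, sx, srcs, minvs, step, True)
        return vol
    sino = np.zeros(g.stack_shape)
    _k_cone(vol_values, sino, oz, oy, ox, sz, sy, sx, srcs, minvs, step, False)
    return sino


def forward_project(vol: VolumeGrid, geom: ScanGeometry,
                    cfg: ProjectorConfig | None = None) -> ProjectionStack:
    """Ray-driven projection of a volume: the on-the-fly A x."""
    cfg = cfg or ProjectorConfig()
    _check_volume(vol, geom)
    return ProjectionStack(_run_forward(vol.values, geom, cfg, adjoint=False), geom)


def forward_project_transpose(stack: ProjectionStack, geom: ScanGeometry,
                              cfg: ProjectorConfig | None = None) -> VolumeGrid:
    """Exact transpose A^T y of the ray-driven forward projector
    (ray-driven splatting along the identical sample trajectory)."""
    cfg = cfg or ProjectorConfig()
    if stack.geometry != geom:
        raise ValueError("stack geometry does not match the scan geometry")
    return VolumeGrid(_run_forward(stack.values.copy(), geom, cfg, adjoint=True),
                      geom.volume)


def _run_back(stack_values: np.ndarray, geom: ScanGeometry,
              cfg: ProjectorConfig, adjoint: bool) -> np.ndarray:
    g = geom
    dbeta = g.angle_increment
    if g.beam == "parallel2d":
        oy, ox = g.volume.origin
        sy, sx = g.volume.spacing
        args = (oy, ox, sy, sx, g.angles, g.detector.spacing[0],
                g.detector.offset[0], dbeta)
        if adjoint:
            sino = np.zeros(g.stack_shape)
            _k_bp_par(stack_values, sino, *args, True)
            return sino
        vol = np.zeros(g.volume.shape)
        _k_bp_par(vol, stack_values, *args, False)
        return vol
    if g.beam == "fan2d":
        oy, ox = g.volume.origin
        sy, sx = g.volume.spacing
        args = (oy, ox, sy, sx, g.angles, g.detector.spacing[0],
                g.detector.offset[0], g.source_isocenter_distance,
                g.source_detector_distance, dbeta, cfg.fbp_weighting)
        if adjoint:
            sino = np.zeros(g.stack_shape)
            _k_bp_fan(stack_values, sino, *args, True)
            return sino
        vol = np.zeros(g.volume.shape)
        _k_bp_fan(vol, stack_values, *args, False)
        return vol
    mats, _, _ = _cone_arrays(g)
    oz, oy, ox = g.volume.origin
    sz, sy, sx = g.volume.spacing
    args = (oz, oy, ox, sz, sy, sx, mats, float(g.source_isocenter_distance),
            dbeta, cfg.fbp_weighting)
    if adjoint:
        sino = np.zeros(g.stack_shape)
        _k_bp_cone(stack_values, sino, *args, True)
        return sino
    vol = np.zeros(g.volume.shape)
    _k_bp_cone(vol, stack_values, *args, False)
    return vol


def back_project(stack: ProjectionStack, geom: ScanGeometry,
                 cfg: ProjectorConfig | None = None) -> VolumeGrid:
    """Voxel-driven back projection, scaled by the angular increment.

    Detector coordinates falling outside the measured rows contribute zero.
    The raw adjoint-like sum is the result divided by ``geom.angle_increment``.
    """
    cfg = cfg or ProjectorConfig()
    if stack.geometry != geom:
        raise ValueError("stack geometry does not match the scan geometry")
    return VolumeGrid(_run_back(stack.values, geom, cfg, adjoint=False),
                      geom.volume)


def back_project_transpose(vol: VolumeGrid, geom: ScanGeometry,
                           cfg: ProjectorConfig | None = None) -> ProjectionStack:
    """Exact transpose B^T x of the voxel-driven back projector (voxel-driven
    scatter into detector bins with the identical interpolation weights)."""
    cfg = cfg or ProjectorConfig()
    _check_volume(vol, geom)
    return ProjectionStack(_run_back(vol.values.copy(), geom, cfg, adjoint=True),
                           geom)


def explicit_system_matrix(geom: ScanGeometry,
                           cfg: ProjectorConfig | None = None,
                           max_entries: int = 2 ** 22) -> np.ndarray:
    """Materialise A as a dense (n_rays x n_voxels) matrix for tiny problems.

    Column j is the forward projection of the j-th unit basis volume; the
    result is the exact matrix of the on-the-fly operator and serves as the
    adjoint/linearity oracle.
    """
    cfg = cfg or ProjectorConfig()
    n_rays = int(np.prod(geom.stack_shape))
    n_vox = geom.volume.n_voxels
    if n_rays * n_vox > max_entries:
        raise ValueError(f"refusing to materialise {n_rays}x{n_vox} system matrix "
                         f"(> {max_entries} entries)")
    A = np.zeros((n_rays, n_vox))
    basis = np.zeros(geom.volume.shape)
    flat = basis.reshape(-1)
    for j in range(n_vox):
        flat[j] = 1.0
        A[:, j] = _run_forward(basis, geom, cfg, adjoint=False).ravel()
        flat[j] = 0.0
    return A
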