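"""File formats: MetaImage MHD/RAW volumes and projection stacks, multi-page
TIFF export, plain-text projection matrices, and YAML geometry configs.

On disk data is float32 by default; everything is promoted to float64 in
memory (the gradient checks need double precision).  MHD axis metadata is
stored in (x, y[, z]) order per the MetaImage convention while in-memory
arrays are C-ordered with x fastest, so spacing/origin tuples are reversed
at the boundary.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import tifffile
import yaml

from .geometry import (DetectorGeometry, ProjectionMatrix, ScanGeometry,
                       VolumeGeometry, cone_beam, fan_beam, parallel_beam)
from .phantoms import VolumeGrid
from .projectors import ProjectionStack

__all__ = [
    "read_volume", "write_volume",
    "read_projection_stack", "write_projection_stack",
    "write_projection_tiff",
    "read_projection_matrices", "write_projection_matrices",
    "load_geometry_config", "save_geometry_config",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


def write_volume(path: str | Path, vol: VolumeGrid,
                 dtype: str = "float32") -> None:
    """Write a volume as MHD header + RAW data (little endian)."""
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.values, dtype=dtype))
    img.SetSpacing(tuple(vol.geometry.spacing[::-1]))
    img.SetOrigin(tuple(vol.geometry.origin[::-1]))
    sitk.WriteImage(img, str(path))


def read_volume(path: str | Path) -> VolumeGrid:
    """Read an MHD/RAW volume; values are promoted to float64."""
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise FormatError(f"cannot read MHD volume {path}: {exc}") from exc
    values = sitk.GetArrayFromImage(img).astype(float)
    spacing = tuple(img.GetSpacing()[::-1])
    origin = tuple(img.GetOrigin()[::-1])
    geom = VolumeGeometry(values.shape, spacing, origin)
    return VolumeGrid(values, geom)


def write_projection_stack(path: str | Path, stack: ProjectionStack,
                           dtype: str = "float32") -> None:
    """Write a projection stack as MHD with views as slices."""
    img = sitk.GetImageFromArray(np.ascontiguousarray(stack.values, dtype=dtype))
    sitk.WriteImage(img, str(path))


def read_projection_stack(path: str | Path, geom: ScanGeometry
                          ) -> ProjectionStack:
    """Read a projection stack and attach its scan geometry."""
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise FormatError(f"cannot read MHD stack {path}: {exc}") from exc
    values = sitk.GetArrayFromImage(img).astype(float)
    if values.shape != geom.stack_shape:
        raise FormatError(f"stack {path} has shape {values.shape}, geometry "
                          f"expects {geom.stack_shape}")
    return ProjectionStack(values, geom)


def write_projection_tiff(path: str | Path, stack: ProjectionStack) -> None:
    """Convenience multi-page TIFF export (one page per view)."""
    pages = stack.values.astype(np.float32)
    if pages.ndim == 2:
        pages = pages[:, None, :]
    tifffile.imwrite(str(path), pages)


# ---------------------------------------------------------------------------
# projection matrices: 3 rows of 4 whitespace-separated floats per view,
# views separated by blank lines

def write_projection_matrices(path: str | Path,
                              matrices) -> None:
    lines = []
    for m in matrices:
        entries = m.entries if isinstance(m, ProjectionMatrix) else np.asarray(m)
        for row in entries:
            lines.append(" ".join(f"{v:.17g}" for v in row))
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_projection_matrices(path: str | Path) -> list[ProjectionMatrix]:
    mats: list[ProjectionMatrix] = []
    rows: list[list[float]] = []
    start_line = 0
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            if rows:
                if len(rows) != 3:
                    raise FormatError(f"{path}:{start_line}: matrix block has "
                                      f"{len(rows)} rows, expected 3")
                mats.append(ProjectionMatrix(np.array(rows)))
                rows = []
            continue
        parts = stripped.split()
        if len(parts) != 4:
            raise FormatError(f"{path}:{lineno}: expected 4 floats per row, "
                              f"got {len(parts)}")
        try:
            row = [float(v) for v in parts]
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric entry") from exc
        if not rows:
            start_line = lineno
        rows.append(row)
    if rows:
        if len(rows) != 3:
            raise FormatError(f"{path}:{start_line}: matrix block has "
                              f"{len(rows)} rows, expected 3")
        mats.append(ProjectionMatrix(np.array(rows)))
    return mats


# ---------------------------------------------------------------------------
# geometry configs

def save_geometry_config(path: str | Path, geom: ScanGeometry) -> None:
    cfg = {
        "beam": geom.beam,
        "volume_shape": list(geom.volume.shape),
        "volume_spacing": list(geom.volume.spacing),
        "detector_shape": list(geom.detector.shape),
        "detector_spacing": list(geom.detector.spacing),
        "n_views": geom.n_views,
        "angular_range_deg": math.degrees(geom.angular_range),
        "start_angle_deg": math.degrees(float(geom.angles[0])),
    }
    if geom.beam != "parallel2d":
        cfg["sid_mm"] = geom.source_isocenter_distance
        cfg["sdd_mm"] = geom.source_detector_distance
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def load_geometry_config(path: str | Path) -> ScanGeometry:
    """Build a ScanGeometry from a YAML config (angles given in degrees)."""
    try:
        cfg = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise FormatError(f"cannot parse geometry config {path}: {exc}") from exc
    if not isinstance(cfg, dict):
        raise FormatError(f"geometry config {path} must be a mapping")
    try:
        beam = cfg["beam"]
        volume = VolumeGeometry(tuple(cfg["volume_shape"]),
                                tuple(np.atleast_1d(cfg["volume_spacing"])))
        detector = DetectorGeometry(tuple(np.atleast_1d(cfg["detector_shape"])),
                                    tuple(np.atleast_1d(cfg["detector_spacing"])))
        n_views = int(cfg["n_views"])
    except KeyError as exc:
        raise FormatError(f"geometry config {path}: missing key {exc}") from exc
    start = math.radians(float(cfg.get("start_angle_deg", 0.0)))
    rng = cfg.get("angular_range_deg")
    rng = math.radians(float(rng)) if rng is not None else None
    if beam == "parallel2d":
        return parallel_beam(volume, detector, n_views,
                             rng if rng is not None else math.pi, start)
    try:
        sid, sdd = float(cfg["sid_mm"]), float(cfg["sdd_mm"])
    except KeyError as exc:
        raise FormatError(f"geometry config {path}: missing key {exc}") from exc
    if beam == "fan2d":
        return fan_beam(volume, detector, n_views, sid, sdd, rng, start)
    if beam == "cone3d":
        return cone_beam(volume, detector, n_views, sid, sdd, rng, start)
    raise FormatError(f"geometry config {path}: unknown beam {beam!r}")
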