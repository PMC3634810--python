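"""Image-stack I/O and the physical-unit <-> voxel coordinate contract.

Every array in this package is indexed ``data[x, y, z]`` with ``z`` the
optical slice index, 0-based. The physical coordinate of the *center* of
voxel ``(i, j, k)`` is ``origin_um + (i, j, k) * spacing``. All user-facing
parameters are micrometres; conversion to per-axis voxel counts happens at
module boundaries, because sensible parameter values depend only on the
physical resolution of the images, not on their pixel counts.

On disk, stacks are multi-page TIFFs (or directories of 2D slices) whose
pages are constant-z planes with pixel rows mapping to y and columns to x;
:func:`load_stack` / :func:`save_stack` transpose between the two layouts
bit-exactly for 8- and 16-bit data.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageStack",
    "PhysicalParams",
    "load_stack",
    "save_stack",
    "um_to_vox",
    "vox_to_um",
    "write_results",
]

_SUPPORTED_DTYPES = (np.uint8, np.uint16)


@dataclass
class ImageStack:
    """A 3D scalar intensity volume with per-axis physical voxel spacing.

    Parameters
    ----------
    data
        3D array indexed ``(x, y, z)``; intensities must be finite and
        non-negative.
    spacing
        Per-axis voxel size ``(sx, sy, sz)`` in micrometres, all positive.
        The default matches sub-micron whole-brain optical sectioning
        (0.35 x 0.35 x 1 um^3).
    origin_um
        Global physical offset of voxel ``(0, 0, 0)`` in micrometres.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (0.35, 0.35, 1.0)
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"stack data must be 3D, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError(f"stack shape must be >= 1 per axis, got {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        self.origin_um = tuple(float(o) for o in self.origin_um)
        if np.issubdtype(self.data.dtype, np.floating):
            if not np.isfinite(self.data).all():
                raise ValueError("stack intensities must be finite")
            if self.data.size and float(self.data.min()) < 0:
                raise ValueError("stack intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical edge lengths of the stack (shape times spacing)."""
        return tuple(n * s for n, s in zip(self.data.shape, self.spacing))

    @property
    def voxel_volume_um3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz


@dataclass
class PhysicalParams:
    """Physical (micrometre) parameters of the detection pipeline.

    Defaults are calibrated to mouse cortical somas imaged at sub-micron
    resolution: soma diameters span 15-27 um with a ~21 um average, hence
    the multi-scale closing range ``[d_min, d_max] = [12, 21]`` um with a
    2 um step, 60 um sub-stacks with 30 um overlap (overlap must exceed
    the largest soma so each soma is wholly inside at least one tile),
    a 10 um fusion radius (half the average soma), a 5 um centroid match
    tolerance (a quarter of the average soma) and a 3.5 um reverse
    gradient search.
    """

    d_min: float = 12.0
    d_max: float = 21.0
    d_step: float = 2.0
    tile_side: float = 60.0
    tile_overlap: float = 30.0
    fuse_dist: float = 10.0
    match_dist: float = 5.0
    reverse_search_dist: float = 3.5
    smoothing_sigma: float = 1.5

    def __post_init__(self) -> None:
        if not (0 < self.d_min <= self.d_max):
            raise ValueError(f"need 0 < d_min <= d_max, got {self.d_min}, {self.d_max}")
        if self.d_step <= 0:
            raise ValueError("d_step must be positive")
        for name in ("fuse_dist", "match_dist", "reverse_search_dist"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be >= 0")
        if not (0 < self.tile_overlap < self.tile_side):
            raise ValueError("need 0 < tile_overlap < tile_side")
        if self.tile_overlap < self.d_max:
            warnings.warn(
                f"tile_overlap ({self.tile_overlap} um) < d_max ({self.d_max} um): "
                "somas larger than the overlap may straddle every tile and be missed",
                stacklevel=2,
            )

    def to_json(self, path: str | os.PathLike) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "PhysicalParams":
        return cls(**json.loads(Path(path).read_text()))


def um_to_vox(point_um, stack: ImageStack) -> tuple[int, int, int]:
    """Convert a physical point (um) to the index of the nearest voxel.

    Raises ``ValueError`` when the point lies outside the physical extent
    of the stack (beyond half a voxel outside the outermost voxel centers).
    """
    p = np.asarray(point_um, dtype=float)
    rel = (p - np.asarray(stack.origin_um)) / np.asarray(stack.spacing)
    idx = np.round(rel).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.asarray(stack.shape)):
        raise ValueError(
            f"point {tuple(p)} um is outside the stack extent {stack.extent_um} um"
        )
    return tuple(int(i) for i in idx)


def vox_to_um(index, stack: ImageStack) -> tuple[float, float, float]:
    """Physical coordinate (um) of a voxel center; inverse of :func:`um_to_vox`."""
    idx = np.asarray(index, dtype=float)
    p = np.asarray(stack.origin_um) + idx * np.asarray(stack.spacing)
    return tuple(float(v) for v in p)


def _check_dtype(arr: np.ndarray, where: str) -> None:
    if arr.dtype not in [np.dtype(d) for d in _SUPPORTED_DTYPES]:
        raise ValueError(f"unsupported bit depth {arr.dtype} in {where}; expected 8- or 16-bit")


def load_stack(path: str | os.PathLike, spacing=(0.35, 0.35, 1.0)) -> ImageStack:
    """Read a multi-page TIFF or a directory of 2D slices as an ImageStack.

    Directory entries are sorted lexicographically and stacked as z-slices.
    Pages must share one shape and be 8- or 16-bit.
    """
    import imageio.v3 as iio

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such stack: {path}")
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.is_file())
        if not files:
            raise FileNotFoundError(f"directory {path} holds no image files")
        pages = []
        for f in files:
            page = np.asarray(iio.imread(f))
            if page.ndim != 2:
                raise ValueError(f"{f} is not a single-channel 2D image")
            pages.append(page)
        shapes = {p.shape for p in pages}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent page sizes in {path}: {sorted(shapes)}")
        planes = np.stack(pages, axis=0)
    else:
        planes = tifffile.imread(path)
        if planes.ndim == 2:
            planes = planes[None]
        if planes.ndim != 3:
            raise ValueError(f"{path}: expected 2D pages, got array of ndim {planes.ndim}")
    _check_dtype(planes, str(path))
    # pages are (z, row=y, col=x) -> (x, y, z)
    data = np.ascontiguousarray(np.transpose(planes, (2, 1, 0)))
    return ImageStack(data=data, spacing=spacing)


def save_stack(stack: ImageStack, path: str | os.PathLike) -> None:
    """Write an 8- or 16-bit stack as a multi-page TIFF (inverse of load_stack)."""
    _check_dtype(stack.data, "save_stack")
    planes = np.ascontiguousarray(np.transpose(stack.data, (2, 1, 0)))
    tifffile.imwrite(Path(path), planes)


def _paint_labels(canvas: np.ndarray, mask: np.ndarray, lo_vox, value: int) -> None:
    """Write ``value`` into canvas where a bbox-cropped mask (at offset lo_vox) is set."""
    lo = np.asarray(lo_vox, dtype=int)
    hi = lo + np.asarray(mask.shape)
    clo = np.maximum(lo, 0)
    chi = np.minimum(hi, np.asarray(canvas.shape))
    if np.any(clo >= chi):
        return
    sl_c = tuple(slice(a, b) for a, b in zip(clo, chi))
    sl_m = tuple(slice(a - l, b - l) for a, b, l in zip(clo, chi, lo))
    view = canvas[sl_c]
    view[mask[sl_m]] = value


def write_results(somas, out_dir, *, shape_vox, spacing=(0.35, 0.35, 1.0),
                  origin_um=(0.0, 0.0, 0.0), write_mask: bool = True) -> dict:
    """Write final soma records: centroid CSV, label mask TIFF, PLY surfaces.

    Parameters
    ----------
    somas
        Finalized :class:`~somafinder.fuse.SomaRecord` objects.
    out_dir
        Destination directory (created if missing).
    shape_vox, spacing, origin_um
        Geometry of the global stack the records refer to (needed to
        rasterize the label mask).
    write_mask
        Skip the (potentially large) label TIFF when False.

    Returns a dict of written paths. Soma ids above 65535 do not fit in the
    16-bit label mask and raise.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc

    ref = ImageStack(np.zeros((1, 1, 1), np.uint8), spacing=spacing, origin_um=origin_um)
    rows = []
    for rec in somas:
        x, y, z = rec.centroid_um
        i, j, k = np.round(
            (np.asarray(rec.centroid_um) - np.asarray(origin_um)) / np.asarray(spacing)
        ).astype(int)
        rows.append(dict(id=rec.soma_id, x_um=x, y_um=y, z_um=z,
                         x_vox=int(i), y_vox=int(j), z_vox=int(k),
                         scale_um=rec.scale_um))
    csv_path = out_dir / "somas.csv"
    pd.DataFrame(rows, columns=["id", "x_um", "y_um", "z_um",
                                "x_vox", "y_vox", "z_vox", "scale_um"]).to_csv(
        csv_path, index=False)

    written = {"centroids_csv": csv_path}

    if write_mask:
        if any(rec.soma_id > 65535 for rec in somas):
            raise ValueError("more than 65535 somas do not fit a 16-bit label mask")
        canvas = np.zeros(tuple(shape_vox), dtype=np.uint16)
        for rec in somas:
            mask, lo = rec.best_mask()
            _paint_labels(canvas, mask, lo, rec.soma_id)
        mask_path = out_dir / "soma_labels.tif"
        save_stack(ImageStack(canvas, spacing=spacing, origin_um=origin_um), mask_path)
        written["label_mask_tiff"] = mask_path

    ply_paths = []
    for rec in somas:
        if rec.surface_points is None:
            continue
        ply = out_dir / f"soma_{rec.soma_id:04d}.ply"
        _write_ply(ply, np.asarray(rec.surface_points), rec.surface_faces)
        ply_paths.append(ply)
    if ply_paths:
        written["surfaces_ply"] = ply_paths
    return written


def _write_ply(path: Path, vertices: np.ndarray, faces=None) -> None:
    """ASCII PLY export; a watertight mesh when faces are given, else points."""
    import trimesh

    if faces is not None:
        mesh = trimesh.Trimesh(vertices=vertices, faces=np.asarray(faces), process=False)
        path.write_bytes(trimesh.exchange.ply.export_ply(mesh, encoding="ascii"))
    else:
        cloud = trimesh.PointCloud(vertices)
        path.write_bytes(trimesh.exchange.ply.export_ply(cloud, encoding="ascii"))
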