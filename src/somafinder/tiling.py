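"""Deblocking a large stack into overlapping cubic sub-stacks.

Maximum-intensity projections of a whole stack superimpose many somas into
inseparable clusters, so detection runs on small sub-stacks instead. Tiles
of physical side ``tile_side`` advance with stride ``tile_side - overlap``
per axis; as long as the overlap exceeds the largest soma diameter, every
soma is wholly contained in at least one tile, which is the correctness
argument for deblocking. The last tile per axis is shifted inward (keeping
its full size) so morphology near the stack border sees full context.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .volume_io import ImageStack

__all__ = ["TileBox", "tile_grid", "make_tiles", "extract"]


@dataclass(frozen=True)
class TileBox:
    """An axis-aligned sub-stack region in global voxel coordinates."""

    lo: tuple[int, int, int]   # inclusive
    hi: tuple[int, int, int]   # exclusive
    tile_id: tuple[int, int, int]

    def __post_init__(self):
        if not all(l < h for l, h in zip(self.lo, self.hi)):
            raise ValueError(f"degenerate tile box lo={self.lo} hi={self.hi}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(h - l for l, h in zip(self.lo, self.hi))


def _axis_starts(n: int, side: int, stride: int) -> list[int]:
    """Start indices along one axis: stride steps, last tile shifted inward."""
    if side >= n:
        return [0]
    starts = list(range(0, n - side + 1, stride))
    if starts[-1] + side < n:
        starts.append(n - side)
    return starts


def tile_grid(shape_vox, spacing, tile_side: float, overlap: float,
              d_max: float | None = None) -> list[TileBox]:
    """Enumerate the full Cartesian grid of overlapping tiles.

    Guarantees that any axis-aligned cube of physical side <= ``overlap``
    lying inside the stack is fully contained in at least one tile, because
    the voxel stride is computed as ``side_vox - overlap_vox`` exactly.
    Axes physically shorter than ``tile_side`` get a single spanning tile.
    """
    if not (0 < overlap < tile_side):
        raise ValueError(f"need 0 < overlap < tile_side, got {overlap}, {tile_side}")
    if d_max is not None and overlap < d_max:
        warnings.warn(
            f"tile overlap {overlap} um is below the largest soma diameter "
            f"{d_max} um; somas may straddle every tile", stacklevel=2)
    shape_vox = tuple(int(n) for n in shape_vox)
    side_vox = [min(n, max(1, int(round(tile_side / s)))) for n, s in zip(shape_vox, spacing)]
    overlap_vox = [max(0, int(round(overlap / s))) for s in spacing]
    stride = [max(1, sv - ov) for sv, ov in zip(side_vox, overlap_vox)]
    axes = [_axis_starts(n, sv, st) for n, sv, st in zip(shape_vox, side_vox, stride)]
    boxes = []
    for i, sx in enumerate(axes[0]):
        for j, sy in enumerate(axes[1]):
            for k, sz in enumerate(axes[2]):
                lo = (sx, sy, sz)
                hi = (sx + side_vox[0], sy + side_vox[1], sz + side_vox[2])
                boxes.append(TileBox(lo=lo, hi=hi, tile_id=(i, j, k)))
    return boxes


def make_tiles(stack: ImageStack, tile_side: float = 60.0, overlap: float = 30.0,
               d_max: float | None = None) -> list[TileBox]:
    """Tile a stack into overlapping cubes of physical side ``tile_side`` um."""
    return tile_grid(stack.shape, stack.spacing, tile_side, overlap, d_max=d_max)


def extract(stack: ImageStack, box: TileBox) -> ImageStack:
    """Copy one tile out of the stack, preserving global physical coordinates."""
    shape = np.asarray(stack.shape)
    lo = np.asarray(box.lo)
    hi = np.asarray(box.hi)
    if np.any(lo < 0) or np.any(hi > shape):
        raise ValueError(f"tile box {box} exceeds stack shape {stack.shape}")
    sl = tuple(slice(l, h) for l, h in zip(box.lo, box.hi))
    origin = tuple(o + l * s for o, l, s in zip(stack.origin_um, box.lo, stack.spacing))
    return ImageStack(stack.data[sl].copy(), spacing=stack.spacing, origin_um=origin)
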