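"""End-to-end orchestration: tile -> localize -> fuse -> surface -> write.

Everything here is a thin, deterministic composition of the stage modules;
running the stages separately (locate, then surface) gives byte-identical
results to one monolithic run.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .volume_io import ImageStack, PhysicalParams, write_results
from .tiling import make_tiles, extract
from .localize import find_candidates
from .fuse import SomaRecord, fuse_candidates
from .rayburst import ray_directions, detect_surface

__all__ = ["locate_somas", "detect_surfaces", "run_pipeline"]

log = logging.getLogger("somafinder")


def _maybe_invert(stack: ImageStack, invert: bool) -> ImageStack:
    if not invert:
        return stack
    data = stack.data
    top = np.iinfo(data.dtype).max if np.issubdtype(data.dtype, np.integer) else data.max()
    return ImageStack(top - data, spacing=stack.spacing, origin_um=stack.origin_um)


def locate_somas(stack: ImageStack, params: PhysicalParams | None = None,
                 invert: bool = False) -> list[SomaRecord]:
    """Tile the stack, detect candidates per tile, fuse repeats."""
    params = params or PhysicalParams()
    stack = _maybe_invert(stack, invert)
    tiles = make_tiles(stack, params.tile_side, params.tile_overlap, d_max=params.d_max)
    log.debug("tile grid: %d tiles", len(tiles))
    cands = []
    for box in tiles:
        sub = extract(stack, box)
        found = find_candidates(sub, params, tile_id=box.tile_id,
                                stack_shape=stack.shape)
        if found:
            log.info("tile %s: %d candidate(s) at scale %.1f um",
                     box.tile_id, len(found), found[0].scale_um)
        cands.extend(found)
    records = fuse_candidates(cands, params.fuse_dist)
    log.info("%d candidates fused into %d somas", len(cands), len(records))
    return records


def detect_surfaces(stack: ImageStack, records: list[SomaRecord],
                    params: PhysicalParams | None = None,
                    invert: bool = False, ray_level: int = 2) -> list[SomaRecord]:
    """Gradient-based Rayburst surface detection for every fused soma."""
    params = params or PhysicalParams()
    stack = _maybe_invert(stack, invert)
    fan = ray_directions(ray_level)
    for rec in records:
        detect_surface(rec, stack, params, fan=fan)
    return records


def run_pipeline(stack: ImageStack, params: PhysicalParams | None = None,
                 out_dir: str | Path | None = None, invert: bool = False,
                 ray_level: int = 2, write_mask: bool = True) -> list[SomaRecord]:
    """Full pipeline; writes centroid CSV, label mask and PLY surfaces when
    ``out_dir`` is given, and returns the finalized records."""
    params = params or PhysicalParams()
    records = locate_somas(stack, params, invert=invert)
    records = detect_surfaces(stack, records, params, invert=invert, ray_level=ray_level)
    if out_dir is not None:
        write_results(records, out_dir, shape_vox=stack.shape, spacing=stack.spacing,
                      origin_um=stack.origin_um, write_mask=write_mask)
    return records
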