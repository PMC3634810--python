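"""Merging soma candidates detected repeatedly in overlapping tiles.

With 30 um overlap a soma is typically detected in several adjacent tiles.
Candidates whose centroids lie strictly closer than ``fuse_dist`` (default
10 um, half the average soma diameter) are grouped by single-linkage
(transitive) clustering, which is order-independent; each cluster becomes
one final record whose centroid is the unweighted mean of its members and
whose retained volume-intersection mask is that of the member nearest the
fused centroid (ties go to the larger mask).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .localize import SomaCandidate

__all__ = ["SomaRecord", "fuse_candidates"]


@dataclass
class SomaRecord:
    """A fused final soma.

    ``mask``/``mask_lo_vox`` hold the representative binary volume
    intersection (bounding-box cropped, with its global voxel offset).
    ``surface_points`` (global um, one per ray), ``surface_faces`` (the ray
    fan's icosphere triangulation) and ``volume_mask``/``volume_lo_vox``
    are filled by surface detection.
    """

    soma_id: int
    centroid_um: tuple[float, float, float]
    mask: np.ndarray
    mask_lo_vox: tuple[int, int, int]
    scale_um: float
    surface_points: np.ndarray | None = None
    surface_flags: np.ndarray | None = None
    surface_faces: np.ndarray | None = None
    volume_mask: np.ndarray | None = None
    volume_lo_vox: tuple[int, int, int] | None = None

    def best_mask(self) -> tuple[np.ndarray, tuple[int, int, int]]:
        """The rasterized soma volume when available, else the hull mask."""
        if self.volume_mask is not None:
            return self.volume_mask, self.volume_lo_vox
        return self.mask, self.mask_lo_vox


def fuse_candidates(cands: list[SomaCandidate], fuse_dist: float = 10.0) -> list[SomaRecord]:
    """Single-linkage fusion of candidates under strict distance < fuse_dist.

    Deterministic and invariant to input order: clusters are connected
    components of the strict-distance graph, output records are sorted by
    fused centroid (z, y, x) and numbered from 1.
    """
    if fuse_dist <= 0:
        raise ValueError("fuse_dist must be positive")
    if not cands:
        return []
    pts = np.asarray([c.centroid_um for c in cands], dtype=float)
    n = len(cands)
    if n == 1:
        labels = np.zeros(1, dtype=int)
    else:
        d = squareform(pdist(pts))
        adj = coo_matrix(d < fuse_dist)
        _, labels = connected_components(adj, directed=False)

    records = []
    for lab in np.unique(labels):
        members = np.nonzero(labels == lab)[0]
        # tiles that cut a soma yield truncated components with biased
        # centroids; the overlap guarantees at least one tile embraces the
        # soma whole, so whole-component members outvote truncated ones
        whole = [m for m in members if not getattr(cands[m], "truncated", False)]
        if whole:
            members = np.asarray(whole)
        centroid = pts[members].mean(axis=0)
        # representative: nearest member centroid, ties -> larger mask, then input order
        dists = np.linalg.norm(pts[members] - centroid, axis=1)
        order = sorted(
            range(len(members)),
            key=lambda i: (round(dists[i], 9), -cands[members[i]].n_voxels, members[i]))
        rep = cands[members[order[0]]]
        records.append(SomaRecord(
            soma_id=0,
            centroid_um=tuple(float(v) for v in centroid),
            mask=rep.mask,
            mask_lo_vox=rep.mask_lo_vox,
            scale_um=rep.scale_um,
        ))
    records.sort(key=lambda r: (r.centroid_um[2], r.centroid_um[1], r.centroid_um[0]))
    for i, rec in enumerate(records, start=1):
        rec.soma_id = i
    return records
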