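"""Soma candidate detection in one sub-stack (the 2.5D morphological method).

Per sub-stack: three orthogonal maximum-intensity projections -> Gaussian
smoothing and percentile contrast stretch -> multi-scale grayscale closing
with a physically circular template -> Otsu threshold per projection ->
backprojection into the 3D visual hull -> 26-connected component labeling
-> soma-size volume filter -> centroids. Template diameters descend from
``d_max`` to ``d_min``; the scan stops at the first scale that yields any
surviving component (larger somas fire at the maximum template, smaller
ones after a few reductions once the template no longer bridges them into
surrounding neurites).

The pipeline assumes bright structures on a dark background (closing fills
dark gaps in bright somas; MIPs propagate maxima). Dark-stained stacks must
be inverted upstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi

from .volume_io import ImageStack, PhysicalParams

__all__ = [
    "ProjectionSet",
    "SomaCandidate",
    "project_max",
    "preprocess",
    "template_scales",
    "close_gray",
    "otsu_value",
    "otsu_threshold",
    "backproject",
    "ball_volume_um3",
    "find_candidates",
]

_CONN_3D = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity


@dataclass
class ProjectionSet:
    """The three orthogonal maximum-intensity projections of a sub-stack.

    ``i_xy`` is (nx, ny) (max over z), ``i_xz`` is (nx, nz) (max over y),
    ``i_yz`` is (ny, nz) (max over x); each carries its in-plane spacing.
    """

    i_xy: np.ndarray
    i_xz: np.ndarray
    i_yz: np.ndarray
    spacing_xy: tuple[float, float]
    spacing_xz: tuple[float, float]
    spacing_yz: tuple[float, float]

    def planes(self):
        return ((self.i_xy, self.spacing_xy),
                (self.i_xz, self.spacing_xz),
                (self.i_yz, self.spacing_yz))


@dataclass
class SomaCandidate:
    """One per-sub-stack detection.

    ``mask`` is the opened core of the candidate's connected component of
    the binary volume intersection (protruding sub-soma-caliber stubs
    removed), cropped to the component bounding box; ``mask_lo_vox`` places
    it in global voxel coordinates. ``centroid_um`` is the mean voxel coordinate
    of the mask in global micrometres; ``scale_um`` is the template
    diameter at which it was detected.
    """

    centroid_um: tuple[float, float, float]
    mask: np.ndarray
    mask_lo_vox: tuple[int, int, int]
    scale_um: float
    tile_id: tuple[int, int, int] | None = None
    truncated: bool = False   # component touches the tile boundary (soma cut by the tile)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def project_max(sub: ImageStack) -> ProjectionSet:
    """Maximum intensity projections along the three orthogonal directions."""
    if sub.data.size == 0:
        raise ValueError("empty sub-stack")
    sx, sy, sz = sub.spacing
    return ProjectionSet(
        i_xy=sub.data.max(axis=2),
        i_xz=sub.data.max(axis=1),
        i_yz=sub.data.max(axis=0),
        spacing_xy=(sx, sy),
        spacing_xz=(sx, sz),
        spacing_yz=(sy, sz),
    )


def preprocess(img: np.ndarray, sigma_um: float, spacing,
               p_low: float = 1.0, p_high: float = 99.0,
               stretch: bool = True) -> np.ndarray:
    """Gaussian smoothing followed by a percentile contrast stretch.

    Smoothing evens out the patchy staining inside somas; the stretch maps
    the [p_low, p_high] intensity percentiles to [0, 1] (clipping outside)
    so the subsequent Otsu threshold sees a normalized histogram. Sigma is
    physical (um) and converted per axis; ``sigma_um=0`` disables smoothing
    and a constant image passes through unchanged.
    """
    if sigma_um < 0:
        raise ValueError("sigma must be >= 0")
    out = np.asarray(img, dtype=np.float64)
    if sigma_um > 0:
        out = ndi.gaussian_filter(out, sigma=[sigma_um / s for s in spacing])
    if not stretch:
        return out
    lo, hi = np.percentile(out, [p_low, p_high])
    if hi <= lo:
        return out
    return np.clip((out - lo) / (hi - lo), 0.0, 1.0)


def template_scales(d_max: float, d_min: float, step: float) -> list[float]:
    """Descending template diameters d_max, d_max-step, ...; d_min appended
    if the ladder does not hit it exactly, so the smallest scale is always
    tried."""
    if not (0 < d_min <= d_max):
        raise ValueError("need 0 < d_min <= d_max")
    if step <= 0:
        raise ValueError("step must be positive")
    scales = []
    d = float(d_max)
    while d > d_min + 1e-9:
        scales.append(round(d, 9))
        d -= step
    if not scales or abs(scales[-1] - d_min) > 1e-9:
        scales.append(float(d_min))
    return scales


def _ellipse_radii_px(diameter_um: float, spacing) -> tuple[int, int]:
    return tuple(max(0, int(round(0.5 * diameter_um / s))) for s in spacing)


def ellipse_footprint(r0: int, r1: int) -> np.ndarray:
    """Flat elliptical structuring element with integer semi-axes (pixels).

    Membership uses exact integer arithmetic: (dx0*r1)^2 + (dx1*r0)^2 <=
    (r0*r1)^2, which the row decomposition in :func:`close_gray` reproduces
    identically.
    """
    d0 = np.arange(-r0, r0 + 1)[:, None]
    d1 = np.arange(-r1, r1 + 1)[None, :]
    if r0 == 0 and r1 == 0:
        return np.ones((1, 1), bool)
    rr0, rr1 = max(r0, 1), max(r1, 1)
    return (d0 * rr1) ** 2 + (d1 * rr0) ** 2 <= (rr0 * rr1) ** 2


def _row_halfwidths(r0: int, r1: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-row-offset half-widths of the elliptical footprint (exact)."""
    import math

    offs = np.arange(-r0, r0 + 1)
    rr0, rr1 = max(r0, 1), max(r1, 1)
    widths = np.array(
        [math.isqrt(rr1 * rr1 * (rr0 * rr0 - o * o)) // rr0 for o in offs], dtype=int)
    return offs, widths


def _shift_extremum(out: np.ndarray, line: np.ndarray, o: int, op) -> None:
    n0 = out.shape[0]
    if o >= 0:
        op(out[: n0 - o], line[o:], out=out[: n0 - o])
    else:
        op(out[-o:], line[: n0 + o], out=out[-o:])


def _flat_morph(img: np.ndarray, r0: int, r1: int, dilate: bool) -> np.ndarray:
    """Exact flat dilation/erosion by the elliptical SE via row decomposition.

    The ellipse is a union of horizontal segments, so dilation is the
    running max over per-row 1D max filters (and dually for erosion).
    Out-of-image samples are ignored (-inf / +inf padding), i.e. morphology
    restricted to the image domain.
    """
    fill = -np.inf if dilate else np.inf
    f1d = ndi.maximum_filter1d if dilate else ndi.minimum_filter1d
    op = np.maximum if dilate else np.minimum
    offs, widths = _row_halfwidths(r0, r1)
    out = np.full(img.shape, fill, dtype=np.float64)
    img = np.asarray(img, dtype=np.float64)
    for o, w in zip(offs, widths):
        line = f1d(img, 2 * int(w) + 1, axis=1, mode="constant", cval=fill)
        _shift_extremum(out, line, int(o), op)
    return out


def close_gray(img: np.ndarray, diameter_um: float, spacing) -> np.ndarray:
    """Grayscale morphological closing with a physically circular template.

    The flat structuring element has physical diameter ``diameter_um``
    along both in-plane axes, i.e. anisotropic pixel radii, so a "circular"
    template stays circular in micrometres regardless of the 0.35 vs 1 um
    pixel pitch. Closing is extensive (output >= input), idempotent and
    increasing, and fills dark gaps smaller than the template inside bright
    structures — which is what bridges the unstained interior of a hollow
    soma in each projection.

    The image is treated as a window into a scene that continues at the
    image minimum beyond its borders (pad-with-minimum convention). The
    border must not act as a bright object: morphology restricted to the
    image domain glues any blob closer than the template diameter to the
    border, producing spurious foreground wedges in near-border tiles.
    """
    if diameter_um <= 0:
        raise ValueError("template diameter must be positive")
    r0, r1 = _ellipse_radii_px(diameter_um, spacing)
    if 2 * r0 + 1 > img.shape[0] or 2 * r1 + 1 > img.shape[1]:
        raise ValueError(
            f"structuring element {(2 * r0 + 1, 2 * r1 + 1)} px exceeds image {img.shape}")
    img = np.asarray(img, dtype=np.float64)
    padded = np.pad(img, ((2 * r0,), (2 * r1,)), constant_values=img.min())
    dil = _flat_morph(padded, r0, r1, dilate=True)
    closed = _flat_morph(dil, r0, r1, dilate=False)
    return closed[2 * r0: closed.shape[0] - 2 * r0, 2 * r1: closed.shape[1] - 2 * r1]


def otsu_value(img: np.ndarray) -> float:
    """Otsu's threshold: maximize between-class variance over the histogram.

    Integer images with a narrow range use one bin per gray level; anything
    else is rebinned to 256 equal bins (16-bit: 65536 -> 256). Ties break
    toward the lower threshold. Foreground is ``img > t``.
    """
    a = np.asarray(img).ravel()
    amin, amax = a.min(), a.max()
    if amin == amax:
        raise ValueError("constant image has no Otsu threshold")
    if np.issubdtype(a.dtype, np.integer) and int(amax) - int(amin) < 256:
        levels = np.arange(int(amin), int(amax) + 1)
        hist = np.bincount(a.astype(np.int64) - int(amin), minlength=levels.size)
    else:
        hist, edges = np.histogram(a, bins=256, range=(float(amin), float(amax)))
        levels = 0.5 * (edges[:-1] + edges[1:])
    hist = hist.astype(np.float64)
    w0 = np.cumsum(hist)
    w1 = w0[-1] - w0
    m = np.cumsum(hist * levels)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = m / w0
        mu1 = (m[-1] - m) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    k = int(np.argmax(sigma_b[:-1]))  # split after bin k; first (lowest) argmax wins
    return float(levels[k])


def otsu_threshold(img: np.ndarray) -> np.ndarray:
    """Binary foreground by Otsu's method; constant images warn and give
    all-background (no soma evidence)."""
    a = np.asarray(img)
    if a.min() == a.max():
        warnings.warn("constant image: Otsu has no evidence, returning all background",
                      stacklevel=2)
        return np.zeros(a.shape, dtype=bool)
    return a > otsu_value(a)


def backproject(b_xy: np.ndarray, b_xz: np.ndarray, b_yz: np.ndarray) -> np.ndarray:
    """Lift three binary projections into the 3D visual hull.

    ``V(x, y, z) = B_xy(x, y) & B_xz(x, z) & B_yz(y, z)``. The hull is a
    superset of any solid whose thresholded projections are contained in
    the three foregrounds.
    """
    b_xy, b_xz, b_yz = (np.asarray(b, bool) for b in (b_xy, b_xz, b_yz))
    nx, ny = b_xy.shape
    if b_xz.shape[0] != nx or b_yz.shape[0] != ny or b_xz.shape[1] != b_yz.shape[1]:
        raise ValueError(
            f"inconsistent projection shapes {b_xy.shape}, {b_xz.shape}, {b_yz.shape}")
    return b_xy[:, :, None] & b_xz[:, None, :] & b_yz[None, :, :]


def ball_volume_um3(diameter_um: float) -> float:
    return (np.pi / 6.0) * diameter_um ** 3


def find_candidates(sub: ImageStack, params: PhysicalParams,
                    tile_id=None, on_scale=None, stack_shape=None) -> list[SomaCandidate]:
    """Detect soma candidates in one sub-stack with early scale termination.

    Iterates template diameters descending; at each scale the full chain
    (MIPs -> preprocess -> closing -> Otsu -> backprojection -> 26-connected
    labeling -> volume filter) runs, and the first scale with at least one
    surviving component wins. The visual hull of several objects contains
    ghost intersections — rods, slabs and hubs traced out by neurites and
    closing-filled gaps between them — so components pass three soma
    priors: (a) physical volume between that of a ball of diameter
    ``0.5 * d_min`` and one of ``2 * d_max``; (b) largest inscribed ball of
    diameter at least ``0.5 * d_min`` (anisotropic Euclidean distance
    transform — any true soma's hull contains a ball of the soma's own
    caliber, while ghosts are thin somewhere); (c) a bright interior: the
    median raw intensity inside the component must exceed the midpoint
    between the sub-stack's background level and its brightest structures,
    because a soma is a solid bright body whereas hull ghosts enclose
    mostly background between neurites.

    ``on_scale(scale_um, n_survivors)`` is called per evaluated scale
    (instrumentation hook for the early-termination contract).
    """
    proj = project_max(sub)
    pre = [preprocess(img, params.smoothing_sigma, sp) for img, sp in proj.planes()]
    spacings = [sp for _, sp in proj.planes()]
    vmin = ball_volume_um3(0.5 * params.d_min)
    vmax = ball_volume_um3(2.0 * params.d_max)
    voxvol = sub.voxel_volume_um3
    sub_lo_vox = np.round(np.asarray(sub.origin_um) / np.asarray(sub.spacing)).astype(int)
    raw = np.asarray(sub.data)
    # bright-interior floor: halfway between the background level (the volume
    # median — stained voxels are sparse) and the brightest stained structures.
    # A global Otsu would sink into the noise here because foreground occupies
    # well under a percent of a sub-stack.
    bg_level, fg_level = np.percentile(raw, [50.0, 99.9])
    brightness_floor = 0.5 * (bg_level + fg_level) if fg_level > bg_level else np.inf

    for scale in template_scales(params.d_max, params.d_min, params.d_step):
        bins = []
        for img, sp in zip(pre, spacings):
            closed = close_gray(img, scale, sp)
            bins.append(otsu_threshold(closed))
        hull = backproject(*bins)
        labels, n = ndi.label(hull, structure=_CONN_3D)
        cands: list[SomaCandidate] = []
        if n:
            counts = np.bincount(labels.ravel(), minlength=n + 1)
            objects = ndi.find_objects(labels)
            for lab in range(1, n + 1):
                vol = counts[lab] * voxvol
                if not (vmin <= vol <= vmax):
                    continue
                sl = objects[lab - 1]
                comp = labels[sl] == lab
                # inscribed-ball caliber: pad so the bbox crop itself is background
                edt = ndi.distance_transform_edt(
                    np.pad(comp, 1), sampling=sub.spacing)
                if float(edt.max()) < 0.25 * params.d_min:
                    continue
                if float(np.median(raw[sl][comp])) <= brightness_floor:
                    continue
                # blob core: opening with the 0.5*d_min ball strips protruding
                # neurite stubs (the soma proper is what is left after
                # protruding processes are eroded away). The core is used both
                # for the centroid — stubs bias the plain voxel average — and
                # as the stored ray-casting constraint, so rays cannot leak
                # along attached neurites. Any soma remains a subset of the
                # core because its caliber (>= d_min) exceeds the opening ball.
                r_open = 0.25 * params.d_min
                eroded = edt > r_open
                if eroded.any():
                    back = ndi.distance_transform_edt(~eroded, sampling=sub.spacing)
                    core = (back <= r_open)[1:-1, 1:-1, 1:-1] & comp
                    core_labels, n_core = ndi.label(core, structure=_CONN_3D)
                    if n_core > 1:
                        core_counts = np.bincount(core_labels.ravel())[1:]
                        core = core_labels == (int(np.argmax(core_counts)) + 1)
                else:
                    core = comp
                idx = np.nonzero(core)
                lo_local = np.array([s.start for s in sl])
                mean_vox = np.array([c.mean() for c in idx]) + lo_local
                centroid = tuple(
                    float(o + v * s) for o, v, s
                    in zip(sub.origin_um, mean_vox, sub.spacing))
                # cut by the tile (not by the stack itself: a face shared with
                # the stack boundary is the same cut in every tile)
                truncated = False
                for ax, (s, dim) in enumerate(zip(sl, sub.shape)):
                    g_lo = sub_lo_vox[ax]
                    g_hi = g_lo + dim
                    at_stack_lo = g_lo == 0
                    at_stack_hi = stack_shape is not None and g_hi >= stack_shape[ax]
                    if (s.start == 0 and not at_stack_lo) or \
                       (s.stop == dim and not (stack_shape is None or at_stack_hi)):
                        truncated = True
                cands.append(SomaCandidate(
                    centroid_um=centroid,
                    mask=core,
                    mask_lo_vox=tuple(int(v) for v in (sub_lo_vox + lo_local)),
                    scale_um=float(scale),
                    tile_id=tile_id,
                    truncated=truncated,
                ))
        if on_scale is not None:
            on_scale(float(scale), len(cands))
        if cands:
            return cands
    return []
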