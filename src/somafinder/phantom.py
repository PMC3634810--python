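"""Synthetic 3D stacks with known soma ground truth.

The phantom emulates the salient features of Golgi-stained whole-brain
stacks: sparse bright blob-like somas 15-27 um across, about half of them
with an unstained interior cavity ("hollowness"), embedded among bright
tubular neurites on a dark background with additive Gaussian noise, at
anisotropic sub-micron voxel spacing. It does not attempt photorealistic
optics (no PSF, no depth attenuation) — it exists so the whole detection
pipeline can be exercised and validated without any external data.

Default soma placement uses a jittered grid in the xy plane at the tile
pitch (60 um) with free depth. That guarantees every soma pair stays
separate in at least the xy projection, which is the regime in which the
2.5D morphological method is well-posed: grayscale closing with a template
of diameter T bridges two blobs whose projected gap is below T, so pairs
closer than roughly (d1 + d2)/2 + T in *every* projection merge into one
hull component — the method's documented failure mode, not a generator
artifact. A ``uniform`` mode with plain dart-throwing at
``min_separation_um`` exists to exercise exactly that regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume_io import ImageStack

__all__ = ["PhantomSpec", "GroundTruthSoma", "GroundTruth",
           "generate_phantom", "hollow_sphere_stack"]


@dataclass
class PhantomSpec:
    """Parameters of the synthetic stack.

    Intensities are 8-bit gray levels; geometry is micrometres. The default
    extent (240 x 240 x 100 um at 0.35 x 0.35 x 1 um spacing) holds a 4 x 4
    grid of somas at 60 um xy pitch plus 28 neurite tubes, half of them
    attached to soma surfaces.
    """

    shape_um: tuple[float, float, float] = (240.0, 240.0, 100.0)
    spacing: tuple[float, float, float] = (0.35, 0.35, 1.0)
    n_somas: int = 16
    soma_diam_range: tuple[float, float] = (15.0, 27.0)
    hollow_fraction: float = 0.5
    cavity_rel_radius: float = 0.45
    cavity_mode: str = "interior"       # "interior" | "surface" (hole breaks the wall)
    n_neurites: int = 28
    neurite_radius_um: float = 0.5
    foreground_intensity: float = 200.0
    background_intensity: float = 30.0
    noise_sigma: float = 10.0
    min_separation_um: float = 35.0
    placement: str = "grid"             # "grid" | "uniform"
    grid_pitch_um: float = 60.0
    jitter_um: float = 2.0
    ellipticity: float = 0.08           # relative axis perturbation of somas
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.soma_diam_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid soma_diam_range {self.soma_diam_range}")
        if self.n_somas > 0 and hi >= min(self.shape_um):
            raise ValueError(f"soma_diam_range {self.soma_diam_range} must fit the "
                             f"extent {self.shape_um}")
        if not (0.0 <= self.hollow_fraction <= 1.0):
            raise ValueError("hollow_fraction must be in [0, 1]")
        if not (0.0 < self.cavity_rel_radius < 1.0):
            raise ValueError("cavity_rel_radius must be in (0, 1)")
        if self.cavity_mode not in ("interior", "surface"):
            raise ValueError("cavity_mode must be 'interior' or 'surface'")
        if self.placement not in ("grid", "uniform"):
            raise ValueError("placement must be 'grid' or 'uniform'")
        if self.min_separation_um <= 0:
            raise ValueError("min_separation_um must be positive")


@dataclass
class GroundTruthSoma:
    """One true soma: center, diameter, and its solid (cavity-filled) mask."""

    soma_id: int
    centroid_um: tuple[float, float, float]
    diameter_um: float
    hollow: bool
    mask: np.ndarray
    mask_lo_vox: tuple[int, int, int]


@dataclass
class GroundTruth:
    somas: list[GroundTruthSoma]
    neurite_paths: list[np.ndarray] = field(default_factory=list)

    @property
    def centroids_um(self) -> np.ndarray:
        return np.asarray([s.centroid_um for s in self.somas], dtype=float).reshape(-1, 3)


def _shape_vox(shape_um, spacing) -> tuple[int, int, int]:
    return tuple(max(1, int(round(e / s))) for e, s in zip(shape_um, spacing))


def _stamp_ellipsoid(canvas, center_um, radii_um, spacing, value) -> tuple[np.ndarray, np.ndarray]:
    """Set voxels inside an ellipsoid; returns (lo_vox, bbox bool mask)."""
    sp = np.asarray(spacing)
    c = np.asarray(center_um)
    r = np.asarray(radii_um)
    lo = np.maximum(np.floor((c - r) / sp).astype(int) - 1, 0)
    hi = np.minimum(np.ceil((c + r) / sp).astype(int) + 2, np.asarray(canvas.shape))
    axes = [(np.arange(l, h) * s - cc) / rr for l, h, s, cc, rr in zip(lo, hi, sp, c, r)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    inside = gx ** 2 + gy ** 2 + gz ** 2 <= 1.0
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    canvas[sl][inside] = value
    return lo, inside


def _place_grid(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Jittered xy-grid placement with free depth (well-separated mode)."""
    r_max = 0.5 * spec.soma_diam_range[1]
    margin = r_max + 2.0
    pitch = spec.grid_pitch_um
    counts = []
    for extent in spec.shape_um[:2]:
        k = int(np.floor((extent - 2 * margin) / pitch)) + 1
        counts.append(max(k, 1))
    capacity = counts[0] * counts[1]
    if spec.n_somas > capacity:
        raise ValueError(
            f"cannot place {spec.n_somas} somas on a {counts[0]}x{counts[1]} grid at "
            f"{pitch} um pitch within {spec.shape_um[:2]} um; enlarge the extent")
    cells = [(i, j) for i in range(counts[0]) for j in range(counts[1])]
    chosen = [cells[i] for i in rng.permutation(len(cells))[: spec.n_somas]]
    centers = []
    for i, j in chosen:
        cx = spec.shape_um[0] / 2 + (i - (counts[0] - 1) / 2) * pitch
        cy = spec.shape_um[1] / 2 + (j - (counts[1] - 1) / 2) * pitch
        cz = rng.uniform(margin, spec.shape_um[2] - margin)
        jit = rng.uniform(-spec.jitter_um, spec.jitter_um, size=2)
        centers.append([cx + jit[0], cy + jit[1], cz])
    return np.asarray(centers)


def _place_uniform(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Dart-throwing placement at min_separation_um (stress-test mode)."""
    r_max = 0.5 * spec.soma_diam_range[1]
    margin = r_max + 2.0
    lo = np.full(3, margin)
    hi = np.asarray(spec.shape_um) - margin
    if np.any(hi <= lo):
        raise ValueError("extent too small for the soma size")
    centers: list[np.ndarray] = []
    for _ in range(20000):
        if len(centers) == spec.n_somas:
            break
        p = rng.uniform(lo, hi)
        if all(np.linalg.norm(p - q) >= spec.min_separation_um for q in centers):
            centers.append(p)
    else:
        raise ValueError(
            f"could not place {spec.n_somas} somas at {spec.min_separation_um} um "
            f"separation within {spec.shape_um} um after bounded retries")
    return np.asarray(centers)


def _neurite_path(rng: np.random.Generator, start, direction, shape_um,
                  length_um: float, step_um: float = 1.0, wobble: float = 0.25) -> np.ndarray:
    """Random smooth tube centerline: a direction-perturbed walk reflected
    at the stack boundary."""
    p = np.asarray(start, dtype=float).copy()
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    pts = [p.copy()]
    hi = np.asarray(shape_um)
    for _ in range(int(length_um / step_um)):
        d = d + wobble * rng.normal(size=3)
        d /= np.linalg.norm(d)
        p = p + step_um * d
        for ax in range(3):
            if p[ax] < 0:
                p[ax] = -p[ax]
                d[ax] = -d[ax]
            elif p[ax] > hi[ax]:
                p[ax] = 2 * hi[ax] - p[ax]
                d[ax] = -d[ax]
        pts.append(p.copy())
    return np.asarray(pts)


def _stamp_tube(canvas, path_um, radius_um, spacing, value, background) -> None:
    """Sweep a soft-edged sphere along the centerline (max-composited).

    Thin neurites are rendered with a partial-volume profile: voxel
    intensity ramps from foreground at the axis to background one coarse
    voxel outside the radius, mimicking how structures thinner than the
    axial sampling appear dimmer than somas in real stacks (a tube of
    1 um caliber at 1 um optical sectioning never fills a voxel).
    """
    sp = np.asarray(spacing)
    pv = float(sp.max())  # partial-volume length scale: the coarsest pitch
    reach = radius_um + pv
    r_vox = np.maximum(np.ceil(reach / sp).astype(int), 1)
    offs = np.stack(np.meshgrid(*[np.arange(-r, r + 1) for r in r_vox], indexing="ij"),
                    axis=-1).reshape(-1, 3)
    d_off = np.sqrt(((offs * sp) ** 2).sum(axis=1))
    keep = d_off <= reach + 1e-9
    offs, d_off = offs[keep], d_off[keep]
    shape = np.asarray(canvas.shape)
    # densify the centerline to half the smallest voxel pitch
    seglens = np.linalg.norm(np.diff(path_um, axis=0), axis=1)
    dense = [path_um[0]]
    for a, b, L in zip(path_um[:-1], path_um[1:], seglens):
        k = max(1, int(np.ceil(L / (0.5 * sp.min()))))
        for t in np.linspace(0, 1, k + 1)[1:]:
            dense.append(a + t * (b - a))
    for p in dense:
        c = np.round(np.asarray(p) / sp).astype(int)
        idx = c[None, :] + offs
        # distance from voxel center to this sample, not to the snapped center
        d = np.sqrt((((idx * sp) - np.asarray(p)) ** 2).sum(axis=1))
        cov = np.clip((radius_um - d) / pv + 0.5, 0.0, 1.0)
        ok = np.all((idx >= 0) & (idx < shape), axis=1) & (cov > 0)
        ii, cc = idx[ok], cov[ok]
        vals = background + (value - background) * cc
        cur = canvas[ii[:, 0], ii[:, 1], ii[:, 2]]
        canvas[ii[:, 0], ii[:, 1], ii[:, 2]] = np.maximum(cur, vals.astype(canvas.dtype))


def generate_phantom(spec: PhantomSpec) -> tuple[ImageStack, GroundTruth]:
    """Deterministic synthetic stack plus ground truth for a spec.

    Somas are mildly ellipsoidal bright blobs; a ``hollow_fraction`` of
    them get an interior cavity at background intensity (strictly inside
    the wall by default). Neurites are swept spheres along random-walk
    centerlines; every other tube starts on a soma surface pointing
    radially outward. Gaussian noise is added and the result clipped to
    the 8-bit range. Identical specs (seed included) give identical
    stacks.
    """
    rng = np.random.default_rng(spec.seed)
    shape = _shape_vox(spec.shape_um, spec.spacing)
    canvas = np.full(shape, float(spec.background_intensity), dtype=np.float32)

    if spec.placement == "grid":
        centers = _place_grid(spec, rng) if spec.n_somas else np.empty((0, 3))
    else:
        centers = _place_uniform(spec, rng) if spec.n_somas else np.empty((0, 3))
    diams = rng.uniform(*spec.soma_diam_range, size=spec.n_somas)
    hollow = rng.random(spec.n_somas) < spec.hollow_fraction
    ax_scale = 1.0 + rng.uniform(-spec.ellipticity, spec.ellipticity,
                                 size=(spec.n_somas, 3))

    # neurites first so soma interiors (and cavities) overwrite crossing tubes
    paths = []
    for t in range(spec.n_neurites):
        length = rng.uniform(60.0, 150.0)
        if spec.n_somas and t % 2 == 0:
            s = t // 2 % spec.n_somas
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            start = centers[s] + d * (0.5 * diams[s] * ax_scale[s].min() * 0.98)
            path = _neurite_path(rng, start, d, spec.shape_um, length)
        else:
            start = rng.uniform(np.zeros(3), np.asarray(spec.shape_um))
            d = rng.normal(size=3)
            path = _neurite_path(rng, start, d / np.linalg.norm(d), spec.shape_um, length)
        paths.append(path)
        _stamp_tube(canvas, path, spec.neurite_radius_um, spec.spacing,
                    float(spec.foreground_intensity), float(spec.background_intensity))

    truth_somas = []
    for s in range(spec.n_somas):
        radii = 0.5 * diams[s] * ax_scale[s]
        lo, mask = _stamp_ellipsoid(canvas, centers[s], radii, spec.spacing,
                                    float(spec.foreground_intensity))
        if hollow[s]:
            cav_r = spec.cavity_rel_radius * radii.min()
            if spec.cavity_mode == "interior":
                cav_c = centers[s]
            else:
                # cavity shifted so the hole breaks the soma wall
                d = rng.normal(size=3)
                d /= np.linalg.norm(d)
                cav_c = centers[s] + d * radii.min()
            _stamp_ellipsoid(canvas, cav_c, np.full(3, cav_r), spec.spacing,
                             float(spec.background_intensity))
        truth_somas.append(GroundTruthSoma(
            soma_id=s + 1,
            centroid_um=tuple(float(v) for v in centers[s]),
            diameter_um=float(diams[s]),
            hollow=bool(hollow[s]),
            mask=mask,
            mask_lo_vox=tuple(int(v) for v in lo),
        ))

    if spec.noise_sigma > 0:
        canvas += rng.normal(0.0, spec.noise_sigma, size=canvas.shape).astype(np.float32)
    data = np.clip(canvas, 0, 255).astype(np.uint8)
    stack = ImageStack(data, spacing=spec.spacing)
    return stack, GroundTruth(somas=truth_somas, neurite_paths=paths)


def hollow_sphere_stack(radius_um: float, shell_um: float,
                        spacing=(0.35, 0.35, 1.0), margin_um: float = 5.0,
                        foreground: float = 200.0, background: float = 30.0) -> ImageStack:
    """A bright spherical shell fixture: dark inside and outside.

    Voxels at radial distance in ``[radius_um - shell_um, radius_um]`` from
    the center are bright. This is the canonical hollow-soma test object:
    its gradient magnitude peaks at both walls, and intensity-threshold ray
    termination stops at the inner wall while gradient-based refinement
    must stop at the outer one.
    """
    if shell_um <= 0 or radius_um <= shell_um:
        raise ValueError("need 0 < shell_um < radius_um")
    sp = np.asarray(spacing, dtype=float)
    half = radius_um + margin_um
    shape = tuple(int(np.ceil(2 * half / s)) | 1 for s in sp)  # odd -> exact center voxel
    center = (np.asarray(shape) // 2) * sp
    axes = [np.arange(n) * s - c for n, s, c in zip(shape, sp, center)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    r = np.sqrt(gx ** 2 + gy ** 2 + gz ** 2)
    data = np.full(shape, background, dtype=np.float32)
    data[(r >= radius_um - shell_um) & (r <= radius_um)] = foreground
    return ImageStack(data, spacing=tuple(sp))
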