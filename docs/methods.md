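# Methods

## Problem and overall model

`somafinder` detects the cell bodies (somas) of sparsely labeled neurons in
large 3D grayscale image stacks and reconstructs each soma's surface. The
target imagery is Golgi-stained whole-brain tissue acquired by micro-optical
sectioning at anisotropic sub-micron resolution (0.35 × 0.35 × 1 µm³ voxels):
bright blob-like somas 15–27 µm across (average ≈ 21 µm), frequently with an
unstained interior cavity ("hollowness"), embedded among thin bright
neurites on a dark, noisy background. Two failure modes of simpler methods
drive the design: (i) whole-stack intensity projections superimpose many
somas into inseparable clusters, and (ii) intensity-threshold surface
tracing (classical Rayburst Sampling) terminates prematurely inside hollow
somas.

The pipeline is:

1. **Deblocking.** The stack is cut into overlapping cubic sub-stacks
   (default side 60 µm, overlap 30 µm). Because the overlap exceeds the
   largest soma diameter, every soma lies wholly inside at least one tile;
   the last tile per axis is shifted inward rather than truncated so border
   morphology sees full context.
2. **Per-tile 2.5D localization.** Three orthogonal maximum-intensity
   projections are smoothed (Gaussian, σ = 1.5 µm), contrast-stretched
   (1st/99th percentiles → [0, 1]), closed in grayscale with a flat circular
   template whose *physical* diameter steps down 21, 19, …, 13, 12 µm,
   thresholded per projection with Otsu's method, and backprojected into the
   3D visual hull `V(x,y,z) = B_xy ∧ B_xz ∧ B_yz`. 26-connected components
   passing the soma priors (below) become candidates; the scan stops at the
   first template size that yields any survivor.
3. **Fusion.** Candidates detected repeatedly in overlapping tiles are
   merged by single-linkage clustering at strict centroid distance
   < 10 µm (half the average soma).
4. **Surface detection.** For each fused soma, rays are cast from the
   centroid to the stored volume-intersection hull, then refined by a
   reverse search for a local maximum of the Sobel gradient magnitude, and
   the refined star-shaped surface is rasterized back into a voxel volume.

## Parameters

All user-facing parameters are micrometres; conversion to anisotropic pixel
radii happens at module boundaries, so one configuration transfers across
image resolutions.

| parameter | default | meaning |
|---|---|---|
| `d_max`, `d_min`, `d_step` | 21, 12, 2 µm | closing template ladder, spanning the soma size range (the largest template rejects neurite-scale structure; smaller ones recover somas that merged into their surroundings at coarser scales) |
| `tile_side`, `tile_overlap` | 60, 30 µm | deblocking geometry; overlap must exceed the largest soma |
| `fuse_dist` | 10 µm | half the average soma diameter; strict `<` |
| `match_dist` | 5 µm | validation matching, a quarter of the average soma; strict `<` |
| `reverse_search_dist` | 3.5 µm | gradient reverse-search reach; must cover the gap between the hull (which overshoots along its diagonal corners by ≈ 0.22·r) and the true wall, yet stay well short of cavity walls |
| `smoothing_sigma` | 1.5 µm | projection smoothing; evens patchy staining and dims sub-resolution neurites relative to somas |
| ray fan | icosphere level 2 (162 rays) | quasi-uniform directions; the icosphere triangulation doubles as a watertight export mesh |

## Candidate filtering (soma priors)

The visual hull of several objects contains *ghost* components — rods,
slabs and hubs traced out by neurites and by closing-filled gaps between
them. Three priors separate somas from ghosts, all derived from the soma
size range rather than tuned per dataset:

- **Volume window:** component volume within [ball(0.5·d_min), ball(2·d_max)].
- **Inscribed ball:** the component must contain a ball of diameter
  0.5·d_min (computed by anisotropic Euclidean distance transform). A true
  soma's hull contains a ball of the soma's own caliber; ghosts are thin in
  at least one direction.
- **Bright interior:** the median raw intensity inside the component must
  exceed the midpoint between the sub-stack's background level (its median)
  and its brightest structures (99.9th percentile). Hull ghosts enclose
  mostly empty space between neurites; somas are solid bright bodies. A
  plain Otsu threshold on the raw volume is unusable here because stained
  voxels are far below one percent of a sub-stack.

Candidate centroids are averaged over the component's *opened core*
(morphological opening with the 0.5·d_min ball): the soma proper is the
smooth blob remaining after protruding neurite stubs are eroded, and stubs
otherwise bias the plain voxel average by 1–3 µm. The stored mask remains
the full component, since the ray-casting constraint must stay a superset
of the soma.

During fusion, members whose component touches a tile face (other than a
face shared with the stack boundary) are treated as truncated: a tile that
cuts a soma produces a component whose centroid is biased toward the
retained half and whose mask would cap the rays. The deblocking overlap
guarantees at least one whole-component member per soma, so truncated
members are outvoted for both the fused centroid and the representative
mask. This restricted mean replaced a plain mean over all members, which
left ≈ 2.3 µm mean centroid error on the default phantom versus ≈ 0.3 µm
after the change.

## Gradient-based ray termination

The gradient field is built by applying the standard unnormalized 3×3 Sobel
kernel within the local xy, xz and yz planes through each voxel; `G_ab` is
the 2D gradient magnitude in plane `ab` and the field magnitude is
`sqrt(G_xy² + G_xz² + G_yz²)` (borders replicate edge values). On a unit
ramp along x this gives 8√2 at interior voxels.

The reverse search samples the magnitude by trilinear interpolation from
each hull point inward in steps of min(spacing)/2 over 3.5 µm, and moves
the surface point to the **outermost local maximum whose height is at least
half the window maximum**. Taking the outermost qualifying maximum (rather
than the global maximum of the window) is essential for hollow somas: inner
and outer walls produce gradient peaks of comparable magnitude, and when
the search window reaches the cavity wall a global maximum would land there
on roughly half the rays by discretization luck. The half-height rule
rejects noise bumps (whose prominence is far below a genuine wall edge).
Rays with a flat profile (range below 1 % of the field's global range) or
no qualifying interior maximum keep their hull point, flagged as such; the
refined radius never exceeds the hull radius, so neurites cannot drag rays
outward and the search degrades gracefully where the wall has holes.

Surface-to-volume conversion rasterizes the star-shaped solid: a voxel is
foreground iff its distance from the seed is at most the radius
interpolated over the three angularly nearest ray directions (inverse
angular distance weights). The result always contains the seed and is
connected. The method is exact for star-shaped somas and is not intended
for strongly non-convex (sickle-like) cell bodies.

## Synthetic phantom

The generator emulates the features that matter to the pipeline, with
ground truth: bright somas (mildly ellipsoidal, ±8 % axes) of 15–27 µm,
half given a strictly interior cavity at background intensity (a
`surface` cavity mode exists to exercise broken-wall somas); neurite tubes
of 1 µm caliber swept along random-walk centerlines, half of them attached
radially to soma surfaces; additive Gaussian noise (σ = 10 gray levels on a
30/200 background/foreground 8-bit scale), clipped to [0, 255].

Two deliberate realism choices:

- **Partial-volume neurites.** Tubes are rendered with an analytic
  partial-volume intensity ramp (full intensity on the axis, background one
  coarse-voxel pitch outside the radius). Structures thinner than the 1 µm
  axial sampling genuinely appear dimmer than somas in this modality, and
  that brightness gap is what lets smoothing + Otsu isolate somas from
  neurites. Rendering tubes at full soma brightness makes the phantom
  unrepresentative of the imaging physics and defeats any
  projection-threshold method.
- **Well-separated placement.** Default placement is a jittered xy grid at
  the 60 µm tile pitch with free depth (minimum 3D separation ≈ 54 µm ≥ the
  documented 35 µm condition). Grayscale closing with a template of
  diameter T bridges two blobs whose projected gap is below T, so soma
  pairs closer than roughly (d₁+d₂)/2 + T in *every* projection merge into
  a single hull component — the method's documented failure mode, not a
  generator artifact. Guaranteeing separation in at least the xy projection
  keeps the default phantom inside the regime where the method is
  well-posed; a `uniform` dart-throwing mode at `min_separation_um`
  exercises the failure regime on demand.

What passing tests on this phantom do **not** show: robustness to the
point-spread function, depth-dependent attenuation, periodic scanning
artifacts, staining-intensity variation between cells, densely packed soma
clusters (< ≈ 35 µm), or strongly non-star-shaped somas. Those either
require real data or are documented non-goals.

## Numerical choices

- Grayscale closing uses an exact row decomposition of the elliptical flat
  structuring element (per-row 1D max/min filters); this is identical to
  sliding-window max/min with the full footprint (the footprint membership
  test is done in integer arithmetic so both formulations agree exactly)
  but roughly fifty times faster at the 61-pixel templates the defaults
  imply. Borders use the pad-with-minimum convention: the projection is a
  window into a scene that continues at background level, so the border
  never acts as a bright object (domain-restricted morphology glues any
  blob nearer than the template diameter to the border, creating spurious
  foreground wedges in near-border tiles). Closing remains extensive and
  idempotent under this convention, including at borders.
- Otsu's threshold uses one bin per gray level for 8-bit-range integer
  images and 256 equal bins otherwise (16-bit data is effectively rebinned
  65536 → 256); ties break toward the lower threshold; foreground is
  strictly above threshold. A constant image yields all-background with a
  warning.
- The template ladder descends from `d_max` in steps of `d_step` and
  appends `d_min` when the ladder does not hit it exactly, so the smallest
  template is always tried.
- Connectivity is 26-connected in 3D, 8-connected in 2D.
- Coordinates: arrays are indexed (x, y, z) with the voxel-center
  convention `coord = origin + index·spacing`; µm↔voxel round trips are
  exact to half a voxel. Physical points, distances and ray directions are
  micrometres throughout; interpolation happens in voxel space.
- Determinism: the phantom is a pure function of its spec (seed included);
  the pipeline itself has no randomness, and reruns are byte-identical.

## Problem sizes

The default phantom is 240 × 240 × 100 µm (686 × 686 × 100 voxels) with 16
somas and 28 neurite tubes — large enough that the tiling, fusion and
ghost-suppression logic is genuinely exercised (147 tiles, multiple
candidates per soma) while a full generate–detect–validate cycle stays
around a minute on one core. The acceptance script additionally measures
surface recovery on the analytic hollow-sphere fixture (outer radius 10 µm,
2 µm wall), where the true answer is known in closed form.

## Known limitations

- Two somas closer than the fusion radius, or merged in all three
  projections, are reported as one (under-segmentation); no splitting is
  attempted.
- Slender or sickle-shaped somas violate the star-shape assumption of the
  rasterizer and the blob priors of the candidate filter.
- The 16-bit label mask caps output at 65 535 somas.
- Processing is in-memory and sequential; stacks must fit in RAM.
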