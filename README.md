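# somafinder

Automated localization and surface reconstruction of neuronal somas in
large 3D grayscale image stacks.

## The problem

Whole-brain imaging of sparsely stained tissue (e.g. Golgi-stained mouse
brain at 0.35 × 0.35 × 1 µm³ voxels) produces stacks in which neuron cell
bodies — bright, roughly spherical blobs 15–27 µm across — must be counted,
localized and measured among dense thin neurites. Two properties of such
data defeat simple approaches: projections of a large stack superimpose
many somas into inseparable clusters, and uneven staining leaves many somas
with a dark interior cavity ("hollowness") that terminates
intensity-threshold surface tracing prematurely.

`somafinder` implements a two-part method for users of such data
(neuroanatomists counting somas, and developers of neuron-tracing tools
that need seed points and soma meshes):

1. **Localization** — the stack is deblocked into overlapping 60 µm cubes
   (overlap 30 µm > largest soma, so every soma is whole in some tile).
   Per tile, the three orthogonal maximum-intensity projections I_xy, I_xz,
   I_yz are smoothed, contrast-stretched, morphologically closed with
   circular templates of descending physical diameter D = 21, 19, …, 12 µm,
   Otsu-thresholded, and backprojected into the visual hull
   V(x,y,z) = B_xy(x,y) ∧ B_xz(x,z) ∧ B_yz(y,z). 26-connected components
   passing soma-size priors become candidates (the scan stops at the first
   template size that fires); repeats across tiles are fused by
   single-linkage clustering at centroid distance < 10 µm.
2. **Surface detection (gradient-based Rayburst Sampling)** — from each
   soma centroid, 162 quasi-uniform rays are cast outward to the binary
   volume-intersection hull (which excludes neurites, so rays cannot leak
   along dendrites), then each ray reverse-searches ≤ 3.5 µm inward for the
   outermost strong local maximum of the Sobel gradient magnitude
   |∇I| = √(G_xy² + G_xz² + G_yz²). A gradient edge, unlike an intensity
   threshold, marks the outer soma wall even when the interior is hollow.
   The refined star-shaped surface is rasterized into a voxel volume and
   exported as a watertight mesh.

A synthetic phantom generator (somas with controllable size, hollowness and
separation, partial-volume-rendered neurite tubes, noise) provides ground
truth for validation, and a metrics module implements the standard
evaluation: strict 5 µm one-to-one centroid matching, recall/precision, and
per-soma Jaccard/Dice volume overlap.

See `docs/methods.md` for assumptions, parameter rationale and limitations.

## Worked example

`examples/03_hollow_soma_surface.py` builds the canonical hollow-soma
fixture — a bright spherical shell of outer radius 10 µm and 2 µm wall,
dark inside and out — and reconstructs it with both ray-termination
criteria:

```
true outer radius:            10.00 um
gradient-based radii:   9.80 - 10.50 um  (median 9.98)
intensity-threshold radii:  0.00 -  0.00 um  (median 0.00)
```

Every gradient-based ray lands within half a voxel of the true outer wall;
the classical intensity-threshold criterion never leaves the cavity (all
radii ≈ 0), which is exactly the failure mode the gradient criterion
removes.

`examples/04_validate_pipeline.py` runs the whole pipeline on a 120 × 120 ×
60 µm phantom with four somas (one hollow) and ten neurite tubes, then
scores it against ground truth:

```
real somas: 4, detected: 4, correct: 4
recall: 100.0%  precision: 100.0%
mean centroid error: 0.18 um
  soma 1: volume overlap (Jaccard) 0.966
  soma 2: volume overlap (Jaccard) 0.957
  soma 3: volume overlap (Jaccard) 0.977
  soma 4: volume overlap (Jaccard) 0.971
fraction of correct somas with overlap > 80%: 100.0%
```

Recall/precision are percent of true somas recovered / of detections that
are correct (a detection is correct within a strict 5 µm centroid match);
the overlap column is the Jaccard ratio between each detected soma volume
and its ground-truth mask.

The same steps are available from the shell:

```sh
soma phantom --out ph                     # synthetic stack + ground truth
soma locate ph/phantom.tif --out loc      # centroid CSV + hull label mask
soma surface ph/phantom.tif --centroids loc/somas.csv \
     --masks loc/soma_labels.tif --out surf    # PLY meshes + soma volumes
soma validate --detected surf/somas.csv --truth ph/truth.csv \
     --detected-masks surf/soma_labels.tif --truth-masks ph/truth_labels.tif
```

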