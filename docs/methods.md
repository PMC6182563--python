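# Methods

## Scope and model

`mycomorph` quantifies mycelial morphology from 2-D micrographs. The object
model is purely planar: each mycelial object is the set of pixels of one
8-connected component, and every descriptor is a function of that pixel set
and the μm-per-pixel calibration. No optical model (point spread, phase
rings), no 3-D reconstruction and no growth kinetics are involved; the
package measures what is in the image plane, the way routine morphometry of
submerged cultures is done.

## Preprocessing and segmentation

Segmentation works on the green plane of the RGB capture (the channel with
the strongest, least chromatically biased contrast in phase-contrast
imaging). The chain is:

1. **Median filter**, default radius 1 (3 × 3), edge-replicated borders.
   The smallest kernel consistent with smoothing ragged object edges while
   preserving ~2 μm spores at high magnification; it is idempotent on
   constant images, never produces values outside the input range, and
   changes a disk's projected area by well under 2 %.
2. **Sobel gradient magnitude**, the standard 3 × 3 kernels,
   √(Gx² + Gy²). Invariant under constant illumination offsets, which is
   what makes one threshold usable across objectives and color shifts.
3. **Threshold** on the gradient histogram — Otsu's method by default, or a
   fixed value. An all-zero gradient yields an empty scene, not an error.
4. **Closing** (disk radius 2 px) bridges 1–2 px contour gaps, then
   **hole filling** turns closed contours into solid objects.
5. **Halo compensation**: the thresholded Sobel ridge of a step edge
   straddles the true boundary by one pixel on each side, so the filled
   region is the true mask dilated by ~1 px. One 3 × 3 erosion
   (`edge_halo_erosion = 1`) recenters the mask; on noise-free synthetic
   disks this recovers the true pixel count to within a few pixels.
   Configurable, 0 disables.
6. **8-connected labeling**, labels 1..n.

Objects are then removed by declarative filter rules (min/max projected
area in μm², min/max circularity, border exclusion with a pixel margin) and
optionally by a polygonal area of interest. The AOI test is
centroid-inside-polygon (inclusive on the boundary) rather than pixel
clipping, so surviving shapes are never truncated. Rule evaluation is
order-independent; each removal is reported as (object id → violated rule),
replacing interactive operator clean-up with an auditable report.
Border-touching objects corrupt size statistics, so border exclusion is on
in the default configuration.

## Descriptors

All descriptors are computed on the object's bounding-box crop; physical
quantities use the calibration (μm/px), which is supplied directly or per
objective through the run configuration.

* **Projected area** A = pixel count × calibration².
* **Mean diameter** D: the chord through the center of gravity, averaged
  over `n_dirs` equally spaced directions in [0, π), 180 by default
  (sensitivity between 180 and 360 directions is far below the
  rasterization error; both are available via `n_dirs`). Chords are sampled
  at 0.25 px steps; a disk measures 2r to ~0.5 %. If the centroid falls
  outside the object (strongly concave shapes) D falls back to Dmax and the
  record is flagged `centroid_outside`.
* **Maximum diameter** Dmax: maximum Feret diameter, the largest pairwise
  distance between boundary-pixel centers, computed via the convex hull of
  the boundary (exactly equal to the brute-force pairwise search).
* **Elongation** E: the pixel-coordinate covariance is diagonalized; E is
  the ratio of the larger to the smaller principal variance — equivalently
  the squared ratio of the standard deviations along and across the
  regression (major principal) axis. E = 1 for a circle; a filled n × m
  rectangle gives ((n²−1)/12)/((m²−1)/12) exactly. Degenerate cases: a
  single pixel is defined as E = 1; a perfectly collinear mask has zero
  transverse variance and returns an `inf` sentinel, flagged
  `elongation_undefined` and excluded from summaries (its Mo is reported
  as 0).
* **Roughness / solidity** R = A / convex area, with the hull rasterized
  over pixel centers. Center-based hulls make the measure idempotent — the
  hull of a hull scores exactly 1 — where corner-offset hulls would drift
  by half a pixel per application.
* **Circularity** 4πA/P². P is the length of the marching-squares boundary
  polygon after a window-3 circular moving average over its vertices: the
  raw marching-squares polygon overestimates a digital circle's perimeter
  by ~5 % (staircase effect), which would put a disk's circularity at 0.87;
  with the smoothing a disk of radius ≥ 10 px scores 0.96–0.99, a 1 × 100 px
  line 0.032, and a square stays within 2.5 % of the exact π/4.
* **Morphology number** Mo = 2·√(A·S) / (√π · Dmax · E), with S ≡ R. This
  is the dimensionally consistent combination that equals exactly 1 for an
  ideal disk (A = πr², S = E = 1, Dmax = 2r); the formula reading is
  recorded in output metadata (`mo_formula` in the run log). Circular
  objects stay near 1 (≥ 0.6), filamentous morphology falls below 0.5.

R, circularity and Mo may exceed 1 by up to a rasterization tolerance of
1.02; tables report the unclipped values together with clipped-to-[0, 1]
convenience columns.

## Statistics

Objects frequently split into two coexisting populations; the partition is
by projected area at a threshold (default 10⁴ μm²; strongly pelleting
cultures need 10⁵ μm²). A < threshold is "small", A ≥ threshold is "large"
— the boundary itself goes to "large", an arbitrary but documented
tie-break. Summaries report, per time × condition × class × parameter, the
arithmetic mean, the sample standard deviation (n − 1 denominator) and the
Student-t confidence half-width t₁₋α/2,n−1 · sd/√n (α = 0.05 default). A
group of n = 1 reports its mean with sd/ci flagged undefined rather than
dividing by zero; non-finite descriptor values (the elongation sentinel)
are excluded.

Core/filament measures of pellets (largest-core diameter, core-to-pellet
diameter ratio, mean filament length, filament-to-diameter ratio, core
count) are computed from explicitly supplied core masks and filament
lengths — generator ground truth or manual annotations — because these are
measurements done by hand on selected images; no automatic core detector is
pretended.

## Synthetic scenes and what they do (and do not) show

No image data accompanies studies of this kind, so validation runs on
generated scenes: dark objects (configurable intensity, default 60/255) on
a bright background (default 220/255), rendered 8-bit RGB with the full
contrast in the green plane, optional Gaussian noise (default sd 3) and
optional halo. The default frame is 2448 × 1920 (a typical camera format);
tests and the shipped timecourse profiles use 600–1200 px frames for
desk-scale runtime. One seeded generator drives all randomness; a fixed
`SceneSpec` reproduces scenes, ground truth and downstream CSVs
byte-for-byte.

Object kinds are geometric stand-ins for the canonical morphologies:
circular and lemon-shaped (elliptical) spores of 2–8 μm (default 4 μm with
0.5 μm spread), germinating spores with a straight germ tube, spore
agglomerates built by sequential attachment (each new member placed in
contact with a random existing one — a geometric, not physical, model),
hairy pellets (disk cores plus radially jittered filaments; core-shell and
1–4-core multicore variants), branching persistent-random-walk clumps and
hyphae, a deterministic sinusoidal filament for analytic tests, and angular
microparticle debris. Debris grains are star polygons with concave fracture
notches (nominal diameter 10 μm, the standard mineral-microparticle size),
because crushed mineral grit is sharp-edged and re-entrant; that geometry
is what makes the circularity filter (spore-image default: min circularity
0.7) separate debris (measured circularity ≤ ~0.5) from spores (≥ ~0.87)
cleanly. Placement is rejection-sampled with a minimum bounding-box gap
(default 12 px) and falls back to an exhaustive shuffled grid scan, so
placement fails only when no gap-respecting slot exists.

Ground truth stores each object's exact mask, and its true descriptors are
computed by the same morphometry routines on the noiseless mask. This
deliberately separates rendering/segmentation error from descriptor error:
recovery tests (A within 5 %, E within 5 %, R within 0.05 for objects
≥ 100 px on noise-free scenes) probe the segmentation, while the oracle
tests (brute-force Feret search, hull-rasterization ratio, closed-form
rectangle/square/disk values) probe the descriptors.

What passing these tests does **not** show: performance on real
phase-contrast optics (halos, shading, defocus), on touching or overlapping
objects (the pipeline, like the procedure it implements, does not split
merged objects — watershed splitting is out of scope), on debris that is
genuinely round, or on densely packed fields. The generator's noise is
additive Gaussian only.

### Timecourse profiles

Four editable YAML presets emulate, qualitatively, the canonical
pellet-formation routes: `agglomerative-spore` (spores swell → agglomerate
ungerminated → germinate from the agglomerate surface → hairy pellets),
`agglomerative-hyphal` (germination first, hyphae and clumps, then hyphal
agglomeration), `perithecia-seeded` (fruiting bodies as agglomeration
centers yielding core-shell pellets with long filaments) and
`non-agglomerative` (large elongated spores, strong swelling, one pellet
per germling, occasional multicore pellets). Each timepoint sets its own
frame size and calibration — mirroring the objective switching a real
timecourse needs as objects grow by orders of magnitude — and its object
composition. The compositions are chosen so the true trajectories exhibit
the canonical qualitative pattern: non-decreasing mean projected area, a
morphology-number dip during germination followed by a rise at pelleting,
and a two-class area structure straddling 10⁴ μm² at the agglomerate stage.
The absolute sizes are order-of-magnitude plausible geometric choices, not
calibrated biology; profile filaments are drawn 3 px wide so that rendered
and segmented pellets keep their hair (1 px filaments would not survive the
halo-compensation erosion).

## Numerical and degenerate-input choices

* Pixel coordinates are 0-based, x rightward, y downward; all physical
  outputs in μm / μm².
* Intensities are processed as float64 regardless of source bit depth;
  8- and 16-bit TIFF/PNG, grayscale or RGB, are accepted.
* Filament/line widths rasterize via dilation of a 1 px polyline by a disk
  of radius round((w−1)/2), so even widths round down to the nearest odd
  width.
* An exact area tie at the class threshold is "large"; an AOI centroid
  exactly on the polygon boundary is kept.
* Empty masks, non-positive calibrations, malformed polygons, unknown
  filter kinds and unknown config keys raise `ValueError` with the
  offending name; unreadable images raise a load error naming the path (the
  CLI logs and skips them, exiting non-zero).

## Known limitations

* No splitting of touching objects; agglomerate membership is geometric.
* Circularity and perimeter are estimator-dependent at small sizes
  (< ~10 px objects); the debris filter is validated for ~10 μm grains
  against ~2–8 μm spores at 0.1 μm/px.
* The mean-diameter chord scan assumes the centroid is inside the object;
  the Dmax fallback is flagged but is an overestimate of D for concave
  shapes.
* Timecourse profiles are qualitative: they reproduce developmental
  patterns, not measured growth curves.
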