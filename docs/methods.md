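# Methods

This note documents the measurement models implemented in `axoquant`, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical decisions made where the design was
genuinely open.

## Coordinate, unit and time conventions

Images follow raster convention: `x` = column, `y` = row, origin top-left,
`y` increasing downward. Every physical quantity is derived from pixel and
frame units solely through a `Calibration` (µm/px per axis, s/frame).
Setting pixel size and frame interval to 1 makes physical outputs equal
pixel/frame outputs, which the tests exploit. Anisotropic pixel sizes are
supported where they are meaningful (areas, kymograph axes) and rejected
where a single pixel size is required (arc rasterization, skeleton
geodesics, path sampling). Total movie duration uses
T = n_frames × frame_interval, so a 360-frame movie at 2 fps spans 180 s;
this convention also scales dash lifetimes (below).

## Sholl semicircle counting

The axon field is binarized (`mask = image > t`; fixed `t` for
cross-condition comparability, Otsu's criterion otherwise, the value always
recorded in the mask metadata). For each radius r = k·step the 1-px
semicircular arc around the growth direction is rasterized by dense angular
sampling with consecutive deduplication (equivalent to a midpoint circle
restricted to the half-plane `(p − c)·d ≥ 0`), and the count at r is the
number of maximal runs of foreground pixels along the ordered arc chain; a
run breaks at a background pixel or where the chain leaves the image. This
counts crossing *processes* rather than foreground pixels. Bin sums use
half-open membership `(lo, hi]` so a radius on an edge is counted exactly
once and contiguous bins conserve the profile total.

Defaults: 2-µm steps to 1500 µm, bins 0/500/1000/1500 µm, direction +x
(growth away from the microgroove edge).

The generator's analytic oracle computes, per radius, the exact
segment–circle crossings of every ray/branch, assigns each crossing the
angular extent of the rendered stroke (half-width asin(h/r)), and merges
intervals closer than one pixel of arc. This merge-aware form is required
for correctness: near the origin, or just distal to a branch fork, a
semicircular arc is only a few pixels long and physically distinct
processes fuse into one foreground run — any oracle ignoring stroke width
would disagree with *any* correct arc counter there. For rays separated by
more than the merge scale the oracle reduces to "number of rays with
length ≥ r". The random-arbor suite therefore enforces a minimum angular
separation (0.23 rad) and samples radii at 16-µm steps on 0.5-µm pixels,
which guarantees no merging at any sampled radius and makes the comparison
exact; radii within 1 px of a ray endpoint are exempt (±2), because an arc
grazing a stroke tip tangentially can rasterize into two short runs.

## Growth-cone morphometry

Area is the foreground pixel count times pixel area. Perimeter is the
polygon length of the outer marching-squares contour (level 0.5), which
converges to the analytic perimeter for smooth shapes but retains a small
staircase excess (≈5 % for a rasterized circle); since all conditions share
it, comparisons are unaffected. Elongation is the major/minor axis ratio
of the equal-second-moment ellipse — the standard concrete reading of
"best-fit ellipse" when no fit criterion is given.

The mask is thinned to a 1-px skeleton and condensed to a weighted graph:
nodes are skeleton pixels of degree ≠ 2 (endpoints, junctions, isolated
pixels), edges are the pixel chains between them with geodesic length
(1 or √2 px per step, scaled by pixel size); isolated cycles promote one
pixel to a node. Spurs shorter than `prune_len_um` (default 0.5 µm) are
removed iteratively to a fixed point — which makes pruning idempotent —
and junctions left with degree 2 are collapsed.

LSP is the maximum over node pairs of the shortest-path distance along the
graph, computed exactly by Dijkstra from every node (node counts are a few
hundred at most, so no heuristic is needed). Degree-2 path pixels
contribute length but are not candidate endpoints. The test oracle
recomputes all-pairs distances by dense Floyd–Warshall on the raw
adjacency matrix; graph edge lengths in those tests are quarter-integers
so the two summation orders agree exactly in floating point.

A filopodium is a terminal edge (junction → endpoint) longer than
`min_filopodium_len_um` (default 1.0 µm); a junction-free skeleton has
zero filopodia by definition. Note the measured length runs from the
junction on the body's medial axis, so it includes the medial-axis-to-
boundary offset; the generator-based count tests use thin bodies (or bare
junction geometries) where this offset is a fraction of the threshold,
keeping the expected counts unambiguous. Axon-shaft exclusion is the
caller's responsibility via mask cropping.

## Axial intensity profiles

A 1-µm-wide segmented line, first vertex at the axon tip, is resampled at
1-px arc-length steps; at each step the value is the mean over
perpendicular offsets spanning the width (3 evenly spaced offsets per µm
of width, forced odd so the path center is always sampled; bilinear
interpolation). Background measured in a cell-free region is subtracted as
a scalar with no clipping — negatives are preserved so integrals stay
linear and fold changes unbiased.

Two per-axon baseline conventions exist for visualization only:
`tip_anchor` subtracts the value at 0 µm (corrected tip ≡ 0);
`distal_window` subtracts the mean of the distal 45–50 µm window
(corrected window mean ≡ 0). Corrected profiles are flagged and rejected
by the quantitative operations. Quantification uses uncorrected,
background-subtracted profiles: trapezoidal integrals over 0–50 µm,
per-profile fold change against the control-group mean integral, and the
terminal fraction (percentage of the total integral within the first
10 µm; in [0, 100] and monotone in the window).

## EB3 comet dynamics

Mobile/static separation is a temporal difference of Gaussians: each
pixel's time series is blurred along frames with σ = 4 (mobile) and σ = 50
(static), reflect boundaries, and the static estimate subtracted. The
sigmas are in frames; the temporal reading is the only one under which a
50-sigma blur isolates static structure. Linearity makes suppression of
time-constant content exact (a constant series is a fixed point of both
blurs), and reflect boundaries avoid edge dimming that would truncate
early/late growth events. Negative values are kept.

Kymographs sample the (separated) movie along a 1-µm-wide line per frame
with the same width-averaging as profiles: row t = frame t. A dash with
endpoint deltas (Δx, Δy) in kymograph pixels yields
track = |Δx|·Δs, lifetime = (Δy/Y)·T = Δy·Δt, rate = track/lifetime.
Projections are computed from endpoint deltas, never trigonometrically —
exactly equivalent to the L·cosθ / L·sinθ formulation for isotropic
kymograph pixels (property-tested) and robust to anisotropic axes. Dashes
are orientation-normalized so time increases; retrograde events keep a
signed Δx but track length uses the magnitude. A full-height dash spans
exactly T (180 s for the default movie).

Automatic dash detection (provided so the synthetic pipeline is end to
end; traced-dash CSV input bypasses it): threshold the positive part
(Otsu default), close single-row gaps, discard components whose peak is
below twice the threshold (noise floor), refine each component at half its
own peak, then fit position against time by intensity-weighted least
squares of per-row centroids and evaluate the line at the first/last
refined rows. Per-row centroids are unbiased by the symmetric PSF, the
half-max refinement recovers the true temporal extent of a
blur-smeared edge, and the slope fit excludes 4 rows at each end (scaled
down for short dashes) because the temporal blur holds the apparent
position stationary while a comet fades in/out, which otherwise flattens
the slope by ~10 % at 20-s lifetimes. With these choices the 50-comet
reference movie is recovered with ~1–2 % error in mean rate and lifetime.

## Colocalization and puncta

Manders coefficients use the thresholded variant — both numerator and
denominator restricted to above-threshold pixels of the reference
channel — because identical per-channel thresholds are applied before
computing the coefficients; the variant id is recorded in the result.
M1 = M2 = 1 for a channel against itself, the coefficients are invariant
under a common positive rescaling of images and thresholds, and M1 is
non-increasing in the other channel's threshold.

Puncta are 8-connected components of `image > threshold` with area in
[2, 200] px (package defaults; surfaced in config since no published size
window exists), counted when the component centroid lies inside the mask —
centroid membership is deterministic for boundary-straddling dots. A
single-pixel cross-element closing bridges threshold-level noise dips
before labeling; measured over 2000 synthetic fields at SNR ≈ 7 and
4σ spot separation, this reduced miscounts from 3/2000 (split puncta,
no closing) to 1/2000, while a full 3×3 closing fused neighboring puncta
(11/2000). Per-cell counts require a caller-supplied labeled-region mask;
no segmentation is performed.

## Synthetic generator: what it emulates, and what it does not

Each generator renders one acquisition type with exact truth records:
axon arbors as 1-px rays dilated once (so binarization/skeletonization
behave as on real traces) with analytic crossing counts; growth cones as
filled ellipses with boundary-anchored filopodia; comet movies as moving
isotropic Gaussian spots (σ = 1.5 px, diffraction-limited scale) over
static spots with additive Gaussian noise (optional Poisson resampling);
two-channel pairs sharing an exact fraction of spot centers, all other
centers > 4σ apart; puncta fields with known inside/outside counts, ≥ 4σ
separation and a 2-px margin from the mask boundary (a punctum centered on
the boundary has no well-defined side, so exact-count comparisons would be
ill-posed); profile phantoms as straight stripes with a prescribed axial
intensity plus a uniform baseline. Identical parameters and seed reproduce
every output bit for bit.

The reference dynamics scenario — 50 comets on a 50-µm axis over 180 s,
velocities U(0.05, 0.15) µm/s, lifetimes U(10, 30) s, noise at a fifth of
the comet amplitude — draws each comet's kinematics once and
rejection-packs start positions/times so space-time footprints (padded by
0.8 µm and 3.5 s) are disjoint, emulating kymographs in which individual
growth events are distinguishable enough to trace. Packing proceeds from
the largest footprint down, which keeps the uniform marginals while
fitting the domain.

Not emulated: real optics (PSF shape, photobleaching, camera gain),
3-D stacks, curved/branching axons in movies, comet pauses or
catastrophes, intensity heterogeneity between comets, and hand-curation
of binarized fields. Passing tests therefore demonstrate correctness of
the measurement definitions and their numerics on resolvable,
well-calibrated scenes — not robustness to optical artifacts or crowded
fields where events overlap.

## Problem sizes and determinism

The verification suites use 20 random arbors (3–12 rays, 100–1400 µm,
0.5-µm pixels), 30 random skeleton graphs (≤ 200 nodes), 10⁴ random
dashes, one 360-frame 520×30 px movie with 50 comets, 40-spot
colocalization pairs at overlap fractions {0, 0.25, 0.5, 1}, and 20 puncta
fields — sizes at which every oracle is exact or near-exact and the whole
suite runs in well under a minute per stage on one CPU. All randomness
flows through seeded `numpy` generators; pipeline runs record their
configuration, seed, input hashes and package version in a JSON manifest,
and rerunning a manifest's configuration reproduces every CSV byte for
byte.

## Known limitations

- Perimeter carries the marching-squares staircase excess (~5 % on
  circles); consistent across conditions but not an unbiased estimator.
- Filopodium lengths are junction-to-endpoint geodesics and include the
  intra-body segment; with large round bodies this inflates lengths by up
  to the body half-width.
- Arc-run Sholl counting saturates where processes are closer than the
  stroke width (near the origin, just past branch forks) — an intrinsic
  property of intersection counting at finite resolution, reproduced
  faithfully by the analytic oracle.
- Automatic dash detection assumes anterograde-dominant, non-crossing
  dashes; crossing events merge into single components and should be
  traced manually.
- Otsu thresholds are data-dependent; cross-condition comparisons should
  fix thresholds explicitly (the config defaults leave them fixed-value
  `None` only for single-image exploration).
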