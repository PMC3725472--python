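# Methods

This note records the models, numerical choices and their rationale, and the
limits of what the package's tests demonstrate.

## World model and enclosures

The world is a continuous 2-D plane with vertical, textured wall segments of
uniform height (default 2.0 world units; units are arbitrary — nothing in
the model fixes a physical scale).  Origin is at the lower-left of the
bounding box, y points up, angles run counter-clockwise from +x; radians
internally, degrees at every user interface.  An enclosure's boundary must
form closed loops: the gap check pairs the multiset of segment endpoints
within ε_gap = 10⁻⁶ world units and reports dangling endpoints.  Obstacles
are axis-aligned rectangles stored as 4-segment groups that participate in
raycasting and validity exactly like boundary walls; point-in-enclosure is
the even-odd crossing rule over the union of all segments, which handles
boundary plus obstacles in one query.

Preset generators: a rectangular box, a circle (regular n-gon inscribed in
the radius), and a star maze with `arms` equidistant arms of given width and
length around a central radius (4·arms segments; a parameter error explains
when adjacent arms would overlap at the center).  Custom plans are plain
text, one `x1 y1 x2 y2 [texture]` line per segment — chosen over any binary
format for hand-editing and diffing.  Wall textures come from a registry
that either cycles through the available set or applies one texture
everywhere; five procedural patterns (stripes, checker, noise, diagonal, at
distinct mean luminances) are built in so the package needs no bundled image
assets, and user image directories override them.

## Movement model

The rat is controlled statistically, never directly.  Random foraging draws
a turn u ~ Uniform(−arc, +arc) per step and blends the proposed direction
with the current one: dir_new ∝ momentum·dir(h) + (1−momentum)·dir(h+u).
This realizes "higher momentum → straighter paths", keeps the expected
signed turn at zero in open space, and bounds every heading change by arc.
Waypoint following steers greedily toward the current waypoint with the
turn clipped to ±arc, plus Gaussian positional noise (path_noise, default
0.5 world units) for irregularity; a waypoint counts as reached within a
capture radius of 2·speed (prevents orbiting under coarse steps), after the
last waypoint the route wraps around (`loop`) or the agent is reset to the
first waypoint.

Wall handling keeps three invariants simultaneously: every emitted position
is valid at the min_wall_dist margin, per-step displacement never exceeds
speed, and |Δheading| ≤ arc.  A blocked step searches candidate headings
within ±arc of the previous heading (steps of arc/8, alternating sides),
then retries at halved and quartered speed, and as a last resort stays in
place and turns by exactly arc — so the agent pivots out of corners over a
few steps rather than tunnelling or violating the turn bound.  A stall with
arc = 0 is unrecoverable and raises a simulation error.  A waypoint the
agent cannot approach for 500 consecutive steps raises an error rather than
looping forever.

Defaults (speed 0.2 wu/step, momentum 0.6, arc 60°, min_wall_dist 1.0) give
a 20,000-step walk that covers a 10×10 box densely — the study conditions
for the scaled end-to-end runs.

## Renderer

A software raycaster replaces hardware rendering so frames are deterministic
and dependency-free.  Column c of a W-pixel frame looks along azimuth
heading + fov/2 − c·fov/(W−1); the W−1 divisor renders both FoV edge rays,
making the span between first and last column exactly the field of view
(320° rat vision, 55° camera mode).  This is an equidistant-azimuth
(cylindrical) projection — a planar perspective projection cannot represent
a 320° field.  Per column one ray is cast; the wall fills a vertical span of
height_px · wall_height / distance pixels centered on the horizon, clamped
to the frame, with nearest-neighbour texture sampling (one texture repeat
per 2 world units of wall).  Sky above and floor below are fixed gray levels
(200 and 40): the vertical luminance step supplies the low-level structure
the first SFA layer needs without modelling textured floors.  No fog or
distance shading.  Default frame size is 320 × 40 grayscale — not free: it
is forced jointly by the 63 × 9 layer-1 grid and the receptive-field tiling
below.

## SFA core

The fitting pipeline per node is: (optionally quadratically) expand →
add seeded Gaussian regularization noise (fitting only) → center → whiten →
eigendecompose the forward-difference covariance, keeping the k smallest
eigenvalue directions; the eigenvalues are the Δ values.  Details:

* Temporal derivative: forward differences, ẏ(t) ≈ y(t+1) − y(t); T
  samples give T−1 derivative samples.  Moments use the 1/T (population)
  convention throughout.
* Whitening keeps principal directions with eigenvalue > 10⁻⁷ × the
  largest; near-degenerate directions (e.g. constant sky pixels) are
  dropped instead of amplified.  A rank short of the requested output count
  raises an error advising noise when σ = 0, and silently reduces the
  output count otherwise.
* Regularization noise is an absolute seeded σ (default 10⁻⁴) added to the
  expanded signal during fitting only.  An absolute σ (rather than a
  per-batch relative one) keeps the accumulated moments independent of the
  batch split; frames are normalized to [0, 1] and inter-layer signals are
  unit variance, so 10⁻⁴ is of the order of 10⁻³–10⁻⁴ relative in practice.
* Batch training accumulates Σz, Σzzᵀ and Σdz dzᵀ additively; the last
  frame of each batch is carried into the next so the boundary difference
  is included.  Training is therefore *exactly* independent of the batch
  size (the NumPy generator's draw stream is also split-independent), which
  the batch-equivalence test asserts at 10⁻⁶ and which in fact holds to
  machine precision.
* Constraints (zero mean, unit variance, decorrelation) hold on the fitting
  ensemble by construction — whitening is exact for the empirical
  covariance — and the trainer stores the measured residuals; on held-out
  data they hold only approximately.
* `apply` is a deterministic affine-plus-expansion map, injects no noise,
  and accepts a single frame (the model responds in real time to one input).

The ICA step is rotation-only FastICA on the (already white) SFA outputs:
tanh-nonlinearity negentropy contrast, symmetric decorrelation each
iteration, seeded random orthogonal initialization, tolerance 10⁻⁵, at most
500 iterations.  Being a rotation it preserves output variance exactly.
Non-convergence is a warning plus the best iterate, flagged on the model —
on some fixtures (notably small synthetic networks) the contrast landscape
is flat and the rotation is still perfectly usable.

## Hierarchy

Receptive fields and strides are not dictated by the layer grids alone; the
package uses layer 1 rf 10 × 8 px stride 5 × 4 (tiling 320 × 40 exactly to
63 × 9 with ~50% overlap) and layer 2 rf 14 × 5 nodes stride 7 × 4 (63 × 9 →
8 × 2); layer 3 is one node over all sixteen layer-2 nodes.  Node internals
everywhere: linear SFA to 16 dims → quadratic expansion (16 → 152) → SFA to
32 outputs; the hierarchy exists precisely so each eigenproblem stays this
small.  Layer-2/3 inputs are concatenations of the 32-signal node outputs
inside the window (layer-3 input 16·32 = 512 dims).  Fitting noise is
applied at each node's first (input) stage only: the second stage consumes
the first stage's whitened, unit-variance outputs, which are non-degenerate
by construction.

Layers train strictly bottom-up; after each layer the whole sequence is
propagated to form the next layer's input.  Generic training fits the lower
layers on arbitrary image sequences (conformed with the center-crop tool)
and freezes them; `train_top` then fits only the top layer (+ICA) per
environment, and `add_ica` attaches the sparse-coding rotation to a trained
network without touching any SFA parameter.  The model keeps no memory
state: retraining the top layer in a second enclosure destroys the first
enclosure's place code (asserted as median |r| < 0.5 between before/after
maps).

A reduced architecture — input 64 × 16, rf 9 × 8 stride 5 × 4 → 12 × 3, rf
4 × 3 stride 4 × 1 → 3 × 1, single top node, same node internals — is a
first-class configuration for fast experiments; the 320 × 40 default
reproduces the full geometry.  Training is single-threaded and
deterministic per seed (per-node seeds are spawned from one master
SeedSequence); GPU and cluster parallelism are out of scope.

## Sampling and scores

Place maps: the enclosure is discretized at a default spacing of 1/20 of
its larger extent (map smoothness vs. runtime); every valid cell is rendered
at the eight compass headings, giving per signal eight directional maps
plus their pointwise average.  Head-direction curves average each signal
over a seeded sample of valid positions per heading.  Because the ICA (and
SFA) sign is arbitrary, each signal is flipped — consistently across its
nine maps — so its spatial maximum exceeds |minimum|; plot color scales are
per-map min–max, since absolute response scales carry no meaning after the
rotation.

The directionality score of a signal is 1 − min over directions of the
Pearson correlation between directional and averaged map, clamped to
[0, 1]: 0 for a perfectly direction-invariant place field, large when some
traversal direction sees a different field.  Constant maps make the
correlation undefined and raise an error rather than returning a value.

## Synthetic data and what the tests show

All training data are generated by the package itself (trajectory +
renderer); tests additionally use smooth drifting sinusoidal "videos" and
toy source mixtures where ground truth is known.  The rendered world
emulates the geometry of real foraging — egocentric panoramic input whose
slow variables are position and heading — but not photometric reality: no
lighting, shadows, floor texture, motion blur, or visual noise, and textures
repeat periodically.  Passing tests therefore show that the algorithmic
pipeline extracts the slow spatial variables this visual world actually
contains; they do not show robustness to real-camera nuisances.

Problem sizes are scaled to desk hardware as the package's own test
conditions: the end-to-end place-field run uses the reduced architecture on
a 20,000-step walk (place fields are already robust at a few thousand
steps); the directionality comparison trains the route network on a 12,000
step one-way loop; determinism is asserted on an 800-step pipeline, since
bit-identity is size-independent.

## Known limitations

* The frame container and network file are this package's own documented
  formats; no compatibility with any other tool's files is claimed.
* Whitening-cutoff rank reduction can silently shrink a node's output count
  on pathologically uniform input regions; downstream layers pad with
  zeros.
* The wallcheck overview guarantees pixel-exact walls only when drawn
  without antialiasing; grid labels may overlap walls for extreme aspect
  ratios.
* Very narrow passages (width ≲ 2·min_wall_dist + speed) can pocket the
  agent; it escapes by pivoting but coverage of such regions is poor.
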