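# Methods

## Problem and model

Thin-leaved plants (wheat is the motivating case) defeat spatially blind
segmentation: leaf tips fade toward the background, and at a twist the leaf
turns edge-on so its apparent width pinches to (sub-)pixel scale, splitting
one leaf into disjoint mask fragments.  `leafrefine` treats the inaccurate
binary mask as a *shape prior*: wherever the mask boundary turns sharply, a
feature (tip, axil, twist, intersection) was probably clipped nearby, and
the image's local edge orientations say in which direction it lies.  The
refinement therefore combines three classical ingredients - contour
curvature analysis, orientation-field tracing, and fixed-endpoint active
contours - into a hybrid, spatially guided pass that only ever *adds*
plant area to the initial mask.

Coordinates are (row, col), 0-based, with pixel centres at integers;
sub-pixel positions are used everywhere downstream of contour extraction.
An angle theta denotes the unit vector (cos theta, sin theta) in (row, col)
components.

## Stage by stage

**Cleaning and contours.** The mask is opened with an m x m square (erosion
then dilation): this removes speckle noise and never adds foreground, which
is what the cleaning step is for.  Outer boundaries of 8-connected
components are traced at sub-pixel precision (marching squares on the
padded component, largest loop only - leaves are thin ribbons, inner holes
carry no information); orientation is normalized to counter-clockwise in
the (row, col) plane so the outward normal of a tangent (dr, dc) is
(dc, -dr).

**Contour smoothing and curvature.** Each closed contour is smoothed by a
Gaussian-weighted circular moving average over offsets -r..+r with weights
exp(-k^2 / (2 (r/2)^2)); raw threshold boundaries are too jagged to carry a
meaningful curvature signal.  Signed curvature uses circular central
differences; a counter-clockwise circle of radius R measures +1/R.

**Control points.** Peaks of |kappa| (strict local maxima over +-r, with a
one-sided non-strict comparison so a two-point discrete plateau yields
exactly one peak) above kappa_min become control points.  Walking from a
peak toward both sides, the first index that is a local |kappa| minimum or
falls below 0.1 px^-1 becomes the anchor p_L / p_R; the walk toward
increasing indices stops one step short of the other anchor so the two are
always distinct.  D = |p_L - p_R| estimates the local leaf width.

**Orientation field.** The guiding signal is the edge-*tangent* angle: the
image gradient (central differences inside, one-sided at borders, after
isotropic Gaussian smoothing with std sigma) rotated a quarter turn, kept
as a full 0..2 pi angle.  On the two sides of a bright ribbon the tangents
are antipodal, so a histogram of tangent angles over a w x w window
straddling a leaf shows two dominant modes ~pi apart while noisy background
spreads uniformly.  Zero-gradient pixels carry no orientation and are not
counted.  The histogram is circularly smoothed with a 3-bin moving average.

**Mode pairing.**  The first mode is the largest circular local maximum;
the second is the strongest local maximum within 45 degrees of the first
mode's antipode, falling back to the exact antipode when none exists.  The
antipodal window matters: near a truncated fragment's blunt end the cap
edge produces a third orientation ~90 degrees off, and without the
restriction it hijacks the direction average and steers the particle
sideways.

**Step direction.** With reference direction V (the contour normal on the
first step, the previous step after that), the mode differing most from V
is labelled theta_2 and reversed:
theta_bar = (theta_1 + theta_2 + pi sgn(theta_1 - theta_2)) / 2,
sgn(0) := +1.  The per-step change of heading is clamped to 30 degrees - a
leaf edge cannot turn faster per pixel of arc, and the clamp keeps noise
modes in weak-gradient windows from spinning a particle in place.

**Stopping criteria**, checked in sequence every step:

* *Tip* (outward particles): the smoothed histogram count at theta_1's bin
  drops to <= epsilon - the travel direction has lost its edge support.
* *Axil* (inward particles): along the line through the particle
  perpendicular to its motion, the dot product between the tangent field
  and the travel direction is sampled at unit spacing and smoothed over 3
  samples.  Strong lobes (|s| >= 0.6) immediately left and right mark the
  notch walls; when the first extremum on *both* sides flips sign or
  vanishes, the vertex has been passed.  (A directional tangent field gives
  the two walls mirrored signs - (+,-) left-to-right in a dark notch,
  (-,+) inside a bright ribbon - so the flip test is sign-agnostic, and the
  chirality distinguishes genuine notch travel from a particle that strayed
  into leaf material; the latter accumulates a "no notch evidence" streak
  and is abandoned after 8 steps.)
* *Edge / twist*: the particle entered another object's contour (point-in-
  polygon on the traced boundary).  Within w/2 of one of that contour's
  control points it crossed a twist of a broken leaf; otherwise two leaves
  intersect.
* *Aborted*: the particle left the image or exhausted its step budget
  (max(h, w)/4 steps by default - reported feature displacements are a few
  percent of the image diagonal, so a quarter-width walk has failed).
  Aborted particles contribute nothing downstream.

**Corner localization.** Tip and axil stops are refined by maximizing the
Harris-Stephens response R = det M - 0.04 trace^2 M (structure tensor of
first derivatives, Gaussian-integrated with sigma_c = 2, reflective
boundaries) inside the w-window around the terminus.  Run globally the
detector would drown in unrelated corners; inside the small window exactly
one corner is expected and dominates.

**Snakes.** Each surviving particle yields a left/right pair of open
curves: the path translated +-D/2 along its orthogonal, head pinned at
p_L / p_R, tail pinned at the corner (tip/axil - both tails coincide), at
the matched foreign control point's anchors (twist), or at +-D/2 along the
foreign contour's tangent at the entry point (edge).  Curves are resampled
to ~1 px spacing.  The energy

    E = sum_i alpha |v_{i+1} - v_i|^2 + lambda E_ext(v_i),
    E_ext = -|grad(G_sigma * I)|^2

is minimized by semi-implicit Euler: the membrane term is solved implicitly
(tridiagonal system with Dirichlet endpoints), the external force applied
explicitly through bilinear interpolation, with step size starting at
1/(4 alpha + 1) and a backtracking line search that halves the step until
the energy decreases - total energy is non-increasing by construction.
Points are resampled to ~unit spacing every 25 iterations without reducing
the point count (uniform spacing minimizes the membrane term for a fixed
count, so re-measured energy cannot jump).  Iteration stops when the
largest displacement falls below 0.05 px or after 500 iterations.  Only a
first-order internal term is used: the model has exactly two weights, one
shortening the curve and one attracting it to edges.  A pair whose evolved
curves end up more than w/2 from their initialization (max point-to-
polyline distance) has latched onto an unrelated edge and is discarded;
genuine recoveries move a few pixels at most.

**Composition.** Each pair's circuit (left curve, tail chord, reversed
right curve, head chord) is rasterized with Bresenham strokes, dilated by
one pixel to close sub-pixel gaps, flood-filled from the border complement,
eroded back, and unioned with the *original* initial mask.  Re-rasterizing
the object contours themselves is deliberately avoided: rounding sub-pixel
boundary points inflates every object by a half-pixel halo that costs more
overlap than the recovered features gain.  The union guarantees the
monotonicity invariant (output is a superset of the input) and makes
composition idempotent.

## Parameters

| name      | meaning                                   | default | scaled (9 px leaves) |
|-----------|-------------------------------------------|---------|----------------------|
| m         | opening element width (px)                | 5       | 3                    |
| r         | contour smoother radius (points)          | 10      | 5                    |
| w         | moving-window width (px)                  | 20      | 20                   |
| sigma     | image Gaussian std (px)                   | 1       | 1                    |
| alpha     | snake length-penalty weight               | 7       | 7                    |
| lam       | snake edge-attraction weight              | 1000    | 1000                 |
| epsilon   | tip criterion count threshold             | w/4     | w/2 = 10             |
| kappa_min | control-point curvature floor (px^-1)     | 0.15    | 1.1/width = 0.122    |
| n_bins    | orientation histogram bins                | 90      | 90                   |
| max_steps | particle budget (0 = max(h,w)/4)          | 0       | 0                    |

The defaults suit mid-resolution imagery with leaves a few tens of pixels
wide.  `RefinementConfig.for_leaf_width(width)` applies the scaling rules
that govern the resolution-dependent knobs: the window spans about twice
the leaf width (background visible on both sides, neighbours excluded),
the smoother radius is about half the width, and kappa_min sits at half
the curvature of a blunt leaf-end cap (2/width).  The tip threshold
deserves its own note: the criterion compares the count at a histogram
*mode*, and in pure background the strongest of ~n_bins near-Poisson bins
reaches about w^2/n_bins + 3 sqrt(w^2/(3 n_bins)) (~9 for w = 20,
n_bins = 90) while a genuine leaf-edge mode concentrates ~15-25 counts;
epsilon = w/2 separates the two, whereas w/4 never fires.

## Synthetic study conditions

The generator renders 3-5 anti-aliased ribbon leaves (quadratic Bezier
centerlines fanned about vertical with jitter, base width 7-11 px, linear
taper to 25 % at the tip) over a noisy background (mean 0.35, Gaussian
noise std 0.03, optional band-limited "coarse soil" texture), with a solid
crown disc at the common base as real shoots have.  Leaf intensity is 0.8,
fading linearly beyond 55-65 % of arc length to ~0.45-0.49 at the tip; a
twist pinches the width by 80 % and dips the intensity to ~0.47 (the faint
sliver of a leaf seen edge-on).  The initial segmentation is a 0.55
threshold followed by a 3 x 3 opening; by construction it terminates before
every faded tip and splits every twisted leaf, while ground-truth masks,
per-leaf labels and tip coordinates are exact.

What the fixtures do *not* emulate: real soil texture and shadows
(gradients there are weaker and more isotropic than real clutter), colour
information, specular highlights, overlapping plants, and perspective
blur.  Passing the surrogate study shows the machinery recovers faint tips
and bridges twists under controlled contrast and noise; it does not bound
performance on field imagery, where background gradients compete with leaf
edges in the orientation field and the improvement shrinks as background
inhomogeneity grows.

At these conditions (ten 512 x 512 scenes, seeds 0-9) the refinement
reduces the mean tip distance to ~0.2 of its initial value, corrects ~97 %
of the breakages and improves the Dice overlap in 9 of 10 scenes; the
whole study runs in a few seconds on one CPU.  These problem sizes were
chosen so the full suite and the acceptance script each complete within
minutes.

## Numerical choices and degenerate inputs

* Contours shorter than 2r+1 points skip smoothing (with a warning);
  components whose boundary has < 8 points are ignored.
* Repeated contour points get curvature 0; zero-length tangents make the
  normal undefined and the control point is skipped.
* Normal orientation is decided by probing the mask 2 px along both
  candidates; if both probes agree, the counter-clockwise polygon
  convention decides (with a warning).
* The initial inward/outward choice adds a trial point at +-3 px along the
  normal and keeps the direction that lengthens the local polyline; exact
  ties choose outward.
* Histogram bin boundaries map angles by floor division; mode ties break
  toward the lower bin index.  An all-zero histogram (possible only in a
  window of exactly-flat pixels) aborts the particle.
* Any exception while processing one control point skips that control
  point, never the run.

## Known limitations

* Axil recovery under union-only composition can only add area; when the
  initial mask already covers an axil correctly, a fired axil stop adds a
  small wedge of the notch.  The chirality evidence and the drift gate keep
  this below the gains elsewhere, but scenes whose only defects are axils
  would see no net benefit.
* Two leaves crossing *within* the initial mask form one component, so the
  edge/twist criteria (defined via "another contour") cannot fire between
  them; mislabelled particles there are contained by the step budget and
  the drift gate rather than classified correctly.
* The tip threshold trades premature stops on faint leaves against delayed
  stops in background; with very low contrast (< ~0.1 above background)
  tips stop early by up to half a window.
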