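# Methods

## The construction

The benchmark scene is built so that the true transformation is known
exactly, including where it is multi-valued or undefined. The fixed image is
rendered deterministically from a `SceneSpec`: a bright disk (the "ball",
default radius 42 px with mild radial shading so it is not one flat level) on
a band-limited random texture (uniform noise smoothed with a Gaussian of
σ = 3 px, rescaled into a dark-to-mid band so the ball stays the brightest
object). The moving image is the fixed image with its top-left
`region_width × region_height` rectangle copied and pasted `shift` pixels to
the right, over existing content.

Defaults: canvas 206×256 (width × height), region 156×196, shift 50. With
these values the pasted copy lands flush in the top-right corner
(156 + 50 = 206) and the scene contains all four ground-truth regions:

| label | mechanics                  | admissible displacements | area (default) |
|-------|----------------------------|--------------------------|-----------------|
| A     | copied, not pasted over    | {(0,0), (shift,0)}       | 50×196 = 9 800  |
| B     | copied and pasted over     | {(shift,0)}              | 106×196 = 20 776|
| C     | pasted over, never copied  | ∅ (undefined)            | 50×196 = 9 800  |
| D     | untouched                  | {(0,0)}                  | 12 360          |

Coordinates are 0-based with x = column (rightward) and y = row (downward);
a displacement u at fixed pixel (x, y) points to moving location
(x + u_x, y + u_y). Labels are derived from the copy/paste mechanics rather
than hard-coded rectangles, so non-default geometries (including
shift ≥ region_width, which empties B) label correctly.

Because the construction is exact, intensity constancy
`moving[y + u_y, x + u_x] == fixed[y, x]` holds bit-exactly for every
admissible u on A, B and D; the test suite checks this exhaustively.
Additive Gaussian noise is available (`add_noise`) but off by default: the
permutation-null identities below require exact intensity conservation, and
the benchmark's point is sharpest when the moving image is a purely
geometric rearrangement of the fixed one.

The `unique-ramp` texture assigns every pixel a distinct intensity (widening
the integer range past 8 bits when the canvas has more pixels than levels,
with the largest values placed inside the disk). It exists for oracle tests
where rank matching must be unambiguous.

## CURT

CURT sorts the pixels of each image in order of increasing intensity and
maps each fixed pixel to the moving pixel at the same index in the sort
order. By the rearrangement inequality this pairing minimizes the sum of
squared paired differences over *all* permutations, so it is the global
optimum of intensity similarity within the permutation group — while being,
by design, spatially meaningless. Two consequences are tested directly:

* **Rank-matching optimality**, verified against brute-force enumeration of
  all 720 permutations of 6-pixel images.
* **Permutation-null identity**: if the moving image is any spatial
  permutation of the fixed image, the sorted intensity sequences coincide
  and CURT's reformatted output reproduces the fixed image bit for bit, so
  RRMS = 0 and EID = 0 exactly and CC = 1.

Ties between equal intensities are broken by ascending row-major index in
both images (stable sort). Any tie rule gives identical similarity values
(tied pixels carry equal intensities); stability makes the permutation, and
hence the displacement field, reproducible. Images with unequal pixel counts
are rejected rather than resampled.

Field-based resampling (`reformat_by_field`) uses nearest-neighbor rounding;
CURT itself is purely discrete, and interpolation would break exact
conservation. Out-of-range samples clamp to the nearest edge pixel (count
reported on request); a periodic `wrap` mode exists for illustration but is
deliberately not the default — wraparound resampling is an artifact this
benchmark is designed to expose, not emulate.

## Similarity metrics

* **RRMS** (intensity units): √(mean (a−b)²). A metric on images; 0 iff
  identical.
* **CC** (dimensionless): Pearson correlation of paired intensities;
  undefined on constant images (raises). Note RRMS = 0 forces CC = 1 under
  this definition, and the package asserts that internal consistency.
* **EID** (bits by default): Shannon entropy of the normalized histogram of
  the integer difference image, one bin per integer value — exact and
  parameter-free for 8-bit data; 0 iff the difference is constant. Bin width
  (for non-integer data) and logarithm base are configurable.

These are the standard definitions; the metric layer is isolated so variants
can be swapped in.

## Correspondence evaluation

The pointwise error of an estimated displacement is its minimum Euclidean
distance to the admissible set — multi-valued truth scores the best
admissible match, since both mappings in region A are equally correct.
Region C (empty set) is excluded from every aggregate; its pixel count is
reported. Aggregates: mean, median, max, and fraction-correct at a tolerance
of 0.5 px by default (the sub-pixel rounding bound; configurable), with
per-region breakdowns. The Euclidean norm and the mean/median/max
aggregation are package choices — the criterion ‖T − T_true‖ fixes neither.

The dissociation report fits each method, computes its similarity triple and
its error summary, and ranks methods both ways: the similarity rank is the
consensus (re-ranked average) of the three per-metric ranks; the
correspondence rank orders by fraction-correct with mean error as
tie-breaker. Methods whose two ranks disagree are flagged as dissociated.
On the default scene CURT is similarity-best and correspondence-worst in
essentially every seed, which is the phenomenon the package demonstrates.

## What the generator does and does not emulate

The synthetic scene reproduces the *structure* of the demonstration — a
salient object, non-constant texture, and a copy-shift-paste geometric
rearrangement with duplicated, displaced, overwritten and unmoved content —
not any particular photograph. Passing tests therefore show that the
dissociation is a property of similarity-based evaluation itself, not of
one image: it emerges on every seeded texture. They do not quantify how
severe the effect is on real data (noise, illumination change, non-rigid
motion, intensity non-constancy), and the default noiseless setting is the
*favorable* case for similarity metrics — adding noise only blurs the
permutation-null identities, not the dissociation.

## Numerical and design choices

* Problem sizes: acceptance-level checks use 100 seeds of the full 206×256
  scene, 100 seeds of 64×64 permutation nulls, and exhaustive enumeration at
  ≤9 pixels; the whole suite runs in seconds on one core.
* Admissibility at floating tolerance: error 0 vs. "admissible" is
  distinguished at 1e−9 px in the contract tests.
* Degenerate inputs: constant images raise on CC; empty method lists,
  malformed configs and unknown config keys are rejected loudly (no silent
  defaults).
* The oracle method fills region C with (0,0); C is excluded from error
  aggregates, but the choice does affect the oracle's *similarity* scores
  (it resamples overwritten content), which is itself illustrative: even a
  perfectly accurate field does not maximize similarity.
* Overlay palette (positive/negative u_x → red/cyan, u_y → yellow/blue,
  opacity by magnitude, white box around the copied region) is purely
  presentational.

## Known limitations

Single 2D grayscale pair, same-size images, translation-only ground truth
from a single copy-shift-paste event; no subpixel matching, no non-rigid
truth, no landmark- or overlap-based accuracy measures, no 3D. The method
seam (`dissociation_report` accepts any mapping of name → estimator with
`fit`/`transform` and a `displacement_field_`) is the intended extension
point for benchmarking real registration algorithms.
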