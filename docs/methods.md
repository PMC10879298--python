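# Methods

## Problem and data model

The package classifies macrophage polarization subtypes (M0, M1, M2) from
single-cell centroid trajectories recorded in time-lapse phase-contrast
cultures. A trajectory is an ordered sequence of (frame, t, x, y) samples
for one cell at a fixed frame interval; the reference recording geometry is
37 frames at 5 minutes per frame (180 min). Ground-truth labels come from
morphology clusters — circular (Cluster C), protruded (Cluster P) and
elongated (Cluster E) cells — used as proxies for M0, M1 and M2
respectively; the alias map is a fixed bijection. Coordinates are kept in
the units of the upstream tracker (image pixels by default); no unit
conversion is applied, and every downstream step is either
translation-invariant or made so by centering.

Only cells tracked continuously from the first to the last frame enter the
analysis (frames exactly {0, …, T−1}); partial tracks are dropped by
`filter_complete_tracks`, which is idempotent and order-preserving.

## Trajectory metrics

For points p_0..p_{T−1}: path length (sum of consecutive Euclidean
distances), net displacement (first-to-last distance), convex hull
perimeter and area, and maximum pairwise distance (the set diameter).
The hull is strict — collinear edge points are not vertices — so the
vertex set is unique and can be checked exactly against a brute-force
oracle. Hull computation delegates to Qhull (scipy); degenerate inputs are
handled explicitly: coincident points collapse to a single vertex,
collinear points to their two extremes. Degenerate-hull conventions follow
the flattened-polygon limit (2-vertex perimeter = twice the segment length,
area 0; 1-vertex hull = (0, 0)), which keeps perimeter ≥ 2 × diameter true
with equality in the collinear case. The diameter is an exact O(n²) scan
(scipy `pdist`), cross-checked in tests against an independent pure-python
loop.

## Synthetic motility model

Real labeled track sets for this problem are not publicly deposited, so the
package ships a generator whose three processes are the minimal stochastic
models of the observed migratory signatures:

* **Spinner (M0)** — noisy circular orbit: point k sits at angle
  φ0 + k·Δ on a circle of radius r, plus isotropic Gaussian noise.
  Defaults: r = 4 px, Δ = 2π/12 rad/frame (three full revolutions over 36
  steps, so the cell ends near its start), noise sd 0.5 px.
* **Jumper (M1)** — jump–diffusion with mean reversion: per frame, a jump
  of length U(7, 14) px in a uniform direction with probability 0.25, else
  a Gaussian step (sd 1 px); after each step the position relaxes toward
  the start by κ = 0.15.
* **Mover (M2)** — persistent random walk: heading diffuses with sd 0.5
  rad/frame; step length 1.6 px plus Gaussian noise (sd 0.35), truncated
  at zero.

The defaults were frozen once so that ensembles of ≥ 100 cells per class
reproduce, with clear margins, the culture-level orderings that motivate
the metrics: mean hull area and perimeter M2 > M1 > M0; mean maximum
pairwise distance M1 well above M0 with M1 and M2 similar (the |M1−M2| gap
smaller than the M1−M0 gap); mean net displacement M2 > M1 > M0. These
orderings hold for every seed tried and are asserted statistically in the
tests (means over 100 cells/class), never as point values.

One shared generator, seeded from the config, is consumed class by class
(M0, M1, M2) and cell by cell, so enlarging the dataset never perturbs
earlier draws.

What the generator does *not* emulate: tracking noise and gaps, cell
division and collision, phenotype switching within a culture (a mixing
fraction was considered and left out as out of scope), and the
heavy-tailed heterogeneity of real cells. Passing tests therefore
demonstrate that the pipeline machinery is correct and that the classifier
can learn motility classes of this separation — not that real cultures are
classified at the same accuracy.

## Augmentation

Each labeled track is expanded by the eight symmetries of the coordinate
axes — identity, swap (y, x), the sign flips (−x, y), (−x, −y), (x, −y)
and the swapped flips (−y, x), (−y, −x), (y, −x). These form the dihedral
group of order 8; all are isometries, so every trajectory metric is
preserved (verified to 1e-9 relative tolerance in tests) while the
coordinate series the network sees changes. Variant ids are suffixed with
the op name, so repeated augmentation can never silently re-derive an
original. 70 cells yield 560 records; 71 would yield 568 — the pipeline
reports both counts in its logs and never reconciles them silently.

## Features and split

Each complete track becomes the vector
[x_0..x_{T−1}, y_0..y_{T−1}, path length, net displacement] of length
2T + 2 (= 76 at T = 37) with a one-hot label ordered (M0, M1, M2).
Coordinates are centered on the start point by default: this makes the
features translation-invariant and lets the origin-based symmetries act
about each cell's own starting position. Raw coordinates remain available
via a flag, and an optional z-scoring switch exists for experimentation;
both are off by default. The two scalar features appear once per record,
not per frame.

The split sorts records by cell id (input-order independence), applies a
seeded uniform shuffle, and takes floor(0.8·N) for training — 448/112 at
N = 560. Because the split happens **after** augmentation, symmetry
variants of one cell can land on both sides; this leakage-prone design is
deliberate (it matches how such small augmented datasets are commonly
split) and is flagged wherever validation numbers are reported. A
group-aware split (`group_by_origin=True`) that keeps all 8 variants of a
cell together is provided, off by default.

## Classifier

A dense feed-forward network: eight hidden relu layers of 10, 20, 32, 64,
64, 32, 20, 10 units, then a 3-unit softmax. Loss is categorical
cross-entropy; the optimizer is RMSprop at its conventional default
learning rate 0.001 (ρ = 0.9, ε = 1e-7); training runs exactly the
configured number of epochs (default 100) with minibatches of 32 and no
early stopping, regularization or dropout. The implementation is written
directly on NumPy with the standard framework conventions:
Glorot-uniform initial weights, zero biases, per-epoch uniform shuffling.
All randomness (initialization, batch order) derives from the config seed,
so train/evaluate runs are bit-reproducible on one machine (numeric
results remain device-dependent at float level). Argmax prediction breaks
ties toward the lower class index (M0 < M1 < M2). Histories (train and
validation loss and accuracy) are recorded once per epoch on the full
sets.

Evaluation produces a 3×3 confusion matrix of counts, row-normalized to
percentages (empty rows stay zero); rows are the true morphology clusters,
columns the predicted subtypes, and the diagonal the per-class accuracy.

## Numerical choices and degenerate inputs

* Hull collinearity tolerance: cross products below 1e-12 relative to the
  squared coordinate scale are treated as collinear.
* Test float comparisons use 1e-9 relative tolerance except where
  exactness is guaranteed by construction (counting, degenerate limits).
* Mover step lengths are truncated at zero rather than reflected.
* Tracks shorter than 2 points are rejected by every metric with the cell
  id in the error message.
* CSV round trips are exact: floats are written at shortest
  round-trippable precision and parsed with the round-trip parser.

## Problem sizes

The shipped benchmark uses 70 cells per class (210 tracks, 1680 augmented
records, 1344/336 split) for end-to-end classification and 100 cells per
class for the metric-ordering checks; the geometry oracles run on ~200
random point sets of 3–500 points. At these sizes the full test suite and
the acceptance script each complete in well under a minute on one CPU.

## Known limitations

* Validation accuracy under the default (post-augmentation) split
  overstates generalization to unseen cells; use the group-aware split for
  honest estimates (accuracy then drops, and degrades smoothly as the
  simulated classes are made to overlap — a monotonicity the tests assert
  at three separation levels).
* The simulators are qualitative stand-ins; their parameters are not fit
  to any real track data.
* Variable-length tracks are out of scope: inputs to the classifier must
  be resampled to the training length explicitly by the caller; the
  package does not pad, mask or interpolate.
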