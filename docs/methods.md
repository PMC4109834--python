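# Methods

This note documents the models and procedures implemented in `figcat`,
the parameter choices that matter, and the places where the design was
genuinely open.

## Taxonomy

Figures are classified into five top-level categories — flow chart,
experiment, graph, mix, others — refined into eight leaf categories
(experiment → microscopy, gel electrophoresis; graph → line chart, bar
chart, spot chart, table). The default classifier works at the top level
(`C = 5`); leaf granularity is available via `train(..., granularity="leaf")`.
`mix` denotes compound figures whose panels belong to at least two
distinct top-level categories; it is reached either by training on
composite figures directly or through the panel-wise aggregation rule of
`classify_figure`.

## Panel segmentation

The input is smoothed with a Gaussian kernel (σ = 0.8, 3×3 footprint via
`truncate = 1.25`) and binarized; the binarization threshold is Otsu's
method on the smoothed image (a fixed threshold can be supplied, and
constant images fall back to a mid-scale cut). Dark pixels are
foreground throughout — figures in articles are ink on white.

Scanlines whose foreground count `N_p` is at most 5 are candidate
separators. Design choices here:

* **Runs of candidate lines collapse to one cut at the run's midline**;
  wide gutters would otherwise generate sliver cells.
* **Runs spanning an entire axis produce no cut**: a blank image carries
  no separation evidence.
* The cut grid is applied once (the cartesian product of horizontal and
  vertical cuts); panels are not re-split recursively.
* Cells below 1/20 of the **original** image area are dropped. Measuring
  against the original area (rather than the remaining area after
  earlier drops) is a deliberate choice; it makes the rule independent
  of cell enumeration order.

With no cuts at all the whole image is one region. Note the retained
cells are chosen by area only: a large cell that happens to be blank is
retained, which is why the synthetic two-panel composites frame their
panels (see below).

## Text regions

All layout features are defined over axis-aligned text rectangles
(0-based, half-open, `x` = column). Rectangles come from a ground-truth
manifest or from a pluggable detector; the baseline detector takes
connected foreground components, merges boxes that are horizontally
within 4 px of one another and vertically overlap by at least half the
shorter box (word → line grouping), and drops boxes under 9 px². It
favours recall — non-text ink also produces boxes — and emits line-level
groups. Any callable `mask → [TextRegion]` can replace it.

The entropy and structure features are computed on the **rasterized
text-region mask**, not the raw ink mask. This makes the descriptor a
pure function of text geometry: supplying ground-truth rectangles yields
features independent of whichever detector is plugged in.

## The 100-dimensional descriptor

Block layout (order is fixed): entropy-h (10), entropy-v (10),
Fourier-h j=1..5 (20), Fourier-v j=1..5 (20), regularity-h (10),
regularity-v (10), distance bands 0..4 (20).

* **Noise rule.** On every scanline, foreground runs shorter than 5 px
  are discarded before run statistics are computed.
* **Entropy.** Per scanline, the Shannon entropy (base 2) of the
  retained run-length proportions `p_i = r_i / Σr`; zero for at most one
  run. Per direction, a 10-bin histogram over `[0, max entropy in that
  direction]`, normalized to sum 1; the per-image range keeps the
  histogram informative because entropy has no universal upper bound.
  All-zero directions put all mass in bin 0.
* **Fourier structure.** Per scanline, magnitudes of DFT coefficients
  1–5 of the raw 0/1 signal (DC excluded; the noise rule is not applied
  here because the transform is about periodicity, not run statistics),
  divided by line length so values are resolution-comparable. Per
  coefficient and direction, the (lower quartile, mean, median, upper
  quartile) over scanlines. Magnitudes rather than raw complex
  coefficients are used — phases shift under translation and carry no
  layout information.
* **Gap regularity.** Per scanline, greedy centroid clustering of the
  gap lengths between retained runs: repeatedly merge the two clusters
  whose means are closest while that distance is ≤ τ (default 3 px).
  The score is the largest cluster's share of the gaps, in [0, 1]; fewer
  than two gaps score 0. Per direction, a 10-bin histogram over the
  fixed range [0, 1]. Tables concentrate mass near 1.
* **Neighbour distances.** Rectangle distance is the minimum boundary
  gap (`hypot` of the per-axis gaps, 0 for overlap). With `n` regions,
  `k = max(1, ⌊n/3⌋)` nearest neighbours per region are binned into five
  equal bands of `[0, d_max]` (`d_max` = largest pairwise distance, last
  band closed); per band, the quartile quadruple over regions. Fewer
  than two regions, or `d_max = 0`, yields the zero block. Neighbour
  ties are resolved by sorting distance values, which leaves the chosen
  multiset unchanged.
* Quartiles use linear interpolation at probabilities 0.25/0.5/0.75.

## Sparse-coding class models

Per class `j`, samples are represented by lasso codes against a learned
dictionary `D^(j)` whose columns lie in the unit Euclidean ball:

* **Solver.** Cyclic coordinate descent on
  `½‖x − Dα‖² + λ‖α‖₁` (tolerance 1e−9 on the coefficient change,
  at most 2000 sweeps), vectorized over samples. Solutions are checked
  against the KKT conditions (≤ 1e−6) and against an independent
  LARS implementation in the test suite.
* **Dictionary learning.** Alternating minimization: sparse-code all
  samples (warm-started from the previous codes, which makes the
  recorded objective non-increasing by construction), then update each
  atom by block coordinate descent and project onto the unit ball.
  Atoms are initialized from randomly selected class samples (seeded;
  with replacement when `m` exceeds the class size).
* **Incoherence.** With `η > 0`, the atom update for class `j` exactly
  minimizes its penalized quadratic given the other classes' current
  dictionaries: `(S_jj I + 4η P) d = r` with
  `P = Σ_{l≠j} D^(l) D^(l)ᵀ` (solved through one eigendecomposition of
  `P` per class per sweep), followed by projection. At `η = 0` this
  reduces *exactly* — same seeds, same arithmetic — to independent
  per-class learning, a property the tests assert bitwise.
* **Residual profile.** The code `α̂_{j,i}` is computed once per
  (sample, class) from the full 100-vector; `R[i,j,k]` is the squared
  residual of component `k` under that shared code, so
  `Σ_k R[i,j,k]` is the full squared residual. A per-scalar-feature
  dictionary reading would make each sub-problem a degenerate 1-D
  coding; the shared-code reading keeps the classifier's weighted sum
  consistent with the full reconstruction error.
* **Standardization.** Features are z-scored per component over the
  training set (zero-variance components pass through unscaled); the
  mean and scale vectors are stored in the model. Without this the
  histogram blocks (magnitude ~0.1) would be invisible next to the
  distance quartiles in the ℓ2 loss.

Defaults: `λ = 0.10`; `η = 0.05`; `m = min(class size, 50)` atoms; 30
outer iterations with early stop at relative objective change < 1e−5.
`λ` follows the published setup; `η` and `m` have no published values
and these defaults are the package's own, chosen so the incoherence term
is a perturbation (not the dominant term) and the dictionary is
near-complete for benchmark-sized classes.

## Feature weighting

The LP of the weighting module maximizes the margin `ε` by which each
training sample's weighted residual under its own class undercuts every
other class, with per-sample slacks and `ω` on the simplex. As printed,
the objective `(1/N)Σξ − ε` has a flat ray (adding δ to all `ξ_i` and to
`ε` changes nothing), so the optimum is non-unique; the implementation
multiplies the `ε` coefficient by `(1 − 1e−6)` to break the tie toward
the smallest slack/margin pair and bounds `ε` by the largest total
residual. Both changes are determinism devices; they do not materially
move the optimum. Solved with HiGHS via `scipy.optimize.linprog`;
feasibility is always guaranteed (uniform `ω`, `ε = 0`, large `ξ`).

On the synthetic benchmark the LP typically concentrates weight on a
handful of features (≈ 7 of 100 nonzero), which is the intended
behaviour: most components are redundant given the discriminative ones.

## Prediction and mixed figures

A sample is assigned to the class minimizing the ω-weighted squared
residual; ties break toward the lowest class index. Whole figures go
through `classify_figure`: segment into panels, classify each panel on
its own (clipped) regions, and report `mix` when panel predictions span
two or more distinct top-level categories. The aggregation rule is a
design choice of this package — a published counterpart rule is not
available — and it deliberately errs toward `mix` on disagreement.

## Synthetic figure generator

The generator emulates the *text-layout signature* of each class, which
is the only property the features see; ink content beyond text (curves,
bars, speckle textures, gel bands, connector lines) is rendered so that
segmentation and the baseline detector face realistic foreground, but no
glyphs are drawn. Backgrounds are white, ink dark (≤ 60). Layouts per
class: tables place text blobs on an exactly regular grid with rule
lines; flow charts scatter framed text boxes connected by lines; line,
bar and spot charts carry tick-label columns/rows along L-shaped axes
(bar charts add value labels above bars, spot charts a small legend);
microscopy renders a dense mid-tone speckle field with 2–4 corner
annotations; gel electrophoresis renders lanes with dark bands and one
label per lane; "others" is a caption-like paragraph of long text lines.
Multi-panel composites place two framed panels of distinct classes
separated by a 12 px blank gutter; the 3 px frames guarantee that no
scanline crossing a panel interior is blank, so the gutter (and outer
margins) are the only candidate cuts and the composite segments into
exactly two retained cells.

Figures are bit-deterministic in `(label, seed, width, height)`; dataset
seeds derive from a master seed. Default figure size is 256×256 and
default noise 0; optional salt-and-pepper noise exercises the 5 px noise
rule.

What the generator does **not** emulate — anti-aliased glyph shapes,
JPEG artifacts, gradient backgrounds, overlapping text, rotated labels,
photographic content — bounds what the benchmark shows: passing the
held-out benchmark demonstrates that the pipeline recovers categories
*from text-layout geometry alone* under controlled conditions, not that
it reaches any particular accuracy on figures harvested from real
articles, where text detection quality dominates.

## Benchmark conditions and problem sizes

The held-out benchmark trains on 20 and tests on 20 figures per
top-level class (100 each), repeated for 3 seeds, and requires mean
accuracy ≥ 0.90. Unit and property tests use small instances (toy
dictionaries of 2–15 atoms, region sets up to 9 rectangles, 200 random
lasso instances) where brute-force oracles — dense grid search for the
lasso, exhaustive pairwise enumeration for the distance block,
per-line recounts for projections — are exact and cheap.

## Known limitations

* The baseline text detector is a stand-in: it reports non-text ink as
  text and has no notion of scripts, rotation or font size. Real-corpus
  use should plug in a dedicated detector.
* Segmentation assumes rectangular panel layouts separated by blank
  gutters; collage-style figures with touching panels are returned
  whole.
* Grid-cell retention is area-based only, so large blank cells (wide
  margins in sparse figures) can be retained as panels.
* The incoherence update's joint objective is not guaranteed monotone
  for `η > 0` (the unit-ball projection follows an exact unconstrained
  atom solve); monotonicity is guaranteed and asserted at `η = 0`.
* The `mix` category is heterogeneous by construction; it is the
  dominant error mode on the benchmark.
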