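# Methods

## The encoding

A dice plot is a positional encoding for categorical co-occurrence. Given a
long-format table of (row, column, dot) records, each occupied (row,
column) pair becomes a die face on a grid; each level of the dot variable
owns one fixed pip slot, and the pip is drawn iff at least one record pairs
that level with that grid position. The assignment of levels to slots is a
single global bijection (`SlotMap`), so the reader compares dice purely by
which positions are filled. The design caps the dot variable at **six
levels**: beyond six, die-face patterns stop being preattentively
recognizable and the metaphor collapses. Validation rejects a seventh level
outright rather than truncating.

Pip coordinates live in the unit cell with v pointing up and come from a
seven-anchor vocabulary — corners at 0.2/0.8, edge midpoints at
(0.2, 0.5)/(0.8, 0.5), center (0.5, 0.5) — composed into the traditional
die faces (1 = center, 2 = opposite corners, 3 = diagonal + center,
4 = corners, 5 = corners + center, 6 = corners + edge midpoints). The exact
0.2/0.5/0.8 grid is our choice: it keeps a minimum pairwise pip distance of
0.3 (0.25 is the enforced floor), leaving headroom for the default pip
radius of 0.12 cell edges. The 2-/3-pip diagonal runs bottom-left →
top-right; a `mirror` flag reflects it, since both conventions appear on
physical dice. The `triangle3` variant (equilateral, vertex-up,
circumradius 0.3) is offered for three levels, where the diagonal reads
poorly. The slot count always equals the number of registered levels — a
four-level variable uses the four-corner face, not a sparse six-pip grid —
because the pip count itself encodes the category count.

## Orderings

Axis order is `as-is` (registry order), `manual` (a declared factor,
validated as an exact permutation of the observed labels), or `cluster`.
Clustering operates on **binary presence profiles**: for each axis label,
the vector over dot levels marginal over the other axis. The default
metric is Jaccard distance — natural for presence/absence, and two
all-empty profiles get distance 0 — with Hamming as an option; linkage is
average by default (single/complete available). The agglomeration is
implemented in-package with an explicit determinism contract: ties in merge
height break by lexicographic comparison of each cluster's smallest label,
and within a merge the cluster holding the smaller label goes left. Leaf
order is therefore a pure function of the label → profile mapping —
permuting input records can never change it — which an index-ordered
dendrogram implementation does not guarantee. The O(n³) pair scan is
irrelevant at the ≤ tens of labels this plot type can legibly display. No
dendrogram is drawn; only the leaf order is used.

## Domino extension

For multi-contrast comparisons, pip slots carry the contrast levels
(≤ 6), each tile splits into halves along the two levels of a binary
variable, and pips gain two continuous channels:

- **color**: signed effect size on a diverging ramp (`RdBu_r`) with the
  midpoint pinned at 0 and a symmetric domain [−M, M], M = max |value|
  unless overridden; values outside clamp. An all-zero input widens the
  domain to [−1, 1] so the map stays defined.
- **size**: nonnegative score mapped linearly from [0, max] to radii
  [0.04, 0.14] of the cell edge (an area-linear option uses the sqrt map).

The API treats the size channel as any nonnegative score; the fixtures and
docs use −log10 adjusted p, the conventional volcano-plot companion to a
fold-change color channel. The first split level is always the left (or
top) half in every tile. A record present with missing values is "tested,
no result" and renders as a hollow minimum-size pip; an absent
(contrast, half) combination draws no pip — the two are deliberately
distinguishable. Background tinting defaults off in domino mode (it crowds
the tile) but can be re-enabled. A domino table without a split variable
degenerates to single-half tiles — a dice plot with value-carrying pips —
which is also how a continuous channel is obtained in plain dice use.
In domino mode the dot role may simply alias the contrast column, since
contrasts are what occupy the pip slots.

## Geographic mode

One die per location, placed at a user-supplied lon/lat anchor under an
equirectangular projection (degrees → pixels linearly, north up) —
monotone in both axes and sufficient for glyph overlays; no projection
library is pulled in. A location's pip pattern equals the pattern the same
records yield in a single-column dice grid (mode equivalence). Region
outlines come from GeoJSON FeatureCollections (Polygon/MultiPolygon,
other geometries ignored) and render as neutral strokes beneath the
glyphs. Overlapping anchors are drawn as given with a logged warning; a
largest-ring centroid helper assists anchor construction but anchors
remain explicit inputs.

## Validation and numerical choices

- Level registries order levels by declared factor first, then first
  appearance; declared-but-unobserved labels are kept and surface as
  all-zero profiles / empty axis positions.
- Duplicate categorical keys collapse to the first occurrence (first-wins
  for continuous values) with a warning count; validation is idempotent.
- Continuous columns coerce via pandas; a present-but-unparseable value is
  an error, a genuinely missing one stays NaN. Negative significance
  scores are rejected at validation.
- Layout JSON serializes with sorted keys, compact separators and floats
  rounded to 6 decimals, so export→import→export is a byte-level fixed
  point; NaN exports as null.
- SVG output is deterministic text from stdlib XML serialization: one
  `<g>` per die with sanitized label-derived ids (deduplicated with
  numeric suffixes), `circle.pip` elements carrying `data-level` (and
  `data-split`) attributes, legend artwork under distinct `legend-*`
  classes. Background fills use alpha 0.35 so pips stay legible.
- Grid reading order is the heatmap convention: first row at top, columns
  rightward. Empty grid positions are omitted by default (`draw_empty`
  renders blank dice). The legend's key die shows only observed levels, at
  exactly the plot's slot coordinates.

## Synthetic fixtures

`make_pbmc_like` emulates the *structure* of a PBMC dysregulation summary:
`n_genes` = 40 genes × 8 PBMC cell types × 4 age-sex conditions
(YM/OM/YF/OF), presence Bernoulli(sparsity = 0.2) — chosen so a typical die
shows 1–2 pips, the sparse regime the plot targets — with the top 25 genes
by dysregulated-triple count kept. One XIST-like gene is deterministically
present in both female conditions for every cell type and never in males,
providing the sex-specific signal the background highlight showcases; its
determinism guarantees the signal and its top-k survival at every seed.
`make_zebra_like` emulates a multi-disorder differential-expression
summary: 4 neurodegeneration-linked genes (SPP1, APOE, SERPINA1, PINK1) ×
6 brain cell types × 5 disease-vs-control contrasts × 2 sexes; each
combination is tested with probability 0.9, effects drawn N(0, 1.5) (a
plausible log2FC spread for strongly dysregulated genes) and significance
Exponential(mean 2) as a −log10 p stand-in. Both generators are pure
functions of a single seeded `numpy` Generator — same seed, byte-identical
tables — and always emit tables that validate cleanly.

What passing tests on these fixtures shows: the layout engine's contracts
(conservation, fixity, ordering, determinism) hold on data with the real
use cases' shape. What it does not show: anything about real effect-size
distributions, gene–gene correlation, or whether a particular biological
dataset will be legible — fixtures are independent draws with none of the
block structure real expression data has.

## Problem sizes

The test suite and the acceptance script run on the fixture scales above
plus batches of 20–100 random tables of ≤ 50 records each — the scale at
which these plots are readable — completing in seconds on one CPU.

## Known limitations

- Six pip levels and two split halves are hard ceilings by design.
- No optimal-leaf-ordering/seriation; no dendrogram margins; no overlap
  avoidance in geo mode; no interactive output. SVG and layout JSON are
  the only writers; rasterization is left to external converters.
- Equirectangular projection only; glyphs far from the equator on
  wide-viewport maps will be positionally faithful but area-distorted
  backgrounds are the user's concern.
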