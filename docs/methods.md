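# Methods

## The plot and its contract

A correlation globe displays a table of pairwise correlations — two
variable labels, a domain (category) for each, a signed coefficient — as a
circular chord diagram: domains occupy contiguous rim arcs, variables
occupy slots inside their domain's arc, and each retained correlation is a
ribbon across the interior, colored by sign. The package draws what it is
given; computing the correlations (and any significance filtering) is the
analyst's job upstream. Coefficients are required to be finite and inside
[−1, +1]; a permissive mode keeps out-of-range values with a warning for
users feeding covariance-like scores.

The CSV header contract (`variable1,var1_domain,variable2,var2_domain,coef`)
is enforced exactly, after trimming cosmetic whitespace around each header
field: the documented header is often typeset with spaces after the commas,
but any renaming, reordering or extra column is a different format and is
rejected rather than guessed at. Error messages cite 1-based physical file
lines (header = line 1), tracked through blank lines and quoted newlines.

## Filter semantics

Filtering runs in a fixed order — self-pairs, duplicates, threshold,
domain exclusion — so that each dropped record has exactly one cause and
the drop report satisfies a conservation identity (kept + dropped per cause
= input count). Design choices that were genuinely open:

- **Strict threshold.** A record survives iff |coef| > t. The common verbal
  gloss of the cutoff ("over 0.3 or under −0.3") reads as strict, and
  strictness gives the clean degenerate case that t = 1 always yields an
  empty globe. A coefficient of exactly 0 never renders at any threshold:
  its sign, hence its color, is undefined.
- **Unordered duplicates.** Correlation is symmetric, so (A, B) and (B, A)
  are the same pair; the first occurrence wins. A repeated pair with a
  *different* coefficient is suspicious input and is flagged with a warning
  naming both file lines (`COEF_CONFLICT`); identical repeats warn
  `DUP_PAIR`. Warnings go through the `corrglobe.model` logger with
  machine-readable leading codes.
- **Domain membership is global.** A variable appearing under two domain
  labels anywhere in the file raises `DomainConflict`: silently splitting
  one variable across two rim positions would misrepresent the data.
- **Empty domains are pruned.** A domain whose ribbons are all filtered
  away leaves the rim, keeping arc length proportional to visible content.
  The alternative (an empty arc as a reminder of the domain's existence)
  is defensible but clutters high-threshold views.
- **Domain size** is the count of distinct member variables after
  filtering, not the ribbon count: each variable needs one rim slot, so arc
  length tracks slot demand.

## Layout

Angles are in degrees, clockwise, 0° at 12 o'clock (the convention of the
popular charting libraries this plot family comes from; purely cosmetic but
fixed so snapshots are stable). With n domains and gap g (default 2°, a
value that visually separates arcs without wasting rim), domain i of size
sᵢ gets extent (360 − n·g)·sᵢ/Σs; one gap follows each domain, so extents
and gaps close the circle exactly. Variables sit at midpoints of equal
slots, which keeps every anchor strictly inside its span for any slot
count.

Rim order is one of: descending size (default), input order, or an
explicit permutation; all ties everywhere break by first appearance in the
input, which makes the entire pipeline deterministic with no RNG.

A ribbon is one cubic Bézier: endpoints on the unit circle at the two
anchors, control points at the anchor directions scaled by (1 − pull).
`pull` = 0.8 reproduces the center-swept look of published globes; 0 gives
rim-hugging chords, 1 routes everything through the center. Intra-domain
ribbons (both endpoints in one domain — typically the majority in
co-occurrence data) need no special casing: two distinct variables always
have distinct anchors. Layout is computed on the unit circle; rendering
applies the only scaling.

## Rendering

SVG is the source of truth. The document is a pure function of
(model, layout, style): fixed element order (background, ribbons, rim
arcs, labels), ribbons sorted by |coef| ascending so the strongest draw on
top, and every numeric attribute printed with a fixed 4-decimal format
(−0.0000 folded to 0.0000), so equal inputs give byte-identical output and
one canonical figure is pinned by SHA-256 in the tests. Ribbon width is
linear in |coef| between the configured min/max (min = max recovers
constant width). Each ribbon and rim arc carries an SVG `<title>` —
`var1 (dom1) ↔ var2 (dom2): coef` — the static stand-in for hover
tooltips, also announced by screen readers on focus. Labels are radial,
rotated to read outward and flipped on the left half, truncated to
`label_max_chars` with an ellipsis. Default colors are Okabe–Ito blue
(#0072b2) and vermilion (#d55e00), a pairing distinguishable under the
common color-vision deficiencies; label color flips between dark and light
by background luminance.

PNG, JPG and PDF are produced by re-drawing the identical scene geometry
with matplotlib's Agg backend at 100 dpi, so a `figure_size_px` of 800
yields an exactly 800×800 raster. These exports share the geometry but not
the byte stream; only SVG is snapshot-tested. SVG (and the inline-SVG HTML
companion) require nothing beyond the standard library.

## Style settings

All aesthetics live in one validated `StyleSettings` dataclass that round-
trips through JSON field-for-field. Unknown keys are ignored with a
warning (forward compatibility); known keys with invalid values raise
`MalformedSettings`; colors are normalized to lowercase `#rrggbb` on
construction so object equality is well defined. CLI precedence is flags >
settings file > defaults, applied per field.

## Synthetic data

The generator emulates the shape of the studies this plot serves: a few
domains of unequal size (default 12+6+5+4+3 variables — one taxa-like
domain plus metadata blocks), correlations denser within domains
(intra-density 0.35) than across (0.08), mostly positive
(negative fraction 0.25), magnitudes from Beta(2, 4) so weak correlations
outnumber strong ones, as pairwise screens produce. Each candidate
unordered pair is visited once in deterministic order and included by a
Bernoulli draw, so tables contain no self-pairs or duplicates by
construction; all randomness comes from numpy's PCG64 under a required
seed. The `uniform` magnitude option with negative fraction 0.5 recovers
the symmetric Uniform(−1, 1) coefficient distribution.

`hub_negative_table` reproduces a structure reported in gut-microbiome
co-occurrence networks, where a single genus anchors all negative
associations: the base table is all-positive, and one hub variable
receives 12 negative partners with |coef| ~ Uniform(0.45, 0.95), chosen to
survive the display thresholds 0.2 and 0.4 used in the end-to-end
scenarios. It is a structural regression fixture: after any filtering,
every negative ribbon must still touch the hub, checkable from the model
or from the rendered SVG's tooltips.

What the generator does **not** emulate: positive-semidefiniteness of a
real correlation matrix, p-values/multiplicity, abundance compositionality,
or realistic label text. Passing tests therefore demonstrate the
visualization contract (parsing, filtering, geometry, rendering), not any
statistical property of real data.

## Problem sizes and numerical notes

The test suite checks the format contract over all 120 header permutations
and 500 random round trips; the filter against an independent brute-force
scan on 200 random tables × 10 thresholds; angular conservation on 1000
random layouts (closure within 1e-9°, typically ~1e-13); explicit-order
realizability exhaustively to 6 domains; and render conservation on 100
fixtures — sizes at which the whole suite runs in seconds while exercising
every code path. Bézier endpoints sit on the unit circle to < 1e-12;
swapped-anchor symmetry holds pointwise to < 1e-9. Degenerate inputs
(header-only file, single record, single domain, threshold 1.0, domain
conflicts) each have a documented error or a well-defined rendering.

## Known limitations

- No live interactivity (hover highlighting, drag-to-rearrange); different
  views are different invocations, and tooltips are static.
- No crossing minimization or force-directed ordering: rim order is
  exactly size / input / explicit.
- Label collision avoidance is limited to truncation and radial placement;
  hundreds of domains will crowd.
- Raster text metrics come from matplotlib's font stack, so PNG/PDF label
  placement can differ sub-pixel from an SVG viewer's rendering.
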