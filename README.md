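# corrglobe

Deterministic correlation-globe figures from pairwise correlation tables.

A **correlation globe** (also called an exposome globe) is a circular
chord-style diagram for scanning correlation structure in complex studies:
variables sit on the rim of a circle, grouped into user-assigned **domains**
— microbial taxa, contaminant measurements, clinical or environmental
metadata — and every retained pairwise correlation is drawn as a **ribbon**
across the interior, colored by sign. Where a heat map of an *n* × *n*
correlation matrix becomes unreadable, a globe makes clusters, hubs and
candidate confounding factors visible at a glance: a metagenomics study
correlating taxa against exposures, an epidemiological screen of hundreds
of environment–outcome pairs, or any analysis that ends in a long table of
(variable, variable, r) triples.

`corrglobe` is the static, scriptable take on this plot family: a small
Python library plus a thin CLI that read a correlation CSV, filter and
group it, compute a circular layout, and emit publication-quality figures.
Rendering is a pure function of its inputs — identical data and settings
produce byte-identical SVG — so figures are reproducible and snapshot-
testable. Interactivity is represented statically: every ribbon and rim arc
embeds an SVG `<title>` tooltip that browsers (and screen readers) surface
on hover or focus.

The package performs **no statistical analysis**: it visualizes
correlations you have already computed, with whatever method and
significance handling your study requires.

## Input format

A comma-delimited file whose header line must be exactly

```
variable1,var1_domain,variable2,var2_domain,coef
```

(cosmetic spaces after the commas are tolerated; any renaming or reordering
of the five columns is rejected). Each data row is one pairwise
correlation: two variable labels, the domain each belongs to, and a signed
coefficient in [−1, +1]. Standard CSV quoting, UTF-8 (BOM tolerated), LF or
CRLF endings; blank lines are ignored.

## The model

Given a table, a display threshold *t* and an optional set of excluded
domains, the globe is built in a fixed order: self-pairs are dropped,
duplicate unordered pairs keep their first occurrence, records with
|coef| ≤ *t* are removed (the cutoff is strict, so exactly-zero
coefficients never render), and records touching an excluded domain are
removed. Every dropped row is attributed to exactly one cause, so the
reported counts always sum to the input size. Domains whose ribbons all
vanish are pruned from the rim.

The rim allocates each domain an arc proportional to its variable count:
with *n* domains, gap *g* and domain sizes *sᵢ*,

    extentᵢ = (360° − n·g) · sᵢ / Σs,

placed clockwise from 12 o'clock. Variables sit at midpoints of equal slots
inside their domain's arc, and each ribbon is a single cubic Bézier whose
control points are pulled toward the center (`pull` = 0.8 by default).
Ribbon stroke width encodes |coef| linearly; color encodes sign
(colorblind-safe blue/vermilion by default, fully configurable via a JSON
settings document).

## Worked example

```python
import corrglobe as cg

table = cg.generate(cg.FixtureSpec(seed=7))      # or cg.read_correlations("my.csv")
model = cg.build_globe(table, threshold=0.3)
layout = cg.compute_layout(model, sort_mode="size")
figure = cg.render_svg(model, layout, cg.StyleSettings())
cg.export(figure, "svg", "basic_globe.svg")
```

Running `python examples/plot_basic_globe.py` (this exact pipeline) prints:

```
generated 51 pairwise correlations across 5 domains
|coef| > 0.3 keeps 24 of 51 records (27 were at/below the cutoff)
  domain D1: 10 variables on a 134.6° arc
  domain D3: 5 variables on a 67.3° arc
  domain D2: 4 variables on a 53.8° arc
  domain D4: 4 variables on a 53.8° arc
  domain D5: 3 variables on a 40.4° arc
```

The synthetic table has 51 correlations; the 0.3 cutoff keeps 24 ribbons.
The largest domain (10 of the 26 surviving variables) receives 10/26 of the
350° left after five 2° gaps — the 134.6° arc — and so on down the rim.
The other scripts in `examples/` walk through threshold sweeps, the
negative-hub pattern, and restyling/settings persistence.

Or from the shell:

```
corrglobe fixtures --seed 7 --out demo.csv
corrglobe plot -i demo.csv -o globe.svg --threshold 0.3
corrglobe plot -i demo.csv -o globe.png --threshold 0.2 --sort none
```

`--sort none` keeps the rim in the input order of the CSV instead of
sorting domains by size; `--order` sets an explicit rim order;
`--exclude DOMAIN` removes a domain; `--settings style.json` and per-field
flags control aesthetics (flags beat the file, the file beats defaults).

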