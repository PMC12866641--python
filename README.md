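# diceglyph

A layout engine and SVG renderer for **dice plots** and **domino plots** —
glyph-based grids for high-dimensional categorical data, built for the kind
of question single-cell analysts ask constantly: *which genes (or pathways)
are dysregulated in which cell types, under which conditions, in which
group?*

A dice plot shows up to four categorical variables in one view:

- **rows** and **columns** — two categorical variables (e.g. cell types × genes);
- **pips** — each cell is a die face; every level of a third variable owns a
  fixed pip position (max six levels, like a six-sided die), and a pip is
  drawn iff that level occurs in that (row, column) subset. Because the
  level → position assignment is global, dice are comparable at a glance;
- **background** — an optional fourth variable tints the die behind the pips.

A **domino plot** extends this for multi-contrast differential-expression
summaries: pip slots carry the contrasts (e.g. five disease-vs-control
tests), each tile splits into two halves for a binary variable (e.g. sex),
and each pip encodes a signed effect size (log2 fold change, diverging
color anchored at 0) and a nonnegative significance score (−log10 adjusted
p, pip radius). A geographic mode places dice at longitude/latitude anchors
over optional GeoJSON outlines.

Rows and columns are ordered manually, as observed, or by average-linkage
hierarchical clustering of binary presence profiles under Jaccard distance,
so labels with similar pip patterns sit adjacently.

Everything renders to plain SVG plus a canonical, schema-versioned layout
JSON (sorted keys, 6-decimal floats) that is byte-stable and machine-checkable.

## Worked example

```python
import diceglyph as dg

# Synthetic PBMC-style dysregulation table: 8 cell types, top 25 genes,
# four age-sex conditions, one sex-linked (XIST-like) gene.
table = dg.make_pbmc_like(dg.FixtureConfig(seed=1))
layout = dg.build_dice_layout(table, order_spec={"row": "cluster"})
print(len(layout.row_order.labels), len(layout.col_order.labels),
      layout.slot_map.layout.n_slots)

xist = [c for c in layout.cells if c.col_label == "XIST"]
slots = sorted({s for c in xist for s in c.present_slots})
print([layout.slot_map.dot_levels[s] for s in slots])

svg = dg.render_svg(layout)          # deterministic SVG document
doc = dg.export_layout_json(layout)  # canonical layout export
```

This prints:

```
8 25 4
['YF', 'OF']
```

i.e. an 8 × 25 grid with a 4-slot die face (YM/OM/YF/OF), and the XIST-like
gene's dice contain only the two female-condition pips — exactly the
sex-specific signal the plot is meant to surface. The rendered SVG contains
192 pip circles, one per observed (cell type, gene, condition) triple.

The same from the shell:

```sh
diceglyph fixture --kind pbmc --seed 1 --out pbmc.csv
diceglyph dice --input pbmc.csv --row cell_type --col gene --dot condition \
    --bg group --row-order cluster --out pbmc.svg
diceglyph domino --input zebra.csv --row cell_type --col gene \
    --contrast contrast --split sex --color-value log2fc \
    --size-value neg_log10_p --out zebra.svg
```

The domino counterpart (`dg.make_zebra_like`, seed 1) yields 24 tiles of
4 neurodegeneration genes × 6 brain cell types, each with two sex halves
and up to five contrast pips, with a color domain of [−4.65, 4.65]
symmetric about zero.

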