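# featuretracks

Pixel layout and SVG rendering for position-based protein sequence
annotations — domains, peptides, active sites, modified residues,
disulfide bonds — the track-style drawings familiar from UniProt, Pfam
and protein feature prediction services.

The package is for bioinformaticians and tool authors who need those
drawings outside a browser: it computes *where every glyph goes* (the
part genome/protein viewers usually bury inside their JavaScript),
serializes the fully resolved drawing as a JSON document, and renders it
to SVG. The renderer performs **no** layout math, so the layout JSON is
a complete, exchangeable description of the figure.

## The layout model

A drawing maps a residue window `[requestedStart, requestedStop]` (1-based
inclusive, the UniProt/GFF3 convention) onto a horizontal ruler of

```
rulerLength = sizeX − leftMargin − rightMargin          (px)
unitsize    = rulerLength / windowLength                (px per residue)
x(p)        = leftMargin + (p − requestedStart + 1) · unitsize
```

with half-up rounding applied only when a pixel is finally emitted; a
region `[s, e]` gets `width = round((e − s) · unitsize)`. Three styles
place glyphs vertically:

- **nonOverlapping** — greedy first-fit packs features into the minimum
  number of tracks; on start-sorted intervals this greedy is optimal, so
  the track count equals the maximum overlap depth of the interval set;
- **rows** — one row per feature type, ordered by (category, label);
- **centered** — every glyph straddles the single sequence line.

Single-residue sites draw as typed point glyphs (metal binding → circle,
active site → diamond, lipidation → wave, glycosylation → hexagon, other
modified residues → triangle); regions draw as rectangles, disulfide
bonds as inverted-U bridges. Colors are explicit per feature or assigned
deterministically from a fixed 12-color palette by hashing the type code.

## Worked example

`examples/q8lax3.json` holds one elicitor-peptide feature spanning
residues 74–96 of a 96-residue sequence:

```
$ featuretracks render --input examples/q8lax3.json \
      --out-svg q8lax3.svg --out-json q8lax3.layout.json
INFO segment Q8LAx3: 1 features, 1 tracks, ruler 660 px, unitsize 6.8750 px/residue
INFO wrote layout JSON to q8lax3.layout.json
INFO wrote SVG to q8lax3.svg
```

On the default 700 px canvas with 20 px margins, the 96-residue window
gives `unitsize = 660/96 = 6.875` px/residue. The peptide's left edge is
`20 + 74 × 6.875 = 528.75 → 529` px and its width
`(96 − 74) × 6.875 = 151.25 → 151` px, which is exactly what the layout
JSON records:

```json
"x": 529, "width": 151, ... "unitsize": 6.875
```

Zooming (`--start 74 --stop 96`) re-derives `unitsize = 660/23 ≈ 28.70`,
drops features outside the window and clips (and dash-marks) partial
ones. Synthetic inputs for experimentation come from the fixture
generator:

```
$ featuretracks fixtures --n 12 --length 300 --seed 7 --out demo.json
$ featuretracks render --input demo.json --style rows --out-svg demo.svg
INFO segment synthetic_seed7: 12 features, 7 tracks, ruler 660 px, unitsize 2.2000 px/residue
```

The same pipeline is available as a library — `read_simple_features` /
`read_gff3` → `build_layout` → `write_layout_json` / `render_svg` — with
identical results. The two JSON dialects are documented by the schema
files in `docs/schemas/`.

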