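# Methods

## Coordinate model

All residue coordinates are 1-based inclusive, matching both UniProt
feature annotations and GFF3, so neither reader shifts anything and a
feature written at (s, e) always reads back at (s, e). `start == end` is
legal and marks a single-residue site, drawn as a point glyph;
`start > end` is rejected at construction (no wrap-around intervals).

The horizontal mapping is anchored so that the window origin
(`requestedStart − 1`) lands exactly on the left margin and the window
stop exactly on `leftMargin + rulerLength`:

```
x(p) = leftMargin + (p − requestedStart + 1) · unitsize
```

`unitsize` is kept at full float precision; rounding happens once, at
final pixel emission, with half-up tie-breaking (`floor(v + 0.5)`).
Rounding earlier would accumulate a visible drift across a 600+ px
ruler; rounding region widths independently of edges can overshoot the
ruler end by at most 1 px, so widths are clamped to the ruler extent.
Half-up versus half-even is unobservable in ordinary use (exact .5 ties
require unitsize values like 6.875 meeting even offsets); it was fixed
once for determinism.

## Track packing (nonOverlapping style)

Features are sorted by (start, end, feature_id) — the id tie-break makes
the assignment fully deterministic — and each is placed on the
lowest-index track whose previous feature ends strictly before this one
starts (closed intervals: sharing one residue is an overlap; a bridge
occupies its full span; a site occupies its single residue). This greedy
first-fit on start-sorted intervals is the classic interval-partitioning
algorithm and is optimal: the number of tracks equals the maximum
overlap depth. The test suite checks that equality against a deliberately
naive oracle (per-residue coverage counting) and against intervaltree,
over hundreds of randomized instances.

Track 0 sits nearest the sequence line and tracks grow downward:
`y = sequenceLineY + trackGap + trackIndex · (trackHeight + trackGap)`.
The *rows* style uses the same formula with the row index (one row per
type label, ordered lexicographically by (category, label) — the
ordering is a design choice; any fixed total order works). The
*centered* style puts every glyph at
`y = centeredSequenceLineY − height/2`, rounded half-up.

## Defaults and units

All geometry parameters are integer pixels except `unitsize`
(px/residue, fractional):

| parameter | default | meaning |
|---|---|---|
| sizeX | 700 | canvas width |
| leftMargin / rightMargin | 20 / 20 | unused horizontal borders |
| pixelsDivision | 50 | px between ruler ticks |
| rulerY / aboveRuler / belowRuler | 20 / 10 / 30 | ruler band geometry |
| sequenceLineY (tracks/rows) | 54 | baseline the tracks hang from |
| sequenceLineY (centered) | 95 | baseline of the centered style |
| trackHeight (tracks/rows) | 10 | glyph height / radius |
| trackHeight (centered) | 40 | taller glyphs, one per line |
| trackGap | 2 | vertical space between tracks |

The 2 px track gap and the per-style sequence lines reproduce the
conventional compact view (first track top at y = 56 under a baseline at
54). A placed feature records `r = trackHeight` (the
"height-or-radius" convention of existing track viewers) and, for point
glyphs, `cy = y + height/2`; for rectangles `cx = x`, `cy = y`. Canvas
height is derived, not configured: deepest glyph bottom + belowRuler +
20 px per legend entry (+10 px padding). Legend height is intentionally
computed from the entry count rather than configured.

Ruler ticks sit every `pixelsDivision` px plus a terminal tick at the
ruler end. Labels come from the inverse pixel mapping; the origin is
labeled `requestedStart`, the terminal `requestedStop`, and interior
ticks whose label would repeat an earlier one (heavy zoom, where one
residue spans several divisions) are dropped so labels stay unique and
x positions strictly increasing.

## Zoom and clipping

Zooming replaces the window and re-runs the whole pipeline: features
wholly outside are dropped; partial overlaps are truncated to the window
bounds with `clippedLeft`/`clippedRight` flags, which the renderer draws
as short dashed edge markers rather than restyling the glyph. Zoom to
the current window is exactly the identity (same config in, same
document out) and zoom is idempotent for a fixed window.

## Dialects

The simple-features JSON reader accepts the flat
`featureId/featureStart/featureEnd/...` key set verbatim; unknown keys
log a warning and are ignored (forward compatibility). The layout-JSON
writer emits the conventional key names of track-viewer documents
(`featuresArray`, per-style `nonOverlappingStyle`/`centeredStyle`/
`rowsStyle` blocks with `heightOrRadius`, `configuration.unitsize`,
`pixelsDivision`, ...) so documents are exchangeable with existing
consumers; `dasSources`/`dasReference` are carried as opaque
pass-through strings. Writer and reader are exact inverses on valid
documents; the reader performs no re-layout, with one concession to
foreign writers: entries carrying only pixel geometry get their residue
coordinates recovered by inverting the pixel mapping. GFF3 support is a
single-segment dialect (column 1 is the segment id; a second seqid is an
error) with `ID` → feature id, `Note` → display label, `Ontology_term` →
type code; attributes with no field mapping are preserved in the
evidence text. Validation of the layout dialect is a required-key check
(missing keys are listed in the error); JSON-Schema files under
`docs/schemas/` document both dialects for external tooling.

## Rendering

The renderer is a pure function of the document: zero layout math,
byte-identical output for equal documents (element and attribute order
are fixed), tooltips as SVG `<title>` children in the form
"label — type (start–end) [evidence]", and stable element ids derived
from feature ids. The wave glyph has no canonical path in the wild; here
it is two joined semicircular arcs (crest then trough) spanning 2r
horizontally. Selection is represented statically as an optional
highlighted feature id drawn with a tripled stroke. PNG export probes
for cairosvg at call time and otherwise raises a capability error with a
remediation hint — absence of a raster backend never breaks the SVG
pipeline.

## Synthetic fixtures

The generator emulates a single-protein UniProt-style annotation set:
region starts uniform over the sequence, region lengths geometric with
mean ~25 residues (many short peptides/domains, a long tail) capped at a
quarter of the sequence, and single-residue sites uniform. The default
vocabulary covers every glyph-triggering type label, so one fixture
exercises all drawing paths. Overlap depth is capped by rejection
sampling (a candidate raising the depth above `max_depth` anywhere is
redrawn, 200 attempts before a feasibility error); randomness comes from
`numpy.random.default_rng(seed)`, so fixtures are identical across
platforms for a fixed seed. What the generator does **not** emulate:
correlated feature positions (domains avoiding each other), hierarchical
features, multi-segment files, or realistic type frequencies — tests
passing on fixtures demonstrate geometric and serialization correctness,
not biological plausibility of any particular drawing.

Test and demonstration sizes (hundreds of randomized interval sets of
≤ 200 features, fixtures of ≤ 1000) were chosen because layout cost is
linear and the properties under test are scale-free; the whole suite
runs in a few seconds.

## Known limitations

- No label collision avoidance and no semantic zoom (features are never
  merged at low magnification).
- One segment per document; no multi-protein batch mode.
- Fuzzy/uncertain endpoints are not representable.
- Browser-style interactivity (hover, drag, selection events) is out of
  scope; tooltips and the static highlight are the non-interactive
  stand-ins.
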