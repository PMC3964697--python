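# Methods

## The data model

A key is a taxon × character matrix. Characters are **categorical**
(an ordered vocabulary of state labels; a taxon may carry several states
at once, the way a species can have achenes that are trigonous in some
populations and lenticular in others) or **numeric** (an inclusive
measurement range, e.g. blade width 2–10 mm). A score may be **UNKNOWN**,
a first-class value distinct from every state and from zero; it is never
silently coerced, and in filtering it always retains the taxon. This is
standard multi-access-key practice: eliminating a species because nobody
measured it would produce false negatives that are invisible to the
user.

The CSV dialect is a documented stand-in for the loosely specified
exports of matrix-key editors: header row; first column the taxon name;
categorical characters as one column with multi-state cells joined by a
configurable separator (default `|`); numeric characters as paired
`Name:min`/`Name:max` columns, with a single all-numeric column read as
degenerate ranges `[v, v]`. Two dialect hazards fail loudly rather than
corrupt silently: a state label containing the separator, and a
categorical character whose labels are all numeric (it would be re-read
as a numeric character; pinning a controlled vocabulary in
`MatrixConfig` resolves it, as the fixtures do for stigma number 2 vs
3). Facet labels are capped at 40 characters — facet panes reward
brevity — and a post-truncation collision is an error, never a merge.

## Pyramid geometry

Level `L = ceil(log2(max(w, h)))` is the full-resolution base; level 0
is the 1×1 apex; level `l` has the dimensions obtained by applying
`d -> ceil(d / 2)` exactly `L − l` times. Tile grids use ceiling
division; a tile's nominal `tile_size` cell is expanded by `overlap`
pixels on every side that has a neighbouring tile, then clipped to the
level image, so interior tiles measure `(tile_size + 2·overlap)²` and
adjacent tiles share a `2·overlap` band (clipped only when `overlap > 1`
runs into the image edge). Coordinates are 0-based, x rightward, y
downward, rectangles half-open.

Downsampling is area-weighted averaging with round-half-even, applied
one halving step at a time; each level is computed by iterated halving
of the base image, so the recurrence between stored levels is exact by
construction and the reassembly test can demand byte-for-byte equality
(with PNG tiles; JPEG is the deployment default at quality 90 but is
lossy by nature). The averaging operator is a sparse matrix per axis —
for a ceil-halving each output pixel mixes at most two input pixels per
axis with exact dyadic weights.

Defaults — tile 256 px, overlap 1 px, JPEG quality 90, DZC cell cap
2^8 = 256 px — are the Deep Zoom ecosystem's conventional values; the
format names no parameters of its own. All are config-exposed.
Byte-level parity with any particular historical tiler is not claimed,
only format-level compatibility of the descriptor XML and tile layout.

## Collection packing and CXML

Item `i` sits at Morton position `i`: its cell coordinates are the
de-interleaved bits of the id (column bits in the even, least
significant positions). At collection level `l` the cell is `2^l` px, a
256-px tile holds `(256 / 2^l)²` cells, and an item's thumbnail —
pre-halved to fit 256 px — is rendered at its own `L − l`-halved size at
the cell origin on a white canvas. Only tiles containing at least one
item are written.

CXML is emitted in a minimal subset (Collection, FacetCategories,
Items/Item, Facets/Facet with String and Number values); anything else
is ignored on read and never written. Serialization order is fixed
(items by id, facets in declared category order), numbers print in
shortest round-tripping form, so identical inputs give byte-identical
files — the determinism the acceptance checks rely on. The taxon of an
item travels as a mandatory "Species" String facet; that keeps the
read∘write identity on the plain data model while giving the
normalization view a taxon key, and matches keys whose facet roster
lists the species itself.

Assembly is item-per-image, not item-per-taxon: clustering several
images under one species is a query-time concern, and restricting at
build time would throw data away. Taxa without images are omitted with
a logged warning; an image naming an unknown taxon aborts with the file
name, since it is almost always a typo worth fixing.

## Filter, histogram, normalization, ranking

A taxon remains iff, for **every** selected character, its score is
UNKNOWN, or (categorical) shares at least one state with the selection,
or (numeric) its range overlaps the selected interval (inclusive
endpoints; open-ended intervals via ±inf). Within-character disjunction
and across-character conjunction is the universal matrix-key semantic,
stated here explicitly. Consequences tested as properties: adding a
selection never enlarges the remaining set, and re-filtering the
survivors is a no-op.

Histograms group the remaining taxa by a categorical character;
multi-valued taxa increment every state they carry, UNKNOWN taxa fall
into a dedicated `(unscored)` bucket, so for single-valued characters
the bucket total equals the remaining count. Numeric characters are
refused with a pointer to binning configuration — how measurement
ranges should be bucketed is a presentation decision this library does
not hard-code.

`normalize_view` keeps items whose designated facet carries the
representative value, at most one per taxon: taxa with no matching item
drop out of the view (and are reported in a side list), and several
matches resolve to the lexicographically smallest item name with a
warning — deterministic, and stable under re-ordering of the input.

`rank_characters` is optional sugar, not part of the classic key: it
orders the available characters by Shannon entropy `−Σ p·log₂ p` of
their state distribution among the remaining taxa (UNKNOWN excluded;
ties keep matrix order). For numeric characters, which have no states,
the distribution is over distinct stored ranges — a deliberate,
documented choice; a width-aware measure would need binning
configuration that the histogram path also declines to invent.

## Build, serve, export

The builder runs matrix → pyramids → collection → CXML with
stage-granular logging. Per-image failures are logged and skipped —
long tiling runs must survive one corrupt file — while matrix errors
abort, because every downstream artefact depends on the schema. The
static server exists because deployment fails silently without one
non-default MIME setting: `.cxml`, `.dzc` and `.dzi` must be served as
`text/xml`. The HTML export is a dependency-free static page (item
grid, histogram bars, a normalization toggle pre-rendered from the
engine) rather than a plug-in runtime; the historical viewer stack for
this format is deprecated, and a headless query API plus plain HTML is
the durable replacement.

## Synthetic data

The fixture generator emulates the study conditions of a North American
sedge key: the 20-facet roster (species, geography, culm/blade
measurements, spike sexuality, perigynium and achene shape and size,
style persistence, image author and type), small realistic state
vocabularies (achene cross-section trigonous vs two-sided; provinces as
two-letter codes in keeping with the label-brevity cap), numeric ranges
in centimetres/millimetres at field-guide magnitudes, 20 % UNKNOWN by
default, and per taxon exactly one grey-scale line drawing credited to
a single designated illustrator ("Mackenzie, K. K.") among otherwise
colour field photos — the premise the normalization view needs. The
standard end-to-end fixture is 12 taxa and 30 images at
512×384 / 384×512 / 400×300 px; test and acceptance runs use these
desk-scale sizes, which exercise every geometry branch (odd dimensions,
multi-tile levels, mixed grey/colour) without the bulk of a production
image archive.

Images are coordinate-encoded — each pixel a fixed arithmetic function
of `(x, y, image_id)` — rather than noise or pictures, so any crop of
any level is exactly predictable and reassembly tests are equalities,
not statistics. What the fixtures deliberately do not emulate: real
photographic content (no JPEG artefact structure, no aspect-ratio
extremes, no EXIF), real taxonomic covariance between characters, and
archive-scale image counts. Passing tests therefore establish the
format arithmetic, the dialect round-trips and the key semantics; they
say nothing about e.g. perceptual quality of JPEG tiles on real
specimens.

## Numerical and degenerate-input choices

- Rounding: ceiling for level dimensions and grids; round-half-even for
  pixel averages (so 127.5 → 128); both stated so independent
  implementations can agree.
- A 1×1 image is a valid pyramid (one level, one tile); halving a 1-px
  axis leaves it at 1 px.
- Degenerate numeric ranges `[v, v]` are written as a single Number
  facet value.
- An empty query returns all taxa; an empty collection serializes to
  valid CXML with its declared categories; a header-only matrix CSV is
  a matrix with zero taxa.
- Seeds: every generator takes an explicit integer seed and fixes all
  output bytes.

## Known limitations

- No sparse-pyramid optimisation, progressive JPEG or colour
  management; images are flattened to 8-bit grey or RGB.
- CXML Link/DateTime facet types and viewer extension namespaces are
  out of scope (ignored on read).
- Facets are flat; hierarchical geography (country → province) is not
  modelled.
- No error-tolerant scoring ("allow n mismatches") or dependent
  character trees.
- Native binary matrix-editor formats are not parsed; the CSV dialect
  is the interchange surface.
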