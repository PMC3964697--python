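# zoomkey

Zoomable visual identification keys for taxonomists and biodiversity
informaticians: build Deep Zoom tiled image collections and a faceted
catalogue from a taxon × character matrix plus images, then filter and
group them with multi-access key semantics.

Classic matrix keys scale to hundreds of taxa but show text, not
specimens; image galleries show specimens but cannot be queried. A
*visual key* combines them: the character matrix prunes the candidate
list analytically, and the surviving taxa are compared by eye against
high-resolution, zoomable images. `zoomkey` provides the whole build and
query chain for such a key:

- **matrix** — a CSV dialect for taxon × character matrices (multi-state
  categorical characters, inclusive numeric ranges, explicit UNKNOWN),
  with the facet schema derived from it;
- **pyramid** — Deep Zoom image pyramids (DZI): each image becomes a
  geometric series of ceil-halved levels cut into overlapping fixed-size
  tiles, so resolution is downloaded only on demand;
- **collection** — the Deep Zoom collection (DZC), packing per-item
  thumbnails into shared tiles along the Morton (z-order) curve, and the
  CXML faceted catalogue that ties items, facets and tiles together;
- **keyengine** — the identification semantics: conjunction across
  characters, disjunction within; UNKNOWN never eliminates; numeric
  matching by interval overlap; histogram faceting of the remaining
  taxa; a normalization view keeping one designated representative image
  per taxon (e.g. the single line drawing per species by one
  illustrator) for true one-to-one comparison; and an optional
  entropy-based "best next character" ranking;
- **builder / cli** — one-command end-to-end builds, a static server
  with the MIME types viewers require (`.cxml`/`.dzc`/`.dzi` must be
  `text/xml`), and a dependency-free static HTML gallery export;
- **fixtures** — deterministic synthetic matrices and coordinate-encoded
  images emulating a sedge (*Carex*) key, so everything is testable
  offline.

## Worked example

Generate a synthetic six-species study set, build the deployable site,
and ask a question of it:

```sh
zoomkey fixtures --out fix --n-taxa 6 --images-per-taxon 2 --seed 11
zoomkey build --matrix fix/matrix.csv --manifest fix/images/manifest.csv \
              --images fix/images --out site --format png
```

The build report:

```json
{
  "images_tiled": 12,
  "images_failed": 0,
  "items": 12,
  "facet_categories": 20,
  "tile_files": 178,
  "warnings": []
}
```

Twelve images were tiled into twelve DZI pyramids plus one DZC (178 tile
files in total), and the CXML catalogue declares 20 facet categories:
the 17 matrix characters plus Species, Image author and Image type.
`site/` now serves as a static key (`zoomkey serve site`); `index.html`
is a minimal gallery with histogram bars and the normalization toggle.

A query — *which species have trigonous achenes, and how are they
distributed across Canadian provinces?*:

```sh
echo '{"selections": {"Achene cross-section shape": ["trigonous"]}}' > q.json
zoomkey query --matrix fix/matrix.csv --query q.json \
              --histogram "Canadian province or territory"
```

```json
{
  "remaining": ["Carex ficta 001", "Carex ficta 002", "Carex ficta 003",
                "Carex ficta 005", "Carex ficta 006"],
  "eliminated": ["Carex ficta 004"],
  "characters_chosen": ["Achene cross-section shape"],
  "histogram": {
    "group_by": "Canadian province or territory",
    "buckets": {"NU": 1, "NT": 2, "NB": 0, "QC": 1, "MB": 1, "(unscored)": 2}
  }
}
```

One species is scored two-sided only and is eliminated; species whose
achene shape is unrecorded are retained (missing data never eliminates a
candidate). The histogram tallies the remaining taxa per province —
multi-valued taxa count in every province they occupy, and taxa without
a province score land in `(unscored)`.

The same operations are available as library calls
(`zoomkey.parse_matrix`, `zoomkey.apply_filter`, `zoomkey.histogram`,
`zoomkey.normalize_view`, `zoomkey.build_dzi`, ...).

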