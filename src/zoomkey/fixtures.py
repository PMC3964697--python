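"""Deterministic synthetic fixtures: matrices, images, collections.

Every other module is testable without downloads. The generated data
emulate a sedge (Carices) identification key: a taxon × character matrix
over the standard roster of sedge characters (achene and perigynium shape
and size, culm height, blade width, spike sexuality, geography, ...) and a
set of images per taxon including exactly one grey-scale "line drawing"
credited to the illustrator "Mackenzie, K. K." — the premise the
normalization view relies on.

Images are coordinate-encoded, not noise: each pixel value is a fixed
function of ``(x, y, image_id)``, so any crop of any downsampled level is
predictable and tile-reassembly tests can be exact. All outputs are fixed
byte-for-byte by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .collection import (
    AUTHOR_FACET,
    SPECIES_FACET,
    TYPE_FACET,
    Collection,
    CollectionItem,
    ManifestEntry,
    write_manifest,
)
from .matrix import FacetCategory, Matrix, MatrixConfig, parse_matrix

NORMALIZATION_AUTHOR = "Mackenzie, K. K."
LINE_DRAWING = "line drawing"

#: The 20-entry facet roster of the key, in pane order. The first and last
#: two are collection-level facets; the middle 17 are matrix characters.
CHARACTER_ROSTER = (
    "Species",
    "Country",
    "U.S. state",
    "Canadian province or territory",
    "Section within Carex",
    "Culm height",
    "Blade width",
    "Inflorescence type",
    "Proximal spike sexuality",
    "Terminal spike sexuality",
    "Stigma branch number",
    "Perigynium length",
    "Perigynium width",
    "Perigynium cross-section shape",
    "Achene length",
    "Achene width",
    "Achene cross-section shape",
    "Style: whether deciduous or persistent",
    "Image author",
    "Image type",
)

MATRIX_CHARACTERS = CHARACTER_ROSTER[1:-2]

# state vocabularies for the categorical characters; numeric ones map to
# (lo, lo_span, hi_span, units) for range generation
_VOCAB = {
    "Country": ("Canada", "United States", "Mexico"),
    "U.S. state": ("ME", "NY", "PA", "VA", "MI", "MN", "LA", "CA", "OR", "AK"),
    "Canadian province or territory": (
        "ON", "QC", "BC", "AB", "MB", "SK", "NB", "NS", "PE", "NL", "YT", "NT", "NU",
    ),
    "Section within Carex": ("Acrocystis", "Ovales", "Phacocystis", "Vesicariae"),
    "Inflorescence type": ("spicate", "paniculate", "capitate"),
    "Proximal spike sexuality": ("pistillate", "staminate", "gynecandrous"),
    "Terminal spike sexuality": ("staminate", "gynecandrous", "androgynous"),
    "Stigma branch number": ("2", "3"),
    "Perigynium cross-section shape": ("trigonous", "lenticular", "round"),
    "Achene cross-section shape": ("trigonous", "two-sided"),
    "Style: whether deciduous or persistent": ("deciduous", "persistent"),
}

_NUMERIC = {
    "Culm height": (5.0, 60.0, 40.0, "cm"),
    "Blade width": (1.0, 8.0, 8.0, "mm"),
    "Perigynium length": (1.5, 4.0, 3.0, "mm"),
    "Perigynium width": (0.5, 2.0, 2.0, "mm"),
    "Achene length": (1.0, 2.0, 1.5, "mm"),
    "Achene width": (0.5, 1.0, 1.0, "mm"),
}

#: Characters that may carry several states at once for one taxon.
_MULTIVALUED = {
    "U.S. state",
    "Canadian province or territory",
    "Stigma branch number",
    "Achene cross-section shape",
}


def fixture_matrix_config() -> MatrixConfig:
    """Dialect config matching the generated matrices (pins the
    all-numeric-label vocabulary of stigma number as categorical)."""
    return MatrixConfig(
        vocabularies={"Stigma branch number": _VOCAB["Stigma branch number"]},
        numeric_units={k: v[3] for k, v in _NUMERIC.items()},
    )


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic study set."""

    n_taxa: int = 12
    images_per_taxon: int = 2
    image_dims: tuple = ((512, 384),)
    characters: tuple = MATRIX_CHARACTERS
    unknown_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 0 or self.images_per_taxon < 0:
            raise ValueError("counts must be >= 0")
        if not (0.0 <= self.unknown_rate <= 1.0):
            raise ValueError("unknown_rate must be in [0, 1]")
        unknown = set(self.characters) - set(MATRIX_CHARACTERS)
        if unknown:
            raise ValueError(f"characters outside the roster: {sorted(unknown)}")


def taxon_names(n: int) -> list[str]:
    return [f"Carex ficta {i + 1:03d}" for i in range(n)]


def gen_matrix_csv(spec: FixtureSpec) -> str:
    """Generate the matrix CSV text (seed-deterministic)."""
    rng = np.random.default_rng(spec.seed)
    cfg = fixture_matrix_config()
    header = ["Taxon"]
    for cname in spec.characters:
        if cname in _NUMERIC:
            header += [f"{cname}:min", f"{cname}:max"]
        else:
            header.append(cname)
    lines = [",".join(_csv_quote(h) for h in header)]
    for taxon in taxon_names(spec.n_taxa):
        row = [taxon]
        for cname in spec.characters:
            unknown = rng.random() < spec.unknown_rate
            if cname in _NUMERIC:
                lo0, lo_span, hi_span, _ = _NUMERIC[cname]
                if unknown:
                    row += ["", ""]
                else:
                    lo = round(lo0 + rng.random() * lo_span, 1)
                    hi = round(lo + rng.random() * hi_span, 1)
                    row += [_num_str(lo), _num_str(hi)]
            else:
                vocab = _VOCAB[cname]
                if unknown:
                    row.append("")
                    continue
                if cname in _MULTIVALUED:
                    k = 1 + int(rng.integers(0, min(3, len(vocab))))
                else:
                    k = 1
                picks = rng.choice(len(vocab), size=k, replace=False)
                states = [vocab[i] for i in sorted(picks)]
                row.append("|".join(states))
        lines.append(",".join(_csv_quote(c) for c in row))
    return "\n".join(lines) + "\n"


def _num_str(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else str(v)


def _csv_quote(cell: str) -> str:
    if any(ch in cell for ch in ',"\n'):
        return '"' + cell.replace('"', '""') + '"'
    return cell


def gen_matrix(spec: FixtureSpec) -> Matrix:
    """Generate and parse the matrix in one step."""
    return parse_matrix(gen_matrix_csv(spec), fixture_matrix_config())


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------

def encoded_raster(width: int, height: int, image_id: int, grey: bool = False) -> np.ndarray:
    """Coordinate-encoded raster: pixel value a fixed function of
    ``(x, y, image_id)`` so every crop and tile is predictable."""
    x = np.arange(width, dtype=np.int64)[None, :]
    y = np.arange(height, dtype=np.int64)[:, None]
    if grey:
        return ((2 * x + 3 * y + 17 * image_id) % 256).astype(np.uint8)
    r = (3 * x + 5 * y + 17 * image_id) % 256
    g = (7 * x + 2 * y + 29 * image_id) % 256
    b = (x + 11 * y + 41 * image_id) % 256
    return np.stack(
        [r.astype(np.uint8), g.astype(np.uint8), b.astype(np.uint8)], axis=2
    )


_PHOTO_AUTHORS = ("Jones, S.", "Matson, S.", "Reznicek, A.")


def gen_images(spec: FixtureSpec, out_dir: Path) -> list[ManifestEntry]:
    """Write PNG images plus a ``manifest.csv`` into ``out_dir``.

    Per taxon: image 0 is the grey-scale line drawing by the designated
    illustrator; the rest are colour "field photo" images by a rotating
    author pool. Dimensions cycle through ``spec.image_dims``. Output is
    byte-identical for identical specs (PNG, no timestamps).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries: list[ManifestEntry] = []
    image_id = spec.seed % (2**16)
    for t_idx, taxon in enumerate(taxon_names(spec.n_taxa)):
        slug = taxon.lower().replace(" ", "_")
        for k in range(spec.images_per_taxon):
            w, h = spec.image_dims[(t_idx * spec.images_per_taxon + k) % len(spec.image_dims)]
            drawing = k == 0
            raster = encoded_raster(w, h, image_id, grey=drawing)
            fname = f"{slug}_{'drawing' if drawing else f'photo{k}'}.png"
            Image.fromarray(raster).save(out_dir / fname, format="PNG")
            entries.append(
                ManifestEntry(
                    file=fname,
                    taxon=taxon,
                    author=NORMALIZATION_AUTHOR
                    if drawing
                    else _PHOTO_AUTHORS[(t_idx + k) % len(_PHOTO_AUTHORS)],
                    image_type=LINE_DRAWING if drawing else "field photo",
                )
            )
            image_id += 1
    (out_dir / "manifest.csv").write_text(write_manifest(entries))
    return entries


# ---------------------------------------------------------------------------
# In-memory collections (for serialization round-trips)
# ---------------------------------------------------------------------------

def gen_collection(n_items: int = 12, seed: int = 0, name: str = "fixture") -> Collection:
    """A random faceted collection over the full 20-facet roster."""
    rng = np.random.default_rng(seed)
    categories = [FacetCategory(SPECIES_FACET, "String")]
    for cname in MATRIX_CHARACTERS:
        categories.append(
            FacetCategory(cname[:40], "Number" if cname in _NUMERIC else "String")
        )
    categories.append(FacetCategory(AUTHOR_FACET, "String"))
    categories.append(FacetCategory(TYPE_FACET, "String"))

    items = []
    for i in range(n_items):
        taxon = f"Carex ficta {int(rng.integers(1, 200)):03d}-{i}"
        facets: dict = {SPECIES_FACET: (taxon,)}
        for cname in MATRIX_CHARACTERS:
            if rng.random() < 0.2:
                continue
            if cname in _NUMERIC:
                lo0, lo_span, hi_span, _ = _NUMERIC[cname]
                lo = round(lo0 + rng.random() * lo_span, 1)
                hi = round(lo + rng.random() * hi_span, 1)
                facets[cname[:40]] = (lo,) if rng.random() < 0.3 else (lo, hi)
            else:
                vocab = _VOCAB[cname]
                k = 1 + int(rng.integers(0, 2)) if cname in _MULTIVALUED else 1
                picks = rng.choice(len(vocab), size=k, replace=False)
                facets[cname[:40]] = tuple(vocab[j] for j in sorted(picks))
        facets[AUTHOR_FACET] = (
            NORMALIZATION_AUTHOR if i % 2 == 0 else _PHOTO_AUTHORS[i % 3],
        )
        facets[TYPE_FACET] = (LINE_DRAWING if i % 2 == 0 else "field photo",)
        items.append(
            CollectionItem(id=i, name=f"{taxon} - img{i}", img_ref=f"#{i}", facets=facets)
        )
    return Collection(name, categories, items)
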