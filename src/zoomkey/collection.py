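"""Deep Zoom Collections (DZC) and the faceted CXML collection.

A DZC packs one small thumbnail per item into shared tiles: at collection
level ``l`` each item occupies a ``2**l``-pixel square cell, cells are laid
out on the plane by the Morton (z-order) curve of the item id, and 256-px
collection tiles hold ``(256 / 2**l)**2`` cells each. The CXML file is the
faceted catalogue: one ``Item`` per image, carrying the facet values of its
taxon plus image-level facets, and an ``Img`` reference ``#id`` into the
DZC.

The CXML dialect here is the minimal documented subset — ``Collection``,
``FacetCategories``, ``Items``/``Item``, ``Facets``/``Facet`` with
``String`` and ``Number`` values. Unknown elements are ignored on read and
never emitted, and serialization is deterministic (stable item order by id,
stable facet order), so identical inputs give byte-identical files.
"""

from __future__ import annotations

import csv
import io
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np

from .matrix import (
    CATEGORICAL,
    UNKNOWN,
    FacetCategory,
    Matrix,
    _fmt_num,
    facet_schema,
)
from .pyramid import ImageAsset, PyramidSpec, _halve_once

logger = logging.getLogger(__name__)

CXML_NS = "http://schemas.microsoft.com/collection/metadata/2009"
DZC_NS = "http://schemas.microsoft.com/deepzoom/2008"

SPECIES_FACET = "Species"
AUTHOR_FACET = "Image author"
TYPE_FACET = "Image type"


class CollectionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Morton (z-order) curve
# ---------------------------------------------------------------------------

def morton_encode(col: int, row: int) -> int:
    """Interleave bits, column bits in the even (least-significant) slots."""
    if col < 0 or row < 0:
        raise CollectionError("morton coordinates must be >= 0")
    out = 0
    shift = 0
    while col or row:
        out |= (col & 1) << shift
        out |= (row & 1) << (shift + 1)
        col >>= 1
        row >>= 1
        shift += 2
    return out


def morton_decode(index: int) -> tuple[int, int]:
    """Inverse of :func:`morton_encode`."""
    if index < 0:
        raise CollectionError("morton index must be >= 0")
    col = row = 0
    shift = 0
    while index:
        col |= (index & 1) << shift
        row |= ((index >> 1) & 1) << shift
        index >>= 2
        shift += 1
    return col, row


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------

@dataclass
class CollectionItem:
    """One collection entry (one image).

    ``facets`` maps a facet-category name to a tuple of strings (String
    facet, possibly multi-valued) or a tuple of floats (Number facet).
    """

    id: int
    name: str
    img_ref: str
    facets: dict = field(default_factory=dict)

    @property
    def taxon(self) -> str | None:
        species = self.facets.get(SPECIES_FACET)
        return species[0] if species else None


@dataclass
class Collection:
    name: str
    facet_categories: list[FacetCategory]
    items: list[CollectionItem] = field(default_factory=list)
    dzc_ref: str = "collection.dzc"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        names = [c.name for c in self.facet_categories]
        if len(set(names)) != len(names):
            raise CollectionError("duplicate facet category names")
        types = dict((c.name, c.type) for c in self.facet_categories)
        for pos, item in enumerate(self.items):
            if item.id != pos:
                raise CollectionError(
                    f"item ids must be dense 0..N-1 in order; item at position "
                    f"{pos} has id {item.id}"
                )
            for fname, values in item.facets.items():
                if fname not in types:
                    raise CollectionError(
                        f"item {item.id}: facet {fname!r} not declared"
                    )
                if types[fname] == "Number":
                    for v in values:
                        if not math.isfinite(float(v)):
                            raise CollectionError(
                                f"item {item.id}: non-finite Number facet {fname!r}"
                            )


# ---------------------------------------------------------------------------
# DZC packing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellPlacement:
    """Where one item lands at one collection level."""

    tile_col: int
    tile_row: int
    x_off: int  # pixel offset of the cell inside its tile
    y_off: int
    cell: int  # cell edge in pixels (2**level)


def dzc_placement(item_id: int, level: int, tile_size: int = 256) -> CellPlacement:
    """Morton placement arithmetic for one item at one level."""
    if level < 0:
        raise CollectionError("level must be >= 0")
    cell = 1 << level
    if cell > tile_size:
        raise CollectionError(
            f"cell {cell} exceeds tile size {tile_size}; lower the collection level"
        )
    cells_per_tile = tile_size // cell
    ccol, crow = morton_decode(item_id)
    return CellPlacement(
        tile_col=ccol // cells_per_tile,
        tile_row=crow // cells_per_tile,
        x_off=(ccol % cells_per_tile) * cell,
        y_off=(crow % cells_per_tile) * cell,
        cell=cell,
    )


@dataclass(frozen=True)
class DzcResult:
    name: str
    descriptor_path: Path
    max_level: int
    tile_counts: dict  # level -> number of tile files written
    n_items: int

    @property
    def tile_count(self) -> int:
        return sum(self.tile_counts.values())


def _thumb_for_level(thumb: np.ndarray, steps: int) -> np.ndarray:
    out = thumb
    for _ in range(steps):
        if max(out.shape[:2]) == 1:
            break
        out = _halve_once(out)
    return out


def build_dzc(
    thumbnails: list[np.ndarray],
    spec: PyramidSpec,
    out_dir: Path,
    name: str = "collection",
    max_level: int = 8,
    sources: list[str] | None = None,
) -> DzcResult:
    """Pack item thumbnails into a collection tile tree plus descriptor.

    ``thumbnails[i]`` is the base thumbnail of item id ``i`` (uint8 raster,
    max dimension ≤ ``2**max_level``). Cells are placed by Morton order of
    the id; tiles are ``spec.tile_size`` squares on a white background.
    """
    out_dir = Path(out_dir)
    cap = 1 << max_level
    if spec.tile_size < cap:
        raise CollectionError(
            f"tile size {spec.tile_size} smaller than top-level cell {cap}"
        )
    for i, thumb in enumerate(thumbnails):
        if max(thumb.shape[:2]) > cap:
            raise CollectionError(
                f"item {i}: thumbnail {thumb.shape[1]}x{thumb.shape[0]} exceeds "
                f"{cap} px; pre-resize it below 2**max_level"
            )
    from PIL import Image  # local import keeps module import light

    files_dir = out_dir / f"{name}_files"
    tile_counts: dict[int, int] = {}
    for level in range(max_level, -1, -1):
        steps = max_level - level
        tiles: dict[tuple[int, int], np.ndarray] = {}
        for item_id, thumb in enumerate(thumbnails):
            placed = dzc_placement(item_id, level, spec.tile_size)
            small = _thumb_for_level(thumb, steps)
            if small.ndim == 2:
                small = np.stack([small] * 3, axis=2)
            key = (placed.tile_col, placed.tile_row)
            canvas = tiles.get(key)
            if canvas is None:
                canvas = np.full(
                    (spec.tile_size, spec.tile_size, 3), 255, dtype=np.uint8
                )
                tiles[key] = canvas
            h, w = small.shape[:2]
            canvas[
                placed.y_off : placed.y_off + h, placed.x_off : placed.x_off + w
            ] = small
        level_dir = files_dir / str(level)
        level_dir.mkdir(parents=True, exist_ok=True)
        for (tc, tr), canvas in sorted(tiles.items()):
            im = Image.fromarray(canvas)
            path = level_dir / f"{tc}_{tr}.{spec.format}"
            if spec.format == "jpeg":
                im.save(path, format="JPEG", quality=spec.jpeg_quality)
            else:
                im.save(path, format="PNG")
        tile_counts[level] = len(tiles)

    root = ET.Element(
        "Collection",
        {
            "MaxLevel": str(max_level),
            "TileSize": str(spec.tile_size),
            "Format": spec.format,
            "NextItemId": str(len(thumbnails)),
            "xmlns": DZC_NS,
        },
    )
    items_el = ET.SubElement(root, "Items")
    for item_id, thumb in enumerate(thumbnails):
        attrs = {"Id": str(item_id), "N": str(item_id)}
        if sources is not None:
            attrs["Source"] = sources[item_id]
        i_el = ET.SubElement(items_el, "I", attrs)
        ET.SubElement(
            i_el,
            "Size",
            {"Width": str(thumb.shape[1]), "Height": str(thumb.shape[0])},
        )
    descriptor = out_dir / f"{name}.dzc"
    descriptor.write_bytes(ET.tostring(root, encoding="utf-8", xml_declaration=True))
    return DzcResult(name, descriptor, max_level, tile_counts, len(thumbnails))


def make_thumbnail(raster: np.ndarray, cap: int = 256) -> np.ndarray:
    """Halve a raster until its max dimension fits the collection cell cap."""
    out = raster
    while max(out.shape[:2]) > cap:
        out = _halve_once(out)
    return out


# ---------------------------------------------------------------------------
# CXML
# ---------------------------------------------------------------------------

def write_cxml(collection: Collection) -> bytes:
    """Serialize to CXML, deterministically (byte-identical across runs)."""
    collection.validate()
    root = ET.Element(
        "Collection",
        {"xmlns": CXML_NS, "Name": collection.name, "SchemaVersion": "1.0"},
    )
    cats = ET.SubElement(root, "FacetCategories")
    types = {}
    for cat in collection.facet_categories:
        ET.SubElement(cats, "FacetCategory", {"Name": cat.name, "Type": cat.type})
        types[cat.name] = cat.type
    items_el = ET.SubElement(root, "Items", {"ImgBase": collection.dzc_ref})
    for item in collection.items:
        item_el = ET.SubElement(
            items_el,
            "Item",
            {"Id": str(item.id), "Img": item.img_ref, "Name": item.name},
        )
        if item.facets:
            facets_el = ET.SubElement(item_el, "Facets")
            for cat in collection.facet_categories:
                if cat.name not in item.facets:
                    continue
                facet_el = ET.SubElement(facets_el, "Facet", {"Name": cat.name})
                for v in item.facets[cat.name]:
                    if types[cat.name] == "Number":
                        ET.SubElement(facet_el, "Number", {"Value": _fmt_num(v)})
                    else:
                        ET.SubElement(facet_el, "String", {"Value": str(v)})
    return ET.tostring(root, encoding="utf-8", xml_declaration=True)


def _local(tag: str) -> str:
    return tag.split("}")[-1]


def read_cxml(xml_text: bytes | str) -> Collection:
    """Parse CXML back into the data model; unknown elements are ignored.

    Schema violations raise :class:`CollectionError` with an XPath-like
    locus, e.g. ``/Collection/Items/Item[2]: missing Id``.
    """
    root = ET.fromstring(xml_text)
    if _local(root.tag) != "Collection":
        raise CollectionError(f"/: root element is {_local(root.tag)!r}, not Collection")
    name = root.attrib.get("Name", "")
    categories: list[FacetCategory] = []
    items: list[CollectionItem] = []
    dzc_ref = "collection.dzc"
    for child in root:
        tag = _local(child.tag)
        if tag == "FacetCategories":
            for i, cat_el in enumerate(child):
                if _local(cat_el.tag) != "FacetCategory":
                    continue
                if "Name" not in cat_el.attrib:
                    raise CollectionError(
                        f"/Collection/FacetCategories/FacetCategory[{i}]: missing Name"
                    )
                ftype = cat_el.attrib.get("Type", "String")
                if ftype not in ("String", "Number"):
                    raise CollectionError(
                        f"/Collection/FacetCategories/FacetCategory[{i}]: "
                        f"unsupported Type {ftype!r}"
                    )
                categories.append(FacetCategory(cat_el.attrib["Name"], ftype))
        elif tag == "Items":
            dzc_ref = child.attrib.get("ImgBase", dzc_ref)
            types = {c.name: c.type for c in categories}
            for i, item_el in enumerate(child):
                if _local(item_el.tag) != "Item":
                    continue
                locus = f"/Collection/Items/Item[{i}]"
                if "Id" not in item_el.attrib:
                    raise CollectionError(f"{locus}: missing Id")
                facets: dict = {}
                for sub in item_el:
                    if _local(sub.tag) != "Facets":
                        continue
                    for facet_el in sub:
                        if _local(facet_el.tag) != "Facet":
                            continue
                        fname = facet_el.attrib.get("Name")
                        if fname is None:
                            raise CollectionError(f"{locus}/Facets/Facet: missing Name")
                        if fname not in types:
                            raise CollectionError(
                                f"{locus}/Facets/Facet: undeclared category {fname!r}"
                            )
                        values: list = []
                        for v_el in facet_el:
                            vtag = _local(v_el.tag)
                            if vtag not in ("String", "Number"):
                                continue
                            if vtag != types[fname]:
                                raise CollectionError(
                                    f"{locus}/Facets/Facet[@Name={fname!r}]: "
                                    f"{vtag} value in a {types[fname]} facet"
                                )
                            raw = v_el.attrib.get("Value")
                            if raw is None:
                                raise CollectionError(
                                    f"{locus}/Facets/Facet[@Name={fname!r}]: missing Value"
                                )
                            values.append(float(raw) if vtag == "Number" else raw)
                        if values:
                            facets[fname] = tuple(values)
                items.append(
                    CollectionItem(
                        id=int(item_el.attrib["Id"]),
                        name=item_el.attrib.get("Name", ""),
                        img_ref=item_el.attrib.get("Img", f"#{item_el.attrib['Id']}"),
                        facets=facets,
                    )
                )
    return Collection(name, categories, items, dzc_ref)


# ---------------------------------------------------------------------------
# Image manifest + assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ManifestEntry:
    file: str
    taxon: str
    author: str
    image_type: str


def parse_manifest(csv_text: str) -> list[ManifestEntry]:
    """Read the image manifest CSV (columns: file, taxon, author, image_type)."""
    rows = list(csv.reader(io.StringIO(csv_text)))
    rows = [r for r in rows if any(c.strip() for c in r)]
    if not rows:
        raise CollectionError("empty manifest: header required")
    header = [h.strip().lower() for h in rows[0]]
    required = ["file", "taxon", "author", "image_type"]
    missing = [c for c in required if c not in header]
    if missing:
        raise CollectionError(f"manifest missing columns: {missing}")
    idx = {c: header.index(c) for c in required}
    entries = []
    for row in rows[1:]:
        entries.append(
            ManifestEntry(
                file=row[idx["file"]].strip(),
                taxon=row[idx["taxon"]].strip(),
                author=row[idx["author"]].strip(),
                image_type=row[idx["image_type"]].strip(),
            )
        )
    return entries


def write_manifest(entries: list[ManifestEntry]) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["file", "taxon", "author", "image_type"])
    for e in entries:
        writer.writerow([e.file, e.taxon, e.author, e.image_type])
    return buf.getvalue()


def assemble_collection(
    matrix: Matrix,
    manifest: list[ManifestEntry],
    dzi_index: dict | None = None,
    dzc_ref: str = "collection.dzc",
    name: str = "collection",
    label_cap: int = 40,
) -> Collection:
    """Join matrix scores with the image manifest into a faceted collection.

    One item per image, in manifest order; each item inherits every facet
    value of its taxon and adds its own "Image author" / "Image type". The
    taxon itself travels as a "Species" String facet (prepended when the
    matrix has no such character). Taxa that have no image are omitted with
    a logged warning; an image whose taxon is absent from the matrix is an
    error naming the file.
    """
    categories = list(facet_schema(matrix, max_label_len=label_cap))
    names = {c.name for c in categories}
    if SPECIES_FACET not in names:
        categories.insert(0, FacetCategory(SPECIES_FACET, "String"))
    for extra in (AUTHOR_FACET, TYPE_FACET):
        if extra not in names:
            categories.append(FacetCategory(extra, "String"))

    taxa = {t.taxon: t for t in matrix.taxa}
    items: list[CollectionItem] = []
    char_by_name = {c.name: c for c in matrix.characters}
    for entry in manifest:
        if entry.taxon not in taxa:
            raise CollectionError(
                f"image {entry.file!r} references unknown taxon {entry.taxon!r}"
            )
        score = taxa[entry.taxon]
        facets: dict = {SPECIES_FACET: (entry.taxon,)}
        for char in matrix.characters:
            value = score.get(char.name)
            if value is UNKNOWN:
                continue
            label = char.name[:label_cap]
            if char.kind == CATEGORICAL:
                facets[label] = tuple(s for s in char.states if s in value)
            else:
                lo, hi = value
                facets[label] = (lo,) if lo == hi else (lo, hi)
        facets[AUTHOR_FACET] = (entry.author,)
        facets[TYPE_FACET] = (entry.image_type,)
        item_id = len(items)
        items.append(
            CollectionItem(
                id=item_id,
                name=f"{entry.taxon} - {Path(entry.file).stem}",
                img_ref=f"#{item_id}",
                facets=facets,
            )
        )
    imaged = {e.taxon for e in manifest}
    for t in matrix.taxa:
        if t.taxon not in imaged:
            logger.warning("taxon %r has no images; omitted from collection", t.taxon)
    return Collection(name, categories, items, dzc_ref)


def load_assets(manifest: list[ManifestEntry], images_dir: Path) -> list[ImageAsset]:
    """Resolve manifest entries to on-disk images with measured dimensions."""
    from PIL import Image

    assets = []
    for entry in manifest:
        path = Path(images_dir) / entry.file
        with Image.open(path) as im:
            w, h = im.size
        assets.append(
            ImageAsset(
                path=path,
                width=w,
                height=h,
                taxon=entry.taxon,
                author=entry.author,
                image_type=entry.image_type,
            )
        )
    return assets
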