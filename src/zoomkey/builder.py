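"""End-to-end build orchestration, static serving, HTML export.

The build mirrors the production workflow of a zoomable visual key: read
the character matrix, read the image manifest, tile every image into its
own Deep Zoom pyramid (DZI), pack per-item thumbnails into one Deep Zoom
collection (DZC), join matrix and manifest into the faceted CXML, and drop
everything into one deployable directory. Per-image failures are logged
and skipped — a long tiling run must not die on one bad file — while
matrix errors abort, since every downstream artefact depends on the
schema. Identical inputs produce byte-identical CXML and DZC descriptors.

Serving needs one piece of non-default configuration: ``.cxml``, ``.dzc``
and ``.dzi`` must go out as ``text/xml`` or viewers silently fail.
"""

from __future__ import annotations

import html
import json
import logging
import threading
from dataclasses import dataclass, field
from functools import partial
from http.server import SimpleHTTPRequestHandler, ThreadingHTTPServer
from pathlib import Path

import yaml

from . import collection as coll
from . import keyengine, matrix as mx, pyramid

logger = logging.getLogger(__name__)

#: extension → Content-Type; the XML trio is the part that bites.
MIME_TYPES = {
    ".cxml": "text/xml",
    ".dzc": "text/xml",
    ".dzi": "text/xml",
    ".xml": "text/xml",
    ".jpeg": "image/jpeg",
    ".jpg": "image/jpeg",
    ".png": "image/png",
    ".html": "text/html",
    ".json": "application/json",
}


class BuildError(RuntimeError):
    pass


@dataclass
class BuildConfig:
    """Everything one build needs; loadable from YAML/JSON."""

    matrix_path: Path
    manifest_path: Path
    images_dir: Path
    out_dir: Path
    tile_size: int = 256
    overlap: int = 1
    format: str = "jpeg"
    jpeg_quality: int = 90
    label_cap: int = 40
    collection_name: str = "collection"
    max_collection_level: int = 8
    megapixel_cap: float | None = None  # pre-resize cap; None = off

    @property
    def pyramid_spec(self) -> pyramid.PyramidSpec:
        return pyramid.PyramidSpec(
            self.tile_size, self.overlap, self.format, self.jpeg_quality
        )

    @classmethod
    def from_file(cls, path: Path) -> "BuildConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("matrix_path", "manifest_path", "images_dir", "out_dir"):
            if key not in raw:
                raise BuildError(f"config missing required key {key!r}")
        kwargs = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        for key in ("matrix_path", "manifest_path", "images_dir", "out_dir"):
            kwargs[key] = Path(kwargs[key])
        return cls(**kwargs)


@dataclass
class BuildReport:
    images_tiled: int = 0
    images_failed: int = 0
    items: int = 0
    facet_categories: int = 0
    tile_files: int = 0
    warnings: list = field(default_factory=list)

    def to_json(self) -> dict:
        return {
            "images_tiled": self.images_tiled,
            "images_failed": self.images_failed,
            "items": self.items,
            "facet_categories": self.facet_categories,
            "tile_files": self.tile_files,
            "warnings": list(self.warnings),
        }


def build(config: BuildConfig) -> BuildReport:
    """Run the whole pipeline into ``config.out_dir``."""
    report = BuildReport()
    spec = config.pyramid_spec
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    logger.info("stage 1/4: matrix")
    matrix = mx.parse_matrix(
        Path(config.matrix_path).read_text(),
        mx.MatrixConfig(label_cap=config.label_cap),
    )

    logger.info("stage 2/4: image pyramids")
    manifest = coll.parse_manifest(Path(config.manifest_path).read_text())
    thumbnails = []
    sources = []
    kept_entries = []
    cap = 1 << config.max_collection_level
    for entry in manifest:
        path = Path(config.images_dir) / entry.file
        name = Path(entry.file).stem
        try:
            raster = pyramid.load_raster(path)
            if config.megapixel_cap is not None:
                while raster.shape[0] * raster.shape[1] > config.megapixel_cap * 1e6:
                    raster = pyramid._halve_once(raster)
            h, w = raster.shape[:2]
            asset = pyramid.ImageAsset(
                path, w, h, entry.taxon, entry.author, entry.image_type
            )
            result = pyramid.build_dzi(asset, spec, out_dir, name=name, raster=raster)
        except Exception as exc:  # per-image resilience
            msg = f"image {entry.file!r} failed: {exc}"
            logger.warning(msg)
            report.warnings.append(msg)
            report.images_failed += 1
            continue
        report.images_tiled += 1
        report.tile_files += result.tile_count
        thumbnails.append(coll.make_thumbnail(raster, cap))
        sources.append(f"{name}.dzi")
        kept_entries.append(entry)

    logger.info("stage 3/4: collection packing")
    dzc = coll.build_dzc(
        thumbnails,
        spec,
        out_dir,
        name=config.collection_name,
        max_level=config.max_collection_level,
        sources=sources,
    )
    report.tile_files += dzc.tile_count

    logger.info("stage 4/4: CXML")
    collection = coll.assemble_collection(
        matrix,
        kept_entries,
        dzc_ref=f"{config.collection_name}.dzc",
        name=config.collection_name,
        label_cap=config.label_cap,
    )
    imaged = {e.taxon for e in kept_entries}
    for t in matrix.taxa:
        if t.taxon not in imaged:
            report.warnings.append(f"taxon {t.taxon!r} has no images")
    (out_dir / f"{config.collection_name}.cxml").write_bytes(
        coll.write_cxml(collection)
    )
    report.items = len(collection.items)
    report.facet_categories = len(collection.facet_categories)
    logger.info(
        "build done: %d images tiled, %d items, %d tile files",
        report.images_tiled,
        report.items,
        report.tile_files,
    )
    return report


# ---------------------------------------------------------------------------
# Static server
# ---------------------------------------------------------------------------

class _KeyRequestHandler(SimpleHTTPRequestHandler):
    extensions_map = {**SimpleHTTPRequestHandler.extensions_map, **MIME_TYPES}

    def log_message(self, fmt, *args):  # route through logging, not stderr
        logger.debug("%s - %s", self.address_string(), fmt % args)


def make_server(root: Path, port: int = 0) -> ThreadingHTTPServer:
    """Create (without starting) a static server rooted at ``root``."""
    root = Path(root)
    if not root.is_dir():
        raise BuildError(f"server root {root} does not exist")
    handler = partial(_KeyRequestHandler, directory=str(root))
    return ThreadingHTTPServer(("127.0.0.1", port), handler)


def serve(root: Path, port: int = 8000) -> None:
    """Serve a built output directory until interrupted."""
    server = make_server(root, port)
    logger.info("serving %s on port %d", root, server.server_address[1])
    try:
        server.serve_forever()
    finally:
        server.server_close()


def serve_background(root: Path, port: int = 0) -> tuple[ThreadingHTTPServer, int]:
    """Start a server on a daemon thread; returns (server, bound port)."""
    server = make_server(root, port)
    thread = threading.Thread(target=server.serve_forever, daemon=True)
    thread.start()
    return server, server.server_address[1]


# ---------------------------------------------------------------------------
# Static HTML export
# ---------------------------------------------------------------------------

_PAGE = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>{title}</title>
<style>
body {{ font-family: sans-serif; margin: 1.5rem; }}
.grid {{ display: flex; flex-wrap: wrap; gap: 8px; }}
.card {{ border: 1px solid #ccc; padding: 4px; width: 150px; font-size: 12px; }}
.bar {{ background: #4a7; height: 14px; display: inline-block; }}
.hist td {{ font-size: 12px; padding: 1px 6px; }}
#normalized {{ display: none; }}
body.norm #normalized {{ display: block; }}
body.norm #allitems {{ display: none; }}
</style>
</head>
<body>
<h1>{title}</h1>
<p>{n_items} items &middot; {n_facets} facet categories</p>
<label><input type="checkbox" onchange="document.body.classList.toggle('norm', this.checked)">
one representative image per taxon ({rep_label})</label>
<div id="allitems"><h2>All items</h2><div class="grid">{cards}</div></div>
<div id="normalized"><h2>Normalized view ({n_norm} taxa)</h2>
<div class="grid">{norm_cards}</div></div>
<h2>Histograms</h2>
{histograms}
<script>var collection = {payload};</script>
</body>
</html>
"""


def export_html(
    out_dir: Path,
    collection_name: str = "collection",
    representative: tuple = (coll.AUTHOR_FACET, "Mackenzie, K. K."),
) -> Path:
    """Write a self-contained ``index.html`` gallery next to the CXML.

    Grid of items, a normalization toggle showing at most one image per
    taxon, and histogram bars per categorical facet of the whole
    collection. No external runtime: plain HTML + a few lines of JS.
    """
    out_dir = Path(out_dir)
    cxml = (out_dir / f"{collection_name}.cxml").read_bytes()
    collection = coll.read_cxml(cxml)

    def card(item: coll.CollectionItem) -> str:
        return (
            f'<div class="card"><b>{html.escape(item.name)}</b><br>'
            f"img {html.escape(item.img_ref)}</div>"
        )

    cards = "".join(card(i) for i in collection.items)
    view = keyengine.normalize_view(collection.items, representative)
    norm_cards = "".join(card(i) for i in view.items)

    hist_blocks = []
    string_cats = [c for c in collection.facet_categories if c.type == "String"]
    for cat in string_cats:
        counts: dict[str, int] = {}
        for item in collection.items:
            for v in item.facets.get(cat.name, ()):
                counts[v] = counts.get(v, 0) + 1
        if not counts or cat.name == coll.SPECIES_FACET:
            continue
        peak = max(counts.values())
        rows = "".join(
            f"<tr><td>{html.escape(str(state))}</td>"
            f'<td><span class="bar" style="width:{int(120 * n / peak)}px"></span>'
            f" {n}</td></tr>"
            for state, n in sorted(counts.items())
        )
        hist_blocks.append(
            f"<h3>{html.escape(cat.name)}</h3><table class='hist'>{rows}</table>"
        )

    payload = json.dumps(
        {
            "name": collection.name,
            "items": [
                {"id": i.id, "name": i.name, "img": i.img_ref, "facets": i.facets}
                for i in collection.items
            ],
        },
        sort_keys=True,
    )
    page = _PAGE.format(
        title=html.escape(collection.name),
        n_items=len(collection.items),
        n_facets=len(collection.facet_categories),
        rep_label=html.escape(f"{representative[0]} = {representative[1]}"),
        cards=cards,
        norm_cards=norm_cards,
        n_norm=len(view.items),
        histograms="".join(hist_blocks),
        payload=payload,
    )
    path = out_dir / "index.html"
    path.write_text(page)
    return path
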