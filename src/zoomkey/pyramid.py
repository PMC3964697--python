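"""Deep Zoom image pyramids (DZI): level geometry, tiling, building.

A Deep Zoom pyramid is a geometric series of images: level ``L`` (the base)
is the full-resolution picture, and each level below is the ceil-halving of
the one above, down to level 0, a single pixel. Every level is cut into
fixed-size tiles (default 256 px) that overlap their neighbours by a small
margin (default 1 px) so renderers can seam tiles without filtering
artefacts. Tiles live on disk as ``{name}_files/{level}/{col}_{row}.{fmt}``
next to a small XML descriptor ``{name}.dzi``.

Conventions (fixed so independent implementations agree):

* level dimensions and tile grids use ceiling division;
* pixel averaging uses area weights with round-half-even;
* coordinates are 0-based, x rightward / y downward, rectangles half-open;
* each level is produced by iterated halving of the base image, so the
  halving recurrence holds exactly by construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np
from PIL import Image
from scipy import sparse

logger = logging.getLogger(__name__)

DEEPZOOM_NS = "http://schemas.microsoft.com/deepzoom/2008"


class PyramidError(ValueError):
    pass


@dataclass(frozen=True)
class PyramidSpec:
    """Tiling parameters for one pyramid."""

    tile_size: int = 256
    overlap: int = 1
    format: str = "jpeg"
    jpeg_quality: int = 90

    def __post_init__(self) -> None:
        if self.tile_size < 1:
            raise PyramidError("tile_size must be >= 1")
        if not (0 <= self.overlap < self.tile_size):
            raise PyramidError("overlap must satisfy 0 <= overlap < tile_size")
        if self.format not in ("jpeg", "png"):
            raise PyramidError(f"unsupported tile format {self.format!r}")
        if not (1 <= self.jpeg_quality <= 100):
            raise PyramidError("jpeg_quality must be in 1..100")


@dataclass(frozen=True)
class ImageAsset:
    """One source image with its identification metadata."""

    path: Path
    width: int
    height: int
    taxon: str
    author: str = ""
    image_type: str = ""

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise PyramidError(f"{self.path}: dimensions must be >= 1")


@dataclass(frozen=True)
class TileAddress:
    level: int
    col: int
    row: int

    def __post_init__(self) -> None:
        if self.level < 0 or self.col < 0 or self.row < 0:
            raise PyramidError("tile address components must be >= 0")


def max_level(width: int, height: int) -> int:
    """Smallest L with ``2**L >= max(width, height)``.

    Level 0 is the 1×1 apex; level L holds the full-resolution image.
    """
    if width < 1 or height < 1:
        raise PyramidError("image dimensions must be >= 1")
    return (max(width, height) - 1).bit_length()


def level_dimensions(width: int, height: int, level: int) -> tuple[int, int]:
    """Dimensions of ``level``, by ceil-halving (max_level − level) times."""
    top = max_level(width, height)
    if not (0 <= level <= top):
        raise PyramidError(f"level {level} outside 0..{top}")
    w, h = width, height
    for _ in range(top - level):
        w = (w + 1) // 2
        h = (h + 1) // 2
    return w, h


def tile_grid(width_l: int, height_l: int, spec: PyramidSpec) -> tuple[int, int]:
    """Number of tile (columns, rows) covering a level."""
    if width_l < 1 or height_l < 1:
        raise PyramidError("level dimensions must be >= 1")
    t = spec.tile_size
    return (width_l + t - 1) // t, (height_l + t - 1) // t


def tile_bounds(
    addr: TileAddress, width_l: int, height_l: int, spec: PyramidSpec
) -> tuple[int, int, int, int]:
    """Half-open pixel rectangle ``(x0, y0, x1, y1)`` of one tile.

    The nominal tile_size cell is expanded by ``overlap`` on each side that
    has a neighbouring tile, then clipped to the level image; an interior
    tile therefore measures ``tile_size + 2*overlap`` on each axis.
    """
    cols, rows = tile_grid(width_l, height_l, spec)
    if not (addr.col < cols and addr.row < rows):
        raise PyramidError(
            f"tile ({addr.col},{addr.row}) outside grid {cols}x{rows}"
        )
    t, o = spec.tile_size, spec.overlap
    x0 = addr.col * t - (o if addr.col > 0 else 0)
    y0 = addr.row * t - (o if addr.row > 0 else 0)
    x1 = min((addr.col + 1) * t + (o if addr.col < cols - 1 else 0), width_l)
    y1 = min((addr.row + 1) * t + (o if addr.row < rows - 1 else 0), height_l)
    return x0, y0, x1, y1


def _halving_chain(width: int, height: int) -> list[tuple[int, int]]:
    chain = [(width, height)]
    while max(chain[-1]) > 1:
        w, h = chain[-1]
        chain.append(((w + 1) // 2, (h + 1) // 2))
    return chain


def _avg_operator(src: int, dst: int) -> sparse.csr_array:
    """(dst × src) area-weighted averaging operator for one axis."""
    scale = src / dst
    rows, cols, vals = [], [], []
    for j in range(dst):
        lo, hi = j * scale, (j + 1) * scale
        i0, i1 = int(math.floor(lo)), int(math.ceil(hi))
        for i in range(i0, min(i1, src)):
            w = min(hi, i + 1) - max(lo, i)
            if w > 0:
                rows.append(j)
                cols.append(i)
                vals.append(w / scale)
    return sparse.csr_array((vals, (rows, cols)), shape=(dst, src))


def _halve_once(img: np.ndarray) -> np.ndarray:
    h, w = img.shape[:2]
    ht, wt = (h + 1) // 2, (w + 1) // 2
    wr = _avg_operator(h, ht)
    wc = _avg_operator(w, wt)

    def one_plane(plane: np.ndarray) -> np.ndarray:
        tmp = wr @ plane.astype(np.float64)  # (ht, w)
        return (wc @ tmp.T).T  # (ht, wt)

    if img.ndim == 2:
        out = one_plane(img)
    else:
        out = np.stack(
            [one_plane(img[:, :, k]) for k in range(img.shape[2])], axis=2
        )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def downsample(image: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Area-weighted average downsampling to ``target = (width, height)``.

    The target must lie on the ceil-halving chain of the source dimensions;
    each halving step averages with area weights and rounds half-to-even, so
    every intermediate level is a concrete 8-bit image identical to the one
    the pyramid stores.
    """
    if image.dtype != np.uint8:
        raise PyramidError("downsample expects uint8 rasters")
    h, w = image.shape[:2]
    wt, ht = target
    chain = _halving_chain(w, h)
    if (wt, ht) not in chain:
        raise PyramidError(
            f"target {target} not on the halving chain of ({w}, {h})"
        )
    out = image
    while out.shape[1] != wt or out.shape[0] != ht:
        out = _halve_once(out)
    return out


@dataclass(frozen=True)
class DziResult:
    name: str
    descriptor_path: Path
    levels: int
    tile_count: int
    width: int
    height: int


def total_tiles(width: int, height: int, spec: PyramidSpec) -> int:
    """Closed-form Σ over levels of cols·rows for a pyramid."""
    total = 0
    for level in range(max_level(width, height) + 1):
        wl, hl = level_dimensions(width, height, level)
        cols, rows = tile_grid(wl, hl, spec)
        total += cols * rows
    return total


def dzi_descriptor(width: int, height: int, spec: PyramidSpec) -> bytes:
    """Serialize the DZI XML descriptor."""
    img = ET.Element(
        "Image",
        {
            "TileSize": str(spec.tile_size),
            "Overlap": str(spec.overlap),
            "Format": spec.format,
            "xmlns": DEEPZOOM_NS,
        },
    )
    ET.SubElement(img, "Size", {"Width": str(width), "Height": str(height)})
    return ET.tostring(img, encoding="utf-8", xml_declaration=True)


def parse_dzi(xml_bytes: bytes) -> tuple[int, int, PyramidSpec]:
    """Read (width, height, spec) back from a DZI descriptor."""
    root = ET.fromstring(xml_bytes)
    tag = root.tag.split("}")[-1]
    if tag != "Image":
        raise PyramidError(f"not a DZI descriptor (root {tag!r})")
    size = root.find(f"{{{DEEPZOOM_NS}}}Size")
    if size is None:
        size = root.find("Size")
    if size is None:
        raise PyramidError("DZI descriptor lacks a Size element")
    spec = PyramidSpec(
        tile_size=int(root.attrib["TileSize"]),
        overlap=int(root.attrib["Overlap"]),
        format=root.attrib["Format"],
    )
    return int(size.attrib["Width"]), int(size.attrib["Height"]), spec


def load_raster(path: Path) -> np.ndarray:
    """Load an image as a uint8 array (H×W grey or H×W×3 RGB)."""
    with Image.open(path) as im:
        if im.mode not in ("L", "RGB"):
            im = im.convert("RGB")
        return np.asarray(im)


def _save_tile(arr: np.ndarray, path: Path, spec: PyramidSpec) -> None:
    im = Image.fromarray(arr)
    if spec.format == "jpeg":
        im.save(path, format="JPEG", quality=spec.jpeg_quality)
    else:
        im.save(path, format="PNG")


def build_dzi(
    asset: ImageAsset,
    spec: PyramidSpec,
    out_dir: Path,
    name: str | None = None,
    raster: np.ndarray | None = None,
) -> DziResult:
    """Build the full tile tree and descriptor for one image.

    Writes ``{name}.dzi`` plus ``{name}_files/{level}/{col}_{row}.{fmt}``,
    one folder per level. ``raster`` may be supplied to skip re-reading the
    file (it must match the asset's dimensions).
    """
    out_dir = Path(out_dir)
    name = name or Path(asset.path).stem
    if raster is None:
        raster = load_raster(Path(asset.path))
    h, w = raster.shape[:2]
    if (w, h) != (asset.width, asset.height):
        raise PyramidError(
            f"{asset.path}: raster is {w}x{h}, asset declares "
            f"{asset.width}x{asset.height}"
        )
    top = max_level(w, h)
    files_dir = out_dir / f"{name}_files"
    tile_count = 0
    level_img = raster
    for level in range(top, -1, -1):
        wl, hl = level_dimensions(w, h, level)
        if (level_img.shape[1], level_img.shape[0]) != (wl, hl):
            level_img = _halve_once(level_img)
        level_dir = files_dir / str(level)
        level_dir.mkdir(parents=True, exist_ok=True)
        cols, rows = tile_grid(wl, hl, spec)
        for row in range(rows):
            for col in range(cols):
                x0, y0, x1, y1 = tile_bounds(
                    TileAddress(level, col, row), wl, hl, spec
                )
                tile = level_img[y0:y1, x0:x1]
                _save_tile(
                    tile, level_dir / f"{col}_{row}.{spec.format}", spec
                )
                tile_count += 1
    descriptor = out_dir / f"{name}.dzi"
    descriptor.write_bytes(dzi_descriptor(w, h, spec))
    logger.debug("built DZI %s: %d levels, %d tiles", name, top + 1, tile_count)
    return DziResult(name, descriptor, top + 1, tile_count, w, h)
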