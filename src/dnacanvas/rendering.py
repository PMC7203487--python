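"""Nucleotide-to-color painting, raster assembly, labels and DeepZoom output.

One base = one pixel.  The default palette keeps A, C and T in green/blue
hues with G as the single warm hue, so G-rich regions stand out while the
overall image stays cool; the values are the Okabe-Ito colorblind-safe
set.  Unknown bases are neutral gray and alignment gaps are background
white, so gap runs read as whitespace.

The DeepZoom pyramid halves the image with area averaging at each level
(pixel colors merge rather than alias away), cut into 256 px tiles named
``{level}/{col}_{row}.png`` next to an XML descriptor any DeepZoom viewer
can consume.
"""

from __future__ import annotations

import logging
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw, ImageFont

from .tile_layout import ContigLayoutMap, CapacityError

logger = logging.getLogger(__name__)

__all__ = [
    "Palette",
    "default_palette",
    "render_raster",
    "build_pyramid",
    "draw_label",
    "PATH_TRACE_COLOR",
]

PATH_TRACE_COLOR = (200, 200, 200)  # pale gray used to trace the curve at scale > 1


@dataclass
class Palette:
    """Mapping from sequence character to RGB color."""

    colors: dict[str, tuple[int, int, int]]
    background: tuple[int, int, int] = (255, 255, 255)
    softmask_dim: bool = False  # dim lowercase (soft-masked) bases

    def color_of(self, ch: str) -> tuple[int, int, int]:
        c = self.colors.get(ch)
        if c is None:
            c = self.colors.get(ch.upper())
        if c is None:
            c = self.colors.get("N", (220, 220, 220))
        if self.softmask_dim and ch.islower():
            c = tuple((v + 255) // 2 for v in c)
        return c

    def as_lookup(self) -> np.ndarray:
        """256 x 3 uint8 table indexed by character ordinal."""
        table = np.tile(np.array(self.colors.get("N", (220, 220, 220)), np.uint8), (256, 1))
        for ch, rgb in self.colors.items():
            base = np.array(rgb, np.uint8)
            for variant in {ch, ch.upper(), ch.lower()}:
                rgb_v = base
                if self.softmask_dim and variant.islower():
                    rgb_v = ((base.astype(np.uint16) + 255) // 2).astype(np.uint8)
                table[ord(variant)] = rgb_v
        return table


def default_palette() -> Palette:
    """Colorblind-safe defaults: greens/blues predominate, G is the warm hue."""
    return Palette(
        colors={
            "A": (0, 158, 115),    # green
            "C": (0, 114, 178),    # blue
            "T": (86, 180, 233),   # sky blue
            "G": (230, 159, 0),    # orange: the one warm hue
            "N": (220, 220, 220),  # neutral gray for unknown sequence
            "-": (255, 255, 255),  # alignment gap = background
            "X": (90, 90, 90),
        },
        background=(255, 255, 255),
    )


def render_raster(
    cmap: ContigLayoutMap,
    layout,
    palette: Palette | None = None,
    margin: int = 0,
    trace_path: bool = True,
) -> Image.Image:
    """Paint every placed base at its layout pixel; whitespace = background.

    Works for both tile and Peano layouts (anything exposing
    ``index_to_pixel_array`` and ``capacity``).  For a Peano layout with
    ``scale > 1`` the pixels between consecutive bases are painted a
    neutral gray to trace the path when ``trace_path`` is set.
    """
    if palette is None:
        palette = default_palette()
    if cmap.total_span > layout.capacity:
        raise CapacityError(
            f"placed sequence span {cmap.total_span} exceeds layout capacity "
            f"{layout.capacity}"
        )
    lut = palette.as_lookup()
    xs_all: list[np.ndarray] = []
    ys_all: list[np.ndarray] = []
    cols_all: list[np.ndarray] = []
    scale = getattr(layout, "scale", 1)
    for name, start, length in cmap.entries:
        seq = cmap.contigs[name].seq
        idx = np.arange(start, start + length, dtype=np.int64)
        x, y = layout.index_to_pixel_array(idx)
        codes = np.frombuffer(seq.encode("latin-1"), dtype=np.uint8)
        xs_all.append(x)
        ys_all.append(y)
        cols_all.append(lut[codes])
        if scale > 1 and trace_path and length > 1:
            # paint midpoints between consecutive bases to show the curve
            mx = (x[:-1] + x[1:]) // 2
            my = (y[:-1] + y[1:]) // 2
            xs_all.append(mx)
            ys_all.append(my)
            cols_all.append(np.tile(np.array(PATH_TRACE_COLOR, np.uint8), (len(mx), 1)))
    if not xs_all or sum(len(a) for a in xs_all) == 0:
        canvas = np.tile(np.array(palette.background, np.uint8), (1, 1, 1))
        return Image.fromarray(canvas, "RGB")
    xs = np.concatenate(xs_all)
    ys = np.concatenate(ys_all)
    cols = np.concatenate(cols_all)
    width = int(xs.max()) + 1 + 2 * margin
    height = int(ys.max()) + 1 + 2 * margin
    canvas = np.tile(np.array(palette.background, np.uint8), (height, width, 1))
    canvas[ys + margin, xs + margin] = cols
    return Image.fromarray(canvas, "RGB")


def _halve(arr: np.ndarray) -> np.ndarray:
    """Downscale by 2 with area averaging; odd edges replicate the last row/col."""
    h, w = arr.shape[:2]
    if h % 2:
        arr = np.concatenate([arr, arr[-1:]], axis=0)
    if w % 2:
        arr = np.concatenate([arr, arr[:, -1:]], axis=1)
    h2, w2 = arr.shape[0] // 2, arr.shape[1] // 2
    blocks = arr.reshape(h2, 2, w2, 2, -1).astype(np.float64)
    return np.rint(blocks.mean(axis=(1, 3))).astype(np.uint8)


def build_pyramid(
    image: Image.Image,
    out_dir: str | Path,
    tile_size: int = 256,
    name: str = "image",
) -> dict:
    """Write a DeepZoom (DZI) pyramid for ``image``.

    Level ``L = ceil(log2(max dimension))`` is the full image; each lower
    level halves both dimensions (area average) down to 1x1 at level 0.
    Tiles are written as ``{name}_files/{level}/{col}_{row}.png`` with an
    XML descriptor at ``{name}.dzi``.  Returns a descriptor dict with the
    level geometry.
    """
    if image.width < 1 or image.height < 1:
        raise ValueError("cannot pyramid an empty image")
    out_dir = Path(out_dir)
    files_dir = out_dir / f"{name}_files"
    max_dim = max(image.width, image.height)
    top = max(int(math.ceil(math.log2(max_dim))), 0) if max_dim > 1 else 0
    arr = np.asarray(image.convert("RGB"))
    levels: dict[int, tuple[int, int]] = {}
    level = top
    while True:
        levels[level] = (arr.shape[1], arr.shape[0])
        level_dir = files_dir / str(level)
        level_dir.mkdir(parents=True, exist_ok=True)
        n_cols = -(-arr.shape[1] // tile_size)
        n_rows = -(-arr.shape[0] // tile_size)
        for col in range(n_cols):
            for row in range(n_rows):
                tile = arr[
                    row * tile_size : (row + 1) * tile_size,
                    col * tile_size : (col + 1) * tile_size,
                ]
                Image.fromarray(tile, "RGB").save(level_dir / f"{col}_{row}.png")
        if level == 0:
            break
        arr = _halve(arr)
        level -= 1
    root = ET.Element(
        "Image",
        TileSize=str(tile_size),
        Overlap="0",
        Format="png",
        xmlns="http://schemas.microsoft.com/deepzoom/2008",
    )
    ET.SubElement(root, "Size", Width=str(image.width), Height=str(image.height))
    out_dir.mkdir(parents=True, exist_ok=True)
    ET.ElementTree(root).write(out_dir / f"{name}.dzi", xml_declaration=True, encoding="utf-8")
    return {
        "top_level": top,
        "levels": levels,
        "tile_size": tile_size,
        "descriptor": str(out_dir / f"{name}.dzi"),
    }


def pyramid_level(image: Image.Image, steps: int) -> np.ndarray:
    """The image area-averaged down by ``2**steps`` (no files written)."""
    arr = np.asarray(image.convert("RGB"))
    for _ in range(steps):
        arr = _halve(arr)
    return arr


def _font(size: int):
    try:
        return ImageFont.load_default(size=size)
    except TypeError:  # older Pillow: fixed-size bitmap font
        return ImageFont.load_default()


def draw_label(
    image: Image.Image,
    text: str,
    bbox: tuple[int, int, int, int],
    anchor: str = "top",
    opacity: float = 1.0,
    font_size: int = 14,
) -> Image.Image:
    """Rasterize ``text`` inside ``bbox`` (x0, y0, x1, y1 exclusive).

    ``anchor`` places the text at the top edge, bottom edge, or centroid of
    the box.  If no font size down to 6 px fits the box, the label is
    skipped with a logged warning (tiny features stay unlabeled rather
    than unreadable).
    """
    if anchor not in {"top", "bottom", "centroid"}:
        raise ValueError(f"unknown anchor {anchor!r}")
    x0, y0, x1, y1 = bbox
    box_w, box_h = x1 - x0, y1 - y0
    size = font_size
    font = None
    while size >= 6:
        candidate = _font(size)
        tb = candidate.getbbox(text)
        tw, th = tb[2] - tb[0], tb[3] - tb[1]
        if tw <= box_w and th <= box_h:
            font = candidate
            break
        size -= 1
    if font is None:
        logger.warning("label %r skipped: bbox %s too small for any font", text, bbox)
        return image
    tb = font.getbbox(text)
    tw, th = tb[2] - tb[0], tb[3] - tb[1]
    tx = x0 + (box_w - tw) // 2
    if anchor == "top":
        ty = y0
    elif anchor == "bottom":
        ty = y1 - th - 1
    else:
        ty = y0 + (box_h - th) // 2
    base = image.convert("RGBA")
    overlay = Image.new("RGBA", base.size, (0, 0, 0, 0))
    draw = ImageDraw.Draw(overlay)
    alpha = int(round(255 * max(0.0, min(1.0, opacity))))
    draw.text((tx - tb[0], ty - tb[1]), text, fill=(0, 0, 0, alpha), font=font)
    return Image.alpha_composite(base, overlay).convert("RGB")
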