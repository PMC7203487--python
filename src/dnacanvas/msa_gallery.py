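"""Render a directory of multiple sequence alignments as one labeled canvas.

Each FASTA file in the directory is one MSA block: rows are the aligned
records (all the same length), columns are alignment positions.  Blocks
are packed left to right into shelves and wrap when the canvas width is
exceeded — a deterministic panoramic gallery rather than an optimized bin
packing.  Block origins are recorded so any canvas pixel can be resolved
back to (file, record, alignment column).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .io_formats import FormatError, read_fasta
from .rendering import Palette, default_palette, draw_label

__all__ = ["GalleryError", "MSABlock", "GalleryCanvas", "load_gallery", "layout_gallery", "render_gallery"]

DEFAULT_MAX_WIDTH = 4000
MARGIN = 5        # pixels between blocks and shelves
LABEL_HEIGHT = 12  # reserved above each block for the file-name label


class GalleryError(ValueError):
    """A gallery directory or block violates the MSA contract."""


@dataclass
class MSABlock:
    """One MSA: equal-length aligned rows plus its placement origin."""

    name: str
    rows: list[str]
    origin: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not self.rows:
            raise GalleryError(f"{self.name}: empty alignment")
        widths = {len(r) for r in self.rows}
        if len(widths) != 1:
            raise GalleryError(
                f"{self.name}: ragged alignment (row lengths {sorted(widths)})"
            )
        if self.width < 1:
            raise GalleryError(f"{self.name}: zero-width alignment")

    @property
    def width(self) -> int:
        return len(self.rows[0])

    @property
    def height(self) -> int:
        return len(self.rows)


@dataclass
class GalleryCanvas:
    blocks: list[MSABlock]
    width: int
    height: int

    def lookup(self, x: int, y: int) -> tuple[str, int, int] | None:
        """Resolve a canvas pixel to (file name, record index, column)."""
        for block in self.blocks:
            ox, oy = block.origin
            if ox <= x < ox + block.width and oy <= y < oy + block.height:
                return block.name, y - oy, x - ox
        return None


def load_gallery(directory: str | Path, sort: str = "alphabetical") -> list[MSABlock]:
    """Load every FASTA file in ``directory`` as an MSA block."""
    if sort not in {"alphabetical", "by_count"}:
        raise ValueError(f"unknown sort {sort!r}")
    directory = Path(directory)
    paths = sorted(
        p for p in directory.iterdir()
        if p.suffix.lower() in {".fa", ".fasta", ".fna", ".mfa"}
    )
    if not paths:
        raise GalleryError(f"{directory}: no FASTA files found")
    blocks = []
    for p in paths:
        try:
            contigs = read_fasta(p)
            blocks.append(MSABlock(name=p.name, rows=[c.seq for c in contigs]))
        except (FormatError, GalleryError) as exc:
            raise GalleryError(f"{p.name}: {exc}") from exc
    if sort == "by_count":
        blocks.sort(key=lambda b: -b.height)
    return blocks


def layout_gallery(
    blocks: Sequence[MSABlock], max_width: int = DEFAULT_MAX_WIDTH
) -> GalleryCanvas:
    """Shelf-pack blocks left to right, wrapping at ``max_width``."""
    too_wide = [b.name for b in blocks if b.width > max_width]
    if too_wide:
        raise GalleryError(
            f"blocks wider than max_width={max_width}: {', '.join(too_wide)}; "
            "increase the canvas width"
        )
    x = 0
    shelf_y = 0
    shelf_height = 0
    canvas_w = 0
    for block in blocks:
        if x > 0 and x + block.width > max_width:
            shelf_y += shelf_height + MARGIN
            x = 0
            shelf_height = 0
        block.origin = (x, shelf_y + LABEL_HEIGHT)
        shelf_height = max(shelf_height, block.height + LABEL_HEIGHT)
        x += block.width + MARGIN
        canvas_w = max(canvas_w, x - MARGIN)
    return GalleryCanvas(
        blocks=list(blocks), width=canvas_w, height=shelf_y + shelf_height
    )


def render_gallery(canvas: GalleryCanvas, palette: Palette | None = None) -> Image.Image:
    """Paint all blocks and their file-name labels onto one image."""
    if palette is None:
        palette = default_palette()
    lut = palette.as_lookup()
    arr = np.tile(
        np.array(palette.background, np.uint8), (max(canvas.height, 1), max(canvas.width, 1), 1)
    )
    for block in canvas.blocks:
        ox, oy = block.origin
        codes = np.frombuffer("".join(block.rows).encode("latin-1"), dtype=np.uint8)
        arr[oy : oy + block.height, ox : ox + block.width] = lut[codes].reshape(
            block.height, block.width, 3
        )
    img = Image.fromarray(arr, "RGB")
    for block in canvas.blocks:
        ox, oy = block.origin
        img = draw_label(
            img,
            block.name,
            (ox, oy - LABEL_HEIGHT, max(ox + block.width, ox + 80), oy),
            anchor="bottom",
            opacity=1.0,
            font_size=10,
        )
    return img
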