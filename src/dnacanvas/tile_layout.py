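"""Nested-radix tile layout: an invertible 1D index <-> 2D pixel map.

The layout is a mixed-radix number system whose digits alternate between
the x and y axes (level 0 = x, level 1 = y, level 2 = x, ...).  With the
default radices ``(100, 1000, 100, 26, 999)`` and paddings
``(0, 0, 3, 9, 700)`` a sequence is arranged as rows of 100 bases, columns
of 1000 rows (100 kb), mega-rows of 100 columns (10 Mb), mega-columns of
26 mega-rows (260 Mb per chromosome slot), 999 mega-columns side by side.
Paddings are trailing whitespace per unit, so adjacent columns are
separated by 3 px, mega-rows by 9 px and mega-columns by 700 px.

Every drawable pixel maps back to exactly one sequence index
(:func:`pixel_to_index` returns ``None`` on whitespace), which is what
powers sequence retrieval from a rendered image.
"""

from __future__ import annotations

import ast
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io_formats import Contig

__all__ = [
    "LayoutError",
    "CapacityError",
    "TileLayout",
    "ContigLayoutMap",
    "build_layout",
    "parse_custom_layout",
    "place_contigs",
    "extract_snippet",
    "DEFAULT_RADICES",
    "DEFAULT_PADDINGS",
    "DEFAULT_SNIPPET_LENGTH",
]

DEFAULT_RADICES = (100, 1000, 100, 26, 999)
DEFAULT_PADDINGS = (0, 0, 3, 9, 700)
DEFAULT_SNIPPET_LENGTH = 300


class LayoutError(ValueError):
    """Invalid layout configuration."""


class CapacityError(ValueError):
    """Sequence does not fit into the layout."""


class TileLayout:
    """Mixed-radix tiling with per-level trailing padding.

    Parameters
    ----------
    radices:
        Unit counts per level; level ``i`` lives on the x axis when ``i``
        is even and on the y axis when odd.
    paddings:
        Trailing whitespace (pixels) after each level-``i`` unit.
    """

    def __init__(
        self,
        radices: Sequence[int] = DEFAULT_RADICES,
        paddings: Sequence[int] = DEFAULT_PADDINGS,
    ):
        radices = tuple(int(r) for r in radices)
        paddings = tuple(int(p) for p in paddings)
        if len(radices) != len(paddings):
            raise LayoutError(
                f"radices ({len(radices)}) and paddings ({len(paddings)}) differ in length"
            )
        if len(radices) < 2:
            raise LayoutError("a tile layout needs at least two levels (x and y)")
        if any(r < 1 for r in radices):
            raise LayoutError(f"radices must be positive, got {radices}")
        if any(p < 0 for p in paddings):
            raise LayoutError(f"paddings must be non-negative, got {paddings}")
        self.radices = radices
        self.paddings = paddings
        strides = []
        for i in range(len(radices)):
            if i < 2:
                strides.append(1 + paddings[i])
            else:
                strides.append(radices[i - 2] * strides[i - 2] + paddings[i])
        self.strides = tuple(strides)
        # place value of each digit in the index number system
        pv = [1]
        for r in radices[:-1]:
            pv.append(pv[-1] * r)
        self.place_values = tuple(pv)
        self.capacity = pv[-1] * radices[-1]
        self.x_levels = tuple(i for i in range(len(radices)) if i % 2 == 0)
        self.y_levels = tuple(i for i in range(len(radices)) if i % 2 == 1)

    def __repr__(self) -> str:
        return f"TileLayout(radices={self.radices}, paddings={self.paddings})"

    # -- forward map --------------------------------------------------------

    def index_to_pixel(self, i: int) -> tuple[int, int]:
        """Map a 0-based sequence index to its (x, y) pixel coordinate."""
        if not 0 <= i < self.capacity:
            raise IndexError(f"index {i} outside [0, {self.capacity})")
        x = y = 0
        for lev, (r, pv, s) in enumerate(
            zip(self.radices, self.place_values, self.strides)
        ):
            d = (i // pv) % r
            if lev % 2 == 0:
                x += d * s
            else:
                y += d * s
        return x, y

    def index_to_pixel_array(self, indices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized :meth:`index_to_pixel` for rendering."""
        indices = np.asarray(indices, dtype=np.int64)
        if indices.size and (indices.min() < 0 or indices.max() >= self.capacity):
            raise IndexError("index outside layout capacity")
        x = np.zeros_like(indices)
        y = np.zeros_like(indices)
        for lev, (r, pv, s) in enumerate(
            zip(self.radices, self.place_values, self.strides)
        ):
            d = (indices // pv) % r
            if lev % 2 == 0:
                x += d * s
            else:
                y += d * s
        return x, y

    # -- inverse map --------------------------------------------------------

    def _decompose_axis(self, coord: int, levels: tuple[int, ...]) -> dict[int, int] | None:
        """Greedy digit extraction along one axis; None if coord is whitespace."""
        digits: dict[int, int] = {}
        res = coord
        for lev in sorted(levels, key=lambda l: self.strides[l], reverse=True):
            d, res = divmod(res, self.strides[lev])
            if d >= self.radices[lev]:
                return None
            digits[lev] = d
        if res != 0:
            return None  # inside a unit's trailing padding
        return digits

    def pixel_to_index(self, x: int, y: int) -> int | None:
        """Exact inverse of :meth:`index_to_pixel`; ``None`` on whitespace."""
        if x < 0 or y < 0:
            return None
        dx = self._decompose_axis(x, self.x_levels)
        if dx is None:
            return None
        dy = self._decompose_axis(y, self.y_levels)
        if dy is None:
            return None
        i = 0
        for lev, d in {**dx, **dy}.items():
            i += d * self.place_values[lev]
        return i

    # -- unit sizes ----------------------------------------------------------

    @property
    def column_capacity(self) -> int:
        """Bases in one column (levels 0 and 1)."""
        return self.radices[0] * self.radices[1]

    @property
    def megacolumn_capacity(self) -> int:
        """Bases in one chromosome mega-column (levels 0..3)."""
        cap = self.column_capacity
        if len(self.radices) >= 4:
            cap *= self.radices[2] * self.radices[3]
        return cap


def build_layout(
    radices: Sequence[int] | None = None, paddings: Sequence[int] | None = None
) -> TileLayout:
    """Build a :class:`TileLayout`; with no arguments, the default layout."""
    if radices is None and paddings is None:
        return TileLayout()
    if radices is None or paddings is None:
        raise LayoutError("provide both radices and paddings, or neither")
    return TileLayout(radices, paddings)


def parse_custom_layout(text: str) -> TileLayout:
    """Parse the CLI syntax ``[(r0,r1,...),(p0,p1,...)]`` into a layout."""
    try:
        value = ast.literal_eval(text.strip())
        radices, paddings = value
    except (ValueError, SyntaxError, TypeError) as exc:
        raise LayoutError(f"cannot parse custom layout {text!r}") from exc
    return TileLayout(tuple(radices), tuple(paddings))


@dataclass
class ContigLayoutMap:
    """Assignment of contigs to contiguous index ranges in layout space."""

    entries: list[tuple[str, int, int]] = field(default_factory=list)
    contigs: dict[str, Contig] = field(default_factory=dict)

    @property
    def total_span(self) -> int:
        if not self.entries:
            return 0
        name, start, length = self.entries[-1]
        return start + length

    def start_of(self, name: str) -> int:
        for n, start, _ in self.entries:
            if n == name:
                return start
        raise KeyError(name)

    def locate(self, global_index: int) -> tuple[str, int] | None:
        """Resolve a layout index to (contig name, 0-based offset), or None."""
        for name, start, length in self.entries:
            if start <= global_index < start + length:
                return name, global_index - start
        return None

    def global_index(self, name: str, offset: int) -> int:
        start = self.start_of(name)
        length = next(l for n, s, l in self.entries if n == name)
        if not 0 <= offset < length:
            raise IndexError(f"offset {offset} outside contig {name!r}")
        return start + offset


def place_contigs(
    contigs: Sequence[Contig],
    layout: TileLayout,
    sort_contigs: bool = False,
) -> ContigLayoutMap:
    """Assign each contig a start index at a fresh column boundary.

    Each contig begins at the top of a new column; a contig that does not
    fit in the remainder of the current mega-column starts at the next
    mega-column boundary, so chromosomes sit side by side.
    """
    ordered = list(contigs)
    if sort_contigs:
        ordered.sort(key=lambda c: c.length, reverse=True)
    col = layout.column_capacity
    mega = layout.megacolumn_capacity
    cmap = ContigLayoutMap()
    cursor = 0
    for contig in ordered:
        start = -(-cursor // col) * col  # next column boundary
        remaining = mega - (start % mega) if start % mega else mega
        if contig.length > remaining and remaining < mega:
            start += remaining  # jump to next mega-column boundary
        if start + contig.length > layout.capacity:
            raise CapacityError(
                f"contig {contig.name!r} ({contig.length} bp) exceeds layout "
                f"capacity {layout.capacity}"
            )
        cmap.entries.append((contig.name, start, contig.length))
        cmap.contigs[contig.name] = contig
        cursor = start + contig.length
    return cmap


def place_contigs_compact(contigs: Sequence[Contig], capacity: int | None = None) -> ContigLayoutMap:
    """Back-to-back placement with no boundary alignment (Peano / unique views)."""
    cmap = ContigLayoutMap()
    cursor = 0
    for contig in contigs:
        cmap.entries.append((contig.name, cursor, contig.length))
        cmap.contigs[contig.name] = contig
        cursor += contig.length
    if capacity is not None and cursor > capacity:
        raise CapacityError(
            f"total sequence ({cursor} bp) exceeds layout capacity {capacity}; "
            "use larger radices"
        )
    return cmap


def extract_snippet(
    cmap: ContigLayoutMap,
    layout,
    x: int,
    y: int,
    length: int = DEFAULT_SNIPPET_LENGTH,
) -> tuple[str, int, str] | None:
    """Resolve a pixel to (contig name, offset, snippet of ``length`` bases).

    The snippet is truncated at the contig end; whitespace pixels and
    pixels past the placed sequence give ``None``.  This is the offline
    equivalent of clicking the rendered image to grab sequence.
    """
    idx = layout.pixel_to_index(x, y)
    if idx is None:
        return None
    located = cmap.locate(idx)
    if located is None:
        return None
    name, offset = located
    seq = cmap.contigs[name].seq[offset : offset + length]
    return name, offset, seq
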