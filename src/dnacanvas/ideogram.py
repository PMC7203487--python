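"""Ideogram layout: a continuous Peano-style space-filling curve.

The curve is defined by per-level (x, y) radices, coarse to fine.  At each
level a block is divided into ``x_radices[l] * y_radices[l]`` sub-blocks
visited in boustrophedon (serpentine) order, with alternate sub-blocks
reflected so that the exit cell of one sub-block is grid-adjacent to the
entry cell of the next.  Odd radices are required: an even pass count
would leave the curve on the wrong side of a block to continue without a
jump.  Consecutive sequence positions are therefore always unit grid
steps apart ("no line breaks"), at every scale of the recursion.

``scale`` magnifies the drawing: each nucleotide occupies the pixel at
``(scale * x, scale * y)`` and the gaps in between can be used to trace
the path with a neutral color.  ``scale=1`` paints every pixel.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import prod
from typing import Sequence

import numpy as np

__all__ = [
    "PeanoLayout",
    "build_peano",
    "peano_index_to_pixel",
    "peano_pixel_to_index",
]


class PeanoConfigError(ValueError):
    """Invalid space-filling-curve configuration."""


class PeanoLayout:
    """Space-filling curve over a grid of ``prod(x_radices) x prod(y_radices)`` cells."""

    def __init__(
        self,
        x_radices: Sequence[int],
        y_radices: Sequence[int],
        scale: int = 1,
    ):
        x_radices = tuple(int(r) for r in x_radices)
        y_radices = tuple(int(r) for r in y_radices)
        if len(x_radices) != len(y_radices) or not x_radices:
            raise PeanoConfigError("x and y radix lists must be non-empty and equal length")
        for r in x_radices + y_radices:
            if r < 3 or r % 2 == 0:
                raise PeanoConfigError(
                    f"radix {r} invalid: radices must be odd and >= 3 so the "
                    "serpentine exits each block adjacent to the next (continuity)"
                )
        if scale < 1:
            raise PeanoConfigError("scale must be >= 1")
        self.x_radices = x_radices
        self.y_radices = y_radices
        self.scale = int(scale)
        self.grid_width = prod(x_radices)
        self.grid_height = prod(y_radices)
        self.capacity = self.grid_width * self.grid_height
        self._order = self._build_order()
        inv = np.full((self.grid_width, self.grid_height), -1, dtype=np.int64)
        inv[self._order[:, 0], self._order[:, 1]] = np.arange(self.capacity)
        self._inverse = inv

    @property
    def width(self) -> int:
        return self.scale * self.grid_width

    @property
    def height(self) -> int:
        return self.scale * self.grid_height

    def _build_order(self) -> np.ndarray:
        """Enumerate the visit order of all grid cells.

        Recursion state: block origin, and whether the parent has mirrored
        this block in x and/or y.  Within an (unmirrored) block, sub-blocks
        are visited column by column, alternating up/down; the t-th visited
        sub-block is mirrored in y when its column is descending and in x
        when its position within the column is odd, which makes the exit
        corner of each sub-block adjacent to the entry corner of the next.
        """
        n_levels = len(self.x_radices)
        sub_w = [prod(self.x_radices[l:]) for l in range(n_levels + 1)]
        sub_h = [prod(self.y_radices[l:]) for l in range(n_levels + 1)]
        sub_cells = [w * h for w, h in zip(sub_w, sub_h)]
        order = np.empty((self.capacity, 2), dtype=np.int64)

        def emit(level: int, ox: int, oy: int, fx: bool, fy: bool, base: int) -> None:
            if level == n_levels:
                order[base, 0] = ox
                order[base, 1] = oy
                return
            rx, ry = self.x_radices[level], self.y_radices[level]
            w, h, cells = sub_w[level + 1], sub_h[level + 1], sub_cells[level + 1]
            for t in range(rx * ry):
                c0, r0 = divmod(t, ry)
                if c0 % 2:
                    r0 = ry - 1 - r0
                sfx = (t % ry) % 2 == 1
                sfy = c0 % 2 == 1
                c = rx - 1 - c0 if fx else c0
                r = ry - 1 - r0 if fy else r0
                emit(level + 1, ox + c * w, oy + r * h, sfx ^ fx, sfy ^ fy, base + t * cells)

        emit(0, 0, 0, False, False, 0)
        return order

    def index_to_pixel(self, i: int) -> tuple[int, int]:
        if not 0 <= i < self.capacity:
            raise IndexError(f"index {i} outside [0, {self.capacity})")
        x, y = self._order[i]
        return int(x) * self.scale, int(y) * self.scale

    def index_to_pixel_array(self, indices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        indices = np.asarray(indices, dtype=np.int64)
        if indices.size and (indices.min() < 0 or indices.max() >= self.capacity):
            raise IndexError("index outside curve capacity")
        pts = self._order[indices]
        return pts[:, 0] * self.scale, pts[:, 1] * self.scale

    def pixel_to_index(self, x: int, y: int) -> int | None:
        """Inverse of :meth:`index_to_pixel`; None for whitespace (scale > 1 gaps)."""
        if x < 0 or y < 0:
            return None
        if x % self.scale or y % self.scale:
            return None
        cx, cy = x // self.scale, y // self.scale
        if cx >= self.grid_width or cy >= self.grid_height:
            return None
        idx = self._inverse[cx, cy]
        return int(idx) if idx >= 0 else None


def build_peano(
    x_radices: Sequence[int], y_radices: Sequence[int], scale: int = 1
) -> PeanoLayout:
    """Construct a :class:`PeanoLayout` (precomputes the full visit order)."""
    return PeanoLayout(x_radices, y_radices, scale)


def peano_index_to_pixel(layout: PeanoLayout, i: int) -> tuple[int, int]:
    return layout.index_to_pixel(i)


def peano_pixel_to_index(layout: PeanoLayout, x: int, y: int) -> int | None:
    return layout.pixel_to_index(x, y)
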