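"""Annotation painting: highlights, shadows, the parallel track, and labels.

Every placed base receives at most one annotation code, resolved by the
priority CDS > exon > mRNA > gene; repeat annotations live in a parallel
boolean array so a repeat can coexist with a gene.  Highlights blend the
sequence raster toward white (genes: introns faint, exons strong), repeats
toward black, and a secondary gene set of interest gets a drop shadow
around its bounding box.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from PIL import Image

from .io_formats import AnnotationFeature
from .rendering import draw_label
from .tile_layout import ContigLayoutMap, TileLayout

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationError",
    "AnnotationCodeArray",
    "CODE_NONE",
    "CODE_GENE",
    "CODE_MRNA",
    "CODE_EXON",
    "CODE_CDS",
    "flatten_features",
    "overlay_highlights",
    "build_annotation_track",
    "place_labels",
    "label_style_for_area",
    "TRACK_COLORS",
    "INTRON_ALPHA",
    "EXON_ALPHA",
    "REPEAT_ALPHA",
]

CODE_NONE, CODE_GENE, CODE_MRNA, CODE_EXON, CODE_CDS = 0, 1, 2, 3, 4
_PRIORITY = {"gene": CODE_GENE, "mRNA": CODE_MRNA, "exon": CODE_EXON, "CDS": CODE_CDS}

# opacity constants for highlight blending (orderings from the display rules;
# the specific values are this package's defaults, overridable per call)
INTRON_ALPHA = 0.2
EXON_ALPHA = 0.45
REPEAT_ALPHA = 0.35
SHADOW_ALPHA = 0.5
SHADOW_WIDTH = 2

# parallel annotation track colors: introns orange, exons blue, CDS red
TRACK_COLORS = {
    CODE_NONE: (255, 255, 255),
    CODE_GENE: (230, 159, 0),
    CODE_MRNA: (230, 159, 0),
    CODE_EXON: (0, 114, 178),
    CODE_CDS: (200, 30, 30),
}

# font size / opacity lookup keyed by bounding-box area in pixels
_LABEL_TABLE = (
    (1_000, None, None),      # too small: skip
    (10_000, 8, 1.0),
    (1_000_000, 14, 0.8),
    (None, 28, 0.5),
)


class AnnotationError(ValueError):
    """Annotation features cannot be applied to the placed contigs."""


@dataclass
class AnnotationCodeArray:
    """Per-base annotation code over layout index space, plus a repeat mask."""

    codes: np.ndarray   # uint8, one priority code per base
    repeat: np.ndarray  # bool, parallel repeat track


def _feature_index_range(
    feature: AnnotationFeature, cmap: ContigLayoutMap
) -> tuple[int, int]:
    """Clip a feature to its contig and convert to layout index space."""
    start = cmap.start_of(feature.seqid)
    length = next(l for n, s, l in cmap.entries if n == feature.seqid)
    lo = start + max(feature.start0, 0)
    hi = start + min(feature.end0, length)
    return lo, hi


def _check_seqids(features: Iterable[AnnotationFeature], cmap: ContigLayoutMap) -> None:
    placed = {name for name, _, _ in cmap.entries}
    missing = sorted({f.seqid for f in features} - placed)
    if missing:
        raise AnnotationError(
            "annotation seqids not found among placed contigs: "
            + ", ".join(missing)
            + f" (placed: {', '.join(sorted(placed))})"
        )


def flatten_features(
    features: Sequence[AnnotationFeature],
    cmap: ContigLayoutMap,
    repeat_features: Sequence[AnnotationFeature] = (),
) -> AnnotationCodeArray:
    """Resolve overlapping features to one code per base by priority.

    A base covered by gene, exon and CDS gets the CDS code; repeats are
    tracked separately so they do not compete with gene structure.
    """
    _check_seqids(features, cmap)
    _check_seqids(repeat_features, cmap)
    span = cmap.total_span
    codes = np.zeros(span, dtype=np.uint8)
    for f in features:
        code = _PRIORITY.get(f.ftype)
        if code is None:
            continue  # 'other' types carry no display priority
        lo, hi = _feature_index_range(f, cmap)
        if hi > lo:
            np.maximum(codes[lo:hi], code, out=codes[lo:hi])
    repeat = np.zeros(span, dtype=bool)
    for f in repeat_features:
        lo, hi = _feature_index_range(f, cmap)
        repeat[lo:hi] = True
    return AnnotationCodeArray(codes=codes, repeat=repeat)


def _blend(arr: np.ndarray, mask_x, mask_y, target: float, alpha: float) -> None:
    arr[mask_y, mask_x] = np.rint(
        arr[mask_y, mask_x] * (1.0 - alpha) + target * alpha
    ).astype(np.uint8)


def overlay_highlights(
    image: Image.Image,
    layout,
    cmap: ContigLayoutMap,
    features: Sequence[AnnotationFeature],
    role: str = "ref",
    margin: int = 0,
) -> Image.Image:
    """Blend annotation highlights onto a sequence raster.

    ``ref``: lighten toward white, introns at alpha 0.2 and exons at 0.45,
    so exonic pixels are strictly lighter than intronic ones, which are
    lighter than plain sequence.  Overlapping calls stack ("doubly
    highlighted").  ``repeat``: darken toward black.  ``query``: draw a
    2 px drop shadow around each feature's bounding box; shadow pixels
    that collide with annotated sequence are shifted inward.
    """
    if role not in {"ref", "query", "repeat"}:
        raise ValueError(f"unknown role {role!r}")
    arr = np.asarray(image.convert("RGB")).copy()
    if role in {"ref", "repeat"}:
        flat = flatten_features(
            features if role == "ref" else [],
            cmap,
            repeat_features=features if role == "repeat" else (),
        )
        if role == "ref":
            for mask, alpha in (
                (np.isin(flat.codes, (CODE_GENE, CODE_MRNA)), INTRON_ALPHA),
                (np.isin(flat.codes, (CODE_EXON, CODE_CDS)), EXON_ALPHA),
            ):
                idx = np.nonzero(mask)[0]
                if idx.size:
                    x, y = layout.index_to_pixel_array(idx)
                    _blend(arr, x + margin, y + margin, 255.0, alpha)
        else:
            idx = np.nonzero(flat.repeat)[0]
            if idx.size:
                x, y = layout.index_to_pixel_array(idx)
                _blend(arr, x + margin, y + margin, 0.0, REPEAT_ALPHA)
        return Image.fromarray(arr, "RGB")

    # query role: drop shadows around feature bounding boxes
    _check_seqids(features, cmap)
    annotated = np.zeros(arr.shape[:2], dtype=bool)
    all_flat = flatten_features(features, cmap)
    idx = np.nonzero(all_flat.codes)[0]
    if idx.size:
        x, y = layout.index_to_pixel_array(idx)
        annotated[y + margin, x + margin] = True
    h, w = arr.shape[:2]
    for f in features:
        lo, hi = _feature_index_range(f, cmap)
        if hi <= lo:
            continue
        x, y = layout.index_to_pixel_array(np.arange(lo, hi))
        x0, x1 = int(x.min()) + margin, int(x.max()) + margin
        y0, y1 = int(y.min()) + margin, int(y.max()) + margin
        ring = np.zeros_like(annotated)
        ry0, ry1 = max(y0 - SHADOW_WIDTH, 0), min(y1 + SHADOW_WIDTH + 1, h)
        rx0, rx1 = max(x0 - SHADOW_WIDTH, 0), min(x1 + SHADOW_WIDTH + 1, w)
        ring[ry0:ry1, rx0:rx1] = True
        ring[y0 : y1 + 1, x0 : x1 + 1] = False
        collision = ring & annotated
        if collision.any():
            # shift colliding shadow inward by its overlap: draw an inner ring
            n = int(collision.sum())
            logger.info(
                "shadow for %r collides on %d px; shifting inward", f.label or f.seqid, n
            )
            ring &= ~annotated
            inner = np.zeros_like(ring)
            inner[y0 : y1 + 1, x0 : x1 + 1] = True
            iy0, iy1 = y0 + SHADOW_WIDTH, y1 - SHADOW_WIDTH + 1
            ix0, ix1 = x0 + SHADOW_WIDTH, x1 - SHADOW_WIDTH + 1
            if iy1 > iy0 and ix1 > ix0:
                inner[iy0:iy1, ix0:ix1] = False
            ring |= inner & ~annotated
        ys, xs = np.nonzero(ring)
        if ys.size:
            _blend(arr, xs, ys, 0.0, SHADOW_ALPHA)
    return Image.fromarray(arr, "RGB")


def median_column(lo: int, hi: int, column_capacity: int) -> int:
    """The median covered column of index range [lo, hi): where a label goes
    when a feature spans several columns."""
    cols = np.unique(np.arange(lo, hi) // column_capacity)
    return int(cols[len(cols) // 2])


def label_style_for_area(area: int) -> tuple[int, float] | None:
    """Monotone lookup: larger boxes get larger, more transparent labels."""
    for limit, size, opacity in _LABEL_TABLE:
        if limit is None or area < limit:
            return None if size is None else (size, opacity)
    return None


def place_labels(
    features: Sequence[AnnotationFeature],
    cmap: ContigLayoutMap,
    layout,
    layout_kind: str = "tile",
) -> list[tuple[str, tuple[int, int, int, int], str, float, int]]:
    """Compute (text, bbox, anchor, opacity, font_size) for each feature.

    Tile layout: the bbox is the feature's first column segment; labels sit
    at the start of the gene respective of strand (+ at the top of the box,
    - at the bottom).  Ideogram: the bbox spans the min/max of the mapped
    pixels and the label anchors at their geometric centroid.
    """
    if layout_kind not in {"tile", "ideogram"}:
        raise ValueError(f"unknown layout kind {layout_kind!r}")
    _check_seqids(features, cmap)
    placements = []
    for f in features:
        if not f.label:
            continue
        lo, hi = _feature_index_range(f, cmap)
        if hi <= lo:
            continue
        x, y = layout.index_to_pixel_array(np.arange(lo, hi))
        if layout_kind == "tile":
            assert isinstance(layout, TileLayout)
            col_cap = layout.column_capacity
            first_col = lo // col_cap
            seg_mask = (np.arange(lo, hi) // col_cap) == first_col
            sx, sy = x[seg_mask], y[seg_mask]
            # the full column width makes a readable label box
            col_origin_x = int(sx[0]) - int((lo % layout.radices[0])) * layout.strides[0]
            bbox = (col_origin_x, int(sy.min()),
                    col_origin_x + layout.radices[0] * layout.strides[0], int(sy.max()) + 1)
            anchor = "top" if f.strand == "+" else ("bottom" if f.strand == "-" else "top")
        else:
            bbox = (int(x.min()), int(y.min()), int(x.max()) + 1, int(y.max()) + 1)
            anchor = "centroid"
        area = (bbox[2] - bbox[0]) * (bbox[3] - bbox[1])
        style = label_style_for_area(area)
        if style is None:
            logger.info("label %r skipped: area %d below threshold", f.label, area)
            continue
        size, opacity = style
        placements.append((f.label, bbox, anchor, opacity, size))
    return placements


def build_annotation_track(
    features: Sequence[AnnotationFeature],
    cmap: ContigLayoutMap,
    layout: TileLayout,
    annotation_width: int = 4,
    image: Image.Image | None = None,
    palette=None,
) -> Image.Image:
    """Interlace an annotation pseudosequence track with the sequence columns.

    Each sequence column gains a companion column of ``annotation_width``
    pixels on its left showing the per-base annotation code (introns
    orange, exons blue, CDS red, unannotated white).  When a feature spans
    several columns its label is drawn in the median covered column.
    """
    if annotation_width < 1:
        raise ValueError("annotation_width must be >= 1")
    from .rendering import render_raster, default_palette

    if palette is None:
        palette = default_palette()
    if image is None:
        image = render_raster(cmap, layout, palette)
    flat = flatten_features(features, cmap)
    arr = np.asarray(image.convert("RGB"))
    h, w = arr.shape[:2]
    aw = annotation_width

    span = cmap.total_span
    idx = np.arange(span, dtype=np.int64)
    x, y = layout.index_to_pixel_array(idx)
    d0 = idx % layout.radices[0]
    col_start_x = x - d0 * layout.strides[0]
    uniq_cols = np.unique(col_start_x)
    ranks = np.searchsorted(uniq_cols, col_start_x)

    new_w = w + aw * len(uniq_cols)
    out = np.tile(np.array(palette.background, np.uint8), (h, new_w, 1))
    # each sequence pixel shifts right by (rank of its column + 1) * aw
    new_x = x + (ranks + 1) * aw
    out[y, new_x] = arr[y, x]
    # track pixels: an aw-px track row summarizes one sequence row by
    # subsampling (pixel k shows the code of base floor(k*row_width/aw))
    colors = np.array([TRACK_COLORS[c] for c in range(5)], dtype=np.uint8)
    track_rgb = colors[flat.codes]
    track_x0 = col_start_x + ranks * aw
    r0 = layout.radices[0]
    for k in range(aw):
        sel = d0 == (k * r0) // aw
        out[y[sel], track_x0[sel] + k] = track_rgb[sel]
    img = Image.fromarray(out, "RGB")

    # labels at the median covered column
    col_cap = layout.column_capacity
    for f in features:
        if not f.label or f.ftype not in _PRIORITY:
            continue
        lo, hi = _feature_index_range(f, cmap)
        if hi <= lo:
            continue
        median_col = median_column(lo, hi, col_cap)
        seg = (np.arange(lo, hi) // col_cap) == median_col
        sy = y[lo:hi][seg]
        scx = track_x0[lo:hi][seg]
        bbox = (int(scx.min()), int(sy.min()), int(scx.max()) + aw, int(sy.max()) + 1)
        style = label_style_for_area((bbox[2] - bbox[0]) * (bbox[3] - bbox[1]))
        if style is None:
            continue
        size, opacity = style
        img = draw_label(img, f.label, bbox, anchor="top", opacity=opacity, font_size=size)
    return img
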