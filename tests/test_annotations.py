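"""Annotation flattening priority, highlight blending, track and labels."""

import numpy as np
import pytest
from PIL import Image

from dnacanvas.annotations import (
    CODE_CDS,
    CODE_EXON,
    CODE_GENE,
    CODE_MRNA,
    CODE_NONE,
    AnnotationError,
    TRACK_COLORS,
    build_annotation_track,
    flatten_features,
    label_style_for_area,
    median_column,
    overlay_highlights,
    place_labels,
)
from dnacanvas.io_formats import AnnotationFeature, Contig
from dnacanvas.rendering import render_raster
from dnacanvas.tile_layout import TileLayout, place_contigs
from conftest import random_contig

_PRIORITY_ORDER = {"gene": CODE_GENE, "mRNA": CODE_MRNA, "exon": CODE_EXON, "CDS": CODE_CDS}


def feat(seqid, ftype, start, end, strand="+", label=""):
    return AnnotationFeature(seqid, "t", ftype, start, end, strand, label=label)


@pytest.fixture
def placed():
    layout = TileLayout(radices=(10, 10, 4, 3), paddings=(0, 0, 1, 1))
    contigs = [random_contig(150, 1, "chr1"), random_contig(80, 2, "chr2")]
    return layout, place_contigs(contigs, layout)


class TestFlatten:
    def test_priority_example(self, placed):
        _, cmap = placed
        feats = [
            feat("chr1", "gene", 1, 100),
            feat("chr1", "exon", 10, 30),
            feat("chr1", "CDS", 15, 25),
        ]
        flat = flatten_features(feats, cmap)
        assert flat.codes[19] == CODE_CDS   # base 20 (1-based)
        assert flat.codes[11] == CODE_EXON  # base 12
        assert flat.codes[4] == CODE_GENE   # base 5
        assert flat.codes[100] == CODE_NONE

    def test_no_features_all_none(self, placed):
        _, cmap = placed
        assert not flatten_features([], cmap).codes.any()

    def test_overlapping_genes_stay_gene(self, placed):
        _, cmap = placed
        flat = flatten_features([feat("chr1", "gene", 1, 50), feat("chr1", "gene", 25, 80)], cmap)
        assert (flat.codes[:80] == CODE_GENE).all()

    def test_matches_brute_force_oracle(self, placed):
        _, cmap = placed
        rng = np.random.default_rng(12)
        names = ["chr1", "chr2"]
        lengths = {"chr1": 150, "chr2": 80}
        feats = []
        for _ in range(40):
            name = names[rng.integers(0, 2)]
            a = int(rng.integers(1, lengths[name] - 1))
            b = int(rng.integers(a, lengths[name]))
            ftype = ["gene", "mRNA", "exon", "CDS"][rng.integers(0, 4)]
            feats.append(feat(name, ftype, a, b))
        flat = flatten_features(feats, cmap)
        # independent per-base maximum-priority scan
        expected = np.zeros(cmap.total_span, dtype=int)
        for f in feats:
            start = cmap.start_of(f.seqid)
            for pos in range(f.start - 1, f.end):
                code = _PRIORITY_ORDER[f.ftype]
                expected[start + pos] = max(expected[start + pos], code)
        assert (flat.codes == expected).all()

    def test_unresolvable_seqid_listed(self, placed):
        _, cmap = placed
        with pytest.raises(AnnotationError, match="chrX"):
            flatten_features([feat("chrX", "gene", 1, 10)], cmap)

    def test_repeats_tracked_separately(self, placed):
        _, cmap = placed
        flat = flatten_features(
            [feat("chr1", "gene", 1, 50)],
            cmap,
            repeat_features=[feat("chr1", "other", 40, 60)],
        )
        assert flat.codes[44] == CODE_GENE and flat.repeat[44]


class TestHighlights:
    def test_exon_lighter_than_intron_lighter_than_plain(self, placed):
        layout, cmap = placed
        img = render_raster(cmap, layout)
        feats = [feat("chr1", "gene", 1, 100), feat("chr1", "exon", 20, 40)]
        out = np.asarray(overlay_highlights(img, layout, cmap, feats, role="ref"), dtype=int)
        base = np.asarray(img, dtype=int)

        def px(i):
            x, y = layout.index_to_pixel(i)
            return x, y

        x_e, y_e = px(25)   # exon
        x_i, y_i = px(5)    # intron (gene only)
        x_p, y_p = px(120)  # plain
        assert out[y_e, x_e].sum() > out[y_i, x_i].sum() > base[y_i, x_i].sum()
        assert (out[y_p, x_p] == base[y_p, x_p]).all()

    def test_double_highlight_stacks(self, placed):
        layout, cmap = placed
        img = render_raster(cmap, layout)
        feats = [feat("chr1", "gene", 1, 50)]
        once = np.asarray(overlay_highlights(img, layout, cmap, feats, role="ref"), dtype=int)
        twice = np.asarray(
            overlay_highlights(Image.fromarray(once.astype(np.uint8)), layout, cmap, feats, role="ref"),
            dtype=int,
        )
        x, y = layout.index_to_pixel(10)
        assert twice[y, x].sum() > once[y, x].sum()

    def test_repeat_darkens(self, placed):
        layout, cmap = placed
        img = render_raster(cmap, layout)
        out = np.asarray(overlay_highlights(img, layout, cmap, [feat("chr1", "other", 1, 30)], role="repeat"))
        base = np.asarray(img)
        x, y = layout.index_to_pixel(10)
        assert (out[y, x] <= base[y, x]).all()
        assert out[y, x].sum() < base[y, x].sum()

    def test_query_shadow_darkens_ring(self, placed):
        layout, cmap = placed
        img = render_raster(cmap, layout)
        out = np.asarray(overlay_highlights(img, layout, cmap, [feat("chr1", "gene", 12, 18)], role="query"))
        base = np.asarray(img)
        assert out.astype(int).sum() < base.astype(int).sum()


class TestTrack:
    def test_track_colors(self, placed):
        layout, cmap = placed
        feats = [
            feat("chr1", "gene", 1, 60, label="G1"),
            feat("chr1", "exon", 10, 20),
            feat("chr1", "CDS", 12, 16),
        ]
        img = np.asarray(build_annotation_track(feats, cmap, layout, annotation_width=2))
        # rows hold 10 bases; track pixel k of a row subsamples base 5k
        # row 0, k=0 -> base 0 (gene body): orange intron color
        assert tuple(img[0, 0]) == TRACK_COLORS[CODE_GENE]
        # row 1, k=0 -> base 10 (1-based 11, exon): blue
        assert tuple(img[1, 0]) == TRACK_COLORS[CODE_EXON]
        # row 1, k=1 -> base 15 (1-based 16, CDS): red
        assert tuple(img[1, 1]) == TRACK_COLORS[CODE_CDS]
        # unannotated row stays background white
        assert tuple(img[9, 0]) == TRACK_COLORS[CODE_NONE]

    def test_track_width_one(self, placed):
        layout, cmap = placed
        img = build_annotation_track([feat("chr1", "gene", 1, 5)], cmap, layout, annotation_width=1)
        base = render_raster(cmap, layout)
        n_cols = 2 + 1  # chr1 spans 2 columns of 100, chr2 one column
        assert img.width == base.width + n_cols

    def test_median_column_rule(self):
        # a feature spanning columns 3..5 labels column 4
        assert median_column(300, 600, 100) == 4
        assert median_column(0, 100, 100) == 0


class TestLabels:
    def test_strand_anchors(self, default_layout):
        layout = default_layout
        cmap = place_contigs([random_contig(6000, 5, "chr1")], layout)
        feats = [
            feat("chr1", "gene", 1, 2500, strand="+", label="PLUS"),
            feat("chr1", "gene", 3000, 5500, strand="-", label="MINUS"),
        ]
        placements = {t: anchor for t, _, anchor, _, _ in place_labels(feats, cmap, layout, "tile")}
        assert placements["PLUS"] == "top"
        assert placements["MINUS"] == "bottom"

    def test_ideogram_centroid_bbox(self):
        from dnacanvas.ideogram import build_peano
        from dnacanvas.tile_layout import place_contigs_compact

        layout = build_peano((3, 3, 3), (5, 3, 3))
        cmap = place_contigs_compact([random_contig(1215, 3, "chr1")], capacity=1215)
        feats = [feat("chr1", "gene", 1, 1215, label="BLOB")]
        ((text, bbox, anchor, _, _),) = place_labels(feats, cmap, layout, "ideogram")
        assert anchor == "centroid"
        assert bbox == (0, 0, 27, 45)  # min/max of the mapped pixels

    def test_style_lookup_monotone(self):
        sizes = []
        for area in (500, 5_000, 500_000, 5_000_000):
            style = label_style_for_area(area)
            sizes.append(style if style is None else style[0])
        assert sizes[0] is None
        assert sizes[1] < sizes[2] < sizes[3]
        # opacity decreases as size increases
        assert label_style_for_area(5_000)[1] > label_style_for_area(5_000_000)[1]
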