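# dnacanvas

**Every nucleotide of a genome as one pixel.**

`dnacanvas` renders DNA sequence at single-base resolution: each base is
painted as one colored pixel in a deterministic, *invertible* 2D layout, so a
whole chromosome becomes an image you can zoom from chromosome structure down
to individual bases — and any pixel can be mapped back to the exact sequence
position it came from. It is aimed at genome assembly QC, comparative
genomics, and repeat/annotation inspection, where summary tracks hide the
texture of the actual sequence.

## What it does

* **Tile layout** — a nested mixed-radix arrangement: rows of 100 bases,
  columns of 1000 rows (100 kb), mega-rows of 100 columns (10 Mb), and
  260 Mb chromosome mega-columns side by side, with whitespace padding
  between units (`[(100,1000,100,26,999), (0,0,3,9,700)]` by default).
  The index↔pixel map is an exact bijection on drawable pixels: if
  `d_k` are the mixed-radix digits of sequence index `i`, then
  `x = Σ_{even k} d_k·stride_k` and `y = Σ_{odd k} d_k·stride_k`, and the
  inverse greedily decomposes a pixel by descending strides (whitespace
  resolves to "no base").
* **Ideogram layout** — a continuous Peano-style space-filling curve defined
  by per-level (x, y) radices (all odd), e.g. `x=(3,3,3), y=(5,3,3)`:
  consecutive bases are always grid-adjacent at every scale, so locality in
  the image reflects locality in the sequence.
* **Annotations** — GFF3/GFF2/GTF features painted as highlights (introns
  faint, exons strong, repeats dark, priority CDS > exon > mRNA > gene), an
  interlaced annotation track (introns orange, exons blue, CDS red), and
  strand-aware labels.
* **Whole-genome alignments** — UCSC chain (liftOver) files are linearized
  into a gapped reference/query pair with per-base provenance: the
  highest-scoring ("master") chain fixes the coordinate frame, secondary
  chains are spliced in at their reference positions, and backgrounds mark
  syntenic (white), intrachromosomal (blue) and interchromosomal (red)
  sources. Output includes the four-column view (reference, two difference
  columns, query), a "unique" render of reference-only sequence, and a
  statistics table (coverage, identity, gap-size spectrum).
* **MSA gallery** — a directory of aligned FASTA files rendered as labeled
  blocks in one panoramic canvas.
* **DeepZoom pyramids** — every render can emit a DZI tile pyramid
  (area-averaged halvings) for constant-cost pan and zoom in any
  DeepZoom/OpenSeadragon viewer.
* **Synthetic fixtures** — a seeded generator produces genomes, GFF3
  annotations, and mutated query genomes *with the exactly corresponding
  chain file and known alignment statistics*, so the whole pipeline is
  testable without downloading anything.

## Worked example

Generate a synthetic dataset and visualize the alignment:

```bash
dnacanvas fixtures --out demo_data --seed 7 --ref_len 3000
dnacanvas render --fasta demo_data/ref.fa --query_fasta demo_data/query.fa \
    --chainfile demo_data/alignment.chain --outname human_vs_query_demo --no_webpage
cat results/human_vs_query_demo/stats.tsv
```

```
Feature	chr1
Reference length (N's included)	3000
Reference length (no N's)	3000
Total alignment length	3000
Unaligned sequence within reference	0
Alignment length/Reference length (%)	100.00
Identical bases within alignment	2990
Non-identical bases within alignment	10
Identical bases/Alignment length (%)	99.67
...
```

The seed-7 recipe planted 10 SNPs and no indels, so the composite covers
100% of the reference at 99.67% identity with zero gap events — the table is
the mutation set read back from the alignment. The run directory also holds
`master.png` (the four-column render) and copies of the inputs under
`sources/`.

Because layouts are invertible, a pixel on any render resolves back to
sequence (the offline equivalent of mousing over the image in a browser):

```bash
dnacanvas render --fasta demo_data/ref.fa --outname tile_demo --no_webpage
dnacanvas query results/tile_demo --pixel 50,3
# chr1	350	CGGACGTAGACTCTAAGAAGCGTAGTGAAAGC... (300 bp)
```

Pixel (50, 3) is row 3, column position 50 of the default layout — sequence
index 3·100 + 50 = 350 — and the command appends the 300 bp snippet starting
there to `results/tile_demo/snippets.log`.

The same library surface is importable (`dnacanvas.TileLayout`,
`dnacanvas.composite_alignment`, `dnacanvas.compute_stats`, ...); see
`docs/methods.md` for the model details and design choices.

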