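# Methods

This note documents the models and procedures behind `dnacanvas`, the
parameters that matter, and the design choices made where more than one
reasonable implementation exists.

## Tile layout

The tile layout is a mixed-radix positional number system whose digits
alternate between the two image axes. A layout is a pair of equal-length
lists, `radices` and `paddings`; level 0 is the fastest-varying digit on x,
level 1 on y, level 2 on x again, and so on. Strides satisfy

```
stride[i] = 1 + padding[i]                              (first level on an axis)
stride[i] = radices[i-2] * stride[i-2] + padding[i]     (otherwise)
```

so each unit's trailing whitespace is part of its own stride. With the
default `[(100, 1000, 100, 26, 999), (0, 0, 3, 9, 700)]` this yields
x-strides (1, 103, 11000) and y-strides (1, 1009): rows of 100 bases,
100 kb columns separated by 3 px, 10 Mb mega-rows separated by 9 px, and
260 Mb chromosome mega-columns separated by 700 px of padding (703 px of
total whitespace, because the last column of a mega-column also carries its
own 3 px trailing pad — whitespace figures in the tests are defined
operationally through the forward map, not from the padding list).

The forward map takes the mixed-radix digits of an index and sums
digit·stride per axis. The inverse greedily decomposes each coordinate by
descending strides; any residue that lands in trailing padding, or a digit
that exceeds its radix, means the pixel is whitespace and maps to no base.
Forward∘inverse is the identity on drawable pixels and inverse∘forward the
identity on indices; this bijection is property-tested exhaustively on small
layouts and by sampling on the default one.

**Contig placement.** Every contig starts at the top of a fresh column (the
next multiple of `radices[0]·radices[1]` indices); a contig that does not
fit the remainder of the current mega-column starts at the next mega-column
boundary. No index space is reserved for titles — labels are drawn as
overlay only. `sort_contigs` orders by descending length before placement.

**Snippet extraction.** A pixel resolves to (contig, offset) through the
inverse map and the placement table; the returned snippet is 300 bp by
default, truncated at the contig end. This replaces the interactive
mouseover of a web viewer in an offline setting.

## Ideogram (Peano curve) layout

The ideogram layout threads the sequence along a continuous space-filling
curve over a grid of `prod(x_radices) × prod(y_radices)` cells. At each
recursion level a block is divided into `x_radices[l] × y_radices[l]`
sub-blocks visited in boustrophedon order; alternate sub-blocks are
reflected in x and/or y so the exit cell of one sub-block is grid-adjacent
to the entry cell of the next. Odd radices ≥ 3 are required — an even pass
count would strand the curve on the wrong side of a block and force a jump.

The contract is *bijection* (every cell visited exactly once) and
*continuity* (all consecutive steps have Manhattan length 1 at cell scale).
The exact cell order produced by the reflection bookkeeping is an
implementation choice; correctness is defined and tested through the
contract, not a canonical traversal. `scale > 1` draws each base at
`(scale·x, scale·y)` and paints the midpoint pixels neutral gray to trace
the path; `scale = 1` paints every pixel. There is no default radix set for
a whole chromosome — radices are user-supplied (the documented example is
`x=(3,3,3), y=(5,3,3), scale=2`). A sequence longer than the grid raises a
capacity error suggesting larger radices; a shorter one leaves the tail
background-colored.

## Colors and rendering

The default palette is drawn from the Okabe-Ito colorblind-safe set, chosen
so greens and blues predominate with G as the single warm hue:
A = (0,158,115), C = (0,114,178), T = (86,180,233), G = (230,159,0),
N = neutral gray (220,220,220), gap/background = white. These specific RGB
values are this package's own defaults (overridable per call); only their
qualitative relationships are load-bearing. Lookup is case-insensitive;
soft-masked (lowercase) bases are preserved on read and can optionally be
dimmed at render time.

Rendering is fully deterministic: identical inputs and configuration
produce byte-identical PNGs (no timestamps, no hidden state).

**DeepZoom pyramid.** Level `L = ceil(log2(max dimension))` is the full
image; each lower level halves both dimensions by 2×2 area averaging (odd
edges replicate the last row/column) down to 1×1 at level 0, each level cut
into 256 px tiles named `{level}/{col}_{row}.png` with a standard DZI XML
descriptor. Area averaging conserves total intensity to within integer
rounding per pixel, which is tested.

## Annotations

Each placed base receives at most one annotation code by the priority
CDS > exon > mRNA > gene; repeats occupy a parallel boolean track so a
repeat can coexist with gene structure. GTF `transcript` records are
treated as mRNA; feature types outside this vocabulary carry no display
priority. Labels resolve by attribute precedence Name > ID > gene_id >
gene_name.

Highlights blend the raster linearly toward a target color:
introns α = 0.2 and exons α = 0.45 toward white, repeats α = 0.35 toward
black, secondary-interest genes get a 2 px drop shadow (α = 0.5) around
their bounding box, shifted inward where it collides with annotated pixels.
The α values are this package's constants — only the orderings (exon
lighter than intron lighter than plain; repeats darker) are contractual —
and blending deliberately stacks, so overlapping annotations are visibly
"doubly highlighted".

The interlaced annotation track gives each sequence column a companion
column of `annotation_width` pixels on its left. Since an
`annotation_width`-px track row summarizes a full sequence row, the track
subsamples: pixel k of a track row shows the code of base
`floor(k · row_width / annotation_width)`. Colors are introns orange, exons
blue, CDS red, unannotated white. A feature spanning several columns is
labeled in its median covered column.

Label styling uses a monotone lookup on bounding-box area: below 10³ px²
skip, below 10⁴ 8 px at full opacity, below 10⁶ 14 px at 0.8, above that
28 px at 0.5 — larger features get larger, fainter labels. In tile layouts
the label box is the feature's first column segment, anchored top for +
strand and bottom for −; in ideogram layouts the label sits at the
geometric centroid of the feature's mapped pixels with the bounding box
taken from their min/max coordinates.

## Whole-genome alignment compositing

A liftOver chain file is linearized per reference chromosome:

1. The highest-scoring chain targeting the chromosome is the **master**
   (liftOver files are score-sorted, so "first large chain" ≡ maximum
   score; no size threshold is needed). Remaining chains are processed in
   reference-start order.
2. Walking the master's blocks: aligned blocks copy both sequences; `dt`
   gaps leave reference-only sequence (query row shows `-`); `dq` gaps pull
   the intervening *unaligned query sequence* in as an insertion (reference
   row shows `-`).
3. Each secondary chain is spliced in at its reference position, filling
   positions the master left uncovered. Overlaps with already-composited
   aligned positions are truncated and logged — rearrangements within
   rearrangements are not portrayed. Secondary `dq` gaps do **not** pull in
   query sequence; only the master establishes query-side insertions. This
   master-only rule is a declared design choice, not a claim about any
   other tool's behavior.
4. `-` strand chains contribute reverse-complemented query sequence
   (chain query coordinates on the reverse strand are handled per the UCSC
   convention).

The reference keeps its order and copy number: stripping `-` from the
reference row reproduces the input chromosome byte-exactly (tested on every
fixture). Provenance intervals partition the gapped length into
`syntenic` (master), `intra` (secondary, same query chromosome),
`inter` (different query chromosome), `unaligned_ref` and
`unaligned_query`; the four-column render colors backgrounds white/blue/red
for the first three.

**Difference columns.** Per gapped position: equal bases (case-insensitive)
→ background in both outputs; mismatch → the reference base in the
reference column *and* the query base in the query column; sequence
opposite a gap → that base in its own column only.

**Unique sequence.** The concatenation of reference bases at positions with
no aligned query — the reference "minus" the query genome — one output
contig per reference chromosome.

**Statistics.** `alignment_length` counts positions where both rows hold
bases. Identity is case-insensitive; positions where either side is N are
excluded from both the identical and non-identical tallies and reported
separately as N-exchange (`refN_to_query_bp`, `queryN_to_ref_bp`), so
`identical + non_identical + N-exchange = alignment_length` (with no Ns
this reduces to the usual two-term identity). A **reference gap** is a
maximal run of reference bases with no aligned query; a **query gap** is a
maximal run of inserted query-only sequence. Gap runs are counted once per
maximal run with size thresholds >10, >100 and >1000 bp. Coverage is
`100·alignment_length/reference_length`.

**Chain coverage profile.** Per chromosome, chains are ranked by score and
coverage is the union of aligned-block footprints of the top k chains
(k = 1, 2, 3, all), reported with and without N/excluded regions. Aligned
sequence is also attributed homologous/non-homologous by comparing query
and reference chromosome names after `chr`-prefix stripping and an optional
explicit name map (e.g. `{"2A": "2", "2B": "2"}` for a split chromosome).

## Synthetic data generator

The generator emulates the inputs the renderer and compositor consume:

* `gen_genome` draws i.i.d. bases at a genome-wide GC of 0.41 (typical
  mammalian composition), with per-region GC overrides to emulate isochores
  and verbatim planted tandem-repeat arrays to emulate repeat texture.
* `gen_features` plants non-overlapping gene > mRNA > exon > CDS nests in
  valid GFF3.
* `mutate_and_chain` applies a `MutationRecipe` (SNP count, indels with a
  side and length, inversions, translocations) and emits the query genome
  together with the chain file a perfect aligner would produce: collinear
  segments become `+` strand chains with `dt`/`dq` entries at the indels,
  inversions become `-` strand chains on the same query contig,
  translocations become chains from a separate query contig. Chain scores
  are proportional to aligned length, so the master is the longest
  collinear segment. Events are placed with a minimum separation so gap
  runs never merge, and region events may not overlap (a recipe error).

Ground-truth statistics are computed during construction, from the recipe —
never by running the compositor. The accounting is aware of the documented
linearization semantics: a query-side insertion inside a *non-master* chain
never reaches the composite, so it is excluded from the query-gap truth.
The generator's reason to exist is the end-to-end identity
`compute_stats(composite(mutate_and_chain(ref, recipe))) == truth`, which
the acceptance suite checks field-by-field for 100 random recipes.

What the generator does **not** emulate: realistic mutation spectra or
repeat evolution, soft-masking, N-runs/assembly gaps, or imperfect chaining
(every true homology is chained). Passing tests therefore demonstrate
correctness of the coordinate transforms, the compositing algebra and the
statistics — not robustness to messy real-world liftOver files beyond the
documented truncation rule.

## Problem sizes and numerical choices

The test and acceptance workloads use references of 3–10 kb with recipes of
up to ~15 SNPs, 3 indels (1–800 bp), 2 inversions and 1 translocation —
sizes chosen to exercise every code path, including all gap-size threshold
classes, while keeping the suite quick. All randomness flows from explicit
integer seeds; reruns are byte-identical. Degenerate inputs are defined:
empty placements render a 1×1 background canvas, an empty alignment reports
0% coverage/identity with a warning, and a full-coverage identical
alignment yields an empty unique contig.

## Known limitations

* Chains with both `dt` and `dq` at one junction emit the reference-only
  run first, then the insertion; real liftOver files rarely encode
  rearrangements this way, and the fixture generator avoids it.
* The interlaced annotation track subsamples rows (see above); it is a
  locator, not a per-base record — the highlight overlay is per-base.
* BGZF/compressed inputs, VCF/BED annotations, FASTA index persistence and
  netting of chains are out of scope; the HTML output is a static stub
  pointing at the DZI pyramid, not an interactive viewer.
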