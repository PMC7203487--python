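"""Linearize a chained liftOver alignment into one gapped reference/query pair.

A liftOver file describes a pairwise whole-genome alignment as scored
chains of gapless blocks.  To paint it, the chains for one reference
chromosome are composited into a single pair of equal-length gapped
sequences:

* the *master chain* (highest score for the chromosome) establishes the
  shared coordinate frame; its ``dq`` gaps pull unaligned query sequence
  in as insertions (gaps in the reference);
* every other chain is inserted at its reference start position, filling
  reference positions the master left uncovered; overlaps with already
  aligned positions are truncated (rearrangements within rearrangements
  are not portrayed);
* a ``-`` strand chain contributes reverse-complemented query sequence.

Each gapped position carries provenance: ``syntenic`` (master chain),
``intra`` (secondary chain from the master's query chromosome — typically
inversions or within-chromosome transpositions), ``inter`` (a different
query chromosome — translocations), ``unaligned_ref`` (reference-only
sequence) or ``unaligned_query`` (inserted query-only sequence).

The reference keeps its order and copy number: stripping the gap
characters from the reference row reproduces the input chromosome exactly.

Statistics follow the alignment summary table conventions: a *reference
gap* is a maximal run of reference sequence with no aligned query (the
query row shows ``-``), a *query gap* is a maximal run of inserted query
sequence (the reference row shows ``-``); identity is case-insensitive and
positions where either side is N are tallied separately as N-exchange
rather than as (non-)identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import Chain, Contig, revcomp

logger = logging.getLogger(__name__)

__all__ = [
    "ProvenanceInterval",
    "CompositeAlignment",
    "AlignmentStats",
    "sort_and_select_chains",
    "composite_alignment",
    "difference_columns",
    "unique_sequence",
    "compute_stats",
    "chain_coverage_profile",
    "stats_table",
    "PROVENANCE_COLORS",
]

# four-column view background colors by provenance class
PROVENANCE_COLORS = {
    "syntenic": (255, 255, 255),
    "intra": (150, 180, 255),   # blue: within-chromosome rearrangement
    "inter": (255, 150, 150),   # red: between-chromosome translocation
    "unaligned_ref": (255, 255, 255),
    "unaligned_query": (255, 255, 255),
}

_CLS_UNALIGNED_REF = 0
_CLS_SYNTENIC = 1
_CLS_INTRA = 2
_CLS_INTER = 3
_CLS_NAMES = {
    _CLS_UNALIGNED_REF: "unaligned_ref",
    _CLS_SYNTENIC: "syntenic",
    _CLS_INTRA: "intra",
    _CLS_INTER: "inter",
}


@dataclass
class ProvenanceInterval:
    """Half-open interval on gapped coordinates with a source class."""

    start: int
    end: int
    cls: str  # syntenic | intra | inter | unaligned_ref | unaligned_query
    source: tuple[int, str, str] | None = None  # (chain_id, qName, qStrand)


@dataclass
class CompositeAlignment:
    """The linearized alignment: two gapped rows plus per-base provenance."""

    ref_name: str
    ref_gapped: str
    query_gapped: str
    provenance: list[ProvenanceInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.ref_gapped) != len(self.query_gapped):
            raise ValueError("gapped rows must have equal length")


@dataclass
class AlignmentStats:
    """Whole-alignment summary, per reference chromosome."""

    ref_len_with_N: int = 0
    ref_len_no_N: int = 0
    alignment_length: int = 0
    unaligned_ref: int = 0
    coverage_pct: float = 0.0
    identical: int = 0
    non_identical: int = 0
    identity_pct: float = 0.0
    ref_gap_count: int = 0
    ref_gaps_gt10: int = 0
    ref_gaps_gt100: int = 0
    ref_gaps_gt1000: int = 0
    query_gap_count: int = 0
    query_gaps_gt10: int = 0
    query_gaps_gt100: int = 0
    query_gaps_gt1000: int = 0
    refN_to_query_bp: int = 0
    queryN_to_ref_bp: int = 0


def sort_and_select_chains(
    chains: Sequence[Chain], ref_name: str
) -> tuple[Chain | None, list[Chain]]:
    """Pick the master chain (max score on ``ref_name``) and sort the rest.

    liftOver files are score-sorted, so "the first large chain" is the
    maximum-score chain; remaining chains come back ordered by their
    reference start.
    """
    candidates = [c for c in chains if c.tName == ref_name]
    if not candidates:
        logger.warning("no chain targets reference %r; empty alignment", ref_name)
        return None, []
    master = max(candidates, key=lambda c: c.score)
    others = sorted((c for c in candidates if c is not master), key=lambda c: c.tStart)
    return master, others


def _query_slice(chain: Chain, qseq: str, q: int, size: int) -> str:
    """Aligned-orientation query bases for strand-aware chain coordinates."""
    if chain.qStrand == "+":
        return qseq[q : q + size]
    # '-' strand coordinates count from the end of the forward sequence
    return revcomp(qseq[chain.qSize - (q + size) : chain.qSize - q])


def composite_alignment(
    ref: Contig,
    query_genome: Sequence[Contig],
    chains: Sequence[Chain],
) -> CompositeAlignment:
    """Composite all chains targeting ``ref`` into one gapped pair."""
    qseqs = {c.name: c.seq for c in query_genome}
    master, others = sort_and_select_chains(chains, ref.name)
    n = ref.length
    qchar = np.full(n, b"-", dtype="S1")
    cls = np.full(n, _CLS_UNALIGNED_REF, dtype=np.uint8)
    srcidx = np.zeros(n, dtype=np.int32)
    sources: list[tuple[int, str, str] | None] = [None]
    insertions: list[tuple[int, str, tuple[int, str, str]]] = []

    def apply_chain(chain: Chain, chain_cls: int, pull_insertions: bool) -> None:
        if chain.qName not in qseqs:
            raise KeyError(f"chain {chain.chain_id}: query contig {chain.qName!r} missing")
        if chain.tEnd > n:
            raise ValueError(
                f"chain {chain.chain_id}: tEnd {chain.tEnd} beyond reference length {n}"
            )
        qseq = qseqs[chain.qName]
        source = (chain.chain_id, chain.qName, chain.qStrand)
        sources.append(source)
        source_i = len(sources) - 1
        t, q = chain.tStart, chain.qStart
        for block in chain.blocks:
            seg = np.frombuffer(
                _query_slice(chain, qseq, q, block.size).encode("latin-1"), dtype="S1"
            )
            window = slice(t, t + block.size)
            free = cls[window] == _CLS_UNALIGNED_REF
            if not free.all():
                logger.info(
                    "chain %d overlaps composited sequence on %s:%d-%d; keeping %d free bp",
                    chain.chain_id, chain.tName, t, t + block.size, int(free.sum()),
                )
            qchar[window][...] = np.where(free, seg, qchar[window])
            cls[window][...] = np.where(free, chain_cls, cls[window])
            srcidx[window][...] = np.where(free, source_i, srcidx[window])
            t += block.size
            q += block.size
            if block.dt:
                t += block.dt
            if block.dq:
                if pull_insertions:
                    ins = _query_slice(chain, qseq, q, block.dq)
                    insertions.append((t, ins, source))
                q += block.dq

    if master is not None:
        apply_chain(master, _CLS_SYNTENIC, pull_insertions=True)
        for chain in others:
            chain_cls = _CLS_INTRA if chain.qName == master.qName else _CLS_INTER
            # only the master chain pulls in unaligned query sequence
            apply_chain(chain, chain_cls, pull_insertions=False)

    # assemble gapped rows, splicing insertions between reference positions
    insertions.sort(key=lambda item: item[0])
    ref_bytes = np.frombuffer(ref.seq.encode("latin-1"), dtype="S1")
    # precompute run boundaries of (class, source)
    if n:
        changed = np.nonzero((np.diff(cls) != 0) | (np.diff(srcidx) != 0))[0] + 1
        run_edges = np.concatenate(([0], changed, [n]))
    else:
        run_edges = np.array([0])
    ref_parts: list[str] = []
    q_parts: list[str] = []
    prov: list[ProvenanceInterval] = []
    gpos = 0
    cursor = 0
    ins_i = 0

    def flush_ref_segment(upto: int) -> None:
        nonlocal cursor, gpos
        while cursor < upto:
            nxt = run_edges[np.searchsorted(run_edges, cursor, side="right")]
            end = min(int(nxt), upto)
            ref_parts.append(ref_bytes[cursor:end].tobytes().decode("latin-1"))
            q_parts.append(qchar[cursor:end].tobytes().decode("latin-1"))
            prov.append(
                ProvenanceInterval(
                    gpos,
                    gpos + (end - cursor),
                    _CLS_NAMES[int(cls[cursor])],
                    sources[int(srcidx[cursor])],
                )
            )
            gpos += end - cursor
            cursor = end

    while ins_i < len(insertions):
        pos, ins, source = insertions[ins_i]
        flush_ref_segment(pos)
        ref_parts.append("-" * len(ins))
        q_parts.append(ins)
        prov.append(ProvenanceInterval(gpos, gpos + len(ins), "unaligned_query", source))
        gpos += len(ins)
        ins_i += 1
    flush_ref_segment(n)

    return CompositeAlignment(
        ref_name=ref.name,
        ref_gapped="".join(ref_parts),
        query_gapped="".join(q_parts),
        provenance=prov,
    )


def _as_bytes(s: str) -> np.ndarray:
    return np.frombuffer(s.upper().encode("latin-1"), dtype="S1")


def difference_columns(comp: CompositeAlignment) -> tuple[str, str]:
    """The two center columns: bases unique to each side, '-' elsewhere.

    Mismatches appear in both outputs; reference sequence opposite a query
    gap appears only in the reference column, and vice versa.  Comparison
    is case-insensitive but the original case is emitted.
    """
    r = _as_bytes(comp.ref_gapped)
    q = _as_bytes(comp.query_gapped)
    r_orig = np.frombuffer(comp.ref_gapped.encode("latin-1"), dtype="S1")
    q_orig = np.frombuffer(comp.query_gapped.encode("latin-1"), dtype="S1")
    rbase = r != b"-"
    qbase = q != b"-"
    differs = rbase & qbase & (r != q)
    ref_unique = np.full(len(r), b"-", dtype="S1")
    query_unique = np.full(len(r), b"-", dtype="S1")
    ref_mask = differs | (rbase & ~qbase)
    query_mask = differs | (qbase & ~rbase)
    ref_unique[ref_mask] = r_orig[ref_mask]
    query_unique[query_mask] = q_orig[query_mask]
    return (
        ref_unique.tobytes().decode("latin-1"),
        query_unique.tobytes().decode("latin-1"),
    )


def unique_sequence(comp: CompositeAlignment) -> Contig:
    """Reference bases not covered by the alignment, concatenated.

    This "subtracts" the query genome from the reference, one output
    contig per reference chromosome.
    """
    r = np.frombuffer(comp.ref_gapped.encode("latin-1"), dtype="S1")
    q = np.frombuffer(comp.query_gapped.encode("latin-1"), dtype="S1")
    mask = (r != b"-") & (q == b"-")
    seq = r[mask].tobytes().decode("latin-1")
    return Contig(name=comp.ref_name, seq=seq, description=f"{comp.ref_name} unique")


def _gap_runs(mask: np.ndarray) -> np.ndarray:
    """Lengths of maximal True runs."""
    if not mask.any():
        return np.empty(0, dtype=np.int64)
    m = mask.astype(np.int8)
    diff = np.diff(np.concatenate(([0], m, [0])))
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0]
    return ends - starts


def compute_stats(comp: CompositeAlignment) -> AlignmentStats:
    """Summary statistics of a composited alignment.

    ``identical``/``non_identical`` exclude positions where either side is
    N; aligned N positions are tallied in the N-exchange fields, so
    ``identical + non_identical + N-exchange == alignment_length``.
    """
    r = _as_bytes(comp.ref_gapped)
    q = _as_bytes(comp.query_gapped)
    rbase = r != b"-"
    qbase = q != b"-"
    rN = r == b"N"
    qN = q == b"N"
    aligned = rbase & qbase
    alignment_length = int(aligned.sum())
    ref_len_with_N = int(rbase.sum())
    ref_len_no_N = int((rbase & ~rN).sum())
    n_mask = aligned & (rN | qN)
    identical = int((aligned & ~n_mask & (r == q)).sum())
    non_identical = alignment_length - identical - int(n_mask.sum())
    refN_to_query_bp = int((aligned & rN).sum())
    queryN_to_ref_bp = int((aligned & qN).sum())
    ref_gaps = _gap_runs(rbase & ~qbase)   # reference sequence with no aligned query
    query_gaps = _gap_runs(qbase & ~rbase)  # inserted query-only sequence
    stats = AlignmentStats(
        ref_len_with_N=ref_len_with_N,
        ref_len_no_N=ref_len_no_N,
        alignment_length=alignment_length,
        unaligned_ref=ref_len_with_N - alignment_length,
        coverage_pct=100.0 * alignment_length / ref_len_with_N if ref_len_with_N else 0.0,
        identical=identical,
        non_identical=non_identical,
        identity_pct=100.0 * identical / alignment_length if alignment_length else 0.0,
        ref_gap_count=len(ref_gaps),
        ref_gaps_gt10=int((ref_gaps > 10).sum()),
        ref_gaps_gt100=int((ref_gaps > 100).sum()),
        ref_gaps_gt1000=int((ref_gaps > 1000).sum()),
        query_gap_count=len(query_gaps),
        query_gaps_gt10=int((query_gaps > 10).sum()),
        query_gaps_gt100=int((query_gaps > 100).sum()),
        query_gaps_gt1000=int((query_gaps > 1000).sum()),
        refN_to_query_bp=refN_to_query_bp,
        queryN_to_ref_bp=queryN_to_ref_bp,
    )
    if alignment_length == 0:
        logger.warning("empty alignment for %r: percentages reported as 0", comp.ref_name)
    return stats


def render_four_column(
    comp: CompositeAlignment,
    layout=None,
    palette=None,
    gutter: int = 20,
):
    """Render the four-column alignment view as one image.

    Left to right: the gapped reference, reference-unique bases,
    query-unique bases, and the gapped (rearranged) query.  Panel
    backgrounds are colored by provenance class — white for syntenic,
    blue for intrachromosomal, red for interchromosomal — so rearranged
    regions stand out behind the difference columns.
    """
    from PIL import Image

    from .io_formats import Contig as _Contig
    from .rendering import default_palette, render_raster
    from .tile_layout import TileLayout, place_contigs_compact

    if palette is None:
        palette = default_palette()
    if layout is None:
        layout = TileLayout()
    ref_u, query_u = difference_columns(comp)
    panels = []
    glen = len(comp.ref_gapped)
    idx = np.arange(glen, dtype=np.int64)
    px, py = layout.index_to_pixel_array(idx)
    w, h = int(px.max()) + 1, int(py.max()) + 1
    bg = np.tile(np.array(palette.background, np.uint8), (h, w, 1))
    for interval in comp.provenance:
        color = PROVENANCE_COLORS[interval.cls]
        if color != tuple(palette.background):
            sel = slice(interval.start, interval.end)
            bg[py[sel], px[sel]] = color
    for row in (comp.ref_gapped, ref_u, query_u, comp.query_gapped):
        panel = bg.copy()
        codes = np.frombuffer(row.encode("latin-1"), dtype=np.uint8)
        drawn = codes != ord("-")
        lut = palette.as_lookup()
        panel[py[drawn], px[drawn]] = lut[codes[drawn]]
        panels.append(panel)
    canvas = np.tile(
        np.array(palette.background, np.uint8), (h, 4 * w + 3 * gutter, 1)
    )
    for k, panel in enumerate(panels):
        x0 = k * (w + gutter)
        canvas[:, x0 : x0 + w] = panel
    return Image.fromarray(canvas, "RGB")


_TABLE_ROWS = (
    ("Reference length (N's included)", "ref_len_with_N"),
    ("Reference length (no N's)", "ref_len_no_N"),
    ("Total alignment length", "alignment_length"),
    ("Unaligned sequence within reference", "unaligned_ref"),
    ("Alignment length/Reference length (%)", "coverage_pct"),
    ("Identical bases within alignment", "identical"),
    ("Non-identical bases within alignment", "non_identical"),
    ("Identical bases/Alignment length (%)", "identity_pct"),
    ("Number of gaps introduced in reference by alignment", "ref_gap_count"),
    ("Ref gaps larger than 10 bp", "ref_gaps_gt10"),
    ("Ref gaps larger than 100 bp", "ref_gaps_gt100"),
    ("Ref gaps larger than 1000 bp", "ref_gaps_gt1000"),
    ("Ref N to query bp", "refN_to_query_bp"),
    ("Query N to ref bp", "queryN_to_ref_bp"),
    ("Number of gaps introduced in query by alignment", "query_gap_count"),
    ("Query gaps larger than 10 bp", "query_gaps_gt10"),
    ("Query gaps larger than 100 bp", "query_gaps_gt100"),
    ("Query gaps larger than 1000 bp", "query_gaps_gt1000"),
)


def stats_table(stats_by_name: Mapping[str, AlignmentStats]) -> str:
    """Render per-chromosome stats as a TSV table, one row per statistic."""
    names = list(stats_by_name)
    lines = ["Feature\t" + "\t".join(names)]
    for title, attr in _TABLE_ROWS:
        values = []
        for name in names:
            v = getattr(stats_by_name[name], attr)
            values.append(f"{v:.2f}" if isinstance(v, float) else str(v))
        lines.append(title + "\t" + "\t".join(values))
    return "\n".join(lines) + "\n"


def chain_coverage_profile(
    chains: Sequence[Chain],
    ref_genome: Sequence[Contig],
    homolog_map: Mapping[str, str] | None = None,
    exclude: Mapping[str, Sequence[tuple[int, int]]] | None = None,
) -> dict:
    """Coverage of the reference by the union of top-k chains per chromosome.

    Per chromosome, chains are ranked by score; coverage is the union of
    aligned block footprints of the top k chains (k = 1, 2, 3, all),
    reported with and without N/excluded regions.  Aligned sequence is
    also split by whether the contributing chain's query chromosome is
    homologous to the reference chromosome under ``homolog_map`` (for
    example ``{"2A": "2", "2B": "2"}`` maps two query chromosomes onto one
    reference chromosome); names match after stripping a ``chr`` prefix.
    """
    homolog_map = dict(homolog_map or {})
    exclude = dict(exclude or {})

    def canon(name: str) -> str:
        stripped = name[3:] if name.lower().startswith("chr") else name
        return homolog_map.get(stripped, homolog_map.get(name, stripped))

    total_len = 0
    total_len_clean = 0
    cov: dict[object, int] = {1: 0, 2: 0, 3: 0, "all": 0}
    cov_clean: dict[object, int] = {1: 0, 2: 0, 3: 0, "all": 0}
    homolog_bp = 0
    non_homolog_bp = 0
    for contig in ref_genome:
        n = contig.length
        keep = np.ones(n, dtype=bool)
        seq = np.frombuffer(contig.seq.upper().encode("latin-1"), dtype="S1")
        keep &= seq != b"N"
        for lo, hi in exclude.get(contig.name, ()):
            keep[lo:hi] = False
        total_len += n
        total_len_clean += int(keep.sum())
        ranked = sorted(
            (c for c in chains if c.tName == contig.name),
            key=lambda c: c.score,
            reverse=True,
        )
        covered = np.zeros(n, dtype=bool)
        by_class = np.zeros(n, dtype=np.uint8)  # 1 homolog, 2 non-homolog
        for rank, chain in enumerate(ranked, start=1):
            t = chain.tStart
            is_homolog = canon(chain.qName) == canon(contig.name)
            for block in chain.blocks:
                newly = ~covered[t : t + block.size]
                covered[t : t + block.size] = True
                cls_val = 1 if is_homolog else 2
                sub = by_class[t : t + block.size]
                sub[newly] = cls_val
                t += block.size + block.dt
            for k in (1, 2, 3):
                if rank == k:
                    cov[k] += int(covered.sum())
                    cov_clean[k] += int((covered & keep).sum())
        n_chains = len(ranked)
        for k in (1, 2, 3):
            if n_chains < k:  # fewer chains than k: union is just all of them
                cov[k] += int(covered.sum())
                cov_clean[k] += int((covered & keep).sum())
        cov["all"] += int(covered.sum())
        cov_clean["all"] += int((covered & keep).sum())
        homolog_bp += int(((by_class == 1) & keep).sum())
        non_homolog_bp += int(((by_class == 2) & keep).sum())
    def pct(num: int, den: int) -> float:
        return 100.0 * num / den if den else 0.0

    return {
        "ref_length": total_len,
        "ref_length_excluded": total_len_clean,
        "coverage_pct": {k: pct(v, total_len) for k, v in cov.items()},
        "coverage_pct_excluded": {k: pct(v, total_len_clean) for k, v in cov_clean.items()},
        "homolog_pct_excluded": pct(homolog_bp, total_len_clean),
        "non_homolog_pct_excluded": pct(non_homolog_bp, total_len_clean),
    }
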