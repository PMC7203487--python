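"""Seeded synthetic data: genomes, annotations, and mutated genome pairs
with the exactly corresponding chain file and known alignment statistics.

The generator exists so the whole pipeline is testable without downloads:
``mutate_and_chain`` applies SNPs, indels, inversions and translocations
to a reference contig, emits the query genome *and* the UCSC chain file
that a perfect aligner would produce for that mutation set, and computes
the resulting alignment statistics during construction — never by running
the alignment module itself.  Inversions become ``-`` strand chains on
the same query chromosome; translocations become chains from a separate
query contig.

Ground-truth accounting follows the linearization semantics of the
compositor: query-side insertions are only visible in the composite when
they sit inside the master chain (the highest-scoring one), so the truth
for query-gap fields counts only those.  All other fields are independent
of which chain is master.

A single integer seed controls every random draw, so fixture files are
byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from pathlib import Path
from typing import Sequence

import numpy as np

from .alignment import AlignmentStats
from .io_formats import (
    AnnotationFeature,
    Chain,
    ChainBlock,
    Contig,
    revcomp,
    write_chain_file,
    write_fasta,
)

__all__ = [
    "RecipeError",
    "MutationRecipe",
    "MutationResult",
    "gen_genome",
    "gen_features",
    "write_gff3",
    "mutate_and_chain",
    "random_recipe",
    "write_fixture_dir",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_MIN_SEP = 2      # aligned bases required between mutation events
_EDGE_MARGIN = 5  # events keep clear of contig and segment boundaries


class RecipeError(ValueError):
    """A mutation recipe is internally inconsistent or cannot be placed."""


def gen_genome(
    n_contigs: int = 3,
    lengths: Sequence[int] | None = None,
    gc: float = 0.41,
    gc_by_region: Sequence[tuple[int, int, int, float]] = (),
    tandem_repeats: Sequence[tuple[int, int, str, int]] = (),
    seed: int = 0,
) -> list[Contig]:
    """Random genome with controllable regional GC and planted repeat arrays.

    ``gc_by_region`` entries are ``(contig_index, start, end, gc_fraction)``
    half-open overrides (emulating isochores); ``tandem_repeats`` entries
    are ``(contig_index, start, unit, copies)`` and overwrite the sequence
    with a verbatim ``unit * copies`` array.  The default genome-wide GC of
    0.41 matches a typical mammalian composition.
    """
    if lengths is None:
        lengths = [1000] * n_contigs
    if len(lengths) != n_contigs:
        raise ValueError("lengths must have n_contigs entries")
    rng = np.random.default_rng(seed)

    def draw(n: int, frac_gc: float) -> np.ndarray:
        is_gc = rng.random(n) < frac_gc
        pick = rng.integers(0, 2, n)
        # A/T when not GC, G/C when GC
        out = np.where(is_gc, np.where(pick == 0, b"G", b"C"), np.where(pick == 0, b"A", b"T"))
        return out.astype("S1")

    contigs = []
    for ci in range(n_contigs):
        n = int(lengths[ci])
        if n < 1:
            raise ValueError("contig lengths must be >= 1")
        arr = draw(n, gc)
        for idx, start, end, frac in gc_by_region:
            if idx == ci:
                arr[start:end] = draw(end - start, frac)
        for idx, start, unit, copies in tandem_repeats:
            if idx == ci:
                rep = np.frombuffer((unit * copies).encode(), dtype="S1")
                arr[start : start + len(rep)] = rep
        contigs.append(Contig(name=f"chr{ci + 1}", seq=arr.tobytes().decode()))
    return contigs


def gen_features(
    contigs: Sequence[Contig], n_genes: int = 5, seed: int = 0
) -> list[AnnotationFeature]:
    """Nested gene > mRNA > exon > CDS features within contig bounds."""
    rng = np.random.default_rng(seed)
    features: list[AnnotationFeature] = []
    used: dict[str, list[tuple[int, int]]] = {c.name: [] for c in contigs}
    weights = np.array([c.length for c in contigs], dtype=float)
    weights /= weights.sum()
    for gi in range(n_genes):
        for _attempt in range(200):
            contig = contigs[rng.choice(len(contigs), p=weights)]
            max_len = min(800, contig.length // max(2, n_genes))
            glen = int(rng.integers(120, max(122, max_len)))
            if contig.length < glen + 2:
                continue
            start = int(rng.integers(1, contig.length - glen))  # 1-based
            end = start + glen - 1
            if any(s <= end and start <= e for s, e in used[contig.name]):
                continue
            used[contig.name].append((start, end))
            break
        else:
            raise RecipeError(f"cannot place gene {gi} without overlap")
        strand = "+" if rng.random() < 0.5 else "-"
        name = f"GENE{gi + 1}"
        features.append(
            AnnotationFeature(contig.name, "synth", "gene", start, end, strand,
                              label=name, attributes={"ID": f"g{gi + 1}", "Name": name})
        )
        features.append(
            AnnotationFeature(contig.name, "synth", "mRNA", start, end, strand,
                              label=name, attributes={"ID": f"t{gi + 1}", "Parent": f"g{gi + 1}",
                                                      "Name": name})
        )
        n_exons = int(rng.integers(1, 4))
        bounds = np.sort(rng.choice(np.arange(start, end), size=2 * n_exons, replace=False))
        for ei in range(n_exons):
            es, ee = int(bounds[2 * ei]), int(bounds[2 * ei + 1])
            if ee < es:
                es, ee = ee, es
            features.append(
                AnnotationFeature(contig.name, "synth", "exon", es, ee, strand,
                                  label="", attributes={"ID": f"e{gi + 1}.{ei + 1}",
                                                        "Parent": f"t{gi + 1}"})
            )
            if rng.random() < 0.7 and ee - es >= 2:
                cs = es + int(rng.integers(0, (ee - es) // 2 + 1))
                ce = min(ee, cs + max(3, (ee - es) // 2))
                features.append(
                    AnnotationFeature(contig.name, "synth", "CDS", cs, ce, strand,
                                      label="", attributes={"ID": f"c{gi + 1}.{ei + 1}",
                                                            "Parent": f"t{gi + 1}"})
                )
    return features


def write_gff3(features: Sequence[AnnotationFeature], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={v}" for k, v in f.attributes.items()) or "."
            ftype = f.raw_type or f.ftype
            out.write(
                f"{f.seqid}\t{f.source}\t{ftype}\t{f.start}\t{f.end}\t.\t{f.strand}\t.\t{attrs}\n"
            )


@dataclass
class MutationRecipe:
    """A fully specified mutation set with seeded event placement.

    ``indels`` entries are ``(side, length)`` where side ``ref`` means the
    reference keeps bases the query lacks (a ``dt`` chain gap) and side
    ``query`` means the query carries an insertion (a ``dq`` gap).
    Inversions are ``(start, length)`` on the reference; translocations
    ``(query_contig_name, start, length)`` move a reference segment to a
    different query chromosome.
    """

    seed: int
    n_snp: int = 0
    indels: list[tuple[str, int]] = dataclass_field(default_factory=list)
    inversions: list[tuple[int, int]] = dataclass_field(default_factory=list)
    translocations: list[tuple[str, int, int]] = dataclass_field(default_factory=list)


@dataclass
class MutationResult:
    query_contigs: list[Contig]
    chains: list[Chain]
    ground_truth: AlignmentStats
    unique_length: int
    class_bp: dict[str, int]
    master_chain_id: int


def _regions_of(recipe: MutationRecipe) -> list[tuple[int, int, str, str | None]]:
    """Inversion/translocation intervals, sorted, as (start, end, kind, qname)."""
    regions = [(s, s + l, "inv", None) for s, l in recipe.inversions]
    regions += [(s, s + l, "trans", qn) for qn, s, l in recipe.translocations]
    regions.sort()
    return regions


def mutate_and_chain(ref: Contig, recipe: MutationRecipe) -> MutationResult:
    """Apply a recipe to ``ref``; emit query contigs, chains and ground truth."""
    n = ref.length
    if "N" in ref.seq.upper():
        raise RecipeError("recipes require an N-free reference")
    rng = np.random.default_rng(recipe.seed)

    regions = _regions_of(recipe)
    prev_end = 0
    for s, e, kind, _ in regions:
        if s < _EDGE_MARGIN or e > n - _EDGE_MARGIN:
            raise RecipeError(f"{kind} region [{s},{e}) too close to contig ends")
        if s < prev_end + _MIN_SEP + 1:
            raise RecipeError(f"overlapping or adjacent mutation regions at {s}")
        prev_end = e
    # runs: maximal collinear segments between regions
    runs: list[tuple[int, int]] = []
    cursor = 0
    for s, e, _, _ in regions:
        if s > cursor:
            runs.append((cursor, s))
        cursor = e
    if cursor < n:
        runs.append((cursor, n))
    if not runs:
        raise RecipeError("recipe leaves no collinear sequence")

    # place indels and SNPs inside runs, pairwise separated
    occupied = [(s, e) for s, e, _, _ in regions]

    def conflicts(lo: int, hi: int) -> bool:
        return any(lo < e + _MIN_SEP and s - _MIN_SEP < hi for s, e in occupied)

    def place(length: int) -> int:
        for _ in range(2000):
            ri = int(rng.integers(0, len(runs)))
            a, b = runs[ri]
            lo_min, lo_max = a + _EDGE_MARGIN, b - _EDGE_MARGIN - length
            if lo_max <= lo_min:
                continue
            p = int(rng.integers(lo_min, lo_max))
            if not conflicts(p, p + length):
                occupied.append((p, p + length))
                return p
        raise RecipeError("cannot place mutation without overlap; reduce event count")

    indel_events = []  # (pos, side, length)
    for side, length in recipe.indels:
        if side not in {"ref", "query"}:
            raise RecipeError(f"indel side must be 'ref' or 'query', got {side!r}")
        span = length if side == "ref" else 1
        indel_events.append((place(span), side, length))
    snp_positions = [place(1) for _ in range(recipe.n_snp)]
    indel_events.sort()
    snp_set = sorted(snp_positions)

    ref_arr = np.frombuffer(ref.seq.encode(), dtype="S1").copy()
    mutated = ref_arr.copy()
    for p in snp_set:
        current = mutated[p]
        alternatives = _BASES[_BASES != current.upper()]
        mutated[p] = alternatives[int(rng.integers(0, len(alternatives)))]

    # per-run aligned length and a unique score so the master is unambiguous
    dt_by_run = [0] * len(runs)
    dq_by_run = [[] for _ in runs]
    for p, side, length in indel_events:
        ri = next(i for i, (a, b) in enumerate(runs) if a <= p < b)
        if side == "ref":
            dt_by_run[ri] += length
        else:
            dq_by_run[ri].append((p, length))
    aligned_by_run = [(b - a) - dt for (a, b), dt in zip(runs, dt_by_run)]
    scores = [al * 10 + (len(runs) - i) for i, al in enumerate(aligned_by_run)]
    master_run = int(np.argmax(scores))
    max_region_len = max((e - s for s, e, _, _ in regions), default=0)
    if max_region_len * 10 >= max(scores):
        raise RecipeError("a rearranged region outscores every collinear chain")

    qname = f"{ref.name}_q"
    query_parts: list[str] = []
    q_cursor = 0
    chains: list[Chain] = []
    pending_minus: list[tuple[Chain, int, int]] = []  # chain, q_fwd_start, q_fwd_end
    decoys: list[Contig] = []
    chain_id = 1
    run_i = 0
    segments: list[tuple[int, int, str, str | None]] = []
    cursor = 0
    for s, e, kind, qn in regions:
        if s > cursor:
            segments.append((cursor, s, "run", None))
        segments.append((s, e, kind, qn))
        cursor = e
    if cursor < n:
        segments.append((cursor, n, "run", None))

    for a, b, kind, qn in segments:
        if kind == "run":
            events = [(p, side, l) for p, side, l in indel_events if a <= p < b]
            blocks: list[ChainBlock] = []
            piece: list[str] = []
            t = a
            q_start = q_cursor
            for p, side, length in events:
                size = p - t
                aligned_seg = mutated[t:p].tobytes().decode()
                piece.append(aligned_seg)
                q_cursor += size
                if side == "ref":
                    blocks.append(ChainBlock(size, dt=length, dq=0))
                    t = p + length
                else:
                    ins = _BASES[rng.integers(0, 4, length)].tobytes().decode()
                    piece.append(ins)
                    q_cursor += length
                    blocks.append(ChainBlock(size, dt=0, dq=length))
                    t = p
            size = b - t
            piece.append(mutated[t:b].tobytes().decode())
            q_cursor += size
            blocks.append(ChainBlock(size))
            query_parts.append("".join(piece))
            chains.append(
                Chain(
                    score=scores[run_i], tName=ref.name, tSize=n, tStrand="+",
                    tStart=a, tEnd=b, qName=qname, qSize=0, qStrand="+",
                    qStart=q_start, qEnd=q_cursor, chain_id=chain_id, blocks=blocks,
                )
            )
            chain_id += 1
            run_i += 1
        elif kind == "inv":
            seg = mutated[a:b].tobytes().decode()
            query_parts.append(revcomp(seg))
            q_start = q_cursor
            q_cursor += b - a
            chain = Chain(
                score=(b - a), tName=ref.name, tSize=n, tStrand="+",
                tStart=a, tEnd=b, qName=qname, qSize=0, qStrand="-",
                qStart=0, qEnd=0, chain_id=chain_id, blocks=[ChainBlock(b - a)],
            )
            pending_minus.append((chain, q_start, q_cursor))
            chains.append(chain)
            chain_id += 1
        else:  # translocation: segment lives on a different query contig
            seg = mutated[a:b].tobytes().decode()
            flank_l = _BASES[rng.integers(0, 4, 50)].tobytes().decode()
            flank_r = _BASES[rng.integers(0, 4, 50)].tobytes().decode()
            decoys.append(Contig(name=qn, seq=flank_l + seg + flank_r))
            chains.append(
                Chain(
                    score=(b - a), tName=ref.name, tSize=n, tStrand="+",
                    tStart=a, tEnd=b, qName=qn, qSize=100 + (b - a), qStrand="+",
                    qStart=50, qEnd=50 + (b - a), chain_id=chain_id,
                    blocks=[ChainBlock(b - a)],
                )
            )
            chain_id += 1

    query_seq = "".join(query_parts)
    q_size = len(query_seq)
    for chain in chains:
        if chain.qName == qname:
            chain.qSize = q_size
    for chain, q_fwd_start, q_fwd_end in pending_minus:
        chain.qStart = q_size - q_fwd_end
        chain.qEnd = q_size - q_fwd_start
    for chain in chains:
        chain.validate()
    query_contigs = [Contig(name=qname, seq=query_seq)] + decoys

    # ground truth, by construction
    total_dt = sum(dt_by_run)
    alignment_length = n - total_dt
    identical = alignment_length - recipe.n_snp
    ref_gap_lens = [l for _, side, l in indel_events if side == "ref"]
    # only master-chain dq gaps are pulled into the composite
    query_gap_lens = [l for _, l in dq_by_run[master_run]]
    truth = AlignmentStats(
        ref_len_with_N=n,
        ref_len_no_N=n,
        alignment_length=alignment_length,
        unaligned_ref=total_dt,
        coverage_pct=100.0 * alignment_length / n if n else 0.0,
        identical=identical,
        non_identical=recipe.n_snp,
        identity_pct=100.0 * identical / alignment_length if alignment_length else 0.0,
        ref_gap_count=len(ref_gap_lens),
        ref_gaps_gt10=sum(1 for l in ref_gap_lens if l > 10),
        ref_gaps_gt100=sum(1 for l in ref_gap_lens if l > 100),
        ref_gaps_gt1000=sum(1 for l in ref_gap_lens if l > 1000),
        query_gap_count=len(query_gap_lens),
        query_gaps_gt10=sum(1 for l in query_gap_lens if l > 10),
        query_gaps_gt100=sum(1 for l in query_gap_lens if l > 100),
        query_gaps_gt1000=sum(1 for l in query_gap_lens if l > 1000),
        refN_to_query_bp=0,
        queryN_to_ref_bp=0,
    )
    class_bp = {
        "syntenic": aligned_by_run[master_run],
        "intra": sum(al for i, al in enumerate(aligned_by_run) if i != master_run)
        + sum(l for _, l in recipe.inversions),
        "inter": sum(l for _, _, l in recipe.translocations),
    }
    master_chain_id = [c for c in chains if c.qName == qname and c.qStrand == "+"][master_run].chain_id
    return MutationResult(
        query_contigs=query_contigs,
        chains=chains,
        ground_truth=truth,
        unique_length=total_dt,
        class_bp=class_bp,
        master_chain_id=master_chain_id,
    )


def random_recipe(seed: int, ref_len: int) -> MutationRecipe:
    """A modest random mutation set that fits comfortably in ``ref_len``."""
    rng = np.random.default_rng(seed)
    n_snp = int(rng.integers(0, 15))
    indels: list[tuple[str, int]] = []
    for _ in range(int(rng.integers(0, 4))):
        side = "ref" if rng.random() < 0.5 else "query"
        scale = rng.choice([5, 40, 400], p=[0.5, 0.35, 0.15])
        length = max(1, int(rng.integers(scale // 2, scale * 2)))
        indels.append((side, length))
    inversions: list[tuple[int, int]] = []
    translocations: list[tuple[str, int, int]] = []
    budget_regions = []
    n_inv = int(rng.integers(0, 3))
    n_trans = int(rng.integers(0, 2))
    slots = np.linspace(0, ref_len, n_inv + n_trans + 2, dtype=int)[1:-1]
    rng.shuffle(slots)
    for k in range(n_inv):
        length = int(rng.integers(60, max(61, ref_len // 12)))
        start = int(slots[k]) - length // 2
        start = max(_EDGE_MARGIN + 1, min(start, ref_len - _EDGE_MARGIN - length - 1))
        budget_regions.append((start, start + length, "inv", None))
    for k in range(n_trans):
        length = int(rng.integers(60, max(61, ref_len // 15)))
        start = int(slots[n_inv + k]) - length // 2
        start = max(_EDGE_MARGIN + 1, min(start, ref_len - _EDGE_MARGIN - length - 1))
        budget_regions.append((start, start + length, "trans", f"chrT{k + 1}"))
    budget_regions.sort()
    prev_end = -(10**9)
    for s, e, kind, qn in budget_regions:
        if s < prev_end + _MIN_SEP + 1:
            continue  # drop colliding draws rather than fail
        if kind == "inv":
            inversions.append((s, e - s))
        else:
            translocations.append((qn, s, e - s))
        prev_end = e
    return MutationRecipe(
        seed=int(rng.integers(0, 2**31 - 1)),
        n_snp=n_snp,
        indels=indels,
        inversions=inversions,
        translocations=translocations,
    )


def write_fixture_dir(out_dir: str | Path, seed: int = 0, ref_len: int = 8000) -> dict:
    """Write a self-contained dataset: ref/query FASTA, GFF3 and chain file."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ref = gen_genome(n_contigs=1, lengths=[ref_len], seed=seed)[0]
    recipe = random_recipe(seed + 1, ref_len)
    result = mutate_and_chain(ref, recipe)
    features = gen_features([ref], n_genes=5, seed=seed + 2)
    write_fasta([ref], out_dir / "ref.fa")
    write_fasta(result.query_contigs, out_dir / "query.fa")
    write_chain_file(result.chains, out_dir / "alignment.chain")
    write_gff3(features, out_dir / "annotations.gff3")
    return {
        "ref": str(out_dir / "ref.fa"),
        "query": str(out_dir / "query.fa"),
        "chain": str(out_dir / "alignment.chain"),
        "gff": str(out_dir / "annotations.gff3"),
        "ground_truth": result.ground_truth,
    }
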