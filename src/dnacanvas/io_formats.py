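"""Readers and writers for FASTA, GFF3/GFF2/GTF and UCSC chain files.

All parsers validate their input strictly and raise :class:`FormatError`
with enough context (file, line, chain id) to locate the problem.

Coordinate conventions
----------------------
* FASTA: a record's ``name`` is the first whitespace-delimited token of the
  header; the full header is kept in ``description``.  Case (soft-masking)
  is preserved.
* GFF/GTF features keep their native 1-based inclusive coordinates in
  ``start``/``end``; the 0-based half-open view used internally is exposed
  as ``start0``/``end0``.
* Chain coordinates are 0-based half-open, target strand always ``+``;
  query coordinates of a ``-`` strand chain refer to the reverse-complemented
  query sequence, as in the UCSC specification.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "FormatError",
    "Contig",
    "AnnotationFeature",
    "Chain",
    "ChainBlock",
    "read_fasta",
    "write_fasta",
    "read_annotations",
    "read_chain_file",
    "write_chain_file",
    "revcomp",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


_COMPLEMENT = str.maketrans(
    "ACGTUacgtuNnRYSWKMBDHVryswkmbdhv-",
    "TGCAAtgcaaNnYRSWMKVHDByrswmkvhdb-",
)


def revcomp(seq: str) -> str:
    """Reverse complement, preserving case and gap characters."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Contig:
    """One named nucleotide sequence from a FASTA record."""

    name: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise FormatError("contig name must be non-empty")

    @property
    def length(self) -> int:
        return len(self.seq)


_KNOWN_FTYPES = {"gene", "mRNA", "exon", "CDS"}


@dataclass
class AnnotationFeature:
    """A typed, stranded genomic interval with a display label.

    ``start``/``end`` are 1-based inclusive, as written in GFF/GTF.
    """

    seqid: str
    source: str
    ftype: str          # one of gene/mRNA/exon/CDS/other
    start: int
    end: int
    strand: str         # '+', '-' or '.'
    label: str = ""
    attributes: dict = field(default_factory=dict)
    raw_type: str = ""  # the type string as written in the file

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"feature on {self.seqid}: end ({self.end}) < start ({self.start})"
            )
        if self.strand not in {"+", "-", "."}:
            raise FormatError(f"invalid strand {self.strand!r}")

    @property
    def start0(self) -> int:
        """0-based half-open start."""
        return self.start - 1

    @property
    def end0(self) -> int:
        """0-based half-open end."""
        return self.end

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class ChainBlock:
    """One gapless aligned block and the gaps that follow it.

    ``dt``/``dq`` are the unaligned stretches on the target (reference) and
    query side between this block and the next; both are 0 for the final
    block of a chain.
    """

    size: int
    dt: int = 0
    dq: int = 0


@dataclass
class Chain:
    """A UCSC liftOver chain: scored series of gapless blocks."""

    score: int
    tName: str
    tSize: int
    tStrand: str
    tStart: int
    tEnd: int
    qName: str
    qSize: int
    qStrand: str
    qStart: int
    qEnd: int
    chain_id: int
    blocks: list[ChainBlock] = field(default_factory=list)

    def validate(self) -> None:
        if self.tStrand != "+":
            raise FormatError(
                f"chain {self.chain_id}: target strand must be '+', got {self.tStrand!r}"
            )
        if self.qStrand not in {"+", "-"}:
            raise FormatError(f"chain {self.chain_id}: bad query strand {self.qStrand!r}")
        t_span = sum(b.size + b.dt for b in self.blocks)
        q_span = sum(b.size + b.dq for b in self.blocks)
        if t_span != self.tEnd - self.tStart:
            raise FormatError(
                f"chain {self.chain_id}: block sum on target ({t_span}) != "
                f"tEnd - tStart ({self.tEnd - self.tStart})"
            )
        if q_span != self.qEnd - self.qStart:
            raise FormatError(
                f"chain {self.chain_id}: block sum on query ({q_span}) != "
                f"qEnd - qStart ({self.qEnd - self.qStart})"
            )
        if self.blocks and (self.blocks[-1].dt or self.blocks[-1].dq):
            raise FormatError(f"chain {self.chain_id}: final block must have no trailing gap")
        for b in self.blocks:
            if b.size < 1 or b.dt < 0 or b.dq < 0:
                raise FormatError(f"chain {self.chain_id}: invalid block {b}")


def read_fasta(path: str | os.PathLike) -> list[Contig]:
    """Read a (multi-)FASTA file into an ordered list of :class:`Contig`."""
    path = Path(path)
    with open(path) as handle:
        text = handle.read()
    stripped = text.lstrip()
    if not stripped:
        raise FormatError(f"{path}: empty FASTA file")
    if not stripped.startswith(">"):
        raise FormatError(f"{path}: first non-blank character must be '>'")
    contigs: list[Contig] = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        if len(rec.seq) == 0:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        contigs.append(Contig(name=rec.id, seq=str(rec.seq), description=rec.description))
    if not contigs:
        raise FormatError(f"{path}: no FASTA records found")
    return contigs


def write_fasta(contigs: Iterable[Contig], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as out:
        for c in contigs:
            header = c.description if c.description else c.name
            out.write(f">{header}\n")
            for i in range(0, len(c.seq), width):
                out.write(c.seq[i : i + width] + "\n")


# --- GFF / GTF -------------------------------------------------------------

def _parse_gff3_attributes(text: str) -> dict:
    attrs = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def _parse_gtf_attributes(text: str) -> dict:
    attrs = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        attrs[key.strip()] = value.strip().strip('"')
    return attrs


_LABEL_PRECEDENCE = ("Name", "ID", "gene_id", "gene_name")


def _detect_dialect(attr_text: str) -> str:
    # GFF3 uses key=value; GTF/GFF2 use key "value" pairs.
    head = attr_text.strip().split(";")[0]
    return "gff3" if "=" in head else "gtf"


def read_annotations(
    path: str | os.PathLike, dialect: str = "auto"
) -> list[AnnotationFeature]:
    """Parse GFF3/GFF2/GTF into :class:`AnnotationFeature` records.

    Labels resolve by precedence Name > ID > gene_id > gene_name; feature
    types outside gene/mRNA/exon/CDS map to ``other`` (``transcript`` is
    treated as mRNA).
    """
    if dialect not in {"gff3", "gff2", "gtf", "auto"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    features: list[AnnotationFeature] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise FormatError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            seqid, source, rtype, start_s, end_s, _score, strand, _frame = cols[:8]
            attr_text = cols[8]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end < start:
                raise FormatError(f"{path}:{lineno}: end ({end}) < start ({start})")
            eff_dialect = dialect
            if eff_dialect == "auto":
                eff_dialect = _detect_dialect(attr_text)
            if eff_dialect == "gff3":
                attrs = _parse_gff3_attributes(attr_text)
            else:  # gtf and gff2 share the quoted key-value syntax
                attrs = _parse_gtf_attributes(attr_text)
            label = ""
            for key in _LABEL_PRECEDENCE:
                if attrs.get(key):
                    label = attrs[key]
                    break
            ftype = rtype if rtype in _KNOWN_FTYPES else (
                "mRNA" if rtype == "transcript" else "other"
            )
            if strand not in {"+", "-", "."}:
                raise FormatError(f"{path}:{lineno}: invalid strand {strand!r}")
            features.append(
                AnnotationFeature(
                    seqid=seqid,
                    source=source,
                    ftype=ftype,
                    start=start,
                    end=end,
                    strand=strand,
                    label=label,
                    attributes=attrs,
                    raw_type=rtype,
                )
            )
    return features


# --- UCSC chain ------------------------------------------------------------

def read_chain_file(path: str | os.PathLike) -> list[Chain]:
    """Parse a UCSC chain file, validating block arithmetic per chain."""
    path = Path(path)
    chains: list[Chain] = []
    current: Chain | None = None
    expecting_blocks = False
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("chain"):
                if current is not None and expecting_blocks:
                    raise FormatError(
                        f"{path}:{lineno}: chain {current.chain_id} has no terminating block"
                    )
                fields = line.split()
                if len(fields) != 13:
                    raise FormatError(
                        f"{path}:{lineno}: chain header needs 13 fields, got {len(fields)}"
                    )
                try:
                    current = Chain(
                        score=int(fields[1]),
                        tName=fields[2],
                        tSize=int(fields[3]),
                        tStrand=fields[4],
                        tStart=int(fields[5]),
                        tEnd=int(fields[6]),
                        qName=fields[7],
                        qSize=int(fields[8]),
                        qStrand=fields[9],
                        qStart=int(fields[10]),
                        qEnd=int(fields[11]),
                        chain_id=int(fields[12]),
                    )
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad chain header") from exc
                chains.append(current)
                expecting_blocks = True
            else:
                if current is None:
                    raise FormatError(f"{path}:{lineno}: block line before any chain header")
                parts = line.split()
                try:
                    nums = [int(p) for p in parts]
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-integer block line") from exc
                if len(nums) == 3:
                    current.blocks.append(ChainBlock(nums[0], nums[1], nums[2]))
                elif len(nums) == 1:
                    current.blocks.append(ChainBlock(nums[0]))
                    expecting_blocks = False
                else:
                    raise FormatError(f"{path}:{lineno}: block line needs 1 or 3 integers")
    for chain in chains:
        chain.validate()
    return chains


def write_chain_file(chains: Sequence[Chain], path: str | os.PathLike) -> None:
    """Write chains back in UCSC chain format (inverse of read_chain_file)."""
    with open(path, "w") as out:
        for c in chains:
            out.write(
                f"chain {c.score} {c.tName} {c.tSize} {c.tStrand} {c.tStart} {c.tEnd} "
                f"{c.qName} {c.qSize} {c.qStrand} {c.qStart} {c.qEnd} {c.chain_id}\n"
            )
            for b in c.blocks[:-1]:
                out.write(f"{b.size} {b.dt} {b.dq}\n")
            if c.blocks:
                out.write(f"{c.blocks[-1].size}\n")
            out.write("\n")
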