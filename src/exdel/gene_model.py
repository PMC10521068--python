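"""Gene models and the combinatorial deletion transcriptome.

A gene of interest is described by a single canonical transcript (one BED12
record). From its N exons, every transcript that lacks one consecutive run of
*internal* exons (edge exons are never deleted — splicing events do not occur
beyond the transcript ends) is enumerated, giving C(N-1, 2) deletion
transcripts. Each deletion transcript carries a novel exon-exon junction whose
transcript coordinate is the anchor for junction-read counting downstream.

Coordinates follow the BED convention throughout: genomic intervals are
0-based, half-open; transcript coordinates are 0-based. Exon ordinals are
1-based in transcript (5'->3') orientation, so on the minus strand exon 1 is
the exon with the highest genomic coordinates.
"""

from __future__ import annotations

import re
import sys
import warnings
from collections.abc import Mapping
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO, Union

__all__ = [
    "ExonInterval",
    "GeneModel",
    "DeletionSpec",
    "DeletionTranscript",
    "BedParseError",
    "reverse_complement",
    "parse_bed12",
    "enumerate_deletions",
    "build_deletion_transcripts",
    "extract_sequences",
    "write_transcriptome_fasta",
    "write_deletion_bed",
]

_COMPLEMENT = str.maketrans("ACGTUacgtuNnRYKMrykm", "TGCAAtgcaaNnYRMKyrmk")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, N kept as N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class BedParseError(ValueError):
    """Raised for malformed or inconsistent BED12 input."""


@dataclass(frozen=True)
class ExonInterval:
    """One exon: genomic half-open interval plus its transcript ordinal."""

    chrom: str
    start: int
    end: int
    ordinal: int  # 1-based, 5'->3' in transcript orientation

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"exon start must be < end, got [{self.start}, {self.end})")
        if self.ordinal < 1:
            raise ValueError("exon ordinal is 1-based")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """Canonical transcript of one gene, exons in 5'->3' order."""

    transcript_id: str
    gene_name: str
    chrom: str
    strand: str
    exons: tuple[ExonInterval, ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError("a gene model needs at least one exon")
        ordinals = [e.ordinal for e in self.exons]
        if ordinals != list(range(1, len(self.exons) + 1)):
            raise ValueError("exon ordinals must be 1..N in order")
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if a.end > b.start:
                raise ValueError("exons overlap")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def canonical_length(self) -> int:
        """Transcript length in bp (sum of exon lengths)."""
        return sum(e.length for e in self.exons)

    @property
    def genomic_span(self) -> tuple[int, int]:
        return min(e.start for e in self.exons), max(e.end for e in self.exons)


_DEL_NAME_RE = re.compile(r"^del(\d+)(?:_(\d+))?$")


@dataclass(frozen=True, order=True)
class DeletionSpec:
    """A consecutive run of internal exons to remove: ordinals [first, last]."""

    first_deleted: int
    last_deleted: int

    def __post_init__(self) -> None:
        if not 2 <= self.first_deleted <= self.last_deleted:
            raise ValueError("deleted run must start at exon >= 2")

    @property
    def name(self) -> str:
        i, j = self.first_deleted, self.last_deleted
        return f"del{i}" if i == j else f"del{i}_{j}"

    @classmethod
    def from_name(cls, name: str) -> "DeletionSpec":
        m = _DEL_NAME_RE.match(name)
        if m is None:
            raise ValueError(f"not a deletion name: {name!r}")
        i = int(m.group(1))
        j = int(m.group(2)) if m.group(2) else i
        return cls(i, j)


@dataclass(frozen=True)
class DeletionTranscript:
    """A transcript with one internal exon run removed.

    ``junction_offset`` is the 0-based transcript coordinate of the first base
    *after* the novel junction, i.e. the cumulative length of retained exons
    preceding the deleted run. A read supports the deletion only if its
    alignment covers bases on both sides of this offset.
    """

    spec: DeletionSpec
    parent: GeneModel
    retained_exons: tuple[ExonInterval, ...]
    length: int
    junction_offset: int

    @property
    def name(self) -> str:
        return self.spec.name

    @property
    def record_id(self) -> str:
        return f"{self.parent.transcript_id}|{self.spec.name}"


def parse_bed12(source: Union[str, TextIO]) -> list[GeneModel]:
    """Parse BED12 records into gene models (one canonical transcript each).

    Exon ordinals follow transcript orientation: block order for ``+`` strand
    records, reversed block order for ``-`` strand. Coordinates stay 0-based
    half-open. Malformed lines raise :class:`BedParseError` naming the line.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source) as fh:
            lines = fh.read().splitlines()

    genes: list[GeneModel] = []
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 12:
            raise BedParseError(f"line {lineno}: expected 12 BED columns, got {len(fields)}")
        try:
            chrom = fields[0]
            chrom_start = int(fields[1])
            chrom_end = int(fields[2])
            name = fields[3]
            strand = fields[5]
            block_count = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
        except ValueError as exc:
            raise BedParseError(f"line {lineno}: {exc}") from exc
        if strand not in "+-":
            raise BedParseError(f"line {lineno}: strand must be '+' or '-', got {strand!r}")
        if len(sizes) != block_count or len(starts) != block_count:
            raise BedParseError(
                f"line {lineno}: blockCount {block_count} inconsistent with "
                f"{len(sizes)} blockSizes / {len(starts)} blockStarts"
            )
        if starts and starts[0] != 0:
            raise BedParseError(f"line {lineno}: first blockStart must be 0")
        if starts and chrom_start + starts[-1] + sizes[-1] != chrom_end:
            raise BedParseError(f"line {lineno}: last block does not end at chromEnd")

        intervals = [
            (chrom_start + off, chrom_start + off + size)
            for off, size in zip(starts, sizes)
        ]
        if strand == "-":
            intervals = intervals[::-1]
        exons = tuple(
            ExonInterval(chrom, s, e, ordinal=i + 1) for i, (s, e) in enumerate(intervals)
        )
        genes.append(
            GeneModel(transcript_id=name, gene_name=name, chrom=chrom, strand=strand, exons=exons)
        )
    return genes


def enumerate_deletions(n_exons: int) -> list[DeletionSpec]:
    """All consecutive internal-exon deletion runs of an N-exon transcript.

    Returns every (i, j) with 2 <= i <= j <= N-1, in ascending (i, j) order.
    There are C(N-1, 2) of them; N < 3 yields an empty list (no internal exon).
    """
    if n_exons < 1:
        raise ValueError("n_exons must be >= 1")
    return [
        DeletionSpec(i, j)
        for i in range(2, n_exons)
        for j in range(i, n_exons)
    ]


def build_deletion_transcripts(gene: GeneModel) -> list[DeletionTranscript]:
    """One :class:`DeletionTranscript` per internal consecutive-exon run."""
    if gene.n_exons < 3:
        warnings.warn(
            f"{gene.transcript_id}: {gene.n_exons} exon(s), no internal exon to delete",
            stacklevel=2,
        )
        return []
    out: list[DeletionTranscript] = []
    for spec in enumerate_deletions(gene.n_exons):
        retained = tuple(
            e for e in gene.exons if not spec.first_deleted <= e.ordinal <= spec.last_deleted
        )
        junction_offset = sum(e.length for e in gene.exons if e.ordinal < spec.first_deleted)
        out.append(
            DeletionTranscript(
                spec=spec,
                parent=gene,
                retained_exons=retained,
                length=sum(e.length for e in retained),
                junction_offset=junction_offset,
            )
        )
    return out


GenomeLike = Union[Mapping, "pyfaidx.Fasta"]  # noqa: F821 - duck-typed


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Fetch genome[chrom][start:end) from a pyfaidx.Fasta or a plain mapping."""
    try:
        record = genome[chrom]
    except KeyError as exc:
        raise KeyError(f"chromosome {chrom!r} not found in genome") from exc
    if end > len(record):
        raise IndexError(
            f"interval [{start}, {end}) beyond end of {chrom!r} (length {len(record)})"
        )
    piece = record[start:end]
    return piece if isinstance(piece, str) else str(piece)


def _spliced_sequence(genome, chrom: str, strand: str, exons: Sequence[ExonInterval]) -> str:
    genomic_order = sorted(exons, key=lambda e: e.start)
    seq = "".join(_fetch(genome, chrom, e.start, e.end) for e in genomic_order)
    return reverse_complement(seq).upper() if strand == "-" else seq.upper()


def extract_sequences(
    genome,
    models: Iterable[Union[GeneModel, DeletionTranscript]],
) -> list[tuple[str, str]]:
    """Spliced transcript sequences, 5'->3', as (record_id, sequence) pairs.

    Minus-strand transcripts are reverse-complemented. Record IDs are the
    transcript ID for a canonical model and ``{transcript_id}|{deletion}`` for
    deletion transcripts. ``genome`` may be a :class:`pyfaidx.Fasta` or any
    mapping of chromosome name to sequence string.
    """
    records: list[tuple[str, str]] = []
    for model in models:
        if isinstance(model, GeneModel):
            seq = _spliced_sequence(genome, model.chrom, model.strand, model.exons)
            records.append((model.transcript_id, seq))
        else:
            parent = model.parent
            seq = _spliced_sequence(genome, parent.chrom, parent.strand, model.retained_exons)
            if len(seq) != model.length:
                raise AssertionError("spliced length mismatch")  # pragma: no cover
            records.append((model.record_id, seq))
    return records


def write_transcriptome_fasta(records: Iterable[tuple[str, str]], path, width: int = 70) -> None:
    """Write (id, sequence) pairs as a multi-record FASTA."""
    fh = sys.stdout if path == "-" else open(path, "w")
    try:
        for rec_id, seq in records:
            fh.write(f">{rec_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    finally:
        if fh is not sys.stdout:
            fh.close()


def write_deletion_bed(transcripts: Iterable[DeletionTranscript], path) -> None:
    """Write one BED12 line per deletion transcript (retained exon blocks)."""
    with open(path, "w") as fh:
        for t in transcripts:
            exons = sorted(t.retained_exons, key=lambda e: e.start)
            chrom_start = exons[0].start
            chrom_end = exons[-1].end
            sizes = ",".join(str(e.length) for e in exons) + ","
            starts = ",".join(str(e.start - chrom_start) for e in exons) + ","
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        t.parent.chrom,
                        chrom_start,
                        chrom_end,
                        t.record_id,
                        0,
                        t.parent.strand,
                        chrom_start,
                        chrom_end,
                        0,
                        len(exons),
                        sizes,
                        starts,
                    )
                )
                + "\n"
            )
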