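"""Read classification against the deletion transcriptome.

Reads are pseudoaligned by intersecting the transcript sets of their matching
k-mers (kallisto-style equivalence classes), in whichever orientation (forward
or reverse complement) matches more k-mers. Because the reference is mutually
exclusive by construction, a read whose equivalence class (EC) is a single
deletion transcript is junction evidence — those reads get extra scrutiny:

* full-coverage check: the whole read must align end-to-end at one offset of
  the transcript with at most ``mismatch`` substitutions (no indels);
* trim test: with ``trim`` bases removed from each end the read must still
  classify to the same singleton EC, so a handful of bases overhanging an
  exon boundary (or soft-clip-like ends) can never be the sole evidence.

Reads failing either check, and all reads with multi-transcript ECs, count
toward the gene total (TC); only robust singleton-deletion reads count toward
that deletion's unique count (UC). Unmapped reads count to neither.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Union

from .kmer_index import KmerIndex, query_orientations
from .gene_model import reverse_complement

__all__ = [
    "MappingParams",
    "ReadRecord",
    "ReadClassification",
    "GeneCounts",
    "classify_read",
    "trim_check",
    "resolve_pair",
    "tally",
    "map_reads",
]


@dataclass(frozen=True)
class MappingParams:
    """Mapping parameters.

    mismatch: max substitutions allowed in the end-to-end check of uniquely
        classified reads (default 2).
    trim: bases removed from each read end in the robustness re-check
        (default 5); must be >= mismatch so that mismatched bases can never be
        the sole junction overhang. trim=0 disables the test.
    min_overhang: junction overhang the trim test effectively enforces; kept
        for reporting and analytic oracles (the trim test is the enforcement
        mechanism, no separate coordinate check is done).
    """

    mismatch: int = 2
    trim: int = 5
    min_overhang: int = 5

    def __post_init__(self) -> None:
        if min(self.mismatch, self.trim, self.min_overhang) < 0:
            raise ValueError("mapping parameters must be >= 0")
        if self.trim < self.mismatch:
            raise ValueError(
                f"trim ({self.trim}) must equal or exceed mismatch ({self.mismatch})"
            )


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    sequence: str
    mate: Optional[int] = None  # 1, 2 or None for single-end

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty read sequence")


@dataclass(frozen=True)
class ReadClassification:
    """Outcome for one read (or resolved pair).

    ``ec`` is the set of compatible transcript ordinals; empty means unmapped.
    ``gene`` is None when unmapped or when the EC straddles genes (ambiguous —
    such reads are evidence for no single gene and are discarded).
    """

    ec: frozenset[int]
    is_unique_deletion: bool = False
    mismatches_used: int = 0
    gene: Optional[str] = None
    deletion_name: Optional[str] = None
    status: str = "mapped"  # mapped | unmapped | too_short | ambiguous

    @property
    def mapped(self) -> bool:
        return self.status == "mapped" and bool(self.ec)


_UNMAPPED = ReadClassification(ec=frozenset(), status="unmapped")


def _hamming_at_most(a: str, b: str, limit: int) -> Optional[int]:
    """Hamming distance if <= limit else None (early exit)."""
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return None
    return d


def _verify_full_coverage(
    read_seq: str, transcript_seq: str, anchor_read_pos: int, kmer: str, mismatch: int
) -> Optional[int]:
    """End-to-end check: anchor the read by an exact k-mer, Hamming-compare.

    Every occurrence of the anchor k-mer in the transcript implies one
    candidate offset; the read must fit within the transcript at that offset
    with <= mismatch substitutions. Returns the best substitution count, or
    None when no offset verifies.
    """
    best: Optional[int] = None
    pos = transcript_seq.find(kmer)
    while pos != -1:
        offset = pos - anchor_read_pos
        if offset >= 0 and offset + len(read_seq) <= len(transcript_seq):
            d = _hamming_at_most(read_seq, transcript_seq[offset : offset + len(read_seq)], mismatch)
            if d is not None and (best is None or d < best):
                best = d
                if best == 0:
                    break
        pos = transcript_seq.find(kmer, pos + 1)
    return best


def classify_read(read: ReadRecord, index: KmerIndex, params: MappingParams) -> ReadClassification:
    """Assign a read to an equivalence class; vet singleton classifications.

    The EC is the intersection of the transcript sets of all matching k-mers,
    taken in the orientation with more matching k-mers (ties prefer forward).
    A singleton EC triggers the full-coverage check; on failure the read is
    demoted to the gene-level (non-unique) EC rather than lost.
    """
    seq = read.sequence.upper()
    if len(seq) < index.k:
        return replace(_UNMAPPED, status="too_short")

    fwd, rev = query_orientations(index, seq)
    if not fwd and not rev:
        return _UNMAPPED
    if len(rev) > len(fwd):
        hits, oriented = rev, reverse_complement(seq)
    else:
        hits, oriented = fwd, seq

    ec: frozenset[int] = hits[0][1]
    for _, members in hits[1:]:
        ec = ec & members
        if not ec:
            return _UNMAPPED

    genes = {index.gene_of(o) for o in ec}
    if len(genes) > 1:
        return ReadClassification(ec=ec, status="ambiguous")
    gene = genes.pop()

    if len(ec) == 1:
        (ordinal,) = ec
        t = index.transcripts[ordinal]
        anchor_pos, anchor_members = hits[0]
        kmer = oriented[anchor_pos : anchor_pos + index.k]
        mm = _verify_full_coverage(oriented, t.sequence, anchor_pos, kmer, params.mismatch)
        if mm is None:
            # incomplete coverage: keep as gene-level expression evidence
            gene_ec = frozenset(index.gene_meta[gene].member_ordinals)
            return ReadClassification(ec=gene_ec, gene=gene, status="mapped")
        return ReadClassification(
            ec=ec,
            is_unique_deletion=t.is_deletion,
            mismatches_used=mm,
            gene=gene,
            deletion_name=t.deletion_name,
        )
    return ReadClassification(ec=ec, gene=gene)


def trim_check(
    read: ReadRecord,
    classification: ReadClassification,
    index: KmerIndex,
    params: MappingParams,
) -> bool:
    """Re-classify the read with ``trim`` bases cut from each end.

    Passes only if the trimmed read still yields the identical singleton EC
    (strict equality); a trimmed read shorter than k fails conservatively.
    trim=0 is the identity and always passes.
    """
    if not classification.is_unique_deletion:
        raise ValueError("trim test applies to unique-deletion classifications only")
    if params.trim == 0:
        return True
    trimmed = read.sequence[params.trim : len(read.sequence) - params.trim]
    if len(trimmed) < index.k:
        return False
    redo = classify_read(ReadRecord(read.read_id, trimmed, read.mate), index, params)
    return redo.ec == classification.ec


def resolve_pair(c1: ReadClassification, c2: ReadClassification) -> ReadClassification:
    """Merge mate classifications, favouring uniqueness.

    The smaller EC wins (it is the more specific signal — junction reads have
    singleton ECs). Equal-size differing ECs are intersected; an empty
    intersection, or mates from different genes, demotes the pair to the
    gene-level non-unique EC (or discards it as ambiguous across genes).
    """
    if not c1.mapped and not c2.mapped:
        # propagate the more informative status (too_short counts as unmapped)
        return c1 if c1.status != "unmapped" else c2
    if not c2.mapped:
        return c1
    if not c1.mapped:
        return c2
    if c1.gene != c2.gene:
        return ReadClassification(ec=c1.ec | c2.ec, status="ambiguous")
    if len(c1.ec) < len(c2.ec):
        return c1
    if len(c2.ec) < len(c1.ec):
        return c2
    if c1.ec == c2.ec:
        return c1
    inter = c1.ec & c2.ec
    if inter:
        # joint evidence, but neither mate passed the unique-read checks on
        # its own: keep it as non-unique gene expression
        return ReadClassification(ec=inter, gene=c1.gene)
    return ReadClassification(
        ec=c1.ec | c2.ec, gene=c1.gene, status="mapped"
    )


@dataclass
class GeneCounts:
    """Per-gene tally: unique counts per deletion plus the gene total.

    TC deliberately excludes UC reads: "all other reads" of the gene. Unmapped
    and cross-gene-ambiguous reads are excluded from both.
    """

    gene: str
    uc: dict[str, int]
    tc: int = 0
    n_unmapped: int = 0
    n_ambiguous: int = 0
    read_length: Optional[int] = None
    paired: bool = False

    @property
    def mapped_total(self) -> int:
        return sum(self.uc.values()) + self.tc


def _new_counts(index: KmerIndex) -> dict[str, GeneCounts]:
    return {
        gene: GeneCounts(gene=gene, uc={name: 0 for name in meta.deletion_names})
        for gene, meta in index.gene_meta.items()
    }


def tally(
    classifications: Iterable[ReadClassification],
    index: KmerIndex,
    params: Optional[MappingParams] = None,
) -> dict[str, GeneCounts]:
    """Aggregate final (post trim, post pair-resolution) classifications.

    UC[d] counts reads/pairs uniquely and robustly supporting deletion d; every
    other mapped read of the gene increments TC. Unmapped reads are excluded
    entirely; cross-gene ambiguous reads count to neither gene.
    """
    counts = _new_counts(index)
    ambiguous = 0
    unmapped = 0
    for c in classifications:
        if c.status == "ambiguous":
            ambiguous += 1
            continue
        if not c.mapped:
            unmapped += 1
            continue
        gc = counts[c.gene]
        if c.is_unique_deletion:
            gc.uc[c.deletion_name] += 1
        else:
            gc.tc += 1
    for gc in counts.values():
        gc.n_unmapped = unmapped
        gc.n_ambiguous = ambiguous
    return counts


# --- FASTQ/FASTA input -----------------------------------------------------


def _open_text(path):
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path)


def iter_reads(path) -> Iterator[ReadRecord]:
    """Yield reads from a FASTA or FASTQ file, optionally gzip-compressed."""
    from Bio.SeqIO.FastaIO import SimpleFastaParser
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    fh = _open_text(path)
    try:
        first = fh.read(1)
        fh.seek(0)
        if first == ">":
            for title, seq in SimpleFastaParser(fh):
                yield ReadRecord(title.split()[0], seq)
        elif first == "@":
            for title, seq, _qual in FastqGeneralIterator(fh):
                yield ReadRecord(title.split()[0], seq)
        elif first:
            raise ValueError(f"{path}: not FASTA or FASTQ")
    finally:
        fh.close()


def _classify_and_vet(read: ReadRecord, index: KmerIndex, params: MappingParams):
    c = classify_read(read, index, params)
    if c.is_unique_deletion and not trim_check(read, c, index, params):
        # robustness failure: "these reads contribute only to the gene total"
        c = ReadClassification(ec=c.ec, gene=c.gene, mismatches_used=c.mismatches_used)
    return c


def map_reads(
    reads: Union[str, Iterable[ReadRecord]],
    index: KmerIndex,
    params: Optional[MappingParams] = None,
    reads2: Union[str, Iterable[ReadRecord], None] = None,
    read_length: Optional[int] = None,
) -> dict[str, GeneCounts]:
    """End-to-end mapping: classify, trim-vet, resolve pairs and tally.

    ``reads``/``reads2`` are FASTQ/FASTA paths or iterables of
    :class:`ReadRecord`; supplying ``reads2`` selects paired-end mode (the two
    streams must be synchronized; unequal lengths raise). Deterministic for
    fixed inputs and parameters. ``read_length`` is the nominated read length
    recorded in the output; defaults to the mode of observed lengths.
    """
    params = params or MappingParams()
    stream1 = iter_reads(reads) if isinstance(reads, str) else iter(reads)
    stream2 = (
        iter_reads(reads2) if isinstance(reads2, str) else iter(reads2) if reads2 is not None else None
    )
    paired = stream2 is not None

    length_tally: dict[int, int] = {}
    finals: list[ReadClassification] = []
    if paired:
        sentinel = object()
        while True:
            r1 = next(stream1, sentinel)
            r2 = next(stream2, sentinel)
            if r1 is sentinel and r2 is sentinel:
                break
            if (r1 is sentinel) != (r2 is sentinel):
                raise ValueError("desynchronized mate files: unequal read counts")
            length_tally[len(r1.sequence)] = length_tally.get(len(r1.sequence), 0) + 1
            length_tally[len(r2.sequence)] = length_tally.get(len(r2.sequence), 0) + 1
            finals.append(
                resolve_pair(
                    _classify_and_vet(r1, index, params),
                    _classify_and_vet(r2, index, params),
                )
            )
    else:
        for r in stream1:
            length_tally[len(r.sequence)] = length_tally.get(len(r.sequence), 0) + 1
            finals.append(_classify_and_vet(r, index, params))

    counts = tally(finals, index, params)
    if read_length is None and length_tally:
        read_length = max(length_tally, key=lambda L: (length_tally[L], -L))
    for gc in counts.values():
        gc.read_length = read_length
        gc.paired = paired
    return counts
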