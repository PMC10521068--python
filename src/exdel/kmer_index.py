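"""k-mer index over the mutually exclusive deletion transcriptome.

The reference for one gene is the canonical transcript plus all internal
consecutive-exon deletion transcripts. Because each deletion creates a novel
exon-exon junction absent from every other transcript, its junction k-mers map
uniquely to it, and pseudoalignment at the equivalence-class level can single
out junction-spanning reads without base-level alignment.

The contract is a plain hash map from k-mer to the set of transcript ordinals
containing it; only forward-strand k-mers are stored and queries try the read
and its reverse complement. Serialization stores k, the transcript records and
gene metadata (versioned, gzipped JSON) and rebuilds the k-mer map on load.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass
from typing import Iterable, Union

from .gene_model import reverse_complement

__all__ = [
    "TranscriptInfo",
    "GeneMeta",
    "KmerIndex",
    "IndexBuildError",
    "IndexLoadError",
    "build_index",
    "save_index",
    "load_index",
]

_FORMAT_VERSION = 1
_ACGT = frozenset("ACGT")


class IndexBuildError(ValueError):
    """Raised when a transcriptome cannot be indexed."""


class IndexLoadError(ValueError):
    """Raised when an index file is missing, corrupt or of the wrong version."""


@dataclass(frozen=True)
class TranscriptInfo:
    """One indexed transcript. ``deletion_name`` is None for the canonical."""

    record_id: str
    gene: str
    length: int
    deletion_name: Union[str, None]
    sequence: str

    @property
    def is_deletion(self) -> bool:
        return self.deletion_name is not None


@dataclass(frozen=True)
class GeneMeta:
    """Per-gene metadata: canonical length and member transcript ordinals."""

    gene: str
    canonical_length: int
    canonical_ordinal: int
    member_ordinals: tuple[int, ...]
    deletion_names: tuple[str, ...]  # index order, matches quantify row order


class KmerIndex:
    """k-mer -> transcript-ordinal-set map plus transcript/gene metadata."""

    def __init__(self, k: int, transcripts: list[TranscriptInfo]):
        if k < 1:
            raise IndexBuildError("k must be >= 1")
        ids = [t.record_id for t in transcripts]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise IndexBuildError(f"duplicate record IDs: {dupes}")
        if all(t.length < k for t in transcripts):
            raise IndexBuildError(f"every transcript is shorter than k={k}")
        self.k = k
        self.transcripts = tuple(transcripts)
        self.kmer_map: dict[str, frozenset[int]] = self._build_kmer_map()
        self.gene_meta: dict[str, GeneMeta] = self._build_gene_meta()

    def _build_kmer_map(self) -> dict[str, frozenset[int]]:
        k = self.k
        acc: dict[str, set[int]] = {}
        for ordinal, t in enumerate(self.transcripts):
            seq = t.sequence.upper()
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if not _ACGT.issuperset(kmer):
                    continue  # ambiguity codes are skipped at build and query
                acc.setdefault(kmer, set()).add(ordinal)
        return {kmer: frozenset(members) for kmer, members in acc.items()}

    def _build_gene_meta(self) -> dict[str, GeneMeta]:
        meta: dict[str, GeneMeta] = {}
        by_gene: dict[str, list[int]] = {}
        for ordinal, t in enumerate(self.transcripts):
            by_gene.setdefault(t.gene, []).append(ordinal)
        for gene, members in by_gene.items():
            canonical = [o for o in members if not self.transcripts[o].is_deletion]
            if len(canonical) != 1:
                raise IndexBuildError(
                    f"gene {gene!r} must have exactly one canonical transcript, "
                    f"found {len(canonical)}"
                )
            meta[gene] = GeneMeta(
                gene=gene,
                canonical_length=self.transcripts[canonical[0]].length,
                canonical_ordinal=canonical[0],
                member_ordinals=tuple(members),
                deletion_names=tuple(
                    self.transcripts[o].deletion_name
                    for o in members
                    if self.transcripts[o].is_deletion
                ),
            )
        return meta

    def lookup(self, kmer: str) -> frozenset[int]:
        """Transcript ordinals whose sequence contains ``kmer`` (forward strand).

        Case-insensitive; a k-mer containing non-ACGT characters returns the
        empty set. Length other than k is a usage error.
        """
        if len(kmer) != self.k:
            raise ValueError(f"k-mer length {len(kmer)} != k={self.k}")
        return self.kmer_map.get(kmer.upper(), frozenset())

    def gene_of(self, ordinal: int) -> str:
        return self.transcripts[ordinal].gene

    def __eq__(self, other) -> bool:  # mainly for round-trip tests
        return (
            isinstance(other, KmerIndex)
            and self.k == other.k
            and self.transcripts == other.transcripts
            and self.kmer_map == other.kmer_map
        )


def _parse_record_id(record_id: str) -> tuple[str, Union[str, None]]:
    """Split 'txid|delname' into (gene, deletion_name); plain IDs are canonical."""
    if "|" in record_id:
        gene, deletion = record_id.split("|", 1)
        return gene, deletion
    return record_id, None


def _read_fasta(path) -> list[tuple[str, str]]:
    from Bio.SeqIO.FastaIO import SimpleFastaParser

    with open(path) as fh:
        return [(title.split()[0], seq) for title, seq in SimpleFastaParser(fh)]


def build_index(transcriptome: Union[str, Iterable[tuple[str, str]]], k: int = 31) -> KmerIndex:
    """Index a deletion transcriptome FASTA (path or (id, sequence) pairs).

    Record IDs follow the builder's convention: the canonical transcript is
    named ``{transcript_id}``, deletions ``{transcript_id}|{deletion_name}``.
    """
    records = _read_fasta(transcriptome) if isinstance(transcriptome, str) else list(transcriptome)
    if not records:
        raise IndexBuildError("empty transcriptome")
    transcripts = []
    for record_id, seq in records:
        gene, deletion = _parse_record_id(record_id)
        transcripts.append(
            TranscriptInfo(
                record_id=record_id,
                gene=gene,
                length=len(seq),
                deletion_name=deletion,
                sequence=seq.upper(),
            )
        )
    return KmerIndex(k=k, transcripts=transcripts)


def save_index(index: KmerIndex, path) -> None:
    """Serialize an index as versioned gzipped JSON."""
    payload = {
        "format": "exdel-index",
        "format_version": _FORMAT_VERSION,
        "k": index.k,
        "transcripts": [
            {
                "record_id": t.record_id,
                "gene": t.gene,
                "length": t.length,
                "deletion_name": t.deletion_name,
                "sequence": t.sequence,
            }
            for t in index.transcripts
        ],
    }
    with gzip.open(path, "wt") as fh:
        json.dump(payload, fh)


def load_index(path) -> KmerIndex:
    """Load an index written by :func:`save_index`; exact round-trip."""
    try:
        with gzip.open(path, "rt") as fh:
            payload = json.load(fh)
    except (OSError, EOFError, json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise IndexLoadError(f"cannot read index file {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != "exdel-index":
        raise IndexLoadError(f"{path} is not an exdel index file")
    if payload.get("format_version") != _FORMAT_VERSION:
        raise IndexLoadError(
            f"index format version {payload.get('format_version')} unsupported "
            f"(expected {_FORMAT_VERSION})"
        )
    transcripts = [
        TranscriptInfo(
            record_id=t["record_id"],
            gene=t["gene"],
            length=t["length"],
            deletion_name=t["deletion_name"],
            sequence=t["sequence"],
        )
        for t in payload["transcripts"]
    ]
    return KmerIndex(k=payload["k"], transcripts=transcripts)


def query_orientations(index: KmerIndex, sequence: str):
    """Matching k-mers of a read in both orientations.

    Returns ``(fwd_hits, rev_hits)`` where each is a list of
    ``(position, members)`` for every k-mer of the (reverse-complemented)
    sequence present in the index. Shared helper for the pseudoaligner.
    """
    k = index.k
    kmer_map = index.kmer_map
    seq = sequence.upper()
    n = len(seq) - k + 1

    def hits(s: str):
        out = []
        for i in range(n):
            members = kmer_map.get(s[i : i + k])
            if members is not None:
                out.append((i, members))
        return out

    fwd = hits(seq)
    # a fully matching forward read cannot be beaten by the reverse orientation
    if len(fwd) == n and n > 0:
        return fwd, []
    return fwd, hits(reverse_complement(seq))
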