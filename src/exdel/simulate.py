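"""Synthetic genes and deletion-isoform read mixtures.

Everything downstream (indexing, pseudoalignment, quantification, cohort
scoring) is testable without external data through this module. The generator
emulates the situation the method targets: a bulk RNA-seq library over one
gene whose transcripts are a mixture of the canonical isoform and internal
exon-deletion isoforms.

Model, deliberately simple:

* exon sequences are i.i.d. uniform ACGT, embedded in a toy genome with
  fixed-length intron spacers (plus strand by default);
* each read (or fragment, for paired ends) picks a source transcript with
  probability proportional to its abundance, then a uniform start position —
  no positional, GC or fragmentation bias;
* sequencing error is i.i.d. per-base substitution; no indels, matching the
  mapper's no-indel contract.

`expected_junction_reads` gives the exact binomial mean of junction-spanning
read counts from the fragment geometry alone, independent of the mapper, so
end-to-end recovery can be checked against an analytic oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .gene_model import (
    DeletionTranscript,
    ExonInterval,
    GeneModel,
    build_deletion_transcripts,
    extract_sequences,
)
from .pseudoalign import ReadRecord

__all__ = [
    "SimulationConfig",
    "SimTruth",
    "random_gene",
    "deletion_transcriptome",
    "simulate_reads",
    "expected_junction_reads",
    "write_fastq",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimulationConfig:
    """Read-mixture parameters.

    abundances maps transcript record IDs (e.g. ``"tx1"``, ``"tx1|del4_7"``)
    to relative read fractions summing to 1. ``fragment_length`` is the outer
    fragment span for paired ends and must be >= read_length.
    """

    abundances: dict[str, float]
    n_reads: int = 1000
    read_length: int = 100
    paired: bool = False
    fragment_length: Optional[int] = None
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.abundances.values()):
            raise ValueError("abundances must be >= 0")
        total = sum(self.abundances.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances must sum to 1, got {total}")
        if self.n_reads < 0 or self.read_length < 1:
            raise ValueError("n_reads and read_length must be positive")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.paired:
            if self.fragment_length is None:
                raise ValueError("paired simulation needs fragment_length")
            if self.fragment_length < self.read_length:
                raise ValueError("fragment_length must be >= read_length")


@dataclass
class SimTruth:
    """Ground truth of a simulated sample.

    ``origins`` records (read_id, source transcript, fragment start offset);
    ``expected_uc`` is the analytic junction-read expectation per deletion,
    computed from fragment geometry only (never from the mapper).
    """

    origins: list[tuple[str, str, int]]
    expected_uc: dict[str, float]


def random_gene(
    n_exons: int,
    exon_lengths: Union[int, Sequence[int]],
    seed: int,
    intron_length: int = 100,
    chrom: str = "chrS",
    transcript_id: str = "tx1",
    strand: str = "+",
) -> tuple[GeneModel, dict[str, str]]:
    """A random gene embedded in a toy genome; deterministic under seed.

    Returns the gene model and a {chrom: sequence} genome mapping usable
    directly by :func:`exdel.gene_model.extract_sequences` (or written out
    with :func:`exdel.gene_model.write_transcriptome_fasta`).
    """
    if isinstance(exon_lengths, int):
        exon_lengths = [exon_lengths] * n_exons
    if len(exon_lengths) != n_exons:
        raise ValueError("need one exon length per exon")
    rng = np.random.default_rng(seed)
    genome_len = sum(exon_lengths) + intron_length * (n_exons + 1)
    genome = _BASES[rng.integers(0, 4, size=genome_len)].tobytes().decode()

    intervals = []
    pos = intron_length
    for length in exon_lengths:
        intervals.append((pos, pos + length))
        pos += length + intron_length
    if strand == "-":
        ordered = intervals[::-1]  # exon 1 = 5'-most = highest coordinates
    else:
        ordered = intervals
    exons = tuple(
        ExonInterval(chrom, s, e, ordinal=i + 1) for i, (s, e) in enumerate(ordered)
    )
    gene = GeneModel(
        transcript_id=transcript_id,
        gene_name=transcript_id,
        chrom=chrom,
        strand=strand,
        exons=exons,
    )
    return gene, {chrom: genome}


def deletion_transcriptome(
    gene: GeneModel, genome: dict[str, str]
) -> tuple[list[tuple[str, str]], list[DeletionTranscript]]:
    """Canonical + all deletion transcript sequences for a simulated gene."""
    deletions = build_deletion_transcripts(gene)
    records = extract_sequences(genome, [gene, *deletions])
    return records, deletions


def _add_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(len(arr)) < error_rate
    if hit.any():
        idx = np.flatnonzero(hit)
        # substitute with one of the three other bases, uniformly
        originals = arr[idx]
        subs = _BASES[rng.integers(0, 4, size=len(idx))]
        clash = subs == originals
        while clash.any():
            subs[clash] = _BASES[rng.integers(0, 4, size=int(clash.sum()))]
            clash = subs == originals
        arr[idx] = subs
    return arr.tobytes().decode()


def simulate_reads(
    config: SimulationConfig,
    transcriptome: Union[dict[str, str], Iterable[tuple[str, str]]],
    deletions: Optional[Sequence[DeletionTranscript]] = None,
) -> tuple[Union[list[ReadRecord], list[tuple[ReadRecord, ReadRecord]]], SimTruth]:
    """Draw reads from a transcript mixture with uniform fragment starts.

    Single-end mode returns a flat list of :class:`ReadRecord`; paired mode a
    list of (mate1, mate2) with mate2 reverse-complemented from the fragment's
    far end. When ``deletions`` is given, the truth carries the analytic
    expected UC per deletion (min_overhang 5, the mapping default).
    """
    seqs = dict(transcriptome)
    for name in config.abundances:
        if name not in seqs:
            raise ValueError(f"abundance given for unknown transcript {name!r}")
        span = config.fragment_length if config.paired else config.read_length
        if span > len(seqs[name]):
            raise ValueError(
                f"read/fragment length {span} exceeds transcript {name!r} "
                f"length {len(seqs[name])}"
            )

    rng = np.random.default_rng(config.seed)
    names = sorted(config.abundances)
    probs = np.array([config.abundances[n] for n in names])
    sources = rng.choice(len(names), size=config.n_reads, p=probs)

    span = config.fragment_length if config.paired else config.read_length
    origins: list[tuple[str, str, int]] = []
    reads: list = []
    for i, src in enumerate(sources):
        name = names[src]
        tseq = seqs[name]
        start = int(rng.integers(0, len(tseq) - span + 1))
        read_id = f"sim{i}"
        origins.append((read_id, name, start))
        fragment = tseq[start : start + span]
        if config.paired:
            m1 = fragment[: config.read_length]
            from .gene_model import reverse_complement

            m2 = reverse_complement(fragment[-config.read_length :])
            reads.append(
                (
                    ReadRecord(read_id, _add_errors(m1, config.error_rate, rng), mate=1),
                    ReadRecord(read_id, _add_errors(m2, config.error_rate, rng), mate=2),
                )
            )
        else:
            reads.append(ReadRecord(read_id, _add_errors(fragment, config.error_rate, rng)))

    expected = {}
    if deletions is not None:
        for d in deletions:
            expected[d.name] = expected_junction_reads(config, d)
    return reads, SimTruth(origins=origins, expected_uc=expected)


def _spanning_starts(
    transcript_length: int, junction_offset: int, read_length: int, min_overhang: int
) -> int:
    """Start positions whose read covers the junction with >= min_overhang
    bases on each side (exact count over the integer range)."""
    lo = max(0, junction_offset - read_length + min_overhang)
    hi = min(transcript_length - read_length, junction_offset - min_overhang)
    return max(0, hi - lo + 1)


def expected_junction_reads(
    config: SimulationConfig,
    deletion: DeletionTranscript,
    min_overhang: int = 5,
) -> float:
    """Exact binomial mean of junction-supporting reads for one deletion.

    E = n_reads * abundance(d) * valid_starts / total_starts, where a start is
    valid if the read covers the novel junction with >= min_overhang bases on
    each side; for pairs, a fragment is valid if either mate does. Meaningful
    in the error-free regime.
    """
    abundance = config.abundances.get(deletion.record_id, 0.0)
    if abundance == 0:
        return 0.0
    L = deletion.length
    j = deletion.junction_offset
    if config.paired:
        F = config.fragment_length
        total = L - F + 1
        valid = 0
        for s in range(total):  # fragment starts; L is small, enumeration is exact
            m1_spans = s + min_overhang <= j <= s + config.read_length - min_overhang
            m2_start = s + F - config.read_length
            m2_spans = m2_start + min_overhang <= j <= s + F - min_overhang
            valid += m1_spans or m2_spans
    else:
        total = L - config.read_length + 1
        valid = _spanning_starts(L, j, config.read_length, min_overhang)
    if total <= 0:
        return 0.0
    return config.n_reads * abundance * valid / total


def write_fastq(reads: Iterable[ReadRecord], path) -> None:
    """Write reads as FASTQ with uniform placeholder qualities."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")
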