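"""Shared fixtures: small simulated genes and brute-force oracles.

The oracles here are deliberately independent of the package's mapping path:
equivalence classes are recomputed by exact substring search over full
transcript sequences, never through the k-mer index.
"""

from __future__ import annotations

import pytest

from exdel import (
    build_index,
    deletion_transcriptome,
    random_gene,
    reverse_complement,
)


@pytest.fixture(scope="session")
def gene8():
    """8-exon, 200 bp-exon gene (IKZF1-like geometry) plus toy genome."""
    gene, genome = random_gene(8, 200, seed=11)
    return gene, genome


@pytest.fixture(scope="session")
def transcriptome8(gene8):
    gene, genome = gene8
    records, deletions = deletion_transcriptome(gene, genome)
    return records, deletions


@pytest.fixture(scope="session")
def index8(transcriptome8):
    records, _ = transcriptome8
    return build_index(records, k=31)


@pytest.fixture(scope="session")
def gene5():
    """Small 5-exon gene with 60 bp exons, for exhaustive oracle checks."""
    gene, genome = random_gene(5, 60, seed=7, intron_length=30)
    return gene, genome


@pytest.fixture(scope="session")
def transcriptome5(gene5):
    gene, genome = gene5
    return deletion_transcriptome(gene, genome)


@pytest.fixture(scope="session")
def index5(transcriptome5):
    records, _ = transcriptome5
    return build_index(records, k=15)


def substring_ec(read_seq: str, records: list[tuple[str, str]]) -> set[str]:
    """Oracle EC: record IDs containing the read as an exact substring,
    in the orientation (forward preferred) that matches at all."""
    fwd = {rid for rid, seq in records if read_seq.upper() in seq}
    if fwd:
        return fwd
    rc = reverse_complement(read_seq.upper())
    return {rid for rid, seq in records if rc in seq}


def oracle_unique_deletion(read_seq: str, records) -> str | None:
    """Oracle: the deletion name the read uniquely supports, else None."""
    ec = substring_ec(read_seq, records)
    if len(ec) == 1:
        (rid,) = ec
        if "|" in rid:
            return rid.split("|", 1)[1]
    return None
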