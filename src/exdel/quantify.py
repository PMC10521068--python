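"""Scaled deletion proportions and the per-sample results CSV.

Only reads overlapping a deletion's novel junction can ever be unique
evidence, so the raw proportion UC/TC shrinks as the gene grows and as reads
shorten. The scaled proportion multiplies UC/TC by
``canonical_length / effective_read_length`` (read length doubled for paired
ends) to put genes and library designs on a comparable scale. It is a
length-based correction, not an unbiased abundance estimator.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, asdict
from typing import Iterable, Optional

import pandas as pd

from .gene_model import DeletionSpec
from .pseudoalign import GeneCounts

__all__ = [
    "DeletionQuantification",
    "compute_scale_factor",
    "quantify",
    "write_results",
    "read_results",
    "RESULT_COLUMNS",
]

RESULT_COLUMNS = [
    "gene",
    "deletion",
    "uc",
    "tc",
    "gene_length",
    "read_length",
    "raw_proportion",
    "scale_factor",
    "scaled_proportion",
    "flags",
]

LOW_EXPRESSION_FLAG = "low_expression"


@dataclass(frozen=True)
class DeletionQuantification:
    """One results row: counts, lengths and proportions for one deletion."""

    gene: str
    deletion: str
    uc: int
    tc: int
    gene_length: int
    read_length: int
    paired: bool
    raw_proportion: float
    scale_factor: float
    scaled_proportion: float
    flags: str = ""


def compute_scale_factor(gene_length: int, read_length: int, paired: bool) -> float:
    """canonical transcript length / effective read length (paired doubles it)."""
    if gene_length <= 0 or read_length <= 0:
        raise ValueError("gene_length and read_length must be positive")
    return gene_length / (read_length * (2 if paired else 1))


def quantify(
    counts: GeneCounts,
    gene_length: int,
    read_length: Optional[int] = None,
) -> list[DeletionQuantification]:
    """One row per deletion of the gene, ordered by (first, last) deleted exon.

    TC = 0 (no gene expression evidence) yields zero proportions flagged
    ``low_expression`` rather than dropped rows, keeping cohort matrices
    rectangular.
    """
    read_length = read_length if read_length is not None else counts.read_length
    if read_length is None:
        raise ValueError("read length unknown: nominate one or map reads first")
    scale = compute_scale_factor(gene_length, read_length, counts.paired)
    flag = LOW_EXPRESSION_FLAG if counts.tc == 0 else ""
    rows = []
    for name in sorted(counts.uc, key=DeletionSpec.from_name):
        uc = counts.uc[name]
        raw = uc / counts.tc if counts.tc > 0 else 0.0
        rows.append(
            DeletionQuantification(
                gene=counts.gene,
                deletion=name,
                uc=uc,
                tc=counts.tc,
                gene_length=gene_length,
                read_length=read_length,
                paired=counts.paired,
                raw_proportion=raw,
                scale_factor=scale,
                scaled_proportion=scale * raw,
                flags=flag,
            )
        )
    return rows


def write_results(rows: Iterable[DeletionQuantification], destination) -> None:
    """Write rows as CSV to a path, or to standard output when given "-"."""
    df = pd.DataFrame([asdict(r) for r in rows])
    if df.empty:
        df = pd.DataFrame(columns=RESULT_COLUMNS)
    else:
        df = df[[c for c in RESULT_COLUMNS if c in df.columns] + ["paired"]]
    target = sys.stdout if destination == "-" else destination
    df.to_csv(target, index=False)


def read_results(path) -> pd.DataFrame:
    """Read a results CSV back (full precision preserved by pandas round-trip)."""
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    missing = [c for c in ("gene", "deletion", "uc", "tc", "scaled_proportion") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: not an exdel results CSV (missing {missing})")
    return df
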