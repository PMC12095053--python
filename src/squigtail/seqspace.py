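"""Sequence-space counterparts of the raw-signal operations.

When reads are basecalled (nanopore cDNA pipelines, or DRS basecalls that
survive mPsi), the terminal pentamer appears as TCTAG in DNA alphabet and
per-read tail lengths arrive as ``pt:i`` tags on the alignment records.
This module detects the terminal pentamer on basecalled sequences, extracts
tag-based tail tables from SAM records, and implements the 3'-RACE
terminal-composition count used to reveal the pentamer orthogonally.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam
from Bio.Seq import Seq

PENTAMER_DNA = "TCTAG"


@dataclass
class BasecalledRead:
    read_id: str
    sequence: str  # 5'->3', over {A,C,G,T,N}
    tail_tag_nt: int | None = None


def _hamming_at_most(a: str, b: str, max_mismatch: int) -> bool:
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > max_mismatch:
                return False
    return True


def find_terminal_pentamer_seq(
    read: BasecalledRead | str,
    pentamer: str = PENTAMER_DNA,
    max_mismatch: int = 0,
    min_a_run: int = 10,
) -> bool:
    """True iff the read ends with the pentamer immediately after a run of
    at least ``min_a_run`` adenosines (substitutions up to
    ``max_mismatch`` allowed within the pentamer)."""
    seq = read.sequence if isinstance(read, BasecalledRead) else read
    if not seq:
        raise ValueError("sequence must be non-empty")
    p = len(pentamer)
    if len(seq) < p + min_a_run:
        return False
    if not _hamming_at_most(seq[-p:], pentamer, max_mismatch):
        return False
    run = seq[-(p + min_a_run) : -p]
    return run == "A" * min_a_run


@dataclass
class TagTailTable:
    table: pd.DataFrame  # columns: read_id, tail_nt, pentamer
    n_excluded: int


def extract_tag_tail(
    source: str | Path | Iterable[pysam.AlignedSegment],
    tag: str = "pt",
    check_pentamer: bool = True,
) -> TagTailTable:
    """Per-read tail table from the ``pt:i`` tag of primary SAM records.

    Secondary and supplementary records are skipped entirely; primary
    records with a missing or negative tag (the "not estimated" sentinel)
    are excluded and counted.  When ``check_pentamer`` is on, each retained
    read's sequence is also screened for the terminal pentamer.
    """
    if isinstance(source, (str, Path)):
        records: Iterable[pysam.AlignedSegment] = pysam.AlignmentFile(
            str(source), check_sq=False
        )
    else:
        records = source
    rows = []
    n_excluded = 0
    for rec in records:
        if rec.is_secondary or rec.is_supplementary:
            continue
        if not rec.has_tag(tag):
            n_excluded += 1
            continue
        value = rec.get_tag(tag)
        if value < 0:
            n_excluded += 1
            continue
        pent = False
        if check_pentamer and rec.query_sequence:
            seq = rec.query_sequence
            if rec.is_reverse:
                seq = str(Seq(seq).reverse_complement())
            pent = find_terminal_pentamer_seq(seq)
        rows.append({"read_id": rec.query_name, "tail_nt": int(value), "pentamer": pent})
    table = pd.DataFrame(rows, columns=["read_id", "tail_nt", "pentamer"])
    return TagTailTable(table=table, n_excluded=n_excluded)


def race_terminal_composition(
    reads: Sequence[str],
    adapter: str,
    min_t_run: int = 6,
    max_insert_len: int = 10,
    pad_a: int = 4,
) -> tuple[pd.DataFrame, int]:
    """3'-end composition from 3'-RACE reads.

    Each raw read is expected to carry the RACE adapter followed by the
    reverse complement of the transcript 3' end (post-tail insert, then the
    poly(A) tail as a T run).  Pipeline: trim everything up to and including
    the adapter; require a run of >= ``min_t_run`` T (the poly(A)
    signature); take the pre-run segment, reverse-complement it into sense
    orientation, keep inserts of length 0..``max_insert_len``; prepend
    ``pad_a`` A (representing the tail) and accumulate per-position base
    counts.

    Returns (position x base count matrix, retained read count).  The
    padded A positions are included in the matrix.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    width = pad_a + max_insert_len
    counts = pd.DataFrame(
        0, index=pd.RangeIndex(width, name="position"), columns=list("ACGT")
    )
    retained = 0
    t_run = "T" * min_t_run
    for raw in reads:
        pos = raw.find(adapter)
        if pos < 0:
            continue
        rest = raw[pos + len(adapter) :]
        cut = rest.find(t_run)
        if cut < 0:
            continue
        insert = str(Seq(rest[:cut]).reverse_complement())
        if len(insert) > max_insert_len:
            continue
        padded = "A" * pad_a + insert
        retained += 1
        for i, base in enumerate(padded):
            if base in counts.columns:
                counts.loc[i, base] += 1
    if retained == 0:
        return counts.iloc[0:0], 0
    return counts, retained
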