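"""Small-RNA read processing: adapter trimming and exact-match counting.

Reads are trimmed by recognising the first 8 bases of the 3' sequencing
adapter (default prefix ``TGGAATTC``); the insert (the sequence before the
first adapter occurrence) is then aligned to mature miRNA sequences with
zero mismatches and zero gaps -- an insert counts for a miRNA iff it is an
exact substring of that miRNA's (U->T normalised) sequence and its length
falls inside a configurable window.

A multi-matching insert increments every matching miRNA by default;
fractional counting (1/k to each of k matches) is available via
``multimap="fractional"``.  The length window defaults to [18, 26] nt,
excluding degradation products and the 30-nt rRNA class.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO

from mirmatch.seq import rna_to_dna
from mirmatch.targets import MatureMiRNA

ADAPTER_PREFIX_LEN = 8
DEFAULT_ADAPTER_PREFIX = "TGGAATTC"
DEFAULT_LENGTH_WINDOW = (18, 26)


@dataclass(frozen=True)
class SRNARead:
    """A small-RNA read and its adapter-trimmed insert."""

    read_id: str
    sequence: str
    insert: str
    trimmed: bool


def trim_adapter(read_id: str, sequence: str, adapter_prefix: str = DEFAULT_ADAPTER_PREFIX) -> SRNARead:
    """Split a read at the first occurrence of the 8-base adapter prefix.

    The insert is everything before the first occurrence; if the prefix is
    absent the whole read is kept untrimmed.
    """
    if not sequence:
        raise ValueError(f"empty read: {read_id}")
    if len(adapter_prefix) != ADAPTER_PREFIX_LEN:
        raise ValueError(
            f"adapter prefix must be {ADAPTER_PREFIX_LEN} nt, got {len(adapter_prefix)}"
        )
    prefix = rna_to_dna(adapter_prefix)
    seq = sequence.upper()
    pos = seq.find(prefix)
    if pos == -1:
        return SRNARead(read_id, seq, seq, False)
    return SRNARead(read_id, seq, seq[:pos], True)


def trim_reads(records, adapter_prefix: str = DEFAULT_ADAPTER_PREFIX) -> list[SRNARead]:
    """Trim an iterable of ``(read_id, sequence)`` pairs or SeqRecords."""
    out = []
    for rec in records:
        if hasattr(rec, "id"):
            out.append(trim_adapter(rec.id, str(rec.seq), adapter_prefix))
        else:
            read_id, seq = rec
            out.append(trim_adapter(read_id, seq, adapter_prefix))
    return out


def read_fastq(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def fastq_to_fasta(fastq_path, fasta_path) -> int:
    """Convert FASTQ to FASTA, discarding qualities. Returns record count."""
    return SeqIO.convert(str(fastq_path), "fastq", str(fasta_path), "fasta")


def quantify(
    reads: list[SRNARead],
    mirnas: list[MatureMiRNA],
    sample: str,
    length_window: tuple[int, int] = DEFAULT_LENGTH_WINDOW,
    multimap: str = "all",
) -> pd.Series:
    """Count exact-substring matches of read inserts against mature miRNAs.

    An insert is counted for miRNA m iff it is an exact substring of m's
    sequence (0 mismatches, 0 gaps) and ``min <= len(insert) <= max``.

    Parameters
    ----------
    multimap
        ``"all"`` (default): an insert matching k miRNAs adds 1 to each;
        ``"fractional"``: adds 1/k to each.

    Returns
    -------
    A float/int Series indexed by miRNA name, named after the sample.
    """
    if not mirnas:
        raise ValueError("empty miRNA set")
    if multimap not in ("all", "fractional"):
        raise ValueError(f"unknown multimap policy: {multimap}")
    lo, hi = length_window
    mature = [(m.name, rna_to_dna(m.sequence)) for m in mirnas]
    counts = {name: 0.0 for name, _ in mature}
    # collapse duplicate inserts: libraries are highly redundant
    insert_counts = Counter(
        r.insert for r in reads if lo <= len(r.insert) <= hi
    )
    for insert, n in insert_counts.items():
        matches = [name for name, seq in mature if insert in seq]
        if not matches:
            continue
        w = n / len(matches) if multimap == "fractional" else n
        for name in matches:
            counts[name] += w
    series = pd.Series(counts, name=sample)
    if multimap == "all":
        series = series.astype(int)
    return series


def count_matrix(columns: list[pd.Series]) -> pd.DataFrame:
    """Assemble per-sample count columns into a miRNA x sample matrix."""
    if not columns:
        raise ValueError("no sample columns")
    mat = pd.concat(columns, axis=1).fillna(0)
    mat.index.name = "mirna_id"
    return mat
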