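"""Nucleotide-string helpers shared across modules.

All scanning is done in DNA space: RNA inputs (mature miRNAs, seeds) are
normalised U->T before any comparison, so U/T-mixed inputs behave
identically.
"""

from __future__ import annotations

_DNA_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

DNA_ALPHABET = frozenset("ACGT")
RNA_ALPHABET = frozenset("ACGU")


def rna_to_dna(seq: str) -> str:
    """Normalise an RNA or mixed-alphabet string to uppercase DNA."""
    return seq.upper().replace("U", "T")


def dna_to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def revcomp_dna(seq: str) -> str:
    """Reverse complement of a DNA string (input normalised U->T first)."""
    return rna_to_dna(seq).translate(_DNA_COMPLEMENT)[::-1]


def is_nucleotide(seq: str, alphabet: frozenset[str] = DNA_ALPHABET) -> bool:
    return all(c in alphabet for c in seq.upper())


def find_all(haystack: str, needle: str) -> list[int]:
    """All start positions of ``needle`` in ``haystack``, overlaps included."""
    if not needle:
        raise ValueError("empty search pattern")
    hits = []
    i = haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits
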