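"""Readers and writers for the pipeline's plain-text interchange formats.

FASTA parsing goes through Biopython.  The tabular dialects follow the
conventions of seed-based target scanners:

* miRNA seed TSV -- three columns: miRNA name, 7-nt seed (nucleotides
  2-8), NCBI taxon id (7227 for Drosophila melanogaster).
* 3'UTR TSV -- three columns: identifier (``gene|transcript|name`` or a
  bare gene id), taxon id, UTR sequence.
* DE label TSV -- two columns: entity id, direction (``up``/``down``).
"""

from __future__ import annotations

import pandas as pd
from Bio import SeqIO

from mirmatch.targets import DROSOPHILA_TAXON, MatureMiRNA, UTRRecord


def read_mirna_fasta(path) -> list[MatureMiRNA]:
    """Mature miRNAs from FASTA with miRBase-dialect headers.

    The record name is the first whitespace-separated header token
    (miRBase headers carry accession and species after the name).
    """
    return [
        MatureMiRNA(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def read_utr_fasta(path) -> list[UTRRecord]:
    """Representative 3'UTRs from FASTA.

    Headers may be ``gene``, ``gene|transcript`` or
    ``gene|transcript|taxon``; missing fields default to ``<gene>.t1``
    and taxon 7227.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        gene = parts[0]
        tx = parts[1] if len(parts) > 1 else f"{gene}.t1"
        taxon = int(parts[2]) if len(parts) > 2 else DROSOPHILA_TAXON
        records.append(UTRRecord(gene, tx, str(rec.seq).upper(), taxon))
    return records


def read_utr_tsv(path) -> list[UTRRecord]:
    """3'UTRs from a three-column TSV (identifier, taxon, sequence)."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["identifier", "taxon_id", "sequence"], dtype=str)
    records = []
    for ident, taxon, seq in df.itertuples(index=False):
        parts = str(ident).split("|")
        gene = parts[0]
        tx = parts[1] if len(parts) > 1 else f"{gene}.t1"
        records.append(UTRRecord(gene, tx, str(seq).upper(), int(taxon)))
    return records


def write_utr_tsv(utrs: list[UTRRecord], path) -> None:
    with open(path, "w") as fh:
        for u in utrs:
            fh.write(f"{u.gene_id}|{u.transcript_id}\t{u.taxon_id}\t{u.sequence}\n")


def write_mirna_seed_tsv(mirnas: list[MatureMiRNA], path,
                         taxon_id: int = DROSOPHILA_TAXON) -> None:
    """Three-column miRNA file: name, seed (nt 2-8), taxon id."""
    with open(path, "w") as fh:
        for m in mirnas:
            fh.write(f"{m.name}\t{m.seed}\t{taxon_id}\n")


def read_mirna_seed_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None,
                       names=["mirna_id", "seed", "taxon_id"])


def read_de_labels(path, id_column: str) -> pd.DataFrame:
    """DE labels: TSV with header ``(<id_column>, direction)``."""
    df = pd.read_csv(path, sep="\t")
    missing = {id_column, "direction"} - set(df.columns)
    if missing:
        raise ValueError(f"DE label table missing columns: {sorted(missing)}")
    bad = set(df["direction"]) - {"up", "down"}
    if bad:
        raise ValueError(f"unknown DE directions: {sorted(bad)}")
    return df[[id_column, "direction"]]


def read_tpm_tsv(path) -> pd.DataFrame:
    """Tidy TPM table ``(gene_id, condition, replicate, tpm)``."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "condition", "replicate", "tpm"} - set(df.columns)
    if missing:
        raise ValueError(f"TPM table missing columns: {sorted(missing)}")
    return df
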