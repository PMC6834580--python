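"""Seed-based miRNA target prediction on representative 3'UTRs.

The canonical determinant of animal miRNA targeting is Watson-Crick
complementarity between the miRNA *seed* (nucleotides 2-8 counted from the
5' end of the mature strand) and the target 3'UTR.  A gene is a predicted
target of a miRNA when its representative 3'UTR (the longest annotated
isoform UTR, ties broken at random) contains at least one exact reverse
complement of the seed.

Site classes follow the standard nomenclature:

* ``7mer-m8`` -- the UTR pairs seed positions 2-8.
* ``8mer``    -- a 7mer-m8 match additionally followed (3' on the UTR,
  target position t1) by an adenosine.
* ``7mer-1A`` -- the UTR pairs seed positions 2-7 and carries a t1
  adenosine.  Off by default: the primary criterion here is full seed
  (2-8) complementarity; the richer class is exposed as an option.

Coordinates are 0-based half-open on the UTR sense strand.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mirmatch.seq import find_all, revcomp_dna, rna_to_dna

SEED_LENGTH = 7
DROSOPHILA_TAXON = 7227


def extract_seed(sequence: str) -> str:
    """Return the 7-nt seed: nucleotides 2-8 (1-based) from the 5' end.

    Parameters
    ----------
    sequence
        Mature miRNA sequence, 5'->3', RNA or DNA alphabet; must be at
        least 8 nt so positions 2-8 exist.
    """
    if len(sequence) < 8:
        raise ValueError(
            f"mature sequence must be >= 8 nt to have a 2-8 seed, got {len(sequence)}"
        )
    return sequence[1:8]


@dataclass(frozen=True)
class MatureMiRNA:
    """A named mature miRNA strand (5'->3') with its derived seed."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 8:
            raise ValueError(f"{self.name}: mature sequence shorter than 8 nt")

    @property
    def seed(self) -> str:
        return extract_seed(self.sequence)


@dataclass(frozen=True)
class UTRRecord:
    """A gene's representative 3'UTR with transcript provenance."""

    gene_id: str
    transcript_id: str
    sequence: str
    taxon_id: int = DROSOPHILA_TAXON

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TargetSiteHit:
    """One seed-complementary site in a UTR (0-based half-open coords)."""

    mirna_name: str
    gene_id: str
    start: int
    end: int
    site_type: str  # {"7mer-m8", "7mer-1A", "8mer"}


@dataclass
class TargetTable:
    """Predicted miRNA -> gene -> site assignments."""

    hits: dict[str, dict[str, list[TargetSiteHit]]] = field(default_factory=dict)

    def is_target(self, mirna_name: str, gene_id: str) -> bool:
        return bool(self.hits.get(mirna_name, {}).get(gene_id))

    def targets_of(self, mirna_name: str) -> set[str]:
        return set(self.hits.get(mirna_name, {}))

    def mirnas(self) -> list[str]:
        return list(self.hits)

    def site_counts(self) -> pd.DataFrame:
        """Long-format per-(miRNA, gene) site counts."""
        rows = [
            (m, g, len(sites))
            for m, genes in self.hits.items()
            for g, sites in genes.items()
        ]
        return pd.DataFrame(rows, columns=["mirna_name", "gene_id", "n_sites"])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table of individual sites."""
        rows = [
            (h.mirna_name, h.gene_id, h.start, h.end, h.site_type)
            for genes in self.hits.values()
            for sites in genes.values()
            for h in sites
        ]
        return pd.DataFrame(
            rows, columns=["mirna_name", "gene_id", "start", "end", "site_type"]
        )


def select_representative_utr(
    candidates,
    rng: np.random.Generator | None = None,
    taxon_id: int = DROSOPHILA_TAXON,
) -> list[UTRRecord]:
    """Pick one representative 3'UTR per gene: the longest annotated one.

    Ties on maximum length are broken by a seeded uniform random choice;
    genes whose transcripts all lack an annotated (nonempty) UTR are
    dropped.

    Parameters
    ----------
    candidates
        Iterable of ``(gene_id, transcript_id, utr_sequence)`` tuples;
        ``utr_sequence`` may be empty/None for unannotated isoforms.
    rng
        Source of randomness for the tie-break (defaults to a fresh
        generator; pass the pipeline RNG for reproducibility).
    """
    if rng is None:
        rng = np.random.default_rng()
    by_gene: dict[str, list[tuple[str, str]]] = {}
    for gene_id, transcript_id, utr in candidates:
        if utr:
            by_gene.setdefault(gene_id, []).append((transcript_id, utr))
    records = []
    for gene_id, isoforms in by_gene.items():
        max_len = max(len(u) for _, u in isoforms)
        longest = [(t, u) for t, u in isoforms if len(u) == max_len]
        tx, utr = longest[rng.integers(len(longest))] if len(longest) > 1 else longest[0]
        records.append(UTRRecord(gene_id, tx, utr, taxon_id))
    return records


def find_sites(
    seed: str,
    utr: UTRRecord,
    mirna_name: str = "",
    include_7mer_1a: bool = False,
) -> list[TargetSiteHit]:
    """Scan a UTR for exact reverse complements of a 7-nt seed.

    Every occurrence is reported, overlaps allowed.  A match of seed
    positions 2-8 is a 7mer-m8, upgraded to 8mer when the UTR base
    immediately 3' of the match (position t1) is 'A'.  With
    ``include_7mer_1a`` the 6-nt (positions 2-7) match plus t1-A is also
    reported where it is not already part of a 7/8mer hit.
    """
    if len(seed) != SEED_LENGTH:
        raise ValueError(f"seed must be {SEED_LENGTH} nt, got {len(seed)}")
    utr_dna = rna_to_dna(utr.sequence)
    if len(utr_dna) < SEED_LENGTH:
        return []
    site7 = revcomp_dna(seed)  # complement of seed nt 2-8
    hits = []
    starts7 = find_all(utr_dna, site7)
    for i in starts7:
        if i + 7 < len(utr_dna) and utr_dna[i + 7] == "A":
            hits.append(TargetSiteHit(mirna_name, utr.gene_id, i, i + 8, "8mer"))
        else:
            hits.append(TargetSiteHit(mirna_name, utr.gene_id, i, i + 7, "7mer-m8"))
    if include_7mer_1a:
        # seed nt 2-7 are the first six characters of the 7-nt seed string
        site_1a = revcomp_dna(seed[:6]) + "A"
        taken = set(starts7)
        for i in find_all(utr_dna, site_1a):
            # a 7mer-1A whose hexamer extends to a full 2-8 match at i-1 is
            # already reported as 7mer-m8/8mer
            if (i - 1) not in taken:
                hits.append(
                    TargetSiteHit(mirna_name, utr.gene_id, i, i + 7, "7mer-1A")
                )
        hits.sort(key=lambda h: (h.start, h.end))
    return hits


def predict_targets(
    mirnas: list[MatureMiRNA],
    utrs: list[UTRRecord],
    include_7mer_1a: bool = False,
) -> TargetTable:
    """Predict targets for every (miRNA, gene) pair by seed complementarity.

    ``is_target(m, g)`` is true iff gene g's representative UTR carries at
    least one site of an enabled class for miRNA m.
    """
    if not mirnas:
        raise ValueError("empty miRNA list")
    if not utrs:
        raise ValueError("empty UTR list")
    gene_ids = [u.gene_id for u in utrs]
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("duplicate gene ids in UTR set; select representatives first")
    table = TargetTable()
    for m in mirnas:
        gene_hits: dict[str, list[TargetSiteHit]] = {}
        for u in utrs:
            sites = find_sites(m.seed, u, m.name, include_7mer_1a)
            if sites:
                gene_hits[u.gene_id] = sites
        table.hits[m.name] = gene_hits
    return table


def export_network(
    target_table: TargetTable,
    de_mirnas: pd.DataFrame,
    de_genes: pd.DataFrame,
    known_genes: set[str] | None = None,
) -> pd.DataFrame:
    """Edge list of predicted interactions among differentially expressed
    miRNAs and genes.

    One edge per (DE miRNA, DE predicted target gene), annotated with both
    direction labels and an ``opposite_direction`` flag (true when the
    miRNA and its target moved in opposite directions, the pattern expected
    under miRNA-mediated repression).

    Parameters
    ----------
    de_mirnas, de_genes
        Data frames with columns ``(mirna_id | gene_id, direction)`` where
        direction is ``up`` or ``down``.
    known_genes
        Optional gene universe (e.g. the representative-UTR gene set); DE
        gene ids outside it raise ``KeyError``.
    """
    for df, col in ((de_mirnas, "mirna_id"), (de_genes, "gene_id")):
        if not df.empty and (
            col not in df.columns or "direction" not in df.columns
        ):
            raise ValueError(f"DE table must have columns ({col}, direction)")
    gene_dir = (
        dict(zip(de_genes["gene_id"], de_genes["direction"]))
        if not de_genes.empty
        else {}
    )
    if known_genes is not None:
        unknown = set(gene_dir) - set(known_genes)
        if unknown:
            raise KeyError(f"unknown gene ids in DE table: {sorted(unknown)[:5]}")
    rows = []
    if not de_mirnas.empty:
        for mirna, mdir in zip(de_mirnas["mirna_id"], de_mirnas["direction"]):
            for gene in sorted(target_table.targets_of(mirna)):
                if gene in gene_dir:
                    gdir = gene_dir[gene]
                    rows.append((mirna, mdir, gene, gdir, mdir != gdir))
    return pd.DataFrame(
        rows,
        columns=["mirna_id", "mirna_direction", "gene_id", "gene_direction",
                 "opposite_direction"],
    )


def write_sif(edges: pd.DataFrame, path) -> None:
    """Write the edge list in simple-interaction format (`mirna targets gene`)."""
    with open(path, "w") as fh:
        for _, row in edges.iterrows():
            fh.write(f"{row.mirna_id}\ttargets\t{row.gene_id}\n")


def pairwise_intersections(
    target_table: TargetTable, mirna_names: list[str]
) -> dict[tuple[str, str], set[str]]:
    """Shared predicted-target sets for every unordered miRNA pair."""
    out = {}
    for a, b in itertools.combinations(mirna_names, 2):
        out[(a, b)] = target_table.targets_of(a) & target_table.targets_of(b)
    return out
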