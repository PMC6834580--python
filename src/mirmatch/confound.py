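"""Diagnosis of 3'UTR-length confounding of predicted target status.

In random (or real) sequence, the expected number of chance matches of a
7-nt seed complement in a UTR of length L is ``(L - 6) * 4^-7``; site
counts therefore grow with UTR length, and any comparison of predicted
targets against non-targets inherits a length bias.  This module
reproduces the exploratory demonstration of that confound: target
prediction with randomly generated seed sequences (default 401 seeds of
length 7, the size of the real miRNA seed set in the fly annotation),
per-gene site counts, a rank-correlation summary (Spearman; the original
demonstration was visual, via cumulative plots, which are exported here
as ECDF tables), and ECDFs stratified by fold-change class.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from mirmatch.seq import revcomp_dna, rna_to_dna
from mirmatch.targets import SEED_LENGTH, TargetTable, UTRRecord

DEFAULT_N_SEEDS = 401

RNA_BASES = np.array(list("ACGU"))


def random_seeds(
    n: int, length: int = SEED_LENGTH, rng: np.random.Generator | None = None
) -> list[str]:
    """``n`` i.i.d. uniform random RNA seed strings of the given length."""
    if n <= 0:
        raise ValueError("n must be > 0")
    if length < 1:
        raise ValueError("length must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    draws = rng.integers(0, 4, size=(n, length))
    return ["".join(RNA_BASES[row]) for row in draws]


def chance_site_counts(utrs: list[UTRRecord], seeds: list[str]) -> np.ndarray:
    """Total seed-complementary site count per UTR, summed over seeds.

    Counts every (possibly overlapping) occurrence of each seed's reverse
    complement, equivalently to scanning each seed with the site finder
    but computed via a per-UTR k-mer table (one pass per UTR instead of
    one per seed) so the 401-seed diagnosis stays fast.
    """
    sites = [revcomp_dna(rna_to_dna(s)) for s in seeds]
    k = len(sites[0])
    if any(len(s) != k for s in sites):
        raise ValueError("seeds must share one length")
    counts = np.zeros(len(utrs), dtype=np.int64)
    site_set = set(sites)
    site_multiplicity = Counter(sites)  # duplicated random seeds count twice
    for i, u in enumerate(utrs):
        seq = rna_to_dna(u.sequence)
        kmers = Counter(seq[j:j + k] for j in range(len(seq) - k + 1))
        counts[i] = sum(
            kmers[s] * m for s, m in site_multiplicity.items() if s in kmers
        ) if site_set else 0
    return counts


@dataclass
class ConfoundReport:
    """Length-vs-site-count association over a gene set."""

    per_gene: pd.DataFrame  # gene_id, utr_length, site_count, fc_class
    spearman_rho: float
    spearman_p: float
    degenerate: bool  # constant lengths or site counts: rho undefined
    ecdf: pd.DataFrame  # fc_class, variable {utr_length|site_count}, value, ecdf


def _ecdf_frame(per_gene: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for fc_class, grp in per_gene.groupby("fc_class"):
        for variable in ("utr_length", "site_count"):
            vals = np.sort(grp[variable].to_numpy())
            ec = np.arange(1, vals.size + 1) / vals.size
            rows.append(
                pd.DataFrame(
                    {"fc_class": fc_class, "variable": variable,
                     "value": vals, "ecdf": ec}
                )
            )
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["fc_class", "variable", "value", "ecdf"]
    )


def site_length_association(
    target_table: TargetTable,
    utrs: list[UTRRecord],
    fc_classes: dict[str, str] | None = None,
) -> ConfoundReport:
    """Correlate per-gene total site count with 3'UTR length.

    Parameters
    ----------
    target_table
        Predictions from any seed set (typically random seeds for the
        null diagnosis); per-gene counts are summed over all seeds.
    fc_classes
        Optional gene_id -> {"up", "down", "not-DE"} labels for the
        stratified cumulative curves; unlabelled genes are "not-DE".

    Raises
    ------
    ValueError
        If the target table is empty, a target gene lacks a UTR record,
        or fewer than two genes are available (correlation undefined).
    """
    if not target_table.hits or not any(target_table.hits.values()):
        raise ValueError("empty target table")
    utr_genes = {u.gene_id for u in utrs}
    target_genes = {g for genes in target_table.hits.values() for g in genes}
    missing = target_genes - utr_genes
    if missing:
        raise ValueError(f"target genes without UTR records: {sorted(missing)[:5]}")
    if len(utrs) < 2:
        raise ValueError("need >= 2 genes for a correlation")
    counts: dict[str, int] = {u.gene_id: 0 for u in utrs}
    for genes in target_table.hits.values():
        for g, sites in genes.items():
            counts[g] += len(sites)
    fc_classes = fc_classes or {}
    per_gene = pd.DataFrame(
        {
            "gene_id": [u.gene_id for u in utrs],
            "utr_length": [u.length for u in utrs],
            "site_count": [counts[u.gene_id] for u in utrs],
            "fc_class": [fc_classes.get(u.gene_id, "not-DE") for u in utrs],
        }
    )
    return _report_from_per_gene(per_gene)


def length_association_from_counts(
    gene_ids, lengths, site_counts, fc_classes: dict[str, str] | None = None
) -> ConfoundReport:
    """As :func:`site_length_association` but from precomputed counts
    (e.g. :func:`chance_site_counts` for the 401-random-seed diagnosis)."""
    if len(gene_ids) < 2:
        raise ValueError("need >= 2 genes for a correlation")
    fc_classes = fc_classes or {}
    per_gene = pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "utr_length": np.asarray(lengths),
            "site_count": np.asarray(site_counts),
            "fc_class": [fc_classes.get(g, "not-DE") for g in gene_ids],
        }
    )
    return _report_from_per_gene(per_gene)


def _report_from_per_gene(per_gene: pd.DataFrame) -> ConfoundReport:
    lengths = per_gene["utr_length"].to_numpy()
    counts = per_gene["site_count"].to_numpy()
    degenerate = (np.unique(lengths).size < 2) or (np.unique(counts).size < 2)
    if degenerate:
        rho, p = float("nan"), float("nan")
    else:
        rho, p = stats.spearmanr(lengths, counts)
        rho, p = float(rho), float(p)
    return ConfoundReport(per_gene, rho, p, degenerate, _ecdf_frame(per_gene))
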