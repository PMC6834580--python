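"""Synthetic inputs with known ground truth.

Generates everything the pipeline consumes: mature miRNA sets with paired
-5p/-3p strands, heterogeneous-length 3'UTRs, seed-site implantation for
designated miRNAs, two-replicate virgin/mated TPM tables with a
configurable repression effect on true targets, and adapter-ligated
small-RNA reads.

The generator emulates the statistical structure that matters to the
analysis rather than the biology of any particular dataset:

* 3'UTR lengths are heavy-tailed (log-normal, median 500 nt, sigma_log
  1.0, truncated at 30 nt), so longer UTRs accumulate more chance seed
  matches -- the length confound the diagnosis module must detect.
* Background sequence is i.i.d. uniform over {A,C,G,T}; chance seed
  matches are expected and deliberately not suppressed.
* Implanted sites overwrite 7 nt in place (never overlapping a previous
  implant), preserving UTR length so length-matching is exercised
  honestly.
* Baseline TPM is log-normal; the condition effect for true targets of
  up-regulated miRNAs is applied on the log2 scale (shift of
  ``-repression_delta``) before multiplicative log-normal replicate noise
  with coefficient of variation ``replicate_cv``.

All randomness flows from ``SimConfig.rng_seed``: identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from mirmatch.seq import revcomp_dna
from mirmatch.targets import MatureMiRNA, UTRRecord, extract_seed

RNA_BASES = np.array(list("ACGU"))
DNA_BASES = np.array(list("ACGT"))

# Illumina TruSeq small-RNA 3' adapter; its first 8 bases are the
# recognition prefix used downstream for trimming.
TRUSEQ_SRNA_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

CONDITION_A = "virgin"
CONDITION_B = "mated"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated study.

    Attributes
    ----------
    n_genes, n_mirnas
        Number of genes (one representative 3'UTR each) and mature miRNA
        strands.
    utr_log_median, utr_log_sigma, utr_min_len
        Log-normal 3'UTR length law: median (nt), sigma of log lengths,
        lower truncation (resampling) bound.
    target_fraction
        Fraction of genes given >=1 implanted seed site per designated
        miRNA.
    repression_delta
        Log2-fold-change shift (>= 0) applied in the mated condition to
        true targets of up-regulated miRNAs.
    replicate_cv
        Coefficient of variation of the multiplicative log-normal
        replicate noise on TPM.
    adapter
        3' sequencing adapter appended to small-RNA inserts.
    read_length
        Sequencer read length (nt); reads are padded/truncated to it.
    insert_length_choices
        Mature miRNA length distribution (mode at 22-23 nt, as observed in
        insect small-RNA libraries).
    rng_seed
        Master seed; every generated artefact derives from it.
    """

    n_genes: int = 2000
    n_mirnas: int = 4
    utr_log_median: float = 500.0
    utr_log_sigma: float = 1.0
    utr_min_len: int = 30
    target_fraction: float = 0.3
    repression_delta: float = 1.0
    replicate_cv: float = 0.2
    adapter: str = TRUSEQ_SRNA_ADAPTER
    read_length: int = 50
    insert_length_choices: tuple[int, ...] = (21, 22, 22, 23, 23)
    base_log2_tpm_mean: float = 5.0
    base_log2_tpm_sd: float = 2.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_mirnas <= 0:
            raise ValueError("n_genes and n_mirnas must be positive")
        if not 0.0 <= self.target_fraction <= 1.0:
            raise ValueError("target_fraction must be in [0, 1]")
        if self.repression_delta < 0:
            raise ValueError("repression_delta must be >= 0")
        if self.replicate_cv < 0:
            raise ValueError("replicate_cv must be >= 0")
        if self.utr_min_len < 7:
            raise ValueError("utr_min_len must allow a 7-nt seed match")
        if self.utr_log_median <= 0 or self.utr_log_sigma < 0:
            raise ValueError("invalid UTR length law")
        if not self.adapter or len(self.adapter) < 8:
            raise ValueError("adapter must be at least 8 nt")

    def rng(self, *stream: int) -> np.random.Generator:
        """Independent child generator for a named stream of this config."""
        return np.random.default_rng([self.rng_seed, *stream])


@dataclass
class TruthTable:
    """Ground-truth target assignments and miRNA direction labels."""

    targets: dict[str, set[str]] = field(default_factory=dict)
    directions: dict[str, str] = field(default_factory=dict)  # up | down | none

    def true_targets(self, mirna_name: str) -> set[str]:
        return self.targets.get(mirna_name, set())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (m, g, self.directions.get(m, "none"))
            for m, genes in self.targets.items()
            for g in sorted(genes)
        ]
        return pd.DataFrame(rows, columns=["mirna_id", "gene_id", "direction"])


def _random_seq(rng: np.random.Generator, length: int, bases: np.ndarray) -> str:
    return "".join(bases[rng.integers(0, 4, size=length)])


def generate_mirnas(cfg: SimConfig) -> list[MatureMiRNA]:
    """Generate ``n_mirnas`` mature strands, paired as -5p/-3p where n permits.

    Sequences are 21-23 nt uniform RNA; names follow the miRBase style
    ``sim-mir-<k>-5p/-3p``.
    """
    rng = cfg.rng(1)
    out = []
    for i in range(cfg.n_mirnas):
        hairpin, arm = divmod(i, 2)
        name = f"sim-mir-{hairpin + 1}-{'5p' if arm == 0 else '3p'}"
        length = int(rng.choice(cfg.insert_length_choices))
        out.append(MatureMiRNA(name, _random_seq(rng, length, RNA_BASES)))
    return out


def sample_utr_lengths(cfg: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    """Truncated log-normal lengths (resample below ``utr_min_len``)."""
    mu = math.log(cfg.utr_log_median)
    lengths = np.empty(n, dtype=np.int64)
    need = np.ones(n, dtype=bool)
    while need.any():
        draw = rng.lognormal(mu, cfg.utr_log_sigma, size=int(need.sum()))
        lengths[need] = np.rint(draw).astype(np.int64)
        need = lengths < cfg.utr_min_len
    return lengths


def generate_utrs(cfg: SimConfig) -> list[UTRRecord]:
    """Generate ``n_genes`` representative 3'UTRs with unique ids."""
    rng = cfg.rng(2)
    lengths = sample_utr_lengths(cfg, rng, cfg.n_genes)
    width = len(str(cfg.n_genes))
    records = []
    for i, length in enumerate(lengths):
        gene = f"gene{i:0{width}d}"
        records.append(
            UTRRecord(gene, f"{gene}.t1", _random_seq(rng, int(length), DNA_BASES))
        )
    return records


def implant_sites(
    utrs: list[UTRRecord],
    mirnas: list[MatureMiRNA],
    cfg: SimConfig,
    designated: dict[str, str] | None = None,
) -> tuple[list[UTRRecord], TruthTable]:
    """Implant exact seed-complementary sites for designated miRNAs.

    For each designated miRNA a ``target_fraction`` subset of genes
    receives one reverse-complement seed site spliced into its UTR,
    overwriting 7 nt in place (length unchanged) at a position not
    overlapping any previous implant in that UTR.

    Parameters
    ----------
    designated
        Mapping miRNA name -> direction label (``up``/``down``); defaults
        to all miRNAs labelled ``up``.

    Returns
    -------
    (new UTR list, TruthTable of implants)
    """
    if designated is None:
        designated = {m.name: "up" for m in mirnas}
    by_name = {m.name: m for m in mirnas}
    unknown = set(designated) - set(by_name)
    if unknown:
        raise ValueError(f"designated miRNAs not in miRNA set: {sorted(unknown)}")
    rng = cfg.rng(3)
    seqs = {u.gene_id: u.sequence for u in utrs}
    occupied: dict[str, list[tuple[int, int]]] = {g: [] for g in seqs}
    truth = TruthTable(directions=dict(designated))
    n_targets = int(round(cfg.target_fraction * len(utrs)))
    gene_ids = [u.gene_id for u in utrs]
    for name in designated:
        site = revcomp_dna(extract_seed(by_name[name].sequence))
        chosen = rng.choice(len(gene_ids), size=n_targets, replace=False)
        implanted: set[str] = set()
        for gi in chosen:
            gene = gene_ids[gi]
            seq = seqs[gene]
            if len(seq) < 7:
                raise ValueError(f"UTR of {gene} shorter than 7 nt")
            pos = _free_position(rng, len(seq), occupied[gene])
            if pos is None:
                continue  # UTR saturated with implants; skip
            seqs[gene] = seq[:pos] + site + seq[pos + 7:]
            occupied[gene].append((pos, pos + 7))
            implanted.add(gene)
        truth.targets[name] = implanted
    new_utrs = [replace(u, sequence=seqs[u.gene_id]) for u in utrs]
    return new_utrs, truth


def _free_position(
    rng: np.random.Generator, utr_len: int, occupied: list[tuple[int, int]],
    max_tries: int = 100,
) -> int | None:
    for _ in range(max_tries):
        pos = int(rng.integers(0, utr_len - 7 + 1))
        if all(pos + 7 <= s or pos >= e for s, e in occupied):
            return pos
    return None


def generate_expression(
    truth: TruthTable,
    gene_ids: list[str],
    cfg: SimConfig,
) -> pd.DataFrame:
    """Two-condition, two-replicate TPM table with repression ground truth.

    Baseline log2 abundance is normal (log-normal TPM).  In the mated
    condition, true targets of up-regulated miRNAs are shifted by
    ``-repression_delta`` log2 units and targets of down-regulated miRNAs
    by ``+repression_delta`` (de-repression), before per-replicate
    multiplicative log-normal noise with CV ``replicate_cv``.

    Returns a tidy frame ``(gene_id, condition, replicate, tpm)``.
    """
    unknown = {
        g for genes in truth.targets.values() for g in genes
    } - set(gene_ids)
    if unknown:
        raise ValueError(f"truth table genes absent from gene set: {sorted(unknown)[:5]}")
    rng = cfg.rng(4)
    n = len(gene_ids)
    index = {g: i for i, g in enumerate(gene_ids)}
    base_log2 = rng.normal(cfg.base_log2_tpm_mean, cfg.base_log2_tpm_sd, size=n)
    shift = np.zeros(n)
    for mirna, genes in truth.targets.items():
        direction = truth.directions.get(mirna, "none")
        if direction == "none":
            continue
        sign = -1.0 if direction == "up" else 1.0
        for g in genes:
            shift[index[g]] += sign * cfg.repression_delta
    # log-normal noise factor with E[factor]=1 and CV = replicate_cv
    if cfg.replicate_cv > 0:
        sigma = math.sqrt(math.log1p(cfg.replicate_cv**2))
        noise = lambda: np.exp(rng.normal(-sigma**2 / 2, sigma, size=n))  # noqa: E731
    else:
        noise = lambda: np.ones(n)  # noqa: E731
    rows = []
    for condition, cond_shift in ((CONDITION_A, 0.0), (CONDITION_B, 1.0)):
        mean_tpm = np.exp2(base_log2 + cond_shift * shift)
        for rep in (1, 2):
            tpm = mean_tpm * noise()
            rows.append(
                pd.DataFrame(
                    {"gene_id": gene_ids, "condition": condition,
                     "replicate": rep, "tpm": tpm}
                )
            )
    return pd.concat(rows, ignore_index=True)


def generate_srna_reads(
    mirnas: list[MatureMiRNA],
    abundances: dict[str, int],
    cfg: SimConfig,
) -> list[tuple[str, str]]:
    """Adapter-ligated small-RNA reads as ``(read_id, sequence)`` pairs.

    Each read is the mature miRNA (DNA alphabet) with the 3' adapter
    appended, padded with 'A' / truncated to the sequencer read length.
    Counts per miRNA equal the requested abundances exactly.
    """
    by_name = {m.name: m for m in mirnas}
    unknown = set(abundances) - set(by_name)
    if unknown:
        raise ValueError(f"abundances for unknown miRNAs: {sorted(unknown)}")
    reads = []
    k = 0
    for name in abundances:
        if abundances[name] < 0:
            raise ValueError("abundances must be nonnegative")
        insert = by_name[name].sequence.upper().replace("U", "T")
        for _ in range(int(abundances[name])):
            raw = insert + cfg.adapter
            seq = (raw + "A" * cfg.read_length)[: cfg.read_length]
            reads.append((f"read{k}", seq))
            k += 1
    return reads


# ---------------------------------------------------------------------------
# Dataset bundle and writers


@dataclass
class SimulatedDataset:
    config: SimConfig
    mirnas: list[MatureMiRNA]
    utrs: list[UTRRecord]
    truth: TruthTable
    expression: pd.DataFrame
    reads: list[tuple[str, str]]
    mirna_abundances: dict[str, int]


def simulate(
    cfg: SimConfig, designated: dict[str, str] | None = None
) -> SimulatedDataset:
    """Full simulation: miRNAs, UTRs with implants, expression, sRNA reads.

    By default the first miRNA strand is the designated up-regulated
    (mated-induced) miRNA whose true targets are repressed.
    """
    mirnas = generate_mirnas(cfg)
    if designated is None:
        designated = {mirnas[0].name: "up"}
    utrs = generate_utrs(cfg)
    utrs, truth = implant_sites(utrs, mirnas, cfg, designated)
    expression = generate_expression(truth, [u.gene_id for u in utrs], cfg)
    rng = cfg.rng(5)
    abundances = {m.name: int(rng.integers(50, 200)) for m in mirnas}
    reads = generate_srna_reads(mirnas, abundances, cfg)
    return SimulatedDataset(cfg, mirnas, utrs, truth, expression, reads, abundances)


def write_dataset(ds: SimulatedDataset, outdir) -> dict[str, str]:
    """Write every artefact of a simulated dataset as plain-text files.

    FASTA for miRNAs/UTRs (miRBase-style ``>name`` headers), FASTQ
    (Phred+33, constant quality 'I') for reads, TSV for truth and
    expression.  Returns the mapping of artefact name to path.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mirnas": outdir / "mature_mirnas.fa",
        "utrs": outdir / "utrs.fa",
        "reads": outdir / "srna_reads.fastq",
        "truth": outdir / "truth.tsv",
        "expression": outdir / "expression.tsv",
    }
    with open(paths["mirnas"], "w") as fh:
        for m in ds.mirnas:
            fh.write(f">{m.name}\n{m.sequence}\n")
    with open(paths["utrs"], "w") as fh:
        for u in ds.utrs:
            fh.write(f">{u.gene_id}|{u.transcript_id}|{u.taxon_id}\n{u.sequence}\n")
    with open(paths["reads"], "w") as fh:
        for read_id, seq in ds.reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
    ds.truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    ds.expression.to_csv(paths["expression"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# Lightweight statistical simulation (no sequences)


def simulate_statistical(
    cfg: SimConfig, designated_direction: str = "up"
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Sequence-free simulation of one miRNA's target structure.

    Draws UTR lengths from the configured law.  Genes become *predicted*
    targets either by implantation (a ``target_fraction`` subset,
    independent of length) or by chance seed matches, whose per-gene
    probability ``1 - (1 - 4^-7)^(L-6)`` increases with UTR length
    exactly as for a random 7-mer in i.i.d. uniform sequence.  The
    repression effect applies to implanted (true) targets only, so chance
    matches dilute the signal just as in the sequence-level pipeline.
    Used for large Monte-Carlo studies of the matched tests where
    per-base sequence realism adds nothing.

    Returns ``(lengths, predicted-target boolean mask, tidy expression
    frame)`` aligned on gene order.
    """
    rng = cfg.rng(2)
    lengths = sample_utr_lengths(cfg, rng, cfg.n_genes)
    # zero-padded ids sort identically to gene order, so downstream tables
    # that sort by gene_id stay aligned with the returned arrays
    width = len(str(cfg.n_genes))
    gene_ids = [f"gene{i:0{width}d}" for i in range(cfg.n_genes)]
    rng_t = cfg.rng(3)
    n_implant = int(round(cfg.target_fraction * cfg.n_genes))
    implanted = np.zeros(cfg.n_genes, dtype=bool)
    if n_implant:
        implanted[rng_t.choice(cfg.n_genes, size=n_implant, replace=False)] = True
    p_chance = 1.0 - (1.0 - 0.25**7) ** np.maximum(lengths - 6, 0)
    is_target = implanted | (rng_t.random(cfg.n_genes) < p_chance)
    truth = TruthTable(
        targets={"sim-mir-1-5p": {g for g, t in zip(gene_ids, implanted) if t}},
        directions={"sim-mir-1-5p": designated_direction},
    )
    expression = generate_expression(truth, gene_ids, cfg)
    return lengths, is_target, expression
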