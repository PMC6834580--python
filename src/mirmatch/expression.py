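"""Expression pre-processing: replicate means, zero filtering, log2 fold change.

Per comparison (e.g. virgin vs mated male abdomen) the per-gene TPM is
averaged over replicates within each condition, genes with zero mean
abundance are discarded, a pseudocount is added, and the log2 ratio
mated-over-virgin is taken as the magnitude of differential expression:

    log2fc = log2((mean_B + c) / (mean_A + c)),   c > 0 (default 1)

Negative log2fc means lower abundance in condition B (mated).  Zero
filtering has two scopes: ``per-comparison`` (default; a gene is dropped
only when its mean is zero in BOTH conditions, keeping the gene sets of
the two conditions identical) and ``per-condition`` (a gene is dropped
whenever either condition mean is zero).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

ZERO_FILTER_SCOPES = ("per-comparison", "per-condition")


@dataclass(frozen=True)
class PrepConfig:
    pseudocount: float = 1.0
    zero_filter_scope: str = "per-comparison"

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.zero_filter_scope not in ZERO_FILTER_SCOPES:
            raise ValueError(f"zero_filter_scope must be one of {ZERO_FILTER_SCOPES}")


def summarize_replicates(tpm: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean TPM per gene per condition.

    Parameters
    ----------
    tpm
        Tidy frame ``(gene_id, condition, replicate, tpm)``; every
        condition/replicate must cover the same gene set (rectangular).

    Returns
    -------
    Wide frame indexed by gene_id with one column per condition.
    """
    required = {"gene_id", "condition", "replicate", "tpm"}
    missing = required - set(tpm.columns)
    if missing:
        raise ValueError(f"tpm table missing columns: {sorted(missing)}")
    if (tpm["tpm"] < 0).any():
        raise ValueError("negative TPM values")
    gene_sets = tpm.groupby(["condition", "replicate"])["gene_id"].apply(set)
    first = gene_sets.iloc[0]
    if not all(s == first for s in gene_sets):
        raise ValueError("replicate tables have mismatched gene sets")
    means = tpm.pivot_table(
        index="gene_id", columns="condition", values="tpm", aggfunc="mean"
    )
    means.columns.name = None
    return means


def filter_zero(
    means: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    scope: str = "per-comparison",
) -> pd.DataFrame:
    """Drop zero-abundance genes from a two-condition mean table."""
    if scope not in ZERO_FILTER_SCOPES:
        raise ValueError(f"unknown zero_filter_scope: {scope}")
    a, b = means[condition_a], means[condition_b]
    if scope == "per-comparison":
        keep = (a > 0) | (b > 0)
    else:
        keep = (a > 0) & (b > 0)
    out = means.loc[keep, [condition_a, condition_b]]
    if out.empty:
        log.warning("all genes removed by zero filtering")
    return out


def compute_log2fc(mean_a, mean_b, pseudocount: float = 1.0):
    """Offset log2 fold change log2((B + c)/(A + c)); works on scalars/arrays."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    a = np.asarray(mean_a, dtype=float)
    b = np.asarray(mean_b, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("negative mean TPM")
    out = np.log2((b + pseudocount) / (a + pseudocount))
    return float(out) if out.ndim == 0 else out


def prepare_fold_changes(
    tpm: pd.DataFrame,
    condition_a: str = "virgin",
    condition_b: str = "mated",
    config: PrepConfig | None = None,
    comparison: str | None = None,
) -> pd.DataFrame:
    """Full prep for one comparison: means, zero filter, offset log2fc.

    Returns a frame ``(gene_id, mean_a, mean_b, log2fc)`` with comparison
    metadata in ``DataFrame.attrs`` (orientation is B-over-A, i.e.
    mated-over-virgin by convention).
    """
    config = config or PrepConfig()
    means = summarize_replicates(tpm)
    for cond in (condition_a, condition_b):
        if cond not in means.columns:
            raise ValueError(f"condition {cond!r} absent from TPM table")
    means = filter_zero(means, condition_a, condition_b, config.zero_filter_scope)
    out = pd.DataFrame(
        {
            "gene_id": means.index,
            "mean_a": means[condition_a].to_numpy(),
            "mean_b": means[condition_b].to_numpy(),
        }
    )
    out["log2fc"] = compute_log2fc(out["mean_a"], out["mean_b"], config.pseudocount)
    out.attrs["comparison"] = comparison or f"{condition_a}-vs-{condition_b}"
    out.attrs["orientation"] = f"log2(({condition_b}+c)/({condition_a}+c))"
    out.attrs["pseudocount"] = config.pseudocount
    return out
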