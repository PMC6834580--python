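"""End-to-end orchestration: simulate -> quantify -> predict -> prep -> test.

One :class:`~mirmatch.synthetic.SimConfig` seed determines every artefact;
rerunning with the same configuration reproduces all outputs byte for
byte.  Gene DE labels for the Fisher enrichment test are derived from the
prepared fold changes by a symmetric log2FC threshold (labels are inputs
in a real analysis; the synthetic pipeline needs a labelling rule and a
fixed threshold keeps it deterministic).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mirmatch import expression, matched, quant, synthetic, targets
from mirmatch.synthetic import SimConfig, SimulatedDataset

DEFAULT_DE_LOG2FC_THRESHOLD = 1.0


@dataclass
class PipelineResult:
    dataset: SimulatedDataset
    mirna_counts: pd.Series
    target_table: targets.TargetTable
    fold_changes: pd.DataFrame
    de_genes: pd.DataFrame
    results: pd.DataFrame
    network: pd.DataFrame
    recovered_fraction: float = field(default=float("nan"))


def label_de_genes(
    fold_changes: pd.DataFrame, threshold: float = DEFAULT_DE_LOG2FC_THRESHOLD
) -> pd.DataFrame:
    """Symmetric threshold labelling: |log2fc| >= threshold -> up/down."""
    fc = fold_changes["log2fc"].to_numpy()
    direction = np.where(fc >= threshold, "up", np.where(fc <= -threshold, "down", ""))
    out = pd.DataFrame({"gene_id": fold_changes["gene_id"], "direction": direction})
    return out[out["direction"] != ""].reset_index(drop=True)


def run_pipeline(
    cfg: SimConfig,
    test_cfg: matched.TestConfig | None = None,
    designated: dict[str, str] | None = None,
    de_threshold: float = DEFAULT_DE_LOG2FC_THRESHOLD,
    outdir=None,
) -> PipelineResult:
    """Run the full synthetic analysis from one seeded configuration.

    Steps: simulate inputs; trim + quantify the small-RNA reads; predict
    targets by seed complementarity on the representative UTRs; prepare
    offset log2 fold changes; run the repeated length-matched KS and
    Fisher tests per designated miRNA (plus pairwise combinations of
    same-direction miRNAs); BH-adjust mean p-values; export the DE-DE
    interaction edge list.  With ``outdir`` set, all artefacts are
    written as plain-text files.
    """
    test_cfg = test_cfg or matched.TestConfig(rng_seed=cfg.rng_seed)
    ds = synthetic.simulate(cfg, designated)
    de_mirnas = dict(ds.truth.directions)

    trimmed = quant.trim_reads(ds.reads, ds.config.adapter[:8])
    counts = quant.quantify(trimmed, ds.mirnas, "pooled")

    table = targets.predict_targets(ds.mirnas, ds.utrs)
    recovered = _recovered_fraction(ds, table)

    fc = expression.prepare_fold_changes(ds.expression)
    de_genes = label_de_genes(fc, de_threshold)

    gene_ids = list(fc["gene_id"])
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    lengths = np.zeros(len(gene_ids), dtype=np.int64)
    for u in ds.utrs:
        i = gene_index.get(u.gene_id)
        if i is not None:
            lengths[i] = u.length
    log2fc = fc["log2fc"].to_numpy()
    gene_dir = dict(zip(de_genes["gene_id"], de_genes["direction"]))

    results = []
    for mirna, direction in de_mirnas.items():
        tmask = np.zeros(len(gene_ids), dtype=bool)
        for g in table.targets_of(mirna):
            i = gene_index.get(g)
            if i is not None:
                tmask[i] = True
        opposite = "down" if direction == "up" else "up"
        opp_mask = np.array([gene_dir.get(g) == opposite for g in gene_ids])
        results.append(
            matched.run_matched_test(
                mirna, "ks", direction, tmask, lengths, log2fc=log2fc,
                cfg=test_cfg, comparison="virgin-vs-mated",
            )
        )
        results.append(
            matched.run_matched_test(
                mirna, "fisher", direction, tmask, lengths,
                opposite_de_mask=opp_mask, cfg=test_cfg,
                comparison="virgin-vs-mated",
            )
        )
    targets_by_mirna = {m: table.targets_of(m) for m in de_mirnas}
    opp_masks = {
        m: np.array([
            gene_dir.get(g) == ("down" if d == "up" else "up") for g in gene_ids
        ])
        for m, d in de_mirnas.items()
    }
    for test_type in ("ks", "fisher"):
        results.extend(
            matched.pairwise_combination_tests(
                de_mirnas, targets_by_mirna, gene_ids, lengths,
                log2fc=log2fc, opposite_de_masks=opp_masks,
                test_type=test_type, cfg=test_cfg, comparison="virgin-vs-mated",
            )
        )
    result_frame = matched.results_frame(results, test_cfg.fdr_alpha)

    de_mirna_frame = pd.DataFrame(
        {"mirna_id": list(de_mirnas), "direction": list(de_mirnas.values())}
    )
    network = targets.export_network(
        table, de_mirna_frame, de_genes, known_genes=set(gene_index)
    )

    out = PipelineResult(ds, counts, table, fc, de_genes, result_frame, network,
                         recovered)
    if outdir is not None:
        write_pipeline_outputs(out, outdir)
    return out


def _recovered_fraction(ds: SimulatedDataset, table: targets.TargetTable) -> float:
    """Fraction of implanted (true) targets recovered by prediction."""
    total = hit = 0
    for mirna, genes in ds.truth.targets.items():
        for g in genes:
            total += 1
            hit += table.is_target(mirna, g)
    return hit / total if total else float("nan")


def write_pipeline_outputs(result: PipelineResult, outdir) -> dict[str, str]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = synthetic.write_dataset(result.dataset, outdir)
    artefacts = {
        "counts": outdir / "mirna_counts.tsv",
        "sites": outdir / "predicted_sites.tsv",
        "fold_changes": outdir / "fold_changes.tsv",
        "de_genes": outdir / "de_genes.tsv",
        "results": outdir / "matched_test_results.tsv",
        "network": outdir / "network_edges.tsv",
        "network_sif": outdir / "network.sif",
    }
    result.mirna_counts.to_frame().to_csv(artefacts["counts"], sep="\t")
    result.target_table.to_frame().to_csv(artefacts["sites"], sep="\t", index=False)
    result.fold_changes.to_csv(artefacts["fold_changes"], sep="\t", index=False)
    result.de_genes.to_csv(artefacts["de_genes"], sep="\t", index=False)
    result.results.to_csv(artefacts["results"], sep="\t", index=False)
    result.network.to_csv(artefacts["network"], sep="\t", index=False)
    targets.write_sif(result.network, artefacts["network_sif"])
    paths.update({k: str(v) for k, v in artefacts.items()})
    return paths
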