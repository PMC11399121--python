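"""Scoring a synthetic run against its planted truth.

Used by the validation suite and the reproduction script to turn one
pipeline run into recovery statistics: consensus site recovery, direct-
target precision/recall, planted-TF recovery, network edge recall and the
provenance-flag consistency of the common direct-target core.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .intervals import GenomicInterval, read_bed
from .synthetic import SynthTruth, load_truth

__all__ = ["evaluate_run", "consensus_site_recovery"]


def consensus_site_recovery(
    consensus: list[GenomicInterval], true_sites: list[GenomicInterval]
) -> tuple[int, int]:
    """(number of true sites overlapped by >= 1 consensus peak, total sites)."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in consensus:
        by_chrom.setdefault(p.chrom, []).append(p)
    hit = 0
    for s in true_sites:
        peaks = by_chrom.get(s.chrom, [])
        if any(p.start < s.end and s.start < p.end for p in peaks):
            hit += 1
    return hit, len(true_sites)


def evaluate_run(run_dir: str | Path, truth: SynthTruth | None = None) -> dict:
    """Recovery statistics of one pipeline run against the planted truth."""
    run_dir = Path(run_dir)
    if truth is None:
        truth = load_truth(run_dir / "sim")

    cons_df = pd.read_csv(run_dir / "consensus" / "consensus_peaks.tsv", sep="\t")
    consensus = [
        GenomicInterval(r["chrom"], int(r["start"]), int(r["end"]))
        for _, r in cons_df.iterrows()
    ]
    hit, total = consensus_site_recovery(consensus, truth.true_binding_sites)

    targets = pd.read_csv(run_dir / "integrate" / "target_classes.tsv", sep="\t")
    called_rdg = set(targets.loc[targets["target_class"] == "RDG", "gene_id"])
    true_direct = set(truth.direct_target_ids)
    tp = len(called_rdg & true_direct)
    precision = tp / len(called_rdg) if called_rdg else float("nan")
    recall = tp / len(true_direct) if true_direct else float("nan")

    rdg_tfs = pd.read_csv(run_dir / "integrate" / "rdg_tfs.tsv", sep="\t")
    recovered_tfs = set(rdg_tfs["gene_id"])
    planted_tfs = set(truth.tf_layer)

    edges = pd.read_csv(run_dir / "integrate" / "network_edges.tsv", sep="\t")
    edge_set = set(zip(edges["tf_id"], edges["target_gene_id"]))
    de_a = pd.read_csv(run_dir / "de" / "de_model_a.tsv", sep="\t")
    de_b = pd.read_csv(run_dir / "de" / "de_model_b.tsv", sep="\t")
    with open(run_dir / "config.yaml") as fh:
        import yaml

        de_fdr = yaml.safe_load(fh)["de_fdr"]
    deg_a = set(de_a.loc[de_a["padj"] < de_fdr, "gene_id"])
    deg_b = set(de_b.loc[de_b["padj"] < de_fdr, "gene_id"])
    common_degs = deg_a & deg_b
    # realizable planted edges: the target reached the common-DEG universe
    # and the TF qualified as a coherent direct-target TF
    realizable = [
        (tf, g)
        for (tf, g) in truth.planted_motif_positions
        if g in common_degs and tf in recovered_tfs
    ]
    recalled = sum(1 for e in realizable if e in edge_set)
    edge_recall = recalled / len(realizable) if realizable else float("nan")

    out = {
        "consensus_sites_recovered": hit,
        "consensus_sites_total": total,
        "rdg_precision": precision,
        "rdg_recall": recall,
        "planted_tfs_recovered": len(recovered_tfs & planted_tfs),
        "planted_tfs_total": len(planted_tfs),
        "edge_recall": edge_recall,
        "edges_realizable": len(realizable),
    }

    comm_path = run_dir / "integrate" / "comm_dgs.tsv"
    if comm_path.exists():
        comm = pd.read_csv(comm_path, sep="\t")
        flags = (
            comm["lnc_direct_a"]
            & comm["tf_direct_a"]
            & comm["lnc_deg_b"]
            & comm["tf_deg_b"]
        )
        out["comm_flags_consistent"] = bool((flags == comm["is_common_direct"]).all())
        out["n_comm_dg"] = int(comm["is_common_direct"].sum())
    return out
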