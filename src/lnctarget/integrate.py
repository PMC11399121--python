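"""The classification cascade: direct/indirect target labels, coherent
TF selection across cell models, hierarchical network edges, the common
direct-target core, and the pairwise Spearman correlation matrix.

Vocabulary (from enhancer-lncRNA regulatory genomics):

* RDG -- a *direct* target: differentially expressed upon lncRNA knockdown
  AND carrying at least one consensus binding peak assigned to it.
* RIG -- an *indirect* target: knockdown-responsive with no assigned peak.
* RDG-TF -- a transcription factor (or co-factor) that is itself an RDG in
  the discovery cell model and coherently deregulated (same fold-change
  sign) in the second model.
* comm_DG -- a gene directly bound by both the lncRNA and the cooperating
  TF in the discovery model and deregulated by both knockdowns in the
  second model.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

TARGET_CLASSES = ("RDG", "RIG", "bound_only", "unchanged")

__all__ = [
    "share_pct",
    "classify_targets",
    "identify_rdg_tfs",
    "build_network",
    "common_direct_targets",
    "spearman_matrix",
]


def share_pct(k: int, total: int) -> float:
    """Percentage share rounded to two decimals (the reporting convention)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * k / total, 2)


def classify_targets(
    peak_annotations: pd.DataFrame,
    deg_records: pd.DataFrame,
    de_fdr: float = 0.1,
) -> tuple[pd.DataFrame, dict]:
    """Label every gene as RDG / RIG / bound_only / unchanged.

    A gene counts as *bound* when at least one consensus peak's assigned
    target is that gene, regardless of feature class.  A gene is a DEG when
    padj < de_fdr (equivalently direction != 'ns' in the DE table).  The
    four classes partition the union of genes seen in either input.
    """
    bound_peaks: dict[str, list[str]] = {}
    for _, row in peak_annotations.iterrows():
        g = row["gene_id"]
        if g is not None and not (isinstance(g, float) and np.isnan(g)):
            bound_peaks.setdefault(g, []).append(str(row["peak_id"]))
    deg = deg_records.set_index("gene_id")
    sig = deg["padj"] < de_fdr

    genes = sorted(set(deg.index) | set(bound_peaks))
    rows = []
    for g in genes:
        is_deg = bool(sig.get(g, False))
        is_bound = g in bound_peaks
        if is_deg and is_bound:
            cls = "RDG"
        elif is_deg:
            cls = "RIG"
        elif is_bound:
            cls = "bound_only"
        else:
            cls = "unchanged"
        rows.append(
            {
                "gene_id": g,
                "target_class": cls,
                "n_peaks": len(bound_peaks.get(g, [])),
                "peak_ids": ";".join(bound_peaks.get(g, [])),
                "de_direction": deg["direction"].get(g, "ns"),
                "log2fc": float(deg["log2fc"].get(g, np.nan)),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["gene_id", "target_class", "n_peaks", "peak_ids",
                 "de_direction", "log2fc"],
    )
    n_deg = int(sig.sum())
    n_rdg = int((table["target_class"] == "RDG").sum())
    n_rig = int((table["target_class"] == "RIG").sum())
    n_up = int((deg["direction"] == "up").sum())
    n_down = int((deg["direction"] == "down").sum())
    summary = {
        "n_deg": n_deg,
        "n_up": n_up,
        "n_down": n_down,
        "n_rdg": n_rdg,
        "n_rig": n_rig,
        "n_bound_only": int((table["target_class"] == "bound_only").sum()),
        "n_unchanged": int((table["target_class"] == "unchanged").sum()),
    }
    if n_deg > 0:
        summary["up_pct"] = share_pct(n_up, n_deg)
        summary["down_pct"] = share_pct(n_down, n_deg)
        summary["rdg_pct"] = share_pct(n_rdg, n_deg)
        summary["rig_pct"] = share_pct(n_rig, n_deg)
    assert n_deg == n_rdg + n_rig, "DEG total must equal RDG + RIG"
    return table, summary


def identify_rdg_tfs(
    targets_a: pd.DataFrame,
    deg_b: pd.DataFrame,
    tf_catalog: pd.DataFrame,
    de_fdr: float = 0.1,
) -> pd.DataFrame:
    """Select TFs/co-factors that are direct targets with cross-model
    coherence.

    A catalog gene qualifies when it is an RDG in the discovery model, a
    DEG in the second model, and its fold changes have the same sign in
    both models.  Catalog genes absent from the expression tables are
    skipped with a note in the returned frame's attrs.
    """
    t = targets_a.set_index("gene_id")
    b = deg_b.set_index("gene_id")
    skipped = []
    rows = []
    for _, cat in tf_catalog.iterrows():
        g = cat["gene_id"]
        role = cat["role"]
        if g not in t.index or g not in b.index:
            skipped.append(g)
            continue
        if t.loc[g, "target_class"] != "RDG":
            continue
        if not (b.loc[g, "padj"] < de_fdr):
            continue
        dir_a = t.loc[g, "de_direction"]
        dir_b = b.loc[g, "direction"]
        if dir_a != dir_b or dir_a == "ns":
            continue
        rows.append(
            {
                "gene_id": g,
                "role": role,
                "direction": dir_a,
                "log2fc_a": float(t.loc[g, "log2fc"]),
                "log2fc_b": float(b.loc[g, "log2fc"]),
            }
        )
    out = pd.DataFrame(
        rows, columns=["gene_id", "role", "direction", "log2fc_a", "log2fc_b"]
    ).sort_values("gene_id").reset_index(drop=True)
    out.attrs["skipped_catalog_genes"] = sorted(skipped)
    return out


def build_network(
    rdg_tfs: pd.DataFrame,
    motif_hits: pd.DataFrame,
    common_degs: Iterable[str],
    target_classes: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hierarchical TF -> target edges from promoter motif evidence.

    An edge exists iff the TF has >= 1 retained motif hit in the target's
    promoter window and the target is in the common-DEG universe (genes
    deregulated in both cell models).  The layer label (RDG/RIG) is copied
    from the target's class.  Returns (edges, per-TF layer counts).
    """
    common = set(common_degs)
    cls = target_classes.set_index("gene_id")["target_class"]
    tf_set = set(rdg_tfs["gene_id"])
    edges = {}
    for _, h in motif_hits.iterrows():
        tf, g = h["tf_id"], h["gene_id"]
        if tf not in tf_set or g not in common:
            continue
        layer = cls.get(g)
        if layer not in ("RDG", "RIG"):
            continue
        key = (tf, g)
        if key not in edges:
            edges[key] = {"n_hits": 0, "layer": layer, "evidence": []}
        edges[key]["n_hits"] += 1
        edges[key]["evidence"].append(f"{h['strand']}@{int(h['offset'])}")
    rows = [
        {
            "tf_id": tf,
            "target_gene_id": g,
            "target_class": v["layer"],
            "n_hits": v["n_hits"],
            "evidence": ";".join(v["evidence"]),
        }
        for (tf, g), v in sorted(edges.items())
    ]
    edge_df = pd.DataFrame(
        rows,
        columns=["tf_id", "target_gene_id", "target_class", "n_hits", "evidence"],
    )
    if len(edge_df):
        counts = (
            edge_df.groupby(["tf_id", "target_class"]).size().unstack(fill_value=0)
        )
        for c in ("RDG", "RIG"):
            if c not in counts:
                counts[c] = 0
        counts = counts[["RDG", "RIG"]].reset_index()
    else:
        counts = pd.DataFrame(columns=["tf_id", "RDG", "RIG"])
    return edge_df, counts


def common_direct_targets(
    lnc_direct_a: Iterable[str],
    tf_direct_a: Iterable[str],
    lnc_deg_b: Iterable[str],
    tf_deg_b: Iterable[str],
) -> pd.DataFrame:
    """Common direct-target core with per-gene provenance flags.

    Membership requires all four flags: bound by the lncRNA and by the TF
    in the discovery model, and deregulated by both knockdowns in the
    second model.  The intersection is order-independent.
    """
    A, B, C, D = (set(lnc_direct_a), set(tf_direct_a), set(lnc_deg_b), set(tf_deg_b))
    universe = sorted(A | B | C | D)
    rows = []
    for g in universe:
        fa, fb, fc, fd = g in A, g in B, g in C, g in D
        rows.append(
            {
                "gene_id": g,
                "lnc_direct_a": fa,
                "tf_direct_a": fb,
                "lnc_deg_b": fc,
                "tf_deg_b": fd,
                "is_common_direct": fa and fb and fc and fd,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "lnc_direct_a", "tf_direct_a", "lnc_deg_b",
                 "tf_deg_b", "is_common_direct"],
    )


def spearman_matrix(
    expression: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman correlation of genes (rows) across samples.

    Ties get average ranks; p-values use the t approximation
    t = R sqrt((n-2) / (1-R^2)) with n-2 df, two-sided.  Constant genes
    yield undefined (NaN) correlations with every partner, flagged as
    non-significant.
    """
    n = expression.shape[1]
    if n < 4:
        raise ValueError("spearman_matrix needs >= 4 samples")
    vals = expression.to_numpy(dtype=float)
    constant = vals.std(axis=1) == 0
    ranks = np.apply_along_axis(stats.rankdata, 1, vals)
    with np.errstate(invalid="ignore"):
        R = np.corrcoef(ranks)
    R[constant, :] = np.nan
    R[:, constant] = np.nan
    np.fill_diagonal(R, np.where(constant, np.nan, 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = R * np.sqrt((n - 2) / np.maximum(1.0 - R**2, 1e-300))
        p = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
    np.fill_diagonal(p, np.nan)
    idx = expression.index
    Rdf = pd.DataFrame(R, index=idx, columns=idx)
    pdf = pd.DataFrame(p, index=idx, columns=idx)
    sig = (pdf < alpha).fillna(False)
    return Rdf, pdf, sig
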