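"""Hypergeometric over-representation analysis and term-similarity clustering.

ORA tests a query gene list against GMT gene-set collections with the
upper hypergeometric tail, BH-adjusted across all tested terms.  Enriched
terms are then related by Jaccard similarity of their gene memberships and
grouped with deterministic greedy modularity maximization (a reproducible
stand-in for order-sensitive Louvain clustering).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

__all__ = [
    "read_gmt",
    "write_gmt",
    "ora",
    "jaccard_matrix",
    "TermCluster",
    "cluster_terms",
]


def read_gmt(path: str | Path) -> dict[str, tuple[str, set[str]]]:
    """Read a GMT collection: term -> (description, gene set)."""
    out: dict[str, tuple[str, set[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT lines need term, description, >=1 gene"
                )
            out[parts[0]] = (parts[1], set(g for g in parts[2:] if g))
    return out


def write_gmt(gene_sets: Mapping[str, tuple[str, set[str]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in sorted(gene_sets):
            desc, genes = gene_sets[term]
            fh.write("\t".join([term, desc] + sorted(genes)) + "\n")


def ora(
    query: Iterable[str],
    gene_sets: Mapping[str, tuple[str, set[str]]],
    universe: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of the query in each gene set.

    The universe is the background gene population; query and term sets are
    intersected with it before testing.  p = upper hypergeometric tail
    P(X >= k) with N = |universe|, K = |term|, n = |query|; BH across all
    tested terms.
    """
    uni = set(universe)
    q = set(query) & uni
    if not uni:
        raise ValueError("empty universe")
    if not q:
        raise ValueError("empty query after intersection with universe")
    N, n = len(uni), len(q)
    rows = []
    for term in sorted(gene_sets):
        desc, genes = gene_sets[term]
        K_set = genes & uni
        K = len(K_set)
        if K == 0:
            continue
        overlap = sorted(K_set & q)
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term_id": term,
                "term_name": desc,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": min(p, 1.0),
                "genes": ";".join(overlap),
            }
        )
    res = pd.DataFrame(
        rows, columns=["term_id", "term_name", "k", "K", "n", "N", "p", "genes"]
    )
    if len(res):
        res["padj"] = bh_adjust(res["p"].to_numpy())
        res["significant"] = res["padj"] < alpha
        res = res.sort_values(["p", "term_id"]).reset_index(drop=True)
    else:
        res["padj"] = []
        res["significant"] = []
    return res


def jaccard_matrix(term_sets: Mapping[str, set[str]]) -> pd.DataFrame:
    """Symmetric |A∩B| / |A∪B| similarity between term gene sets.

    An empty set has similarity 0 with everything (including itself,
    flagged by the NaN-free convention of a 0 diagonal entry being
    impossible for non-empty sets: diagonal is 1 for non-empty, 0 for
    empty sets).
    """
    terms = sorted(term_sets)
    m = len(terms)
    J = np.zeros((m, m))
    for i, a in enumerate(terms):
        A = term_sets[a]
        for j in range(i, m):
            B = term_sets[terms[j]]
            union = len(A | B)
            J[i, j] = J[j, i] = (len(A & B) / union) if union else 0.0
    return pd.DataFrame(J, index=terms, columns=terms)


@dataclass
class TermCluster:
    cluster_id: int
    members: list[str]
    representative: str


def cluster_terms(
    similarity: pd.DataFrame,
    edge_min: float = 0.2,
    term_sizes: Optional[Mapping[str, int]] = None,
) -> list[TermCluster]:
    """Group terms by similarity with deterministic greedy modularity.

    Terms are nodes; edges connect pairs with similarity >= edge_min,
    weighted by the similarity.  Greedy modularity maximization with a
    fixed (sorted) node order replaces seed-sensitive Louvain so that the
    partition is reproducible.  Singletons are allowed.  The representative
    of a cluster is its largest member set (ties to the lexicographically
    smaller term id); with no sizes given, the lexicographically smallest
    member.
    """
    if similarity.shape[0] != similarity.shape[1]:
        raise ValueError("similarity matrix must be square")
    terms = sorted(similarity.index)
    G = nx.Graph()
    G.add_nodes_from(terms)
    for i, a in enumerate(terms):
        for b in terms[i + 1 :]:
            w = float(similarity.loc[a, b])
            if w >= edge_min and w > 0:
                G.add_edge(a, b, weight=w)
    if G.number_of_edges() == 0:
        communities = [{t} for t in terms]
    else:
        communities = [
            set(c)
            for c in nx.algorithms.community.greedy_modularity_communities(
                G, weight="weight"
            )
        ]
    def rep(members: list[str]) -> str:
        if term_sizes is None:
            return members[0]
        return min(members, key=lambda t: (-term_sizes.get(t, 0), t))

    clusters = []
    for members in communities:
        ms = sorted(members)
        clusters.append((rep(ms), ms))
    clusters.sort(key=lambda c: c[0])
    return [
        TermCluster(cluster_id=i, members=ms, representative=r)
        for i, (r, ms) in enumerate(clusters)
    ]
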