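"""Hypergeometric over-representation of gene sets within clusters.

For a cluster of n genes and a functional category with K genes out of
an N-gene reference (all genes on the array), the upper-tail
hypergeometric probability P(X >= k) of the observed overlap k measures
over-representation.  Raw p-values are reported alongside a
Benjamini-Hochberg adjustment across terms within each cluster.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import ClusterAssignment
from .diffexpr import bh_fdr
from .io_core import AnalysisConfig, GeneSetCollection, ValidationError

__all__ = [
    "hypergeom_upper_tail",
    "enrich_clusters",
    "enrichment_matrix",
]


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= k <= min(n, K)):
        raise ValidationError(f"need 0 <= k <= min(n, K); got k={k}, n={n}, K={K}")
    if not (K <= N and n <= N):
        raise ValidationError(f"need K <= N and n <= N; got K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); scipy evaluates the tail stably in log space
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_clusters(
    assignment: ClusterAssignment,
    genes: list[str],
    sets: GeneSetCollection,
    reference: list[str] | set[str],
    cfg: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Test every (cluster, term) pair with nonzero overlap.

    ``genes`` gives the identity of the clustered items, aligned with
    ``assignment.labels``.  Term membership is intersected with the
    reference universe before counting K.  Returns one row per record
    with columns cluster, term, k, n, K, N, p, q (BH within cluster),
    sorted by p.
    """
    if len(genes) != len(assignment.labels):
        raise ValidationError("genes and cluster labels differ in length")
    reference = set(reference)
    missing = [g for g in genes if g not in reference]
    if missing:
        raise ValidationError(f"clustered gene {missing[0]!r} absent from reference")
    N = len(reference)
    members_by_term = {
        gs.name: set(gs.members) & reference for gs in sets
    }
    rows = []
    for label in sorted(assignment.exemplars):
        cluster_genes = {g for g, l in zip(genes, assignment.labels) if l == label}
        n = len(cluster_genes)
        for term, members in members_by_term.items():
            K = len(members)
            if K == 0:
                continue
            k = len(cluster_genes & members)
            if k == 0:
                continue
            rows.append(
                {
                    "cluster": label,
                    "term": term,
                    "k": k,
                    "n": n,
                    "K": K,
                    "N": N,
                    "p": hypergeom_upper_tail(k, n, K, N),
                }
            )
    if not rows:
        return pd.DataFrame(columns=["cluster", "term", "k", "n", "K", "N", "p", "q"])
    table = pd.DataFrame(rows)
    table["q"] = np.nan
    for label, idx in table.groupby("cluster").groups.items():
        table.loc[idx, "q"] = bh_fdr(table.loc[idx, "p"].to_numpy())
    return table.sort_values(["p", "cluster", "term"], kind="stable").reset_index(drop=True)


def enrichment_matrix(records: pd.DataFrame) -> pd.DataFrame:
    """Pivot enrichment records into a clusters x terms -log10(p) heat-map
    matrix; absent (cluster, term) pairs are 0 (no evidence)."""
    if records.empty:
        return pd.DataFrame()
    mat = records.pivot(index="cluster", columns="term", values="p")
    return -np.log10(mat).fillna(0.0)
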