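"""Over-representation analysis with Holm correction and kappa clustering.

Per gene set (term) the enrichment p-value is the hypergeometric upper
tail P[X >= k] for k query genes out of n falling in a term of size K
within a universe of size N. Family-wise error is controlled by Holm's
step-down procedure (the "Bonferroni step-down" of enrichment tools).
Redundant significant terms are grouped by pairwise Cohen's kappa between
their query-membership indicator vectors: terms with kappa >= the
threshold (default 0.4) are linked, and clusters are the connected
components of that agreement graph.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Sequence, Set

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

RESULT_COLUMNS = [
    "term_id",
    "term_name",
    "k",
    "K",
    "n",
    "N",
    "p",
    "p_adj",
    "cluster_id",
]


def hypergeom_enrich(
    query: Iterable[str],
    gene_sets: Dict[str, Dict],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of the query in each gene set.

    Gene sets are intersected with the universe; empty (post-intersection)
    sets are skipped. Returns one row per tested term with raw and
    Holm-adjusted p-values, sorted by p.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    query_set = set(query)
    if not query_set:
        raise ValueError("empty query")
    stray = query_set - universe_set
    if stray:
        raise ValueError(
            f"query contains ids outside the universe, e.g. {sorted(stray)[:3]}"
        )

    N = len(universe_set)
    n = len(query_set)
    rows = []
    for term_id, rec in gene_sets.items():
        members = set(rec["members"]) & universe_set
        K = len(members)
        if K == 0:
            continue
        k = len(members & query_set)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term_id": term_id,
                "term_name": rec.get("description", term_id),
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": min(p, 1.0),
            }
        )
    if not rows:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    df = pd.DataFrame(rows)
    df["p_adj"] = multipletests(df["p"].to_numpy(), method="holm")[1]
    df["cluster_id"] = -1
    return df.sort_values("p", kind="mergesort").reset_index(drop=True)


def cohen_kappa(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's kappa between two binary vectors.

    Identical vectors give 1 even when agreement-by-chance is saturated
    (both constant); disjoint covers give kappa <= 0.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("vectors differ in length")
    n = a.size
    po = float(np.mean(a == b))
    pa1, pb1 = float(a.mean()), float(b.mean())
    pe = pa1 * pb1 + (1 - pa1) * (1 - pb1)
    if pe >= 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1.0 - pe)


def kappa_cluster(
    results: pd.DataFrame,
    gene_sets: Dict[str, Dict],
    query: Iterable[str],
    kappa_threshold: float = 0.4,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Assign cluster ids to significant terms by kappa agreement.

    Membership vectors are indicators over the query genes (not the
    universe). Clusters are connected components of the graph linking term
    pairs with kappa >= threshold; singletons keep their own id. Cluster
    ids are ordered by the best (smallest) term p-value within the cluster.
    """
    out = results.copy()
    out["cluster_id"] = -1
    sig = out[out["p_adj"] <= alpha]
    if sig.empty:
        return out

    query_list = sorted(set(query))
    vectors = {
        term: np.array([g in set(gene_sets[term]["members"]) for g in query_list])
        for term in sig["term_id"]
    }
    g = nx.Graph()
    g.add_nodes_from(vectors)
    terms = list(vectors)
    for i, t1 in enumerate(terms):
        for t2 in terms[i + 1 :]:
            if cohen_kappa(vectors[t1], vectors[t2]) >= kappa_threshold:
                g.add_edge(t1, t2)

    best_p = {t: float(out.loc[out["term_id"] == t, "p"].iloc[0]) for t in terms}
    clusters = sorted(
        (sorted(c) for c in nx.connected_components(g)),
        key=lambda c: (min(best_p[t] for t in c), c[0]),
    )
    for cid, cluster in enumerate(clusters):
        out.loc[out["term_id"].isin(cluster), "cluster_id"] = cid
    return out


def enrich(
    query: Iterable[str],
    gene_sets: Dict[str, Dict],
    universe: Iterable[str],
    kappa_threshold: float = 0.4,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full over-representation analysis: test, adjust, cluster."""
    results = hypergeom_enrich(query, gene_sets, universe)
    if results.empty:
        return results
    return kappa_cluster(results, gene_sets, query, kappa_threshold, alpha)
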