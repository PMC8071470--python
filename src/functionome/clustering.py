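"""Ontology clustering of significant GO terms and cluster weight index (CWI).

Significant terms are grouped in the is_a DAG: each term joins the cluster
headed by its highest significant ancestor, where a "highest" ancestor is a
significant term with no significant strict ancestor of its own.  A
significant term with no significant ancestor heads its own cluster, and
terms absent from the ontology form singleton clusters.  Cluster weight is
the sum of -log10(raw p) over members, and the CWI is the cluster's share
of the total weight over all clusters, so CWIs sum to one and rank clusters
by relevance.

The grouping rule and the -log10 weight are deterministic interpretations
of "clusters in the GO tree" weighted by p-values; both are configurable
(see ``weight`` argument) and documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .stats import SetTestResult

__all__ = [
    "GoCluster",
    "build_clusters",
    "rank_clusters",
    "common_top_terms",
    "categorize_terms",
    "clusters_to_frame",
    "load_term_categories",
]

_P_FLOOR = 1e-300  # avoids infinite weight at underflowed p-values


@dataclass
class GoCluster:
    head_term: str
    members: list[str]
    weight: float
    cwi: float = 0.0
    head_p: float = field(default=1.0, repr=False)


def _term_weight(p: float, weight: str) -> float:
    if weight == "neglog10p":
        return -np.log10(max(p, _P_FLOOR))
    if weight == "one_minus_p":
        return 1.0 - p
    raise ValueError(f"unknown weight scheme {weight!r}")


def build_clusters(
    significant: list[SetTestResult],
    graph: nx.DiGraph,
    weight: str = "neglog10p",
) -> list[GoCluster]:
    """Partition significant terms into clusters under their highest
    significant ancestors and compute weights and CWIs.

    In a DAG a term may have several highest significant ancestors; the one
    with the smallest raw p (then lexicographically smallest id) is chosen,
    so the partition is deterministic and independent of input order.
    """
    if not nx.is_directed_acyclic_graph(graph):
        raise ValueError("ontology graph must be acyclic")
    sig = {r.set_id: r for r in significant}

    def highest_heads(term: str) -> list[str]:
        anc = (nx.descendants(graph, term) if term in graph else set()) & sig.keys()
        candidates = anc | {term}
        return [
            c
            for c in candidates
            if not ((nx.descendants(graph, c) if c in graph else set()) & sig.keys())
        ]

    assignment: dict[str, str] = {}
    for term in sorted(sig):
        heads = highest_heads(term)
        head = min(heads, key=lambda h: (sig[h].p_raw, h))
        assignment[term] = head

    clusters: dict[str, GoCluster] = {}
    for term in sorted(assignment):
        head = assignment[term]
        cl = clusters.setdefault(
            head, GoCluster(head_term=head, members=[], weight=0.0, head_p=sig[head].p_raw)
        )
        cl.members.append(term)
        cl.weight += _term_weight(sig[term].p_raw, weight)
    total = sum(cl.weight for cl in clusters.values())
    for cl in clusters.values():
        cl.cwi = cl.weight / total if total > 0 else 0.0
    return list(clusters.values())


def rank_clusters(clusters: list[GoCluster]) -> list[GoCluster]:
    """Descending CWI; ties broken by smaller head-term raw p, then id."""
    if not clusters:
        raise ValueError("no clusters to rank")
    return sorted(clusters, key=lambda c: (-c.cwi, c.head_p, c.head_term))


def common_top_terms(
    ranked_per_group: dict[str, list[str]], k: int = 50
) -> pd.DataFrame:
    """Head terms common to every group's top-k list, in combined order.

    Combined order is the ascending mean of each term's within-group ranks;
    ties break lexicographically.  Per-group original ranks (1-based) are
    reported alongside.  An empty intersection yields an empty table.
    """
    if len(ranked_per_group) < 2:
        raise ValueError("need at least two groups")
    if k < 1:
        raise ValueError("k must be >= 1")
    tops = {g: terms[:k] for g, terms in ranked_per_group.items()}
    common = set.intersection(*(set(t) for t in tops.values()))
    rows = []
    for term in common:
        ranks = {g: tops[g].index(term) + 1 for g in tops}
        rows.append({"term": term, **{f"rank_{g}": r for g, r in ranks.items()},
                     "mean_rank": float(np.mean(list(ranks.values())))})
    if not rows:
        cols = ["order", "term"] + [f"rank_{g}" for g in tops] + ["mean_rank"]
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(rows).sort_values(["mean_rank", "term"]).reset_index(drop=True)
    df.insert(0, "order", np.arange(1, len(df) + 1))
    return df


def categorize_terms(
    terms, category_map: dict[str, str], other_label: str = "others"
) -> dict[str, list[str]]:
    """Partition terms by a curated category map; unmapped terms fall into
    the catch-all category."""
    out: dict[str, list[str]] = {}
    for term in terms:
        cat = category_map.get(term, other_label)
        out.setdefault(cat, []).append(term)
    return out


def load_term_categories() -> dict[str, str]:
    """Curated functional-category assignments for 41 GO terms recurrently
    dysregulated in borderline ovarian tumours, shipped with the package.

    Categories: immune_inflammatory, membrane_transporter,
    cell_cycle_signaling, cell_metabolism, others.
    """
    from importlib.resources import files

    path = files("functionome.resources") / "go_term_categories.tsv"
    with path.open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh, sep="\t")
    return dict(zip(df["term_id"], df["category"]))


def clusters_to_frame(clusters: list[GoCluster], names: dict[str, str] | None = None) -> pd.DataFrame:
    """Ranked cluster table: rank, head term, name, members, weight, CWI."""
    ranked = rank_clusters(clusters)
    names = names or {}
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(ranked) + 1),
            "head_term": [c.head_term for c in ranked],
            "name": [names.get(c.head_term, c.head_term) for c in ranked],
            "members": ["|".join(c.members) for c in ranked],
            "weight": [c.weight for c in ranked],
            "cwi": [c.cwi for c in ranked],
        }
    )
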