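"""Node centralities and before/after comparison of signed interaction
networks.

Centralities ignore edge sign — a negative interaction is as much an edge
as a positive one — and treat the network as an unweighted digraph, since
interaction strengths carry no path-length semantics.
"""

from __future__ import annotations

from typing import Callable

import networkx as nx
import pandas as pd

__all__ = [
    "in_degree",
    "betweenness",
    "compare_networks",
    "overlay_pathways",
    "niche_pathway_summary",
]


def in_degree(network: nx.DiGraph, node) -> int:
    """Number of distinct incoming directed edges of ``node``."""
    if node not in network:
        raise KeyError(f"unknown node {node!r}")
    return int(network.in_degree(node))


def betweenness(network: nx.DiGraph, node=None, normalized: bool = False):
    """Directed, unweighted betweenness centrality (Brandes accumulation).

    For node v: sum over ordered pairs (s, t), s != t != v, of the fraction
    of shortest s-t paths that pass through v.  Unnormalized by default.
    Returns a dict for all nodes, or a float when ``node`` is given.
    """
    if node is not None and node not in network:
        raise KeyError(f"unknown node {node!r}")
    values = nx.betweenness_centrality(network, normalized=normalized)
    if node is not None:
        return float(values[node])
    return {n: float(v) for n, v in values.items()}


def _default_comparator(deg_a: int | None, deg_b: int | None) -> str:
    """Default niche rule from in-degrees in the two networks.

    ``A`` when strictly larger in the first network, ``B`` when strictly
    larger in the second, ``star`` when present in both with equal positive
    in-degree, else ``none``.  Absence counts as in-degree below any
    present value (an absent taxon can never out-rank a present one).
    """
    da = -1 if deg_a is None else deg_a
    db = -1 if deg_b is None else deg_b
    if da > db:
        return "A"
    if db > da:
        return "B"
    if deg_a is not None and deg_b is not None and da == db and da > 0:
        return "star"
    return "none"


def compare_networks(
    net_a: nx.DiGraph,
    net_b: nx.DiGraph,
    comparator: Callable[[int | None, int | None], str] | None = None,
) -> pd.DataFrame:
    """Per-taxon topological-niche labels from two networks' in-degrees.

    Every taxon present in either network receives a label via
    ``comparator(in_degree_a, in_degree_b)`` (``None`` marks absence from
    a network).  The default rule is :func:`_default_comparator`; the
    comparator is pluggable because the niche-assignment convention is an
    interpretation.
    """
    comparator = comparator or _default_comparator
    taxa = sorted(set(net_a.nodes) | set(net_b.nodes))
    rows = []
    for t in taxa:
        da = int(net_a.in_degree(t)) if t in net_a else None
        db = int(net_b.in_degree(t)) if t in net_b else None
        rows.append(
            {
                "taxon": t,
                "in_degree_a": da,
                "in_degree_b": db,
                "niche": comparator(da, db),
            }
        )
    return pd.DataFrame(rows, columns=["taxon", "in_degree_a", "in_degree_b", "niche"])


def overlay_pathways(
    network: nx.DiGraph, annotations: pd.DataFrame
) -> tuple[nx.DiGraph, pd.DataFrame]:
    """Attach pathway categories to nodes and summarize counts per category.

    Nodes without an annotation get category ``"none"``.  Returns the
    annotated copy and a per-category node-count summary.
    """
    g = network.copy()
    cats = (
        annotations["pathway_category"]
        if "pathway_category" in annotations
        else pd.Series(dtype=object)
    )
    for n in g.nodes:
        cat = cats.get(n) if n in cats.index else None
        g.nodes[n]["pathway_category"] = cat if isinstance(cat, str) else "none"
    summary = (
        pd.Series(
            [g.nodes[n]["pathway_category"] for n in g.nodes], dtype=object
        )
        .value_counts()
        .rename_axis("pathway_category")
        .rename("n_nodes")
        .reset_index()
        .sort_values("pathway_category", kind="mergesort")
        .reset_index(drop=True)
    )
    return g, summary


def niche_pathway_summary(
    niche_labels: pd.DataFrame, annotations: pd.DataFrame
) -> pd.DataFrame:
    """Count niche-holding taxa per pathway category per network.

    ``niche_labels`` is the output of :func:`compare_networks`; taxa with
    niche ``A`` count toward the first network, ``B`` toward the second and
    ``star`` toward both.
    """
    cats = (
        annotations["pathway_category"]
        if "pathway_category" in annotations
        else pd.Series(dtype=object)
    )
    rows = []
    for row in niche_labels.itertuples(index=False):
        cat = cats.get(row.taxon)
        cat = cat if isinstance(cat, str) else "none"
        if row.niche in ("A", "star"):
            rows.append({"pathway_category": cat, "network": "A"})
        if row.niche in ("B", "star"):
            rows.append({"pathway_category": cat, "network": "B"})
    if not rows:
        return pd.DataFrame(columns=["pathway_category", "network", "n_niche_taxa"])
    return (
        pd.DataFrame(rows)
        .groupby(["pathway_category", "network"])
        .size()
        .rename("n_niche_taxa")
        .reset_index()
    )
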