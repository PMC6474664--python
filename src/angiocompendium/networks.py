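"""Focus-gene network construction, scoring and comparison.

Networks are grown greedily from high-degree focus-gene seeds over the
global interaction graph and scored as -log10 of the one-tailed Fisher
exact probability that their focus-gene content arises by chance; a score
of 3 therefore corresponds to p = 1e-3, i.e. 99.9% confidence that the
network is not random.  Cross-treatment comparison utilities cover the
common-node matrix, intra-network degree rankings, and the merge of
pathway-anchored networks across treatments with per-treatment regulation
states retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneNetwork",
    "MergedNetwork",
    "common_nodes",
    "build_networks",
    "score_network",
    "degree_ranking",
    "merge_networks",
    "annotate_regulation",
    "overlap_percent",
    "p_from_score",
    "confidence_percent",
]


@dataclass(frozen=True)
class GeneNetwork:
    """A connected focus-gene network with its enrichment score."""

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    seed_gene: str
    score: float
    label: str = ""
    regulation: Mapping[str, str] = field(default_factory=dict)  # node -> up/down/none


@dataclass(frozen=True)
class MergedNetwork:
    """Union of pathway-anchored networks across treatments.

    ``regulation`` keeps one state per source network so that a node that is
    up in one treatment and down in another retains both calls.
    """

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    sources: tuple[str, ...]
    regulation: Mapping[str, Mapping[str, str]]  # node -> {source: state}


def p_from_score(score: float) -> float:
    """Invert the network score convention: score = -log10(p)."""
    return 10.0 ** (-float(score))


def confidence_percent(score: float) -> float:
    """Confidence level 100*(1 - p) implied by a network score."""
    return 100.0 * (1.0 - p_from_score(score))


def common_nodes(focus_sets: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Square matrix of shared focus genes between treatment pairs.

    The diagonal holds each treatment's focus-gene count; off-diagonal
    entries are pairwise intersection sizes.
    """
    if len(focus_sets) < 2:
        raise ValueError("need at least 2 treatments")
    sets = {t: {str(g).upper() for g in genes} for t, genes in focus_sets.items()}
    order = list(focus_sets)
    matrix = np.zeros((len(order), len(order)), dtype=int)
    for i, a in enumerate(order):
        for j, b in enumerate(order):
            matrix[i, j] = len(sets[a] & sets[b])
    return pd.DataFrame(matrix, index=order, columns=order)


def overlap_percent(a: Iterable[str], b: Iterable[str], method: str = "union") -> float:
    """Percent overlap of two gene sets under a stated denominator convention.

    ``method``: "union" (intersection over union), "smaller" (over the
    smaller set) or "mean" (over the mean size).  No single convention is
    canonical for cross-treatment overlap; state the one used when
    reporting.
    """
    sa = {str(g).upper() for g in a}
    sb = {str(g).upper() for g in b}
    inter = len(sa & sb)
    if method == "union":
        denom = len(sa | sb)
    elif method == "smaller":
        denom = min(len(sa), len(sb))
    elif method == "mean":
        denom = (len(sa) + len(sb)) / 2.0
    else:
        raise ValueError(f"unknown method {method!r}")
    return 100.0 * inter / denom if denom else 0.0


def score_network(
    net: GeneNetwork | Iterable[str],
    focus: Iterable[str],
    universe: Iterable[str],
) -> float:
    """-log10 one-tailed Fisher exact p for focus enrichment in the network.

    Scores above 3 correspond to p below 1e-3 (99.9% confidence).
    """
    nodes = {str(g).upper() for g in (net.nodes if isinstance(net, GeneNetwork) else net)}
    fset = {str(g).upper() for g in focus}
    uni = {str(g).upper() for g in universe}
    if not nodes <= uni:
        raise ValueError("network nodes are not a subset of the universe")
    k = len(nodes & fset)
    p = float(stats.hypergeom.sf(k - 1, len(uni), len(fset & uni), len(nodes)))
    p = min(1.0, max(p, 1e-300))
    return float(-np.log10(p))


def build_networks(
    focus: Iterable[str],
    graph: nx.Graph,
    size_cap: int = 35,
    n_networks: int = 3,
) -> list[GeneNetwork]:
    """Grow up to ``n_networks`` connected networks by greedy seeded accretion.

    Each network is seeded at the highest-degree focus gene not covered by a
    previous network, then repeatedly extended with the neighbor maximizing
    (focus-gene gain, graph degree, lexicographically smallest ID) until
    ``size_cap`` nodes or no neighbors remain.  The tie-break order makes
    construction fully deterministic.  Networks never share a seed but may
    share non-seed nodes; results are sorted by score descending.
    """
    fset = {str(g).upper() for g in focus} & set(graph.nodes)
    if not fset:
        warnings.warn("no focus gene appears in the interaction graph", stacklevel=2)
        return []
    universe = set(graph.nodes)
    covered: set[str] = set()
    nets: list[GeneNetwork] = []
    for _ in range(n_networks):
        candidates = sorted(fset - covered, key=lambda g: (-graph.degree(g), g))
        if not candidates:
            break
        seed = candidates[0]
        nodes = {seed}
        while len(nodes) < size_cap:
            neighbors: set[str] = set()
            for u in nodes:
                neighbors.update(graph[u])
            neighbors -= nodes
            if not neighbors:
                break
            best = min(
                neighbors,
                key=lambda g: (-(g in fset), -graph.degree(g), g),
            )
            nodes.add(best)
        edges = frozenset(
            tuple(sorted((u, v))) for u, v in graph.subgraph(nodes).edges()
        )
        nets.append(
            GeneNetwork(
                nodes=frozenset(nodes),
                edges=edges,
                seed_gene=seed,
                score=score_network(nodes, fset, universe),
            )
        )
        covered |= nodes
    nets.sort(key=lambda n: (-n.score, n.seed_gene))
    return nets


def annotate_regulation(net: GeneNetwork, de: pd.DataFrame, label: str | None = None) -> GeneNetwork:
    """Attach per-node up/down regulation states from a DE table.

    Nodes that are not significantly DE get state "none".
    """
    sig = de[de["significant"]]
    directions = {str(g).upper(): d for g, d in zip(sig.index, sig["direction"])}
    regulation = {node: directions.get(node, "none") for node in sorted(net.nodes)}
    return replace(
        net,
        regulation=regulation,
        label=net.label if label is None else label,
    )


def degree_ranking(net: GeneNetwork) -> pd.DataFrame:
    """Rank network nodes by intra-network connection count.

    Only edges inside the network count — a member whose interactions all
    leave the network has degree 0.  Ties break lexicographically.
    """
    degree = {node: 0 for node in net.nodes}
    for u, v in net.edges:
        degree[u] += 1
        degree[v] += 1
    rows = sorted(degree.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        [
            {
                "gene": g,
                "connections": d,
                "regulation": net.regulation.get(g, "none"),
            }
            for g, d in rows
        ],
        columns=["gene", "connections", "regulation"],
    )


def merge_networks(
    nets: Sequence[GeneNetwork], anchor_family: Iterable[str]
) -> MergedNetwork:
    """Union of all networks containing at least one anchor-family member.

    Networks without an anchor member are excluded with a warning.  The
    merged network keeps every source's per-node regulation state keyed by
    the source label (falling back to the seed gene for unlabeled nets).
    """
    anchors = {str(g).upper() for g in anchor_family}
    kept: list[GeneNetwork] = []
    for net in nets:
        if net.nodes & anchors:
            kept.append(net)
        else:
            warnings.warn(
                f"network seeded at {net.seed_gene!r} has no anchor-family "
                "member; excluded from merge",
                stacklevel=2,
            )
    if not kept:
        raise ValueError("no network contains an anchor-family member")
    nodes: set[str] = set()
    edges: set[tuple[str, str]] = set()
    regulation: dict[str, dict[str, str]] = {}
    sources: list[str] = []
    for net in kept:
        source = net.label or net.seed_gene
        sources.append(source)
        nodes |= net.nodes
        edges |= net.edges
        for node, state in net.regulation.items():
            regulation.setdefault(node, {})[source] = state
    return MergedNetwork(
        nodes=frozenset(nodes),
        edges=frozenset(edges),
        sources=tuple(sources),
        regulation=regulation,
    )
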