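"""Interactome analysis: hub metrics, POTSF neighborhood, dense modules.

The interaction network is an undirected simple graph (self-loops and
duplicate/reversed edges are dropped at ingestion).  Per-gene metrics are
degree, clustering coefficient (0 by convention for degree < 2), core
number, and the MCODE vertex weight.  Dense-module detection follows the
published MCODE scheme: vertex weighting by core-density of the closed
neighborhood, seed-and-grow complex prediction with a vertex weight
percentage cutoff, and an optional haircut post-processing step.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .geneset import GeneSetPartition, normalize_symbol


def read_edge_list(path) -> nx.Graph:
    """Read a two-column (optionally scored) TSV edge list into a simple graph.

    Scores are discarded; self-loops and duplicate edges (either orientation)
    are dropped, with counts kept in ``G.graph``.
    """
    G = nx.Graph()
    n_loops = n_dups = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise ValueError(f"malformed edge at line {lineno}: {line!r}")
            a, b = normalize_symbol(parts[0]), normalize_symbol(parts[1])
            if a == b:
                n_loops += 1
                continue
            if G.has_edge(a, b):
                n_dups += 1
                continue
            G.add_edge(a, b)
    G.graph["n_self_loops_dropped"] = n_loops
    G.graph["n_duplicate_edges_dropped"] = n_dups
    return G


def annotate_sets(G: nx.Graph, partition: GeneSetPartition) -> nx.Graph:
    """Attach each node's comparison-set label (NCRG for unknown genes)."""
    for node in G.nodes:
        try:
            label = partition.set_label(node)
        except KeyError:
            label = "NCRG"
        G.nodes[node]["set_label"] = label
    return G


def degree_map(G: nx.Graph) -> dict[str, int]:
    """Number of distinct interaction partners per gene."""
    return dict(G.degree())


def clustering_coefficients(G: nx.Graph) -> dict[str, float]:
    """Local clustering coefficient per gene; 0 for degree < 2 nodes."""
    return {v: float(c) for v, c in nx.clustering(G).items()}


def potsf_neighborhood(
    G: nx.Graph, partition: GeneSetPartition, mode: str = "induced"
) -> nx.Graph:
    """Sub-network of all POTSF genes plus their direct neighbors.

    ``mode="induced"`` (default) keeps every edge among the retained nodes;
    ``mode="star"`` keeps only edges with at least one POTSF endpoint.
    """
    if mode not in ("induced", "star"):
        raise ValueError(f"unknown mode {mode!r}")
    potsf = {g for g in partition.members("POTSF") if g in G}
    nodes = set(potsf)
    for p in potsf:
        nodes.update(G.neighbors(p))
    sub = G.subgraph(nodes).copy()
    if mode == "star":
        drop = [(a, b) for a, b in sub.edges if a not in potsf and b not in potsf]
        sub.remove_edges_from(drop)
    return sub


def mcode_weights(G: nx.Graph) -> dict[str, float]:
    """MCODE vertex weight: density of the highest k-core of the closed
    neighborhood, multiplied by that core's k."""
    weights: dict[str, float] = {}
    for v in G.nodes:
        closed = set(G[v]) | {v}
        H = G.subgraph(closed)
        if H.number_of_edges() == 0:
            weights[v] = 0.0
            continue
        core = nx.core_number(H)
        k = max(core.values())
        core_nodes = [u for u, c in core.items() if c >= k]
        K = H.subgraph(core_nodes)
        weights[v] = k * nx.density(K)
    return weights


def _haircut(sub: nx.Graph) -> nx.Graph:
    """Iteratively strip nodes with fewer than two connections in the complex."""
    sub = sub.copy()
    while True:
        trim = [v for v, d in sub.degree() if d < 2]
        if not trim:
            return sub
        sub.remove_nodes_from(trim)


def mcode_complexes(
    G: nx.Graph,
    vwp: float = 0.2,
    haircut: bool = True,
    fluff: bool = False,
    fluff_density: float = 0.2,
    weights: dict[str, float] | None = None,
) -> list[dict]:
    """Seed-and-grow dense-module detection (MCODE-style).

    Complexes grow breadth-first from the highest-weight unused seed,
    admitting neighbors whose weight is at least ``(1 - vwp)`` times the
    seed weight; each node joins at most one complex.  ``haircut`` prunes
    singly-connected members; ``fluff`` adds unused neighbors whose closed
    neighborhood density exceeds ``fluff_density``.  Results are ranked by
    score = density × size; all ties (seed order, neighbor order, ranking)
    break lexicographically on gene id, so output is independent of node
    insertion order.
    """
    if not 0 <= vwp < 1:
        raise ValueError("vwp must be in [0, 1)")
    if G.number_of_nodes() == 0:
        return []
    w = mcode_weights(G) if weights is None else weights
    order = sorted(G.nodes, key=lambda v: (-w[v], v))
    used: set[str] = set()
    complexes = []
    for seed in order:
        if seed in used or w[seed] <= 0:
            continue
        threshold = (1 - vwp) * w[seed]
        members = {seed}
        frontier = [seed]
        while frontier:
            current = frontier.pop(0)
            for nb in sorted(G[current]):
                if nb in used or nb in members or w[nb] < threshold:
                    continue
                members.add(nb)
                frontier.append(nb)
        used |= members
        sub = G.subgraph(members)
        if fluff:
            extra = set()
            for v in sorted(members):
                for nb in sorted(G[v]):
                    if nb in used or nb in members or nb in extra:
                        continue
                    closed = set(G[nb]) | {nb}
                    if nx.density(G.subgraph(closed)) > fluff_density:
                        extra.add(nb)
            members |= extra
            used |= extra
            sub = G.subgraph(members)
        if haircut:
            sub = _haircut(sub)
        if sub.number_of_nodes() < 2:
            continue
        density = nx.density(sub)
        complexes.append(
            {
                "seed": seed,
                "members": sorted(sub.nodes),
                "size": sub.number_of_nodes(),
                "density": density,
                "score": density * sub.number_of_nodes(),
            }
        )
    complexes.sort(key=lambda c: (-c["score"], -c["size"], c["members"]))
    for rank, c in enumerate(complexes, start=1):
        c["rank"] = rank
    return complexes


def node_metrics(G: nx.Graph, partition: GeneSetPartition | None = None) -> pd.DataFrame:
    """Per-gene degree, clustering coefficient, core number and MCODE weight."""
    degrees = degree_map(G)
    clustering = clustering_coefficients(G)
    cores = nx.core_number(G)
    weights = mcode_weights(G)
    rows = []
    for v in sorted(G.nodes):
        label = None
        if partition is not None:
            try:
                label = partition.set_label(v)
            except KeyError:
                label = "NCRG"
        rows.append(
            {
                "gene": v,
                "set_label": label,
                "degree": degrees[v],
                "clustering": clustering[v],
                "core_number": cores[v],
                "mcode_weight": weights[v],
            }
        )
    df = pd.DataFrame(rows)
    if partition is None:
        df = df.drop(columns=["set_label"])
    return df
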