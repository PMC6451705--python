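"""Per-community interaction networks and greedy modularity clustering.

Each tweet links its author to the users it interacts with: one directed edge
per mentioned user, one to the source user of a retweet, one to the target
user of a reply.  Tweets that interact with nobody contribute a self-loop for
their author.  Parallel interactions of the same type accumulate edge weight.

Clustering follows the Clauset-Newman-Moore (CNM) greedy modularity scheme on
the symmetrized weighted graph with self-loops excluded: start from singleton
clusters and repeatedly merge the pair with the largest modularity gain.  Ties
are broken on the lexicographically smallest cluster-id pair, and a
deterministic local refinement (single-node moves, then cluster merges, until
a fixpoint) follows the agglomeration, so results are reproducible and reach
the modularity optimum on small graphs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .tweet_io import TweetRecord

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionGraph",
    "ClusterPartition",
    "NetworkSummary",
    "build_graph",
    "symmetrized",
    "cluster_graph",
    "greedy_modularity_partition",
    "modularity",
    "summarize_network",
    "write_graphml",
    "write_edge_list",
    "write_partition",
]

EDGE_TYPES = ("mention", "retweet", "reply")

_TOL = 1e-12

# sentinels for the refinement node-move pass
_DETACH = object()
_STAY = object()


@dataclass
class InteractionGraph:
    """Directed, typed, weighted user-interaction multigraph.

    ``graph`` keys parallel edges by interaction type and accumulates
    multiplicity in the ``weight`` attribute.  ``self_loops`` counts, per
    author, the tweets that interacted with nobody.
    """

    graph: nx.MultiDiGraph = field(default_factory=nx.MultiDiGraph)
    self_loops: dict[str, int] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def n_edge_tweets(self) -> int:
        """Total interaction multiplicity (for tweet-conservation checks)."""
        return int(sum(d["weight"] for _, _, d in self.graph.edges(data=True)))


def build_graph(tweets: list[TweetRecord]) -> InteractionGraph:
    """Construct the interaction graph of a corpus.

    Per tweet: an edge author->u for every mentioned user u, author->source
    for a retweet, author->target for a reply.  A tweet producing no edge adds
    one self-loop.  Mentioned users who never authored anything still become
    nodes.
    """
    ig = InteractionGraph()
    g = ig.graph
    for t in tweets:
        targets: list[tuple[str, str]] = [(m, "mention") for m in t.mention_ids]
        if t.is_retweet:
            targets.append((t.source_author_id, "retweet"))
        if t.is_reply:
            targets.append((t.reply_to_user_id, "reply"))
        g.add_node(t.author_id)
        if not targets:
            ig.self_loops[t.author_id] = ig.self_loops.get(t.author_id, 0) + 1
            continue
        for target, etype in targets:
            if g.has_edge(t.author_id, target, key=etype):
                g[t.author_id][target][etype]["weight"] += 1
            else:
                g.add_edge(t.author_id, target, key=etype, weight=1)
    return ig


def symmetrized(ig: InteractionGraph | nx.Graph) -> nx.Graph:
    """Undirected weight-summed view with self-edges removed."""
    if isinstance(ig, nx.Graph) and not ig.is_directed() and not ig.is_multigraph():
        g = nx.Graph()
        g.add_nodes_from(ig.nodes)
        g.add_weighted_edges_from(
            (u, v, d.get("weight", 1)) for u, v, d in ig.edges(data=True) if u != v)
        return g
    graph = ig.graph if isinstance(ig, InteractionGraph) else ig
    g = nx.Graph()
    g.add_nodes_from(graph.nodes)
    for u, v, d in graph.edges(data=True):
        if u == v:
            continue
        w = d.get("weight", 1)
        if g.has_edge(u, v):
            g[u][v]["weight"] += w
        else:
            g.add_edge(u, v, weight=w)
    return g


@dataclass
class ClusterPartition:
    """Node -> cluster assignment with its modularity score."""

    assignment: dict[str, int]
    q: float

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, cid in self.assignment.items():
            out.setdefault(cid, []).append(node)
        return {cid: sorted(nodes) for cid, nodes in sorted(out.items())}


def _labels_to_partition(labels: dict[str, str], q: float) -> ClusterPartition:
    groups: dict[str, list[str]] = {}
    for node, lab in labels.items():
        groups.setdefault(lab, []).append(node)
    # deterministic ids: by size descending, then smallest member
    ordered = sorted(groups.values(), key=lambda ns: (-len(ns), min(ns)))
    assignment = {node: cid for cid, nodes in enumerate(ordered) for node in nodes}
    return ClusterPartition(assignment=assignment, q=q)


def _modularity_from_labels(g: nx.Graph, labels: dict[str, str], m: float) -> float:
    within: dict[str, float] = {}
    strength: dict[str, float] = {}
    for node in g.nodes:
        strength[labels[node]] = strength.get(labels[node], 0.0)
    for u, v, d in g.edges(data=True):
        w = d.get("weight", 1)
        strength[labels[u]] = strength.get(labels[u], 0.0) + w
        strength[labels[v]] = strength.get(labels[v], 0.0) + w
        if labels[u] == labels[v]:
            within[labels[u]] = within.get(labels[u], 0.0) + w
    return sum(within.get(c, 0.0) / m - (s / (2 * m)) ** 2 for c, s in strength.items())


def _cnm_merge(g: nx.Graph, m: float) -> dict[str, str]:
    """Greedy agglomeration: repeatedly merge the best connected pair.

    The full merge path down to one community is explored (the gain sequence
    is not monotone, so stopping at the first non-positive gain can miss the
    peak); the labelling at the highest cumulative modularity is returned.
    """
    labels = {node: node for node in g.nodes}
    strength = {node: float(g.degree(node, weight="weight")) for node in g.nodes}
    conn: dict[str, dict[str, float]] = {node: {} for node in g.nodes}
    for u, v, d in g.edges(data=True):
        w = float(d.get("weight", 1))
        conn[u][v] = conn[u].get(v, 0.0) + w
        conn[v][u] = conn[v].get(u, 0.0) + w
    members: dict[str, list[str]] = {node: [node] for node in g.nodes}
    two_m_sq = 2.0 * m * m
    q = -sum(s * s for s in strength.values()) / (4.0 * m * m)
    best_q, best_labels = q, dict(labels)
    while True:
        best_dq = None
        best_pair: tuple[str, str] | None = None
        for i in sorted(conn):
            for j in sorted(conn[i]):
                if j <= i:
                    continue
                dq = conn[i][j] / m - strength[i] * strength[j] / two_m_sq
                if best_pair is None or dq > best_dq + _TOL:
                    best_dq, best_pair = dq, (i, j)
                elif dq > best_dq - _TOL and (i, j) < best_pair:
                    best_pair = (i, j)
        if best_pair is None:  # no connected pairs left
            break
        i, j = best_pair  # i < j: j folds into i
        q += best_dq
        for k, w in conn[j].items():
            if k == i:
                continue
            conn[i][k] = conn[i].get(k, 0.0) + w
            conn[k][i] = conn[i][k]
            del conn[k][j]
        conn[i].pop(j, None)
        del conn[j]
        strength[i] += strength.pop(j)
        for node in members[j]:
            labels[node] = i
        members[i].extend(members.pop(j))
        if q > best_q + _TOL:
            best_q, best_labels = q, dict(labels)
    return best_labels


def _refine(g: nx.Graph, labels: dict[str, str], m: float) -> dict[str, str]:
    """Deterministic modularity hill-climb: node moves, then cluster merges."""
    strength = {node: float(g.degree(node, weight="weight")) for node in g.nodes}
    comm_strength: dict[str, float] = {}
    for node, lab in labels.items():
        comm_strength[lab] = comm_strength.get(lab, 0.0) + strength[node]

    def canonical(lab: str, nodes_of: dict[str, set]) -> str:
        return min(nodes_of[lab])

    nodes_of: dict[str, set] = {}
    for node, lab in labels.items():
        nodes_of.setdefault(lab, set()).add(node)

    changed = True
    while changed:
        changed = False
        # pass 1: single-node moves
        moved = True
        while moved:
            moved = False
            for v in sorted(g.nodes):
                c = labels[v]
                k_v = strength[v]
                w_to: dict[str, float] = {}
                for u, d in g[v].items():
                    if u == v:
                        continue
                    w_to[labels[u]] = w_to.get(labels[u], 0.0) + float(d.get("weight", 1))
                w_vc = w_to.get(c, 0.0)
                candidates: list[tuple] = sorted(w_to.items())
                if len(nodes_of[c]) > 1:
                    candidates.append((_DETACH, 0.0))  # leave into a singleton
                best_gain, best_d = _TOL, _STAY
                for d_lab, w_vd in candidates:
                    if d_lab == c:
                        continue
                    s_d = 0.0 if d_lab is _DETACH else comm_strength[d_lab]
                    gain = (w_vd - w_vc) / m - k_v * (
                        s_d - comm_strength[c] + k_v) / (2.0 * m * m)
                    if gain > best_gain + _TOL:
                        best_gain, best_d = gain, d_lab
                if best_d is _STAY:
                    continue
                nodes_of[c].discard(v)
                comm_strength[c] -= k_v
                if not nodes_of[c]:
                    del nodes_of[c], comm_strength[c]
                if best_d is _DETACH:
                    best_d = f"\x00detached:{v}"  # fresh label, sorts before node ids
                    nodes_of[best_d] = set()
                    comm_strength[best_d] = 0.0
                nodes_of[best_d].add(v)
                comm_strength[best_d] += k_v
                labels[v] = best_d
                moved = changed = True
        # pass 2: best single cluster merge
        between: dict[tuple[str, str], float] = {}
        for u, v, d in g.edges(data=True):
            cu, cv = labels[u], labels[v]
            if cu == cv:
                continue
            key = (min(cu, cv), max(cu, cv))
            between[key] = between.get(key, 0.0) + float(d.get("weight", 1))
        best_gain, best_pair = _TOL, None
        for (ci, cj), w in sorted(between.items()):
            gain = w / m - comm_strength[ci] * comm_strength[cj] / (2.0 * m * m)
            if gain > best_gain + _TOL:
                best_gain, best_pair = gain, (ci, cj)
        if best_pair is not None:
            ci, cj = best_pair
            for node in nodes_of[cj]:
                labels[node] = ci
            nodes_of[ci] |= nodes_of.pop(cj)
            comm_strength[ci] += comm_strength.pop(cj)
            changed = True
    # relabel by smallest member for stability
    return {node: canonical(lab, nodes_of) for node, lab in labels.items()}


def _exact_partition(g: nx.Graph, m: float) -> dict[str, str]:
    """Globally optimal modularity partition by canonical set-partition search.

    Only viable for very small graphs (Bell(8) = 4140 partitions); used so
    tiny graphs get the true optimum rather than a greedy approximation.
    """
    nodes = sorted(g.nodes)
    best_q = float("-inf")
    best_groups: list[list[str]] | None = None
    groups: list[list[str]] = []

    def rec(i: int) -> None:
        nonlocal best_q, best_groups
        if i == len(nodes):
            labels = {n: grp[0] for grp in groups for n in grp}
            q = _modularity_from_labels(g, labels, m)
            if q > best_q + _TOL:
                best_q, best_groups = q, [list(grp) for grp in groups]
            return
        for grp in groups:
            grp.append(nodes[i])
            rec(i + 1)
            grp.pop()
        groups.append([nodes[i]])
        rec(i + 1)
        groups.pop()

    rec(0)
    assert best_groups is not None
    return {n: grp[0] for grp in best_groups for n in grp}


def greedy_modularity_partition(
    g: nx.Graph, refine: bool = True, exact_max_nodes: int = 8
) -> ClusterPartition:
    """Modularity clustering of an undirected weighted graph.

    Graphs with at most ``exact_max_nodes`` nodes are solved exactly by
    enumeration; larger graphs use CNM greedy agglomeration plus a
    deterministic refinement (see module docstring).
    """
    if g.number_of_nodes() == 0:
        return ClusterPartition(assignment={}, q=0.0)
    m = float(g.size(weight="weight"))
    if m == 0:
        logger.warning("greedy_modularity_partition: edgeless graph; q=0 (degenerate)")
        labels = {node: node for node in g.nodes}
        return _labels_to_partition(labels, 0.0)
    if g.number_of_nodes() <= exact_max_nodes:
        labels = _exact_partition(g, m)
        return _labels_to_partition(labels, _modularity_from_labels(g, labels, m))
    labels = _cnm_merge(g, m)
    if refine:
        labels = _refine(g, labels, m)
        # second deterministic start: hill-climb from singletons; the
        # agglomerative path sometimes overshoots into a merge no sequence of
        # single-node moves can undo
        alt = _refine(g, {node: node for node in g.nodes}, m)
        if _modularity_from_labels(g, alt, m) > _modularity_from_labels(g, labels, m) + _TOL:
            labels = alt
    q = _modularity_from_labels(g, labels, m)
    return _labels_to_partition(labels, q)


def cluster_graph(ig: InteractionGraph | nx.Graph, refine: bool = True) -> ClusterPartition:
    """Cluster an interaction graph (symmetrized, self-loops excluded)."""
    return greedy_modularity_partition(symmetrized(ig), refine=refine)


def modularity(ig: InteractionGraph | nx.Graph, partition: ClusterPartition | dict) -> float:
    """Newman-Girvan Q = sum_c (e_cc - a_c^2) on the symmetrized graph."""
    g = symmetrized(ig)
    assignment = partition.assignment if isinstance(partition, ClusterPartition) else partition
    if set(assignment) != set(g.nodes):
        raise ValueError("modularity: partition does not cover the graph")
    m = float(g.size(weight="weight"))
    if m == 0:
        return 0.0
    labels = {node: str(cid) for node, cid in assignment.items()}
    return _modularity_from_labels(g, labels, m)


@dataclass
class NetworkSummary:
    """Structural digest of one community's interaction graph."""

    n_nodes: int
    n_edges: int
    isolate_fraction: float
    cluster_sizes: list[int]
    cluster_table: pd.DataFrame
    q: float


def summarize_network(
    ig: InteractionGraph, partition: ClusterPartition, hub_threshold: float = 0.5
) -> NetworkSummary:
    """Numeric structure summary: isolates, cluster sizes, hub concentration.

    ``hub_concentration`` of a cluster is the largest within-cluster weighted
    in-degree divided by the total within-cluster edge weight; clusters above
    ``hub_threshold`` are labelled broadcast-like (hub-and-spoke), following
    the usual broadcast vs community-clusters network typology.
    """
    g = ig.graph
    interacting = {u for u, v in g.edges() if u != v} | {v for u, v in g.edges() if u != v}
    isolates = [n for n in g.nodes if n not in interacting]
    clusters = partition.clusters()
    rows = []
    for cid, nodes in clusters.items():
        node_set = set(nodes)
        in_w: dict[str, float] = {}
        total_w = 0.0
        for u, v, d in g.edges(data=True):
            if u != v and u in node_set and v in node_set:
                w = float(d.get("weight", 1))
                in_w[v] = in_w.get(v, 0.0) + w
                total_w += w
        hub = max(in_w.values()) / total_w if total_w > 0 else 0.0
        rows.append({
            "cluster": cid,
            "size": len(nodes),
            "hub_concentration": hub,
            "broadcast_like": bool(hub > hub_threshold and total_w > 0),
        })
    table = pd.DataFrame(rows, columns=["cluster", "size", "hub_concentration",
                                        "broadcast_like"])
    sizes = sorted((len(nodes) for nodes in clusters.values()), reverse=True)
    return NetworkSummary(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        isolate_fraction=len(isolates) / g.number_of_nodes() if g.number_of_nodes() else 0.0,
        cluster_sizes=sizes,
        cluster_table=table,
        q=partition.q,
    )


def write_graphml(ig: InteractionGraph, path: str | Path) -> None:
    g = ig.graph.copy()
    for node, count in ig.self_loops.items():
        g.nodes[node]["self_loop_tweets"] = count
    nx.write_graphml(g, str(path))


def write_edge_list(ig: InteractionGraph, path: str | Path) -> None:
    """TSV edge list: source, target, type, weight (sorted, deterministic)."""
    rows = sorted((u, v, k, d["weight"]) for u, v, k, d in ig.graph.edges(keys=True, data=True))
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("source\ttarget\ttype\tweight\n")
        for u, v, k, w in rows:
            fh.write(f"{u}\t{v}\t{k}\t{w}\n")


def write_partition(partition: ClusterPartition, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("node,cluster\n")
        for node in sorted(partition.assignment):
            fh.write(f"{node},{partition.assignment[node]}\n")
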