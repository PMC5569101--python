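"""Analysis-subgraph extraction and degree-1 compaction of influence graphs.

The analysis graph is carved out of a large signed network by keeping the
union of all shortest directed paths from a set of source pathway nodes to
the observed (variant) genes, then compacted by contracting unobserved
nodes with a single predecessor or successor, composing edge signs along
the contracted path.  Compaction loses no information with respect to the
coloring model: the contracted node's sign is recoverable from its
neighbours, and the projections of retained nodes are unchanged (this is
enforced by a property test rather than assumed).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Dict, Iterable, List, Set, Tuple

import networkx as nx

from .core import Sign, SignedGraph, compose_signs


@dataclass(frozen=True)
class ExtractionResult:
    """Subgraph spanned by shortest source->target paths, plus dropped targets."""

    graph: SignedGraph
    unreachable: Tuple[str, ...]


def _bfs_distances(adj: Dict[str, Set[str]], starts: Iterable[str]) -> Dict[str, int]:
    dist = {s: 0 for s in starts}
    queue = deque(sorted(dist))
    while queue:
        u = queue.popleft()
        for v in sorted(adj.get(u, ())):
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def extract_subgraph(
    graph: SignedGraph, sources: Iterable[str], targets: Iterable[str]
) -> ExtractionResult:
    """Union of all shortest directed paths from any source to each target.

    Path length is the unweighted edge count, minimized over the whole
    source set; all tied shortest paths are kept (no arbitrary witness).
    Unreachable targets are dropped and reported.  Edge signs and node
    roles are preserved; inputs of the subgraph are recomputed as its
    predecessor-free nodes.
    """
    sources = sorted({str(s) for s in sources})
    targets = sorted({str(t) for t in targets})
    if not sources:
        raise ValueError("extract_subgraph requires at least one source node")
    for n in sources + targets:
        if n not in graph:
            raise ValueError(f"unknown node {n!r}")

    fwd: Dict[str, Set[str]] = {}
    rev: Dict[str, Set[str]] = {}
    for u, v, _ in graph.edges:
        fwd.setdefault(u, set()).add(v)
        rev.setdefault(v, set()).add(u)

    dist = _bfs_distances(fwd, sources)
    keep_nodes: Set[str] = set()
    keep_pairs: Set[Tuple[str, str]] = set()
    unreachable: List[str] = []
    for t in targets:
        if t not in dist:
            unreachable.append(t)
            continue
        rdist = _bfs_distances(rev, [t])
        d = dist[t]
        for n, dn in dist.items():
            if n in rdist and dn + rdist[n] == d:
                keep_nodes.add(n)
        for u, v, _ in graph.edges:
            if u in dist and v in rdist and dist[u] + 1 + rdist[v] == d:
                keep_pairs.add((u, v))

    edges = [(u, v, s) for u, v, s in graph.edges if (u, v) in keep_pairs]
    roles = {n: graph.roles[n] for n in keep_nodes}
    sub = SignedGraph(edges, roles)
    return ExtractionResult(sub, tuple(unreachable))


def compact(graph: SignedGraph, observed: Iterable[str]) -> SignedGraph:
    """Contract unobserved nodes with in-degree 1 or out-degree 1 to fixpoint.

    Each removed node's in/out edge pairs are rewired with composed signs
    (double inhibition activates).  Declared inputs and observed nodes are
    never removed; a contraction that would create a self-loop is skipped,
    as are nodes that already carry one.  Nodes are processed in sorted-id
    order per sweep for reproducible output.
    """
    observed = {str(n) for n in observed}
    unknown = observed - graph.nodes
    if unknown:
        raise ValueError(f"observed nodes absent from graph: {sorted(unknown)[:5]}")
    protected = observed | set(graph.inputs)

    edges: Set[Tuple[str, str, Sign]] = set(graph.edges)
    nodes: Set[str] = set(graph.nodes)

    def in_edges(v):
        return [(u, s) for u, w, s in edges if w == v]

    def out_edges(v):
        return [(w, s) for u, w, s in edges if u == v]

    changed = True
    while changed:
        changed = False
        for v in sorted(nodes):
            if v in protected:
                continue
            ins = in_edges(v)
            outs = out_edges(v)
            if len(ins) != 1 and len(outs) != 1:
                continue
            if any(u == v for u, _ in ins):  # self-loop on v
                continue
            if any((p, q) for p, _ in ins for q, _ in outs if p == q):
                continue  # contraction would create a self-loop
            nodes.discard(v)
            for p, a in ins:
                edges.discard((p, v, a))
            for q, b in outs:
                edges.discard((v, q, b))
            for p, a in ins:
                for q, b in outs:
                    edges.add((p, q, compose_signs(a, b)))
            changed = True

    roles = {n: graph.roles[n] for n in nodes}
    inputs = graph.inputs & nodes
    return SignedGraph(sorted(edges), roles, inputs)


def count_connected_genes(
    graph: SignedGraph, node: str, observed: Iterable[str]
) -> Tuple[int, int]:
    """Observed genes reachable downstream of ``node``, with the observed total.

    Returned as ``(downstream, total_observed)``, the numerator/denominator
    of the connectivity ratio reported alongside node signatures.  The node
    itself is never counted, even when it lies on a cycle.
    """
    if node not in graph:
        raise ValueError(f"unknown node {node!r}")
    observed = {str(n) for n in observed} & graph.nodes
    g = graph.to_digraph()
    downstream = nx.descendants(g, node) & observed
    return len(downstream), len(observed)
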