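"""Shared helpers: hand-built splicing graphs and random weighted DAGs."""

import networkx as nx
import numpy as np

from isoweave import SplicingGraph, augment_source_sink


def make_graph(vertices, edges, augment=True) -> SplicingGraph:
    """vertices: {vid: (seq, w)}; edges: [(u, v, w)]."""
    g = nx.DiGraph()
    for vid, (seq, w) in vertices.items():
        g.add_node(vid, seq=seq, w=w)
    for u, v, w in edges:
        g.add_edge(u, v, w=w, ctx="", boundary=0)
    graph = SplicingGraph(g=g, locus_id=0)
    if augment:
        augment_source_sink(graph)
    return graph


def random_dag(rng: np.random.Generator, max_vertices: int = 10) -> SplicingGraph:
    """A random weighted DAG (edges only forward in vertex order), with
    virtual source/sink attached via the production augmentation rule."""
    n = int(rng.integers(1, max_vertices + 1))
    p = rng.uniform(0.2, 0.7)
    vertices = {}
    for v in range(n):
        seq_len = int(rng.integers(1, 200))
        vertices[v] = ("A" * seq_len, float(np.round(rng.uniform(0.5, 10.0), 3)))
    edges = []
    for u in range(n):
        for v in range(u + 1, n):
            if rng.random() < p:
                edges.append((u, v, float(np.round(rng.uniform(0.5, 10.0), 3))))
    return make_graph(vertices, edges)


def brute_force_paths(graph) -> set[tuple[int, ...]]:
    """All s->t vid sequences via networkx (independent of the DFS)."""
    return {tuple(p) for p in nx.all_simple_paths(graph.g, graph.s, graph.t)}


def brute_force_capacity(graph) -> float:
    """Max over all s->t paths of the min vertex/edge weight."""
    best = 0.0
    for p in nx.all_simple_paths(graph.g, graph.s, graph.t):
        vals = [graph.g.edges[u, v]["w"] for u, v in zip(p, p[1:])]
        vals += [graph.g.nodes[v]["w"] for v in p if v not in (graph.s, graph.t)]
        best = max(best, min(vals))
    return best
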