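"""Transcript-representing path extraction from splicing graphs.

Two strategies are offered:

* **Enumeration**: every s->t path is listed by an explicit-stack
  depth-first search (children in ascending vertex order). Sound when
  each locus has few s->t paths; a per-locus cap guards the exponential
  worst case by falling back to the hybrid strategy.
* **Hybrid (length x coverage)**: a dynamic program computes, for every
  vertex v in topological order, capacity(v) -- the best achievable
  bottleneck (max over s->v paths of the minimum vertex/edge weight along
  the path) -- with predecessor ties broken towards the longest path
  (then fewest edges, then smallest vid). Backtracking the predecessors
  from t yields the longest-among-thickest path; its bottleneck coverage
  is then peeled off the graph and the process repeats until all edges
  are covered, the bottleneck falls below a stop threshold, or |E| paths
  have been extracted.

Both outputs pass the same transcript filters: minimum length, minimum
bottleneck coverage, minimum number of exactly-mapped reads and (for
paired data) full fragment coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .assembly_graph import SplicingGraph
from .reads_io import AssemblyParams, UniqueRead

logger = logging.getLogger("isoweave")

_EPS = 1e-12


@dataclass
class TranscriptPath:
    """An s->t path with its spelled sequence and bottleneck coverage."""

    vids: list[int]
    sequence: str
    path_cov: float
    locus_id: int = 0

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class DPState:
    capacity: dict[int, float]
    pred: dict[int, int | None]
    plen: dict[int, int]
    n_edges: dict[int, int] = field(default_factory=dict)


def _spell(graph: SplicingGraph, vids: Sequence[int]) -> str:
    return "".join(graph.g.nodes[v]["seq"] for v in vids)


def _path_cov(graph: SplicingGraph, vids: Sequence[int]) -> float:
    """Minimum weight among the path's edges and non-virtual vertices."""
    g = graph.g
    vals = [g.edges[u, v]["w"] for u, v in zip(vids, vids[1:])]
    vals += [g.nodes[v]["w"] for v in vids if v not in (graph.s, graph.t)]
    return min(vals) if vals else 0.0


def _make_path(graph: SplicingGraph, vids: list[int]) -> TranscriptPath:
    return TranscriptPath(vids=vids, sequence=_spell(graph, vids),
                          path_cov=_path_cov(graph, vids),
                          locus_id=graph.locus_id)


def enumerate_paths(graph: SplicingGraph, max_paths: int | None = None) -> list[TranscriptPath]:
    """All distinct s->t paths in depth-first order (children by
    ascending vid), each emitted exactly once.

    Raises :class:`PathExplosion` if more than ``max_paths`` paths exist.
    """
    g, s, t = graph.g, graph.s, graph.t
    if s not in g or t not in g:
        logger.warning("locus %d: graph lacks s/t, no paths", graph.locus_id)
        return []
    out: list[TranscriptPath] = []
    # stack of (vertex, iterator over successors); the path is the stack
    path = [s]
    iters = [iter(sorted(g.successors(s)))]
    while iters:
        try:
            nxt = next(iters[-1])
        except StopIteration:
            iters.pop()
            path.pop()
            continue
        if nxt == t:
            out.append(_make_path(graph, path + [t]))
            if max_paths is not None and len(out) > max_paths:
                raise PathExplosion(len(out))
            continue
        path.append(nxt)
        iters.append(iter(sorted(g.successors(nxt))))
    if not out:
        logger.warning("locus %d: sink unreachable from source", graph.locus_id)
    return out


class PathExplosion(RuntimeError):
    """Raised when a locus exceeds the enumeration path cap."""


def compute_capacities(graph: SplicingGraph) -> DPState:
    """Bottleneck DP over the DAG in topological order.

    capacity(v) = max over in-edges (u,v) of
    min(capacity(u), w(u,v), w(v)); the maximising predecessor is kept,
    preferring (on capacity ties) the longer path from s, then the one
    with fewer edges, then the smaller vid. capacity(s) = w(s).
    """
    g, s, t = graph.g, graph.s, graph.t
    order = _topo_order(graph)
    cap = {v: 0.0 for v in g.nodes}
    pred: dict[int, int | None] = {v: None for v in g.nodes}
    plen = {v: 0 for v in g.nodes}
    nedge = {v: 0 for v in g.nodes}
    cap[s] = g.nodes[s]["w"]
    for v in order:
        if v == s:
            continue
        best = None
        for u in g.predecessors(v):
            if pred[u] is None and u != s:
                continue  # unreachable predecessor
            c = min(cap[u], g.edges[u, v]["w"], g.nodes[v]["w"])
            key = (c, plen[u], -nedge[u], -u)
            if best is None or key > best[0]:
                best = (key, u, c)
        if best is not None:
            _, u, c = best
            cap[v], pred[v] = c, u
            plen[v] = plen[u] + len(g.nodes[v]["seq"])
            nedge[v] = nedge[u] + 1
    return DPState(capacity=cap, pred=pred, plen=plen, n_edges=nedge)


def _topo_order(graph: SplicingGraph) -> list[int]:
    """Kahn's algorithm with a smallest-vid tie-break (deterministic)."""
    import heapq

    g = graph.g
    indeg = {v: g.in_degree(v) for v in g.nodes}
    heap = [v for v in g.nodes if indeg[v] == 0]
    heapq.heapify(heap)
    order = []
    while heap:
        v = heapq.heappop(heap)
        order.append(v)
        for w in g.successors(v):
            indeg[w] -= 1
            if indeg[w] == 0:
                heapq.heappush(heap, w)
    if len(order) != g.number_of_nodes():
        raise ValueError("splicing graph contains a cycle")
    return order


def extract_hybrid_path(graph: SplicingGraph, state: DPState) -> TranscriptPath | None:
    """Backtrack the predecessor chain from t; None if capacity(t) = 0."""
    if state.capacity.get(graph.t, 0.0) <= _EPS or state.pred.get(graph.t) is None:
        return None
    vids = [graph.t]
    while vids[-1] != graph.s:
        p = state.pred[vids[-1]]
        if p is None:
            return None
        vids.append(p)
    vids.reverse()
    path = _make_path(graph, vids)
    assert abs(path.path_cov - state.capacity[graph.t]) < 1e-9 * max(
        1.0, state.capacity[graph.t]
    ), "backtracked path does not attain capacity(t)"
    return path


def peel_path(graph: SplicingGraph, path: TranscriptPath) -> SplicingGraph:
    """Subtract the path's bottleneck coverage from every vertex and edge
    along it (floored at zero), then restore the source/sink weight
    identities; edges at zero weight count as covered."""
    g = graph.g
    c = path.path_cov
    for v in path.vids:
        if v not in (graph.s, graph.t):
            g.nodes[v]["w"] = max(0.0, g.nodes[v]["w"] - c)
    for u, v in zip(path.vids, path.vids[1:]):
        g.edges[u, v]["w"] = max(0.0, g.edges[u, v]["w"] - c)
    g.nodes[graph.s]["w"] = sum(d["w"] for _, _, d in g.out_edges(graph.s, data=True))
    g.nodes[graph.t]["w"] = sum(d["w"] for _, _, d in g.in_edges(graph.t, data=True))
    return graph


def hybrid_extract_all(graph: SplicingGraph, params: AssemblyParams) -> list[TranscriptPath]:
    """Iterate {capacities, backtrack, peel} until every edge is covered,
    the bottleneck drops below ``hybrid_stop_cov``, or |E| paths have
    been extracted. The graph's weights are consumed; callers needing the
    original weights should re-run ``assign_weights`` afterwards."""
    g = graph.g
    n_edges = g.number_of_edges()
    covered = {e for e in g.edges if g.edges[e]["w"] <= _EPS}
    out: list[TranscriptPath] = []
    while len(out) < n_edges:
        if len(covered) == n_edges:
            break
        state = compute_capacities(graph)
        if state.capacity.get(graph.t, 0.0) < params.hybrid_stop_cov:
            break
        path = extract_hybrid_path(graph, state)
        if path is None:
            break
        out.append(path)
        peel_path(graph, path)
        for e in zip(path.vids, path.vids[1:]):
            if g.edges[e]["w"] <= _EPS:
                covered.add(e)
    return out


def map_read_positions(transcript: str, read_seq: str) -> list[int]:
    """All exact occurrence positions of a read in the transcript."""
    out, i = [], transcript.find(read_seq)
    while i != -1:
        out.append(i)
        i = transcript.find(read_seq, i + 1)
    return out


def filter_transcripts(
    paths: Sequence[TranscriptPath],
    reads: Sequence[UniqueRead],
    params: AssemblyParams,
    paired: bool = False,
    mate_pairs: Sequence[tuple[int, int]] | None = None,
) -> list[TranscriptPath]:
    """Reject fake transcript candidates.

    Kept paths satisfy all of: (i) length strictly above
    ``min_transcript_len``; (ii) bottleneck coverage strictly above
    ``min_transcript_cov``; (iii) at least ``min_mapped_reads`` reads
    (multiplicities summed) occur exactly in the sequence; (iv) with
    paired data, every base covered by a mapped read or by the span of a
    consistently mapped mate pair.
    """
    kept = []
    for p in paths:
        if p.length <= params.min_transcript_len:
            continue
        if p.path_cov <= params.min_transcript_cov:
            continue
        hits = {r.uid: map_read_positions(p.sequence, r.sequence) for r in reads}
        mapped = sum(reads[uid].multiplicity for uid, pos in hits.items() if pos)
        if mapped < params.min_mapped_reads:
            continue
        if paired and not _fragment_covered(p, reads, hits, mate_pairs):
            continue
        kept.append(p)
    return kept


def _fragment_covered(path, reads, hits, mate_pairs) -> bool:
    """Every transcript base inside some mapped fragment interval: a
    single mapped read, or the closest co-mapped mate-pair span."""
    n = path.length
    cov = [False] * n
    for uid, positions in hits.items():
        for pos in positions:
            for i in range(pos, min(n, pos + len(reads[uid].sequence))):
                cov[i] = True
    for a, b in mate_pairs or []:
        pa, pb = hits.get(a, []), hits.get(b, [])
        for p1 in pa:
            downstream = [p2 for p2 in pb if p2 >= p1]
            if downstream:
                p2 = min(downstream)
                for i in range(p1, min(n, p2 + len(reads[b].sequence))):
                    cov[i] = True
    return all(cov)


def extract_transcripts(
    graph: SplicingGraph,
    params: AssemblyParams,
    strategy: str = "enum",
) -> list[TranscriptPath]:
    """Run one extraction strategy on one locus (filters not applied).

    With ``strategy='enum'``, a locus whose path count exceeds
    ``params.max_enum_paths`` falls back to the hybrid strategy.
    """
    if strategy == "enum":
        try:
            return enumerate_paths(graph, max_paths=params.max_enum_paths)
        except PathExplosion:
            logger.warning(
                "locus %d: more than %d s-t paths, falling back to hybrid",
                graph.locus_id, params.max_enum_paths)
            strategy = "hybrid"
    if strategy != "hybrid":
        raise ValueError(f"unknown strategy {strategy!r}")
    return hybrid_extract_all(graph, params)
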