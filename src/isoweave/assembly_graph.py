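"""Contig extension and splicing-graph construction.

Assembly proceeds locus by locus from seed reads:

1. Reads whose multiplicity exceeds the mean are *seeds* (high-coverage
   reads are least likely to be erroneous). An unused seed becomes the
   main contig, which is extended rightwards via the REST and then
   leftwards via the LEST, always by the candidate read with the longest
   terminal overlap; among equally-deep candidates the one whose
   multiplicity is closest to the contig's coverage wins.
2. Candidates seen but not chosen are *divergence points*: each seeds a
   branch contig grown away from its anchor. A branch that incorporates a
   read already placed in a main contig *converges* there, closing an
   alternative-splicing bubble (e.g. an exon-skipping event).
3. Divergence/convergence coordinates cut the contigs into maximal
   unbranched segments; segments become splicing-graph vertices, with
   edges wherever a read (or mate pair) spans the junction. Vertices and
   edges are weighted in reads per base.

The splicing graph is a DAG; a virtual source s and sink t are attached
so transcript candidates are exactly s->t paths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from .overlap_index import OverlapHit, OverlapIndex, build_index
from .reads_io import AssemblyParams, RawRead, UniqueRead

logger = logging.getLogger("isoweave")

S_VID = -1
T_VID = -2


# ---------------------------------------------------------------------------
# contigs


@dataclass
class Divergence:
    """A candidate read seen at an extension step but not chosen.

    ``pos`` is a coordinate on the final contig: for a rightward step the
    end of the terminus at that step (the branch's anchor overlap is
    ``contig[pos-x:pos]``); for a leftward step the left edge (anchor is
    ``contig[pos:pos+x]``).
    """

    side: str  # 'right' | 'left'
    pos: int
    uid: int
    x: int


@dataclass
class Branch:
    main_cid: int
    side: str
    pos: int
    x: int
    sequence: str
    members: list[tuple[int, int]]
    # convergence: (cid, offset_in_that_contig, offset_in_branch) of the
    # first branch read found already placed in a main contig
    conv: tuple[int, int, int] | None = None


@dataclass
class Contig:
    cid: int
    sequence: str
    members: list[tuple[int, int]] = field(default_factory=list)
    divergences: list[Divergence] = field(default_factory=list)
    branches: list[Branch] | None = None  # None = not grown yet

    def coverage(self, reads: Sequence[UniqueRead]) -> float:
        """Total member read-bases divided by contig length."""
        total = sum(reads[uid].multiplicity * len(reads[uid].sequence)
                    for uid, _ in self.members)
        return total / len(self.sequence) if self.sequence else 0.0

    def support(self, reads: Sequence[UniqueRead]) -> np.ndarray:
        """Per-base count of member reads covering each position."""
        prof = np.zeros(len(self.sequence), dtype=int)
        for uid, off in self.members:
            prof[off:off + len(reads[uid].sequence)] += 1
        return prof


def select_seeds(reads: Sequence[UniqueRead],
                 params: AssemblyParams | None = None) -> list[int]:
    """Uids whose multiplicity strictly exceeds the mean, highest first
    (ties by uid). If nothing exceeds the mean (duplicate-free data) or
    ``seed_cov_mode == 'all'``, every uid is a seed in uid order."""
    mode = params.seed_cov_mode if params is not None else "above_mean"
    if mode == "above_mean":
        mean = sum(r.multiplicity for r in reads) / len(reads)
        seeds = [r.uid for r in reads if r.multiplicity > mean]
        if seeds:
            mult = {r.uid: r.multiplicity for r in reads}
            seeds.sort(key=lambda u: (-mult[u], u))
            return seeds
    return sorted(r.uid for r in reads)


def choose_candidate(hit: OverlapHit, contig, reads: Sequence[UniqueRead]) -> int:
    """The candidate whose multiplicity is closest to the contig coverage;
    ties go to the smaller multiplicity, then the smaller uid."""
    if not hit.read_uids:
        raise ValueError("choose_candidate on an empty hit")
    cov = contig.coverage(reads) if isinstance(contig, Contig) else float(contig)
    return min(
        hit.read_uids,
        key=lambda u: (abs(reads[u].multiplicity - cov), reads[u].multiplicity, u),
    )


def _branch_coverage(members, reads, length) -> float:
    total = sum(reads[uid].multiplicity * len(reads[uid].sequence)
                for uid, _ in members)
    return total / length if length else 0.0


def extend_contig(
    seed_uid: int,
    index: OverlapIndex,
    reads: Sequence[UniqueRead] | None = None,
    params: AssemblyParams | None = None,
    used: set[int] | None = None,
    cid: int = 0,
) -> Contig:
    """Extend a seed read into a contig, rightwards then leftwards.

    Each step queries the matching tree for the reads with the longest
    (>= l) overlap with the terminus, picks one candidate and splices in
    its non-overlapping part. A direction stops when no candidate exists
    or the chosen read is already placed in this contig. Every
    incorporated uid is added to ``used`` (ineligible as a later seed);
    unchosen candidates are recorded as divergence points.
    """
    reads = index.reads if reads is None else reads
    params = index.params if params is None else params
    contig = Contig(cid=cid, sequence=reads[seed_uid].sequence,
                    members=[(seed_uid, 0)])
    placed = {seed_uid}
    divs: list[Divergence] = []

    # rightwards: candidate prefixes overlap the 3' terminus
    while True:
        hit = index.query_right(contig.sequence)
        if not hit:
            break
        uid = choose_candidate(hit, contig, reads)
        x = hit.overlap_len
        for u in hit.read_uids:
            if u != uid:
                divs.append(Divergence("right", len(contig.sequence), u, x))
        if uid in placed:
            break
        r = reads[uid].sequence
        assert contig.sequence[-x:] == r[:x], "overlap mismatch during extension"
        contig.members.append((uid, len(contig.sequence) - x))
        contig.sequence += r[x:]
        placed.add(uid)

    # leftwards: candidate suffixes overlap the 5' terminus
    while True:
        hit = index.query_left(contig.sequence)
        if not hit:
            break
        uid = choose_candidate(hit, contig, reads)
        x = hit.overlap_len
        for u in hit.read_uids:
            if u != uid:
                divs.append(Divergence("left", 0, u, x))
        if uid in placed:
            break
        r = reads[uid].sequence
        assert contig.sequence[:x] == r[-x:], "overlap mismatch during extension"
        delta = len(r) - x
        contig.sequence = r[:delta] + contig.sequence
        contig.members = [(u, o + delta) for u, o in contig.members]
        for d in divs:
            d.pos += delta
        contig.members.append((uid, 0))
        placed.add(uid)

    contig.members.sort(key=lambda m: (m[1], m[0]))
    contig.divergences = divs
    if used is not None:
        used.update(placed)
    return contig


def grow_branches(
    contig: Contig,
    index: OverlapIndex,
    used: set[int] | None = None,
    main_placements: dict[int, tuple[int, int]] | None = None,
) -> list[Branch]:
    """Grow a branch contig from each divergence point of ``contig``.

    A branch starts as its divergence read and is extended only away from
    the anchor. It stops when extension fails, when a read would repeat
    within the branch, or when the chosen read is already placed in a
    main contig (convergence; the read is still placed in the branch so
    the exact convergence coordinate can be recovered). Divergence reads
    already placed anywhere are skipped: their junction is captured by an
    earlier branch.
    """
    reads, params = index.reads, index.params
    if main_placements is None:
        main_placements = {uid: (contig.cid, off) for uid, off in contig.members}
    placed_anywhere = set(main_placements)
    branches: list[Branch] = []
    for div in contig.divergences:
        if div.uid in placed_anywhere:
            continue
        seq = reads[div.uid].sequence
        members = [(div.uid, 0)]
        in_branch = {div.uid}
        conv = None
        while True:
            if div.side == "right":
                hit = index.query_right(seq)
            else:
                hit = index.query_left(seq)
            if not hit:
                break
            uid = choose_candidate(
                hit, _branch_coverage(members, reads, len(seq)), reads)
            if uid in in_branch:
                break
            x = hit.overlap_len
            r = reads[uid].sequence
            if div.side == "right":
                off = len(seq) - x
                assert seq[-x:] == r[:x]
                seq += r[x:]
            else:
                assert seq[:x] == r[-x:]
                delta = len(r) - x
                seq = r[:delta] + seq
                members = [(u, o + delta) for u, o in members]
                off = 0
            members.append((uid, off))
            in_branch.add(uid)
            owner = main_placements.get(uid)
            if owner is not None:
                conv = (owner[0], owner[1], off)
                break
        members.sort(key=lambda m: (m[1], m[0]))
        branches.append(Branch(main_cid=contig.cid, side=div.side, pos=div.pos,
                               x=div.x, sequence=seq, members=members, conv=conv))
        placed_anywhere.update(in_branch)
        if used is not None:
            used.update(in_branch)
    contig.branches = branches
    return branches


# ---------------------------------------------------------------------------
# splicing graphs


@dataclass
class SpliceVertex:
    vid: int
    sequence: str
    w: float


@dataclass
class SplicingGraph:
    """Weighted splicing DAG of one locus; ``g`` is a networkx DiGraph
    whose nodes carry ``seq`` and ``w`` attributes and whose edges carry
    ``w`` (plus the junction context used to recompute support)."""

    g: nx.DiGraph
    locus_id: int
    s: int = S_VID
    t: int = T_VID
    augmented: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def vertices(self) -> list[SpliceVertex]:
        return [SpliceVertex(v, self.g.nodes[v]["seq"], self.g.nodes[v]["w"])
                for v in sorted(self.g.nodes)]

    def vertex_seq(self, vid: int) -> str:
        return self.g.nodes[vid]["seq"]

    def w(self, vid: int) -> float:
        return self.g.nodes[vid]["w"]


@dataclass
class _Junction:
    """A resolved divergence: flow leaves the segment ending at
    ``up = (cid, coord)``, optionally traverses ``alt``, and re-enters at
    ``down = (cid, coord)``. Either end may be absent (alternative
    transcript start/end)."""

    up: tuple[int, int] | None
    alt: str
    down: tuple[int, int] | None
    branches: list[Branch] = field(default_factory=list)


def _resolve_branch(branch: Branch, contigs: dict[int, Contig]) -> tuple | None:
    """Turn a grown branch into (junction, zones).

    ``zones`` maps branch-coordinate intervals onto contig coordinates or
    the alt segment, for read-placement projection:
    [(b_start, b_end, kind, cid_or_None, target_start), ...] with kind in
    {'contig', 'alt'}.
    """
    main = contigs[branch.main_cid]
    seq, x = branch.sequence, branch.x
    if branch.side == "right":
        # anchor: seq[0:x] == main[pos-x:pos]; extend the agreement forward
        pos = branch.pos
        j = 0
        while (pos + j < len(main.sequence) and x + j < len(seq)
               and seq[x + j] == main.sequence[pos + j]):
            j += 1
        b_d, up = x + j, (main.cid, pos + j)
        if b_d >= len(seq):
            return None  # branch fully agrees with its main contig
        if branch.conv is not None:
            ccid, o_m, o_b = branch.conv
            cc = contigs[ccid]
            c_b, c_m = o_b, o_m
            while c_b > b_d and c_m > 0 and seq[c_b - 1] == cc.sequence[c_m - 1]:
                c_b, c_m = c_b - 1, c_m - 1
            if c_b < b_d:
                # the converging read starts before the divergence point;
                # shift the convergence forward so the agreement regions
                # do not double-count the overlap (valid within the read)
                diff = b_d - c_b
                c_b, c_m = c_b + diff, c_m + diff
                if c_b > len(seq) or c_m > len(cc.sequence):
                    return None
            alt, down = seq[b_d:c_b], (ccid, c_m)
            if ccid == main.cid and c_m < up[1]:
                return None  # would point backwards: reject (keep the DAG)
            zones = [(0, b_d, "contig", main.cid, up[1] - b_d),
                     (b_d, c_b, "alt", None, 0),
                     (c_b, len(seq), "contig", ccid, c_m)]
        else:
            alt, down = seq[b_d:], None
            zones = [(0, b_d, "contig", main.cid, up[1] - b_d),
                     (b_d, len(seq), "alt", None, 0)]
    else:
        # anchor: seq[-x:] == main[pos:pos+x]; extend the agreement backward
        pos, Lb = branch.pos, len(seq)
        j = 0
        while (pos - 1 - j >= 0 and Lb - x - 1 - j >= 0
               and seq[Lb - x - 1 - j] == main.sequence[pos - 1 - j]):
            j += 1
        b_a, down = Lb - x - j, (main.cid, pos - j)
        if b_a <= 0:
            return None
        if branch.conv is not None:
            ccid, o_m, o_b = branch.conv
            cc = contigs[ccid]
            # agreement starts at the converging read; extend it forward
            c_b2, c_m2 = o_b, o_m
            while (c_b2 < b_a and c_m2 < len(cc.sequence)
                   and seq[c_b2] == cc.sequence[c_m2]):
                c_b2, c_m2 = c_b2 + 1, c_m2 + 1
            alt, up = seq[c_b2:b_a], (ccid, c_m2)
            if ccid == main.cid and c_m2 > down[1]:
                return None
            zones = [(0, c_b2, "contig", ccid, o_m - o_b),
                     (c_b2, b_a, "alt", None, 0),
                     (b_a, Lb, "contig", main.cid, down[1])]
        else:
            alt, up = seq[:b_a], None
            zones = [(0, b_a, "alt", None, 0),
                     (b_a, Lb, "contig", main.cid, down[1])]
    return _Junction(up=up, alt=alt, down=down, branches=[branch]), zones


def _zone_project(zones, off: int, end: int):
    """Split a branch placement [off, end) across the zones, yielding
    (kind, cid_or_None, start, stop) pieces in target coordinates."""
    for b0, b1, kind, cid, tstart in zones:
        lo, hi = max(off, b0), min(end, b1)
        if lo < hi:
            if kind == "contig":
                yield kind, cid, tstart + lo - b0, tstart + hi - b0
            else:
                yield kind, cid, lo - b0, hi - b0


def _junction_support(ctx: str, boundary: int, seq_mult: dict[str, int], L: int) -> float:
    """Reads-per-base weight of a junction: distinct reads found spanning
    ``boundary`` inside the context window, multiplicities summed, over L."""
    found: set[str] = set()
    lo = max(0, boundary - L + 1)
    hi = min(len(ctx) - L, boundary - 1)
    for p in range(lo, hi + 1):
        sub = ctx[p:p + L]
        if sub in seq_mult:
            found.add(sub)
    return sum(seq_mult[s] for s in found) / L


def build_splicing_graphs(
    contigs: Sequence[Contig],
    index: OverlapIndex,
    reads: Sequence[UniqueRead] | None = None,
    params: AssemblyParams | None = None,
    mate_pairs: Sequence[tuple[int, int]] | None = None,
) -> list[SplicingGraph]:
    """Cut contigs at divergence/convergence coordinates and assemble one
    weighted splicing DAG per locus.

    Contigs whose branches have not been grown yet are branched here
    first. Loci are the connected components induced by convergences
    between contigs; vertices are maximal unbranched segments (plus
    non-empty alternative segments from branches); edges require at least
    one spanning read, or failing that one consistently-placed mate pair.
    """
    reads = index.reads if reads is None else reads
    params = index.params if params is None else params
    L = params.L
    cmap = {c.cid: c for c in contigs}
    all_place = {uid: (c.cid, off) for c in contigs for uid, off in c.members}
    for c in contigs:
        if c.branches is None:
            grow_branches(c, index, main_placements=dict(all_place))

    # resolve branches into junction records; dedupe identical junctions
    junctions: list[_Junction] = []
    zones_of: dict[int, list] = {}  # id(branch) -> zones
    jkey: dict[tuple, int] = {}
    for c in contigs:
        for br in c.branches or []:
            res = _resolve_branch(br, cmap)
            if res is None:
                continue
            junc, zones = res
            zones_of[id(br)] = zones
            key = (junc.up, junc.alt, junc.down)
            if key in jkey:
                junctions[jkey[key]].branches.append(br)
            else:
                jkey[key] = len(junctions)
                junctions.append(junc)

    # loci: contigs linked by junctions form one locus
    uf = {c.cid: c.cid for c in contigs}

    def find(a):
        while uf[a] != a:
            uf[a] = uf[uf[a]]
            a = uf[a]
        return a

    for j in junctions:
        cids = [end[0] for end in (j.up, j.down) if end is not None]
        for other in cids[1:]:
            uf[find(cids[0])] = find(other)

    loci: dict[int, list[int]] = {}
    for c in contigs:
        loci.setdefault(find(c.cid), []).append(c.cid)

    seq_mult = {r.sequence: r.multiplicity for r in reads}
    graphs = []
    for locus_id, (root, cids) in enumerate(sorted(loci.items())):
        graphs.append(
            _build_locus_graph(locus_id, [cmap[i] for i in sorted(cids)],
                               junctions, zones_of, reads, seq_mult, L,
                               mate_pairs)
        )
    return graphs


def _build_locus_graph(locus_id, contigs, all_junctions, zones_of, reads,
                       seq_mult, L, mate_pairs) -> SplicingGraph:
    cids = {c.cid for c in contigs}
    cmap = {c.cid: c for c in contigs}
    junctions = [j for j in all_junctions
                 if any(end is not None and end[0] in cids for end in (j.up, j.down))]

    cuts: dict[int, set[int]] = {cid: {0, len(cmap[cid].sequence)} for cid in cids}
    for j in junctions:
        for end in (j.up, j.down):
            if end is not None:
                cuts[end[0]].add(end[1])

    g = nx.DiGraph()
    vid = 0
    seg_start: dict[tuple[int, int], int] = {}  # (cid, start coord) -> vid
    seg_end: dict[tuple[int, int], int] = {}    # (cid, end coord) -> vid
    segments: list[tuple[int, int, int, int]] = []  # (vid, cid, a, b)
    for cid in sorted(cids):
        coords = sorted(cuts[cid])
        for a, b in zip(coords, coords[1:]):
            if b <= a:
                continue
            g.add_node(vid, seq=cmap[cid].sequence[a:b], w=0.0)
            seg_start[(cid, a)] = vid
            seg_end[(cid, b)] = vid
            segments.append((vid, cid, a, b))
            vid += 1

    alts: list[tuple[int, int, str]] = []  # (vid, junction idx, seq)
    jvid: dict[int, int] = {}
    for ji, j in enumerate(junctions):
        if j.alt:
            g.add_node(vid, seq=j.alt, w=0.0)
            alts.append((vid, ji, j.alt))
            jvid[ji] = vid
            vid += 1

    def _add_edge(u, v, ctx, boundary):
        if u == v or g.has_edge(u, v):
            return
        if g.has_node(u) and g.has_node(v) and nx.has_path(g, v, u):
            logger.warning("locus %d: rejecting edge %d->%d (would form a cycle)",
                           locus_id, u, v)
            return
        g.add_edge(u, v, w=0.0, ctx=ctx, boundary=boundary)

    # consecutive segments of one contig
    for cid in sorted(cids):
        coords = sorted(cuts[cid])
        cseq = cmap[cid].sequence
        for b in coords[1:-1]:
            u, v = seg_end.get((cid, b)), seg_start.get((cid, b))
            if u is None or v is None:
                continue
            lo = max(0, b - L + 1)
            ctx = cseq[lo:min(len(cseq), b + L - 1)]
            _add_edge(u, v, ctx, b - lo)

    # junction edges
    for ji, j in enumerate(junctions):
        up_v = seg_end.get(j.up) if j.up is not None else None
        down_v = seg_start.get(j.down) if j.down is not None else None
        up_tail = (cmap[j.up[0]].sequence[max(0, j.up[1] - L + 1):j.up[1]]
                   if j.up is not None else "")
        down_head = (cmap[j.down[0]].sequence[j.down[1]:j.down[1] + L - 1]
                     if j.down is not None else "")
        if j.alt:
            av = jvid[ji]
            if up_v is not None:
                ctx = up_tail + (j.alt + down_head)[:L - 1]
                _add_edge(up_v, av, ctx, len(up_tail))
            if down_v is not None:
                left = (up_tail + j.alt)[-(L - 1):]
                _add_edge(av, down_v, left + down_head, len(left))
        elif up_v is not None and down_v is not None:
            _add_edge(up_v, down_v, up_tail + down_head, len(up_tail))

    graph = SplicingGraph(g=g, locus_id=locus_id)
    graph.meta = {
        "segments": segments,
        "alts": alts,
        "contigs": cmap,
        "junctions": junctions,
        "mate_pairs": mate_pairs,
    }
    assign_weights(graph, contigs, reads)
    return graph


def assign_weights(graph: SplicingGraph, contigs=None, reads: Sequence[UniqueRead] = None) -> SplicingGraph:
    """(Re)compute vertex and edge weights in reads per base.

    w(v) = sum of multiplicities of reads whose placement overlaps the
    vertex segment, divided by the segment length; w(u->v) = sum of
    multiplicities of reads spanning the junction, divided by L. Branch
    placements are projected onto contig coordinates first, and a read
    placed identically by several contigs/branches is counted once. An
    edge with no spanning read falls back to mate-pair support (pairs/L).
    """
    meta = graph.meta
    cmap = meta["contigs"]
    if reads is None:
        raise ValueError("assign_weights needs the unique-read table")
    L = len(reads[0].sequence)
    seq_mult = {r.sequence: r.multiplicity for r in reads}

    # project every placement onto (contig | alt) coordinates, deduped
    proj: set[tuple] = set()  # (kind, tgt, start, stop, uid)
    zones_cache: dict[int, list] = {}
    for cid, c in cmap.items():
        for uid, off in c.members:
            proj.add(("contig", cid, off, off + len(reads[uid].sequence), uid))
    for ji, j in enumerate(meta["junctions"]):
        for br in j.branches:
            zones = zones_cache.get(id(br))
            if zones is None:
                res = _resolve_branch(br, cmap) if br.main_cid in cmap else None
                if res is None:
                    continue
                zones = res[1]
                zones_cache[id(br)] = zones
            for uid, off in br.members:
                end = off + len(reads[uid].sequence)
                for kind, cid, a, b in _zone_project(zones, off, end):
                    tgt = cid if kind == "contig" else ("alt", ji)
                    proj.add((kind, tgt, a, b, uid))

    for v, cid, a, b in meta["segments"]:
        total = sum(reads[uid].multiplicity
                    for kind, tgt, lo, hi, uid in proj
                    if kind == "contig" and tgt == cid and lo < b and hi > a)
        graph.g.nodes[v]["w"] = total / (b - a)
    for av, ji, alt in meta["alts"]:
        total = sum(reads[uid].multiplicity
                    for kind, tgt, lo, hi, uid in proj
                    if kind == "alt" and tgt == ("alt", ji))
        graph.g.nodes[av]["w"] = total / len(alt)

    mate_pairs = meta.get("mate_pairs")
    for u, v, data in graph.g.edges(data=True):
        w = _junction_support(data["ctx"], data["boundary"], seq_mult, L)
        if w == 0.0 and mate_pairs:
            w = _mate_pair_support(u, v, graph, cmap, reads, mate_pairs, L)
        data["w"] = w
    return graph


def _mate_pair_support(u, v, graph, cmap, reads, mate_pairs, L) -> float:
    """Pairs/L for a junction between consecutive segments of one contig
    when no single read spans it: count mate pairs placed in the contig
    with one mate ending at or before the cut and the other starting at
    or after it."""
    segs = {s[0]: s for s in graph.meta["segments"]}
    if u not in segs or v not in segs:
        return 0.0
    _, ucid, _, ub = segs[u]
    _, vcid, va, _ = segs[v]
    if ucid != vcid or ub != va:
        return 0.0
    offs = {}
    for uid, off in cmap[ucid].members:
        offs.setdefault(uid, off)
    pairs = 0
    for a, b in mate_pairs:
        if a in offs and b in offs:
            lo, hi = sorted((offs[a], offs[b]))
            if lo + len(reads[a].sequence) <= ub <= hi:
                pairs += 1
    return pairs / L


def augment_source_sink(graph: SplicingGraph) -> SplicingGraph:
    """Attach the virtual source s and sink t.

    s feeds every in-degree-0 vertex v with edge weight w(v); every
    out-degree-0 vertex u feeds t with weight w(u). w(s) is the total
    weight leaving s and w(t) the total entering t.
    """
    g = graph.g
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("splicing graph must be acyclic before augmentation")
    heads = [v for v in sorted(g.nodes) if g.in_degree(v) == 0]
    tails = [v for v in sorted(g.nodes) if g.out_degree(v) == 0]
    g.add_node(graph.s, seq="", w=0.0)
    g.add_node(graph.t, seq="", w=0.0)
    for v in heads:
        g.add_edge(graph.s, v, w=g.nodes[v]["w"], ctx="", boundary=0)
    for u in tails:
        g.add_edge(u, graph.t, w=g.nodes[u]["w"], ctx="", boundary=0)
    g.nodes[graph.s]["w"] = sum(d["w"] for _, _, d in g.out_edges(graph.s, data=True))
    g.nodes[graph.t]["w"] = sum(d["w"] for _, _, d in g.in_edges(graph.t, data=True))
    graph.augmented = True
    return graph


def trim_graph(graph: SplicingGraph, params: AssemblyParams) -> SplicingGraph:
    """Remove relatively weightless sibling edges, then every vertex that
    no longer lies on an s->t path."""
    g = graph.g
    rel = params.trim_rel_weight
    drop = []
    for u, v, data in g.edges(data=True):
        max_out = max(d["w"] for _, _, d in g.out_edges(u, data=True))
        max_in = max(d["w"] for _, _, d in g.in_edges(v, data=True))
        if data["w"] < rel * max(max_out, max_in):
            drop.append((u, v))
    g.remove_edges_from(drop)
    if graph.augmented:
        on_path = (nx.descendants(g, graph.s) | {graph.s}) & \
                  (nx.ancestors(g, graph.t) | {graph.t})
        g.remove_nodes_from([v for v in list(g.nodes) if v not in on_path
                             and v not in (graph.s, graph.t)])
    return graph


# ---------------------------------------------------------------------------
# pipeline helpers


def mate_uid_pairs(raw_reads: Sequence[RawRead],
                   uniques: Sequence[UniqueRead]) -> list[tuple[int, int]]:
    """Mate pairs lifted to unique-read uids via member raw-read ids."""
    uid_of: dict[str, int] = {}
    for ur in uniques:
        for mid in ur.member_ids:
            uid_of.setdefault(mid, ur.uid)
    pairs = []
    seen = set()
    for r in raw_reads:
        if r.mate_id is None or r.id in seen:
            continue
        seen.add(r.id)
        seen.add(r.mate_id)
        a, b = uid_of.get(r.id), uid_of.get(r.mate_id)
        if a is not None and b is not None:
            pairs.append((a, b))
    return pairs


def assemble_graphs(
    uniques: Sequence[UniqueRead],
    params: AssemblyParams,
    mate_pairs: Sequence[tuple[int, int]] | None = None,
) -> tuple[list[SplicingGraph], list[Contig], OverlapIndex]:
    """Full graph-side pipeline: index, seed loop with interleaved branch
    growth, then per-locus splicing graphs (weighted, augmented, trimmed)."""
    index = build_index(uniques, params)
    used: set[int] = set()
    contigs: list[Contig] = []
    main_placements: dict[int, tuple[int, int]] = {}
    for seed in select_seeds(uniques, params):
        if seed in used:
            continue
        c = extend_contig(seed, index, used=used, cid=len(contigs))
        for uid, off in c.members:
            main_placements.setdefault(uid, (c.cid, off))
        contigs.append(c)
        grow_branches(c, index, used=used, main_placements=main_placements)
    logger.info("assembled %d main contigs from %d unique reads",
                len(contigs), len(uniques))
    graphs = build_splicing_graphs(contigs, index, mate_pairs=mate_pairs)
    for gr in graphs:
        augment_source_sink(gr)
        trim_graph(gr, params)
    return graphs, contigs, index
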