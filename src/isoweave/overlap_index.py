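"""Simplified left/right-extension suffix trees for longest-overlap queries.

The index answers, in O(L) per query, "which reads share the longest
terminal overlap (>= l bases) with this contig end?". Two tries are kept:

* LEST (left-extension suffix tree): built over the (L-1)-character
  prefixes of all unique reads, then annotated with read ids at the end
  node of every read *suffix* of length l..L-1 that exists as a full root
  path. Querying it with a contig's 5' prefix finds reads whose suffix
  matches that prefix, i.e. reads that extend the contig leftwards.
* REST (right-extension suffix tree): holds the *reversals* of every read
  prefix (length l..L-1) that matched an id-bearing LEST path. Querying
  it with the reversed 3' suffix of a contig finds reads whose prefix
  matches the contig end, i.e. rightward extenders.

A read affix can only ever be used in extension if it equals an affix of
some other read, which is why id-free leaves are trimmed away and why the
REST is seeded from the trimmed LEST. Finally the top l levels of both
tries are compressed into a single layer keyed by 2-bit-packed l-mers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .reads_io import AssemblyParams, UniqueRead, reverse_sequence

logger = logging.getLogger("isoweave")

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

LEST = "LEST"
REST = "REST"


@dataclass
class TreeNode:
    # children keys are single characters, or packed l-mer ints at the
    # compressed layer directly under the root
    children: dict = field(default_factory=dict)
    read_ids: list[int] = field(default_factory=list)
    depth: int = 0

    def add_read_id(self, uid: int) -> None:
        """Insert uid keeping the list sorted and duplicate-free."""
        import bisect

        i = bisect.bisect_left(self.read_ids, uid)
        if i == len(self.read_ids) or self.read_ids[i] != uid:
            self.read_ids.insert(i, uid)


@dataclass
class SuffixTree:
    root: TreeNode
    side: str  # LEST or REST
    l: int
    L: int
    compressed: bool = False
    # instrumentation: edge traversals performed by the last longest_overlap call
    last_query_traversals: int = 0

    @property
    def node_count(self) -> int:
        return count_nodes(self)


@dataclass
class OverlapHit:
    """Longest-overlap query answer: overlap length x and the uids at the
    deepest id-bearing node on the matched path (x = 0 iff empty)."""

    overlap_len: int
    read_uids: list[int]

    def __bool__(self) -> bool:
        return self.overlap_len > 0


def encode_lmer(seq: str) -> int:
    """Pack an l-mer (l <= 32) into an integer, 2 bits per base, A=0 C=1
    G=2 T=3, first base most significant."""
    if len(seq) > 32:
        raise ValueError("l-mer longer than 32 bases cannot be packed in 64 bits")
    code = 0
    for ch in seq:
        try:
            code = (code << 2) | _BASE_CODE[ch]
        except KeyError:
            raise ValueError(f"non-ACGT character {ch!r} in l-mer") from None
    return code


def _insert_path(root: TreeNode, seq: str) -> TreeNode:
    """Insert seq char by char under root; return the end node."""
    node = root
    for ch in seq:
        nxt = node.children.get(ch)
        if nxt is None:
            nxt = TreeNode(depth=node.depth + 1)
            node.children[ch] = nxt
        node = nxt
    return node


def _walk(root: TreeNode, seq: str) -> TreeNode | None:
    """Follow seq from root; None if the full path does not exist."""
    node = root
    for ch in seq:
        node = node.children.get(ch)
        if node is None:
            return None
    return node


def build_initial_lest(reads: Sequence[UniqueRead], params: AssemblyParams) -> SuffixTree:
    """Step 1: a trie over the distinct (L-1)-character read prefixes.

    Any suffix usable in left extension must equal a prefix of some read,
    so this trie already covers every path a usable suffix can take.
    """
    if not reads:
        raise ValueError("cannot build an index from an empty read set")
    root = TreeNode()
    for r in reads:
        _insert_path(root, r.sequence[: params.L - 1])
    return SuffixTree(root=root, side=LEST, l=params.l, L=params.L)


def annotate_suffixes(
    tree: SuffixTree, reads: Sequence[UniqueRead], params: AssemblyParams
) -> SuffixTree:
    """Step 2: store each read's uid at the end node of every suffix of
    length l..L-1 that exists as a complete root path."""
    for r in reads:
        for x in range(params.l, params.L):
            node = _walk(tree.root, r.sequence[len(r.sequence) - x:])
            if node is not None:
                node.add_read_id(r.uid)
    return tree


def trim(tree: SuffixTree) -> SuffixTree:
    """Step 3: iteratively delete leaves without stored read ids.

    Runs to fixed point: afterwards every leaf carries ids (or only the
    root remains). Implemented as a post-order sweep, which reaches the
    same fixed point as repeated leaf deletion in one pass.
    """

    def prune(node: TreeNode) -> bool:
        # returns True if the node must be kept
        kept = {}
        for ch, child in node.children.items():
            if prune(child):
                kept[ch] = child
        node.children = kept
        return bool(node.children) or bool(node.read_ids)

    prune(tree.root)
    return tree


def build_rest(
    lest: SuffixTree, reads: Sequence[UniqueRead], params: AssemblyParams
) -> SuffixTree:
    """Step 4: build the right-extension tree from the trimmed LEST.

    For each read, prefixes of length l..L-1 are tried in increasing
    order; a prefix whose path ends at an id-bearing LEST node is a
    usable right-extension affix, so its reversal is inserted into the
    REST with the read's uid at the insertion end node. Prefixes ending
    at id-free nodes, or missing entirely (trimmed away), contribute
    nothing.
    """
    if lest.compressed:
        raise ValueError("REST must be built against the pre-compression LEST")
    root = TreeNode()
    for r in reads:
        for x in range(params.l, params.L):
            node = _walk(lest.root, r.sequence[:x])
            if node is not None and node.read_ids:
                end = _insert_path(root, reverse_sequence(r.sequence[:x]))
                end.add_read_id(r.uid)
    return SuffixTree(root=root, side=REST, l=params.l, L=params.L)


def compress(tree: SuffixTree, params: AssemblyParams) -> SuffixTree:
    """Step 5: collapse each l-character root path into one node keyed by
    its packed l-mer. The depth-l node keeps its ids and subtree."""
    if tree.compressed:
        return tree
    new_children: dict[int, TreeNode] = {}

    def collect(node: TreeNode, prefix: str) -> None:
        if node.depth == params.l:
            new_children[encode_lmer(prefix)] = node
            return
        # ids may only live at depth >= l, so no annotated node can sit
        # above the compression layer
        assert not node.read_ids or node.depth == 0, (
            "id-bearing node above the compression layer"
        )
        assert node.children or node.depth == 0, (
            "trimmed tree has a root path shorter than l"
        )
        for ch, child in node.children.items():
            collect(child, prefix + ch)

    collect(tree.root, "")
    tree.root = TreeNode(children=new_children, read_ids=tree.root.read_ids)
    tree.compressed = True
    return tree


def count_nodes(tree: SuffixTree) -> int:
    """Nodes reachable from the root, root included; a compressed
    l-character path counts as one node."""
    n = 0
    stack = [tree.root]
    while stack:
        node = stack.pop()
        n += 1
        stack.extend(node.children.values())
    return n


def longest_overlap(tree: SuffixTree, terminus: str) -> OverlapHit:
    """Walk ``terminus`` from the root as far as edges allow and return
    the deepest visited node that stores read ids.

    For the LEST the terminus is the contig's 5' prefix read left to
    right; for the REST it is the reversed 3' suffix. On a compressed
    tree the first l characters resolve via one packed-key lookup, so at
    most L-1-l single-character traversals follow.
    """
    tree.last_query_traversals = 0
    if len(terminus) < tree.l:
        logger.warning("longest_overlap: terminus shorter than l, no hit")
        return OverlapHit(0, [])
    if tree.compressed:
        node = tree.root.children.get(encode_lmer(terminus[: tree.l]))
        pos = tree.l
    else:
        node, pos = tree.root, 0
    best_node, best_depth = None, 0
    while node is not None:
        if node.read_ids:
            # node.depth counts characters from the root in both the plain
            # and the compressed tree (a compressed node sits at depth l)
            best_node, best_depth = node, node.depth
        if pos >= len(terminus):
            break
        nxt = node.children.get(terminus[pos])
        if nxt is not None:
            tree.last_query_traversals += 1
        node, pos = nxt, pos + 1
    if best_node is None:
        return OverlapHit(0, [])
    return OverlapHit(best_depth, list(best_node.read_ids))


@dataclass
class OverlapIndex:
    """The paired trees plus the unique-read table they index."""

    lest: SuffixTree
    rest: SuffixTree
    reads: list[UniqueRead]
    params: AssemblyParams

    def query_left(self, contig_seq: str) -> OverlapHit:
        """Reads whose suffix matches the contig's 5' end (left extension)."""
        k = min(self.params.L - 1, len(contig_seq))
        return longest_overlap(self.lest, contig_seq[:k])

    def query_right(self, contig_seq: str) -> OverlapHit:
        """Reads whose prefix matches the contig's 3' end (right extension)."""
        k = min(self.params.L - 1, len(contig_seq))
        return longest_overlap(self.rest, reverse_sequence(contig_seq[-k:]))


def build_index(reads: Sequence[UniqueRead], params: AssemblyParams) -> OverlapIndex:
    """Run construction steps 1-5 and return the paired compressed trees."""
    lest = build_initial_lest(reads, params)
    n0 = count_nodes(lest)
    annotate_suffixes(lest, reads, params)
    trim(lest)
    n1 = count_nodes(lest)
    rest = build_rest(lest, reads, params)
    compress(lest, params)
    compress(rest, params)
    logger.info(
        "index: LEST nodes %d -> %d (trim) -> %d (compress); REST nodes %d",
        n0, n1, count_nodes(lest), count_nodes(rest),
    )
    return OverlapIndex(lest=lest, rest=rest, reads=list(reads), params=params)
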