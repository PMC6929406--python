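"""The simplified extension suffix trees, checked against the printed
worked example and a brute-force affix-scan oracle."""

import itertools

import numpy as np
import pytest

from isoweave import (
    AssemblyParams,
    RawRead,
    annotate_suffixes,
    build_index,
    build_initial_lest,
    build_rest,
    compress,
    count_nodes,
    deduplicate,
    encode_lmer,
    longest_overlap,
    trim,
)
from isoweave.overlap_index import _walk, reverse_sequence


def _staged_trees(uniques, params):
    lest = build_initial_lest(uniques, params)
    annotate_suffixes(lest, uniques, params)
    trim(lest)
    rest = build_rest(lest, uniques, params)
    return lest, rest


class TestWorkedExample:
    def test_node_counts_through_all_stages(self, fig_uniques, fig_params):
        lest = build_initial_lest(fig_uniques, fig_params)
        assert count_nodes(lest) == 16
        annotate_suffixes(lest, fig_uniques, fig_params)
        trim(lest)
        assert count_nodes(lest) == 10
        compress(lest, fig_params)
        assert count_nodes(lest) == 7

    def test_annotation_stores_ids_at_matching_suffix_ends(self, fig_uniques, fig_params):
        lest = build_initial_lest(fig_uniques, fig_params)
        annotate_suffixes(lest, fig_uniques, fig_params)
        # Read1=CATTC: suffix ATTC matches, TTC does not, TC matches
        assert _walk(lest.root, "ATTC").read_ids == [0]
        assert _walk(lest.root, "TTC") is None
        assert 0 in _walk(lest.root, "TC").read_ids
        # Read4=TCCAT: suffixes CAT and AT match
        assert _walk(lest.root, "CAT").read_ids == [3]
        assert _walk(lest.root, "AT").read_ids == [3]

    def test_rest_skips_idfree_prefix_and_inserts_reversal(self, fig_uniques, fig_params):
        lest, rest = _staged_trees(fig_uniques, fig_params)
        # prefix CA of Read1 ends at an id-free node -> nothing under AC
        assert _walk(rest.root, "AC") is None
        # prefix CAT ends at an id-bearing node -> TAC inserted with Read1
        assert _walk(rest.root, "TAC").read_ids == [0]
        # prefix CATT was trimmed away -> TTAC absent
        assert _walk(rest.root, "TTAC") is None

    def test_compressed_lest_keys(self, fig_uniques, fig_params):
        lest, _ = _staged_trees(fig_uniques, fig_params)
        compress(lest, fig_params)
        keys = set(lest.root.children)
        assert keys == {encode_lmer("CA"), encode_lmer("AT"), encode_lmer("TC")}

    def test_lookup_examples(self, fig_index):
        hit = fig_index.query_left("ATTCT")
        assert (hit.overlap_len, hit.read_uids) == (4, [0])
        hit = fig_index.query_right("TCCAT")
        assert (hit.overlap_len, hit.read_uids) == (3, [0])
        assert not fig_index.query_left("GGGG")
        assert not fig_index.query_right("GGGG")

    def test_terminus_shorter_than_min_overlap(self, fig_index):
        assert not longest_overlap(fig_index.lest, "A")


class TestBuildEdgeCases:
    def test_single_read_tree(self):
        params = AssemblyParams(L=4, l=2)
        u = deduplicate([RawRead("a", "AAAA")], params)
        assert count_nodes(build_initial_lest(u, params)) == 4  # root + AAA

    def test_shared_prefix_nodes(self):
        params = AssemblyParams(L=5, l=2)
        u = deduplicate([RawRead("a", "ACGTA"), RawRead("b", "ACGCA")], params)
        # shared ACG path, then one extra node each: 1 + 3 + 1 + 1
        assert count_nodes(build_initial_lest(u, params)) == 6

    def test_empty_read_set_rejected(self):
        with pytest.raises(ValueError):
            build_initial_lest([], AssemblyParams(L=5, l=2))

    def test_trim_erodes_idfree_tree_to_root(self, fig_uniques, fig_params):
        lest = build_initial_lest(fig_uniques, fig_params)  # no ids stored
        trim(lest)
        assert count_nodes(lest) == 1

    def test_trim_is_a_fixed_point_on_annotated_trees(self, fig_uniques, fig_params):
        lest, _ = _staged_trees(fig_uniques, fig_params)
        n = count_nodes(lest)
        trim(lest)
        assert count_nodes(lest) == n

    def test_compression_with_l1_keeps_count(self):
        params = AssemblyParams(L=4, l=1)
        u = deduplicate([RawRead("a", "ACGT"), RawRead("b", "CGTA"),
                         RawRead("c", "GTAC"), RawRead("d", "TACG")], params)
        lest, _ = _staged_trees(u, params)
        n = count_nodes(lest)
        compress(lest, params)
        assert count_nodes(lest) == n

    def test_compression_merges_shared_first_base(self):
        # two root paths AC and AG (l=2): depth-1 node A disappears
        params = AssemblyParams(L=4, l=2)
        u = deduplicate([RawRead("a", "ACTT"), RawRead("b", "AGTT"),
                         RawRead("c", "TACT"), RawRead("d", "TAGT")], params)
        lest, _ = _staged_trees(u, params)
        before = count_nodes(lest)
        compress(lest, params)
        assert count_nodes(lest) == before - 1


class TestEncodeLmer:
    @pytest.mark.parametrize("seq,code", [("AA", 0), ("CA", 4), ("TT", 15)])
    def test_examples(self, seq, code):
        assert encode_lmer(seq) == code

    @pytest.mark.parametrize("l", [1, 2, 3, 6])
    def test_injective_over_all_lmers(self, l):
        codes = {encode_lmer("".join(p)) for p in itertools.product("ACGT", repeat=l)}
        assert len(codes) == 4 ** l

    def test_rejects_non_acgt(self):
        with pytest.raises(ValueError):
            encode_lmer("AN")


def brute_force_overlap(query, uniques, l, L, side):
    """Independent affix-scan oracle: deepest x in [l, L-1] at which the
    query prefix equals a read suffix (LEST) / reversed read prefix (REST)."""
    for x in range(L - 1, l - 1, -1):
        if x > len(query):
            continue
        if side == "LEST":
            uids = [u.uid for u in uniques if u.sequence[-x:] == query[:x]]
        else:
            uids = [u.uid for u in uniques
                    if reverse_sequence(u.sequence[:x]) == query[:x]]
        if uids:
            return x, sorted(uids)
    return 0, []


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(25))
    def test_lookup_matches_affix_scan_at_all_stages(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(8, 31))
        l = int(rng.integers(2, 7))
        n = int(rng.integers(5, 120))
        seqs = ["".join("ACGT"[b] for b in rng.integers(0, 4, L)) for _ in range(n)]
        params = AssemblyParams(L=L, l=l)
        uniques = deduplicate([RawRead(str(i), s) for i, s in enumerate(seqs)], params)

        lest = build_initial_lest(uniques, params)
        annotate_suffixes(lest, uniques, params)
        stages = {}
        stages["lest_annotated"] = [longest_overlap(lest, u.sequence[:L - 1])
                                    for u in uniques]
        trim(lest)
        stages["lest_trimmed"] = [longest_overlap(lest, u.sequence[:L - 1])
                                  for u in uniques]
        rest = build_rest(lest, uniques, params)
        rqueries = [reverse_sequence(u.sequence[-(L - 1):]) for u in uniques]
        stages["rest"] = [longest_overlap(rest, q) for q in rqueries]
        compress(lest, params)
        compress(rest, params)
        stages["lest_compressed"] = [longest_overlap(lest, u.sequence[:L - 1])
                                     for u in uniques]
        stages["rest_compressed"] = [longest_overlap(rest, q) for q in rqueries]

        for u in uniques:
            expect = brute_force_overlap(u.sequence[: L - 1], uniques, l, L, "LEST")
            for stage in ("lest_annotated", "lest_trimmed", "lest_compressed"):
                got = stages[stage][u.uid]
                assert (got.overlap_len, got.read_uids) == expect, stage
        for u, q in zip(uniques, rqueries):
            expect = brute_force_overlap(q, uniques, l, L, "REST")
            for stage in ("rest", "rest_compressed"):
                got = stages[stage][u.uid]
                assert (got.overlap_len, got.read_uids) == expect, stage

        # compressed lookups walk at most L - l edges (one key lookup + chars)
        for u in uniques:
            longest_overlap(lest, u.sequence[:L - 1])
            assert lest.last_query_traversals <= L - l


def test_query_cost_bound_on_worked_example(fig_index):
    fig_index.query_left("ATTCT")
    assert fig_index.lest.last_query_traversals <= 5 - 2
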