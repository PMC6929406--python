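"""Seed selection, contig extension and splicing-graph construction."""

import networkx as nx
import numpy as np
import pytest

from _graphs import make_graph
from isoweave import (
    AssemblyParams,
    RawRead,
    assemble_graphs,
    augment_source_sink,
    build_index,
    choose_candidate,
    deduplicate,
    extend_contig,
    select_seeds,
    trim_graph,
)
from isoweave.overlap_index import OverlapHit
from isoweave.reads_io import UniqueRead
from isoweave.synthetic_data import GeneModel, SimConfig, make_gene_model, simulate_reads


def _uniques(mults):
    return [UniqueRead(uid=i, sequence="ACGT", multiplicity=m, member_ids=[str(i)])
            for i, m in enumerate(mults)]


class TestSelectSeeds:
    def test_only_above_mean_multiplicity(self):
        assert select_seeds(_uniques([5, 1, 1, 1])) == [0]

    def test_all_equal_falls_back_to_every_read(self):
        assert select_seeds(_uniques([2, 2, 2])) == [0, 1, 2]

    def test_ordered_by_multiplicity_then_uid(self):
        assert select_seeds(_uniques([3, 3, 1])) == [0, 1]
        assert select_seeds(_uniques([1, 4, 5])) == [2, 1]


class TestChooseCandidate:
    def test_multiplicity_closest_to_contig_coverage(self):
        reads = _uniques([1, 2, 5])
        assert choose_candidate(OverlapHit(3, [0, 1, 2]), 2.0, reads) == 1

    def test_single_candidate(self):
        assert choose_candidate(OverlapHit(3, [0]), 99.0, _uniques([1])) == 0

    def test_tie_prefers_smaller_multiplicity(self):
        reads = _uniques([2, 4])
        assert choose_candidate(OverlapHit(3, [0, 1]), 3.0, reads) == 0


class TestExtendContig:
    def test_worked_example_extension(self, fig_index):
        contig = extend_contig(3, fig_index)  # seed TCCAT
        assert contig.sequence == "TCCATTCT"
        assert contig.members == [(3, 0), (0, 2), (1, 3)]

    def test_seed_without_overlaps_stays_a_read(self):
        params = AssemblyParams(L=5, l=3)
        u = deduplicate([RawRead("a", "AAAAA"), RawRead("b", "GGGGG")], params)
        idx = build_index(u, params)
        assert extend_contig(1, idx).sequence == "GGGGG"

    def test_circular_overlap_terminates(self):
        params = AssemblyParams(L=4, l=2)
        u = deduplicate([RawRead("a", "ACCA"), RawRead("b", "CAAC")], params)
        idx = build_index(u, params)
        contig = extend_contig(0, idx)  # ACCA + AC, then b's prefix repeats
        assert len(contig.sequence) <= 8  # repeated-read rule stops the loop

    def test_members_match_contig_exactly(self, skipping_assembly, skipping_locus):
        _, contigs, _ = skipping_assembly
        reads = skipping_locus["uniques"]
        for c in contigs:
            for uid, off in c.members:
                assert c.sequence[off:off + 50] == reads[uid].sequence
            assert (c.support(reads) > 0).all()

    @pytest.mark.parametrize("seed_rank", [0, 3, 11])
    def test_uniform_tiling_recovers_full_transcript(self, seed_rank):
        rng = np.random.default_rng(7)
        tx = "".join("ACGT"[b] for b in rng.integers(0, 4, 200))
        L, step = 20, 5
        raw = [RawRead(f"p{p}", tx[p:p + L]) for p in range(0, 181, step)]
        params = AssemblyParams(L=L, l=10)
        u = deduplicate(raw, params)
        idx = build_index(u, params)
        contig = extend_contig(seed_rank, idx)
        assert contig.sequence == tx


class TestSplicingGraphs:
    def test_exon_skipping_gives_three_vertices_and_a_skip_edge(
            self, skipping_assembly, skipping_locus):
        graphs, _, _ = skipping_assembly
        assert len(graphs) == 1
        gr = graphs[0]
        model = skipping_locus["model"]
        real = [v for v in gr.vertices if v.vid not in (gr.s, gr.t)]
        assert [v.sequence for v in real] == model.exons
        edges = {(u, v) for u, v in gr.g.edges if u >= 0 and v >= 0}
        assert edges == {(0, 1), (1, 2), (0, 2)}

    def test_weights_match_tiling_arithmetic(self, skipping_assembly):
        graphs, _, _ = skipping_assembly
        gr = graphs[0]
        # exon A (300b): 126 shared reads at multiplicity 11, plus 48
        # junction reads (24 @6 from ABC, 24 @5 from AC) overlapping it
        assert gr.w(0) == pytest.approx((126 * 11 + 24 * 6 + 24 * 5) / 300)
        # skipped exon B only carries the high-abundance isoform
        assert gr.w(1) == pytest.approx((101 * 6 + 48 * 6) / 250)
        # junction A->B spanned by 24 reads of multiplicity 6
        assert gr.g.edges[0, 1]["w"] == pytest.approx(24 * 6 / 50)
        # skip junction A->C spanned by 24 reads of multiplicity 5
        assert gr.g.edges[0, 2]["w"] == pytest.approx(24 * 5 / 50)

    def test_graphs_are_dags_with_all_vertices_on_st_paths(self, skipping_assembly):
        graphs, _, _ = skipping_assembly
        for gr in graphs:
            assert nx.is_directed_acyclic_graph(gr.g)
            for v in gr.g.nodes:
                if v in (gr.s, gr.t):
                    continue
                assert nx.has_path(gr.g, gr.s, v) and nx.has_path(gr.g, v, gr.t)

    def test_two_unrelated_genes_give_two_loci(self):
        raws = []
        for seed in (11, 12):
            model = make_gene_model(n_exons=1, exon_len_range=(220, 240),
                                    n_isoforms=1, rng_seed=seed, abundances=[4])
            reads, _ = simulate_reads(model, SimConfig(L=30, step=3, rng_seed=seed))
            raws += [RawRead(f"g{seed}_{r.id}", r.sequence) for r in reads]
        params = AssemblyParams(L=30, l=12)
        graphs, _, _ = assemble_graphs(deduplicate(raws, params), params)
        assert len(graphs) == 2
        for gr in graphs:
            real = [v for v in gr.vertices if v.vid not in (gr.s, gr.t)]
            assert len(real) == 1

    def test_determinism_byte_identical_graphs(self, skipping_locus):
        params = skipping_locus["params"]
        outs = []
        for _ in range(2):
            graphs, _, _ = assemble_graphs(skipping_locus["uniques"], params)
            outs.append([
                (sorted((v, d["seq"], round(d["w"], 9))
                        for v, d in g.g.nodes(data=True)),
                 sorted((u, v, round(d["w"], 9))
                        for u, v, d in g.g.edges(data=True)))
                for g in graphs
            ])
        assert outs[0] == outs[1]


class TestAugmentation:
    def test_single_vertex_rule(self):
        gr = make_graph({0: ("AAA", 3.0)}, [])
        assert gr.g.edges[gr.s, 0]["w"] == 3.0
        assert gr.g.edges[0, gr.t]["w"] == 3.0
        assert gr.w(gr.s) == 3.0 and gr.w(gr.t) == 3.0

    def test_source_weight_sums_parallel_chains(self):
        gr = make_graph(
            {0: ("A", 2.0), 1: ("C", 5.0), 2: ("G", 4.0), 3: ("T", 4.0)},
            [(0, 2, 2.0), (1, 3, 5.0)])
        assert gr.w(gr.s) == 7.0

    def test_empty_graph_gets_bare_source_and_sink(self):
        gr = make_graph({}, [])
        assert set(gr.g.nodes) == {gr.s, gr.t}
        assert gr.g.number_of_edges() == 0

    def test_cyclic_graph_rejected(self):
        gr = make_graph({0: ("A", 1.0), 1: ("C", 1.0)},
                        [(0, 1, 1.0), (1, 0, 1.0)], augment=False)
        with pytest.raises(ValueError, match="acyclic"):
            augment_source_sink(gr)


class TestTrimGraph:
    def _params(self):
        return AssemblyParams(L=50, l=10, trim_rel_weight=0.05)

    def test_relatively_weightless_sibling_removed(self):
        gr = make_graph(
            {0: ("A" * 10, 100.0), 1: ("C" * 10, 100.0), 2: ("G" * 10, 1.0)},
            [(0, 1, 100.0), (0, 2, 1.0), (2, 1, 1.0)])
        trim_graph(gr, self._params())
        assert not gr.g.has_edge(0, 2)
        assert 2 not in gr.g.nodes  # isolated vertex dropped too

    def test_equal_siblings_untouched(self):
        gr = make_graph({0: ("A", 5.0), 1: ("C", 5.0), 2: ("G", 5.0)},
                        [(0, 1, 5.0), (0, 2, 5.0)])
        n_edges = gr.g.number_of_edges()
        trim_graph(gr, self._params())
        assert gr.g.number_of_edges() == n_edges


def test_branch_without_convergence_still_yields_skip_paths():
    """If isoform tilings are phase-shifted the branch may never meet the
    main contig's reads; the alternative segment then runs to the end and
    both isoforms must still be spelled by some s->t path."""
    rng = np.random.default_rng(3)
    exons = []
    for n in (301, 251, 349):  # odd lengths de-phase the shared exon C
        exons.append("".join("ACGT"[b] for b in rng.integers(0, 4, n)))
    model = GeneModel(exons=exons, isoforms=[[0, 1, 2], [0, 2]], abundances=[6, 5])
    reads, truth = simulate_reads(model, SimConfig(L=50, step=2, rng_seed=3))
    params = AssemblyParams(L=50, l=15)
    graphs, _, _ = assemble_graphs(deduplicate(reads, params), params)
    spelled = set()
    for gr in graphs:
        for p in nx.all_simple_paths(gr.g, gr.s, gr.t):
            spelled.add("".join(gr.g.nodes[v]["seq"] for v in p))
    assert set(truth.values()) <= spelled
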