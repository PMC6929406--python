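import copy

import pytest

from isoweave import (
    AssemblyParams,
    RawRead,
    assemble_graphs,
    build_index,
    deduplicate,
    simulate_reads,
    two_isoform_locus,
)

# the four-read worked example: L=5, l=2
FIG_READS = ["CATTC", "ATTCT", "AGCTC", "TCCAT"]


@pytest.fixture
def fig_params():
    return AssemblyParams(L=5, l=2)


@pytest.fixture
def fig_raw():
    return [RawRead(f"Read{i + 1}", s) for i, s in enumerate(FIG_READS)]


@pytest.fixture
def fig_uniques(fig_raw, fig_params):
    return deduplicate(fig_raw, fig_params)


@pytest.fixture
def fig_index(fig_uniques, fig_params):
    return build_index(fig_uniques, fig_params)


@pytest.fixture(scope="session")
def skipping_locus():
    """Exon-skipping gene (isoforms ABC and AC), error-free tiled reads."""
    model, cfg = two_isoform_locus(1)
    raw, truth = simulate_reads(model, cfg)
    params = AssemblyParams(L=cfg.L, l=15)
    uniques = deduplicate(raw, params)
    return {"model": model, "config": cfg, "raw": raw, "truth": truth,
            "params": params, "uniques": uniques}


@pytest.fixture(scope="session")
def _skipping_assembly(skipping_locus):
    graphs, contigs, index = assemble_graphs(
        skipping_locus["uniques"], skipping_locus["params"])
    return graphs, contigs, index


@pytest.fixture
def skipping_assembly(_skipping_assembly):
    # graphs are mutated by peeling; hand each test a fresh copy
    graphs, contigs, index = _skipping_assembly
    return copy.deepcopy(graphs), contigs, index
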