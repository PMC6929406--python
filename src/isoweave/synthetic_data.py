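"""Toy gene models and simulated RNA-seq reads with known ground truth.

The generator emulates what the assembler needs to see to be testable
end to end without any external data: a multi-exon gene, a handful of
isoforms (exon chains), and uniform-coverage reads tiled along each
isoform at a fixed stride. With a zero error rate and a stride no larger
than L - l, every adjacent read pair overlaps by at least the minimum
overlap, so error-free reconstruction is exactly recoverable. A
substitution-only error model is available; indels are not modelled
because extension works on exact overlaps.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .reads_io import RawRead

logger = logging.getLogger("isoweave")

_BASES = np.array(list("ACGT"))


@dataclass
class GeneModel:
    exons: list[str]
    isoforms: list[list[int]]  # strictly increasing exon-index chains
    abundances: list[int] = field(default_factory=list)

    def isoform_seq(self, i: int) -> str:
        return "".join(self.exons[e] for e in self.isoforms[i])

    def transcripts(self) -> dict[str, str]:
        return {f"isoform{i}": self.isoform_seq(i)
                for i in range(len(self.isoforms))}

    def to_manifest(self) -> dict:
        return {
            "exon_lengths": [len(e) for e in self.exons],
            "isoforms": self.isoforms,
            "abundances": self.abundances,
        }


@dataclass
class SimConfig:
    """Read-simulation conditions.

    L = 50 matches the shortest common short-read length; step 2 gives
    deep, uniform tiling (coverage ~ abundance * L / step reads so every
    junction is spanned well above the default transcript filters);
    errors default to zero (the exact-overlap regime the assembler
    targets).
    """

    L: int = 50
    step: int = 2
    fragment_len: tuple[float, float] = (250.0, 25.0)  # mean, sd (paired mode)
    sub_error_rate: float = 0.0
    paired: bool = False
    rng_seed: int = 0


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _shares_kmer(a: str, b: str, k: int) -> bool:
    if len(a) < k or len(b) < k:
        return False
    kmers = {a[i:i + k] for i in range(len(a) - k + 1)}
    return any(b[i:i + k] in kmers for i in range(len(b) - k + 1))


def _all_chains(n: int) -> list[list[int]]:
    chains = []
    for mask in range(1, 1 << n):
        chains.append([i for i in range(n) if mask >> i & 1])
    # longer chains first, then lexicographic: deterministic and puts the
    # full-length isoform at the front
    chains.sort(key=lambda c: (-len(c), c))
    return chains


def make_gene_model(
    n_exons: int = 3,
    exon_len_range: tuple[int, int] = (200, 400),
    n_isoforms: int = 2,
    rng_seed: int = 0,
    abundances: list[int] | None = None,
    repeat_screen_k: int = 16,
    max_tries: int = 50,
) -> GeneModel:
    """Random exons (screened against cross-exon k-mer repeats) plus
    isoform chains sampled without replacement; deterministic per seed.

    The first sampled chain is always the full exon chain, so a two-
    isoform model is the canonical exon-skipping event.
    """
    if n_exons > 12:
        raise ValueError("n_exons > 12 not supported (chain enumeration)")
    chains = _all_chains(n_exons)
    if n_isoforms > len(chains):
        raise ValueError("more isoforms requested than distinct exon chains")
    rng = np.random.default_rng(rng_seed)
    exons: list[str] = []
    for _ in range(n_exons):
        # even lengths keep junction tilings phase-aligned across isoforms
        n = int(rng.integers(exon_len_range[0], exon_len_range[1] + 1)) // 2 * 2
        for _ in range(max_tries):
            cand = _random_seq(rng, n)
            if all(not _shares_kmer(cand, e, repeat_screen_k) for e in exons):
                exons.append(cand)
                break
        else:
            raise RuntimeError("could not generate repeat-free exons; "
                               "relax exon_len_range or repeat_screen_k")
    rest = rng.permutation(len(chains) - 1)[: n_isoforms - 1]
    isoforms = [chains[0]] + [chains[1 + i] for i in sorted(rest)]
    if abundances is None:
        abundances = [1] * n_isoforms
    if len(abundances) != n_isoforms:
        raise ValueError("one abundance per isoform required")
    return GeneModel(exons=exons, isoforms=isoforms, abundances=list(abundances))


def two_isoform_locus(rng_seed: int = 0) -> tuple[GeneModel, SimConfig]:
    """The canonical exon-skipping fixture: exons of 300/250/350 bases,
    isoforms [0,1,2] and [0,2] at abundances 6 and 5, error-free
    single-end 50-base reads tiled every 2 bases. Coverage sits above all
    default transcript filters at every vertex and junction."""
    rng = np.random.default_rng(rng_seed)
    exons = []
    for n in (300, 250, 350):
        while True:
            cand = _random_seq(rng, n)
            if all(not _shares_kmer(cand, e, 16) for e in exons):
                exons.append(cand)
                break
    model = GeneModel(exons=exons, isoforms=[[0, 1, 2], [0, 2]],
                      abundances=[6, 5])
    return model, SimConfig(L=50, step=2, rng_seed=rng_seed)


def simulate_reads(model: GeneModel, config: SimConfig) -> tuple[list[RawRead], dict[str, str]]:
    """Tile reads along every isoform and return (reads, truth).

    Positions run 0, step, 2*step, ... plus the final window; abundance k
    replicates each read k times; substitutions are applied per base at
    ``sub_error_rate``. In paired mode, fragments are tiled instead and
    the two mates are the fragment's ends (forward strand, as produced by
    a strand-specific protocol). Isoforms shorter than L are skipped with
    a warning. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.rng_seed)
    L = config.L
    reads: list[RawRead] = []
    truth: dict[str, str] = {}

    def mutate(seq: str) -> str:
        if config.sub_error_rate <= 0:
            return seq
        arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
        hit = rng.random(len(arr)) < config.sub_error_rate
        for i in np.nonzero(hit)[0]:
            choices = [b for b in "ACGT" if b != arr[i]]
            arr[i] = choices[rng.integers(0, 3)]
        return "".join(arr)

    for i, chain in enumerate(model.isoforms):
        tx = model.isoform_seq(i)
        name = f"isoform{i}"
        if len(tx) < L:
            logger.warning("%s shorter than read length, skipped", name)
            continue
        truth[name] = tx
        k = model.abundances[i] if i < len(model.abundances) else 1
        if not config.paired:
            positions = list(range(0, len(tx) - L + 1, config.step))
            if positions[-1] != len(tx) - L:
                positions.append(len(tx) - L)
            for pos in positions:
                window = tx[pos:pos + L]
                for rep in range(k):
                    reads.append(RawRead(id=f"{name}_p{pos}_r{rep}",
                                         sequence=mutate(window)))
        else:
            mean, sd = config.fragment_len
            fmax = len(tx)
            positions = list(range(0, len(tx) - L + 1, config.step))
            for pos in positions:
                flen = int(round(rng.normal(mean, sd)))
                flen = max(L, min(flen, fmax - pos))
                frag = tx[pos:pos + flen]
                for rep in range(k):
                    rid = f"{name}_f{pos}_r{rep}"
                    r1 = RawRead(id=rid + "/1", sequence=mutate(frag[:L]),
                                 mate_id=rid + "/2")
                    r2 = RawRead(id=rid + "/2", sequence=mutate(frag[-L:]),
                                 mate_id=rid + "/1")
                    reads.extend((r1, r2))
    return reads, truth


def write_fasta(entries: dict[str, str] | list[RawRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        if isinstance(entries, dict):
            items = entries.items()
        else:
            items = ((r.id, r.sequence) for r in entries)
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def write_simulation(model: GeneModel, config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Write reads FASTA, truth FASTA and a JSON manifest; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reads, truth = simulate_reads(model, config)
    paths = {
        "reads": outdir / "reads.fasta",
        "truth": outdir / "truth.fasta",
        "manifest": outdir / "manifest.json",
    }
    write_fasta(reads, paths["reads"])
    write_fasta(truth, paths["truth"])
    manifest = model.to_manifest()
    manifest["config"] = {
        "L": config.L, "step": config.step,
        "fragment_len": list(config.fragment_len),
        "sub_error_rate": config.sub_error_rate,
        "paired": config.paired, "rng_seed": config.rng_seed,
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return paths
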