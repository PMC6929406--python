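"""Read parsing, deduplication and assembly output.

The assembler works on fixed-length reads over the {A,C,G,T} alphabet.
Identical raw reads are collapsed into a single :class:`UniqueRead` whose
*multiplicity* (the number of collapsed copies) serves as the read's
coverage everywhere downstream: seed selection, candidate choice and
vertex/edge weighting all consume multiplicities, never raw read lists.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger("isoweave")

_ACGT = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class ReadParseError(ValueError):
    """Raised for malformed read records."""


@dataclass
class RawRead:
    """A single sequencing read as parsed from FASTA/FASTQ."""

    id: str
    sequence: str
    mate_id: str | None = None
    quality: str | None = None


@dataclass
class UniqueRead:
    """A deduplicated read: one sequence, the count of identical copies."""

    uid: int
    sequence: str
    multiplicity: int
    member_ids: list[str] = field(default_factory=list)

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.sequence)


@dataclass
class AssemblyParams:
    """Tunable parameters of the assembler.

    Parameters
    ----------
    L:
        Read length in bases; reads of any other length are dropped.
    l:
        Minimum overlap in bases required between a contig terminus and a
        candidate read (``1 <= l <= L-1``, and ``l <= 32`` so an l-mer fits
        a 64-bit packed integer).
    min_transcript_len:
        Reported transcripts must be strictly longer than this (bases).
    min_transcript_cov:
        Reported transcripts must have a bottleneck coverage (reads per
        base, the minimum vertex/edge weight along the path) strictly
        above this.
    min_mapped_reads:
        At least this many reads (counting multiplicities) must map
        exactly onto the transcript sequence.
    seed_cov_mode:
        ``"above_mean"`` seeds extension from reads whose multiplicity
        strictly exceeds the mean (falling back to all reads when nothing
        exceeds it, e.g. duplicate-free data); ``"all"`` seeds every read.
    hybrid_stop_cov:
        The hybrid path extractor stops once the best remaining bottleneck
        coverage drops below this (reads per base).
    trim_rel_weight:
        Splicing-graph edges lighter than this fraction of their heaviest
        sibling edge are trimmed.
    both_strands:
        Additionally index reverse complements (for non-strand-specific
        libraries). Off by default: the protocol modelled is
        strand-specific.
    """

    L: int
    l: int
    min_transcript_len: int = 200
    min_transcript_cov: float = 2.0
    min_mapped_reads: int = 20
    seed_cov_mode: str = "above_mean"
    hybrid_stop_cov: float = 2.0
    trim_rel_weight: float = 0.05
    max_enum_paths: int = 10_000
    both_strands: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.l <= self.L - 1):
            raise ValueError(f"need 1 <= l <= L-1, got l={self.l}, L={self.L}")
        if self.l > 32:
            raise ValueError("l must be <= 32 (packed-integer compression bound)")
        if self.seed_cov_mode not in ("above_mean", "all"):
            raise ValueError(f"unknown seed_cov_mode {self.seed_cov_mode!r}")


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _sniff_format(path: str | Path) -> str:
    with _open_text(path) as fh:
        for line in fh:
            if line.strip():
                if line.startswith(">"):
                    return "fasta"
                if line.startswith("@"):
                    return "fastq"
                raise ReadParseError(f"{path}: cannot determine format from first record")
    return "fasta"  # empty file; format irrelevant


def parse_reads(path: str | Path, format: str = "auto") -> list[RawRead]:
    """Parse a FASTA or FASTQ file (optionally gzipped) into RawReads.

    Record order is preserved. Malformed records raise
    :class:`ReadParseError` naming the record index; an empty file yields
    an empty list with a warning.
    """
    fmt = _sniff_format(path) if format == "auto" else format
    reads: list[RawRead] = []
    with _open_text(path) as fh:
        try:
            for i, rec in enumerate(SeqIO.parse(fh, fmt)):
                qual = None
                if "phred_quality" in rec.letter_annotations:
                    qual = "".join(
                        chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                    )
                seq = str(rec.seq).upper()
                if not seq:
                    raise ReadParseError(f"{path}: record {i} ({rec.id}) is empty")
                reads.append(RawRead(id=rec.id, sequence=seq, quality=qual))
        except ValueError as exc:  # Bio.SeqIO signals malformed records this way
            raise ReadParseError(
                f"{path}: malformed record at index {len(reads)}: {exc}"
            ) from exc
    if not reads:
        logger.warning("%s: no reads parsed (empty file)", path)
    return reads


def parse_paired_reads(
    path1: str | Path,
    path2: str | Path | None = None,
    format: str = "auto",
    interleaved: bool = False,
) -> list[RawRead]:
    """Parse paired-end reads and link mates via ``mate_id``.

    Pairs are given either as two parallel files (``path1``/``path2``,
    record i of one is the mate of record i of the other) or as a single
    interleaved file (consecutive records are mates).
    """
    if path2 is not None:
        r1 = parse_reads(path1, format)
        r2 = parse_reads(path2, format)
        if len(r1) != len(r2):
            raise ReadParseError(
                f"paired files differ in record count: {len(r1)} vs {len(r2)}"
            )
        for a, b in zip(r1, r2):
            if a.id == b.id:  # disambiguate identical headers
                a.id, b.id = a.id + "/1", b.id + "/2"
            a.mate_id, b.mate_id = b.id, a.id
        return [r for pair in zip(r1, r2) for r in pair]
    if not interleaved:
        raise ValueError("need either a second path or interleaved=True")
    reads = parse_reads(path1, format)
    if len(reads) % 2:
        raise ReadParseError("interleaved file holds an odd number of records")
    for a, b in zip(reads[::2], reads[1::2]):
        if a.id == b.id:
            a.id, b.id = a.id + "/1", b.id + "/2"
        a.mate_id, b.mate_id = b.id, a.id
    return reads


def reverse_sequence(seq: str) -> str:
    """Plain character reversal (not reverse complement)."""
    return seq[::-1]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def deduplicate(reads: Sequence[RawRead], params: AssemblyParams) -> list[UniqueRead]:
    """Collapse identical read sequences into UniqueReads with multiplicities.

    Reads containing non-ACGT characters or whose length differs from
    ``params.L`` are dropped (counted and logged). Surviving identical
    sequences are merged; uids are assigned 0..n-1 in order of first
    occurrence. With ``params.both_strands`` each retained read also
    contributes its reverse complement (member id suffixed ``:rc``).
    """
    n_bad_alpha = n_bad_len = 0
    order: dict[str, UniqueRead] = {}

    def _add(seq: str, member: str) -> None:
        ur = order.get(seq)
        if ur is None:
            order[seq] = UniqueRead(uid=len(order), sequence=seq, multiplicity=1,
                                    member_ids=[member])
        else:
            ur.multiplicity += 1
            ur.member_ids.append(member)

    for r in reads:
        if len(r.sequence) != params.L:
            n_bad_len += 1
            continue
        if not _ACGT.issuperset(r.sequence):
            n_bad_alpha += 1
            continue
        _add(r.sequence, r.id)
        if params.both_strands:
            _add(reverse_complement(r.sequence), r.id + ":rc")
    if n_bad_alpha or n_bad_len:
        logger.info(
            "deduplicate: dropped %d reads with non-ACGT bases, %d with length != %d",
            n_bad_alpha, n_bad_len, params.L,
        )
    if not order:
        raise ValueError("no usable reads")
    return list(order.values())


def expand(unique_reads: Iterable[UniqueRead]) -> list[RawRead]:
    """Inverse of :func:`deduplicate` up to ids: one RawRead per member."""
    out = []
    for ur in unique_reads:
        for mid in ur.member_ids:
            out.append(RawRead(id=mid, sequence=ur.sequence))
    return out


def write_transcripts_fasta(records, path: str | Path) -> int:
    """Write assembled transcripts as FASTA.

    ``records`` yields ``(locus_idx, path_idx, sequence, coverage)``;
    headers follow ``>locus<i>_path<j> len=<n> cov=<c>``.
    """
    n = 0
    with open(path, "w") as fh:
        for locus_idx, path_idx, seq, cov in records:
            fh.write(f">locus{locus_idx}_path{path_idx} len={len(seq)} cov={cov:.3f}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
            n += 1
    return n
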