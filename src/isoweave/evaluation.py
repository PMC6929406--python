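"""Scoring assembled transcripts against an annotation set.

Two notions of success are used, both at a 95% threshold by default:

* a *full-length reconstructed* transcript is an assembled sequence with
  at least 95% identity to some annotated transcript;
* a *full-length identified* transcript is an annotated sequence at
  least 95% of whose bases are covered by a single best-matching
  assembled transcript.

recall = identified / annotated, precision = reconstructed / assembled.

Alignment is done in-process with an affine-gap local aligner (match 1,
mismatch -2, gap open -3, extend -1). Identity is matches divided by the
alignment length, floored below by the shorter sequence length so that a
short perfect block shared by otherwise unrelated sequences cannot score
as identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from Bio import Align

logger = logging.getLogger("isoweave")

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1.0, -2.0, -3.0, -1.0


@dataclass
class MatchRecord:
    assembled_id: str
    annotated_id: str
    identity_fraction: float
    annotated_covered_fraction: float
    score: float = 0.0


@dataclass
class EvalSummary:
    n_annotated: int
    n_assembled: int
    n_full_length_identified: int
    n_full_length_reconstructed: int
    recall: float
    precision: float


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = MATCH
    a.mismatch_score = MISMATCH
    a.open_gap_score = GAP_OPEN
    a.extend_gap_score = GAP_EXTEND
    return a


def align_pair(assembled: str, annotated: str,
               assembled_id: str = "asm", annotated_id: str = "ann") -> MatchRecord:
    """Best local alignment of one assembled/annotated pair.

    identity = matches / max(alignment columns, min sequence length);
    covered = fraction of annotated bases inside aligned (match or
    mismatch) columns.
    """
    if not assembled or not annotated:
        raise ValueError("align_pair requires non-empty sequences")
    if assembled == annotated:  # fast path for the common exact case
        return MatchRecord(assembled_id, annotated_id, 1.0, 1.0,
                           score=float(len(annotated)))
    aln = _aligner().align(assembled, annotated)
    best = aln[0]
    matches = mismatches = columns = 0
    covered_ann = 0
    for (a0, a1), (b0, b1) in zip(*best.aligned):
        block = a1 - a0
        covered_ann += b1 - b0
        for i in range(block):
            if assembled[a0 + i] == annotated[b0 + i]:
                matches += 1
            else:
                mismatches += 1
    # columns of the local alignment, gaps included
    a_span = best.aligned[0][-1][1] - best.aligned[0][0][0]
    b_span = best.aligned[1][-1][1] - best.aligned[1][0][0]
    columns = max(a_span, b_span)
    denom = max(columns, min(len(assembled), len(annotated)))
    identity = matches / denom if denom else 0.0
    covered = covered_ann / len(annotated)
    return MatchRecord(assembled_id, annotated_id, identity, covered,
                       score=float(best.score))


def evaluate_all(assembled: dict[str, str], annotated: dict[str, str]) -> list[MatchRecord]:
    """All pairwise MatchRecords (dense; desk-scale inputs)."""
    out = []
    for aid, aseq in assembled.items():
        for nid, nseq in annotated.items():
            out.append(align_pair(aseq, nseq, aid, nid))
    return out


def classify_full_length(records: Sequence[MatchRecord],
                         threshold: float = 0.95) -> tuple[set[str], set[str]]:
    """(identified annotated ids, reconstructed assembled ids).

    An annotated transcript is identified when its single best-scoring
    assembled partner covers >= threshold of its bases; an assembled
    transcript is reconstructed when its best identity to any annotated
    transcript reaches the threshold.
    """
    reconstructed = set()
    best_ident: dict[str, float] = {}
    best_partner: dict[str, MatchRecord] = {}
    for r in records:
        if r.identity_fraction > best_ident.get(r.assembled_id, -1.0):
            best_ident[r.assembled_id] = r.identity_fraction
        prev = best_partner.get(r.annotated_id)
        if prev is None or r.score > prev.score:
            best_partner[r.annotated_id] = r
    reconstructed = {aid for aid, ident in best_ident.items() if ident >= threshold}
    identified = {nid for nid, r in best_partner.items()
                  if r.annotated_covered_fraction >= threshold}
    return identified, reconstructed


def summarize(identified: set[str], reconstructed: set[str],
              n_annotated: int, n_assembled: int) -> EvalSummary:
    """recall = |identified| / n_annotated; precision = |reconstructed| /
    n_assembled. Zero denominators yield 0 with a warning."""
    if n_annotated == 0 or n_assembled == 0:
        logger.warning("evaluation with zero annotated or assembled transcripts")
    recall = len(identified) / n_annotated if n_annotated else 0.0
    precision = len(reconstructed) / n_assembled if n_assembled else 0.0
    return EvalSummary(
        n_annotated=n_annotated,
        n_assembled=n_assembled,
        n_full_length_identified=len(identified),
        n_full_length_reconstructed=len(reconstructed),
        recall=recall,
        precision=precision,
    )


def evaluate(assembled: dict[str, str], annotated: dict[str, str],
             threshold: float = 0.95) -> tuple[EvalSummary, list[MatchRecord]]:
    """End-to-end evaluation of two transcript sets (id -> sequence)."""
    records = evaluate_all(assembled, annotated)
    identified, reconstructed = classify_full_length(records, threshold)
    return summarize(identified, reconstructed,
                     len(annotated), len(assembled)), records
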