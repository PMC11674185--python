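"""Shared pairwise-alignment helpers.

All alignment in the pipeline (adapter search, 5' read validation, 3' UTR
detection, pileup mapping) runs through Biopython's PairwiseAligner with
simple match/mismatch/gap scores.  This module wraps it so the rest of the
package only sees per-alignment summary statistics.

Identity is defined as matches / alignment columns, where columns include
internal gap columns but never the free end gaps of a semi-global
alignment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from Bio import Align

COMPLEMENT = str.maketrans("ACGTNacgtn*", "TGCANtgcan*")


def revcomp(seq: str) -> str:
    """Reverse-complement a DNA string (N and the mask symbol map to themselves)."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignmentSummary:
    """Summary of one pairwise alignment.

    Spans are 0-based half-open on the original sequences; ``columns``
    counts aligned pairs plus internal gap columns (end gaps excluded).
    """

    score: float
    matches: int
    columns: int
    target_start: int
    target_end: int
    query_start: int
    query_end: int

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0


def make_local_aligner(match: float = 1, mismatch: float = -1,
                       gap: float = -2) -> Align.PairwiseAligner:
    """Smith-Waterman-style local aligner with linear gap penalty."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def make_semiglobal_aligner(match: float = 1, mismatch: float = -1,
                            gap_open: float = -2,
                            gap_extend: float = -1) -> Align.PairwiseAligner:
    """Global aligner with free end gaps on the target (reference overhangs)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    # Reference (target) bases left unmatched at either end cost nothing.
    aligner.open_left_deletion_score = 0
    aligner.extend_left_deletion_score = 0
    aligner.open_right_deletion_score = 0
    aligner.extend_right_deletion_score = 0
    return aligner


def _summarize(alignment, target: str, query: str) -> AlignmentSummary:
    t_blocks, q_blocks = alignment.aligned
    if len(t_blocks) == 0:
        return AlignmentSummary(alignment.score, 0, 0, 0, 0, 0, 0)
    matches = 0
    columns = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        columns += te - ts
        for a, b in zip(target[ts:te], query[qs:qe]):
            if a == b:
                matches += 1
    # internal gap columns between consecutive aligned blocks
    for i in range(1, len(t_blocks)):
        columns += t_blocks[i][0] - t_blocks[i - 1][1]
        columns += q_blocks[i][0] - q_blocks[i - 1][1]
    return AlignmentSummary(
        score=alignment.score,
        matches=matches,
        columns=columns,
        target_start=int(t_blocks[0][0]),
        target_end=int(t_blocks[-1][1]),
        query_start=int(q_blocks[0][0]),
        query_end=int(q_blocks[-1][1]),
    )


def best_alignment(aligner: Align.PairwiseAligner, target: str, query: str,
                   n_coopt: int = 1) -> AlignmentSummary | None:
    """Best alignment of ``query`` against ``target``.

    Among up to ``n_coopt`` co-optimal alignments, the one whose query
    interval starts earliest is returned (deterministic tie-break used by
    the UTR finder).  Returns ``None`` when no alignment with positive
    score exists.
    """
    if not target or not query:
        return None
    alignments = aligner.align(target, query)
    try:
        first = next(iter(alignments))
    except (StopIteration, IndexError):
        return None
    if first.score <= 0:
        return None
    if n_coopt <= 1:
        return _summarize(first, target, query)
    best = _summarize(first, target, query)
    for alt in itertools.islice(alignments, 1, n_coopt):
        if alt.score < first.score:
            break
        cand = _summarize(alt, target, query)
        if cand.query_start < best.query_start:
            best = cand
    return best
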