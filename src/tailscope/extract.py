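"""Valid 3'-read extraction from paired-end amplicon reads.

Each pair should contain one mate that begins with the ligated 3' adapter
(the "3' read", which reads the tail as poly(T)) and one mate covering the
mRNA body (the "5' read").  A pair is kept when

* exactly one mate carries the adapter at its head, aligned over the full
  adapter length at >= 90% identity, and
* the other mate aligns locally to the target mRNA at >= 90% identity
  over >= 200 columns (contamination guard).

Everything else is discarded with a logged reason.  No quality filter is
applied at any point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from ._align import AlignmentSummary, best_alignment, make_local_aligner
from .refcorrect import ReferenceAmplicon
from .seqio import Read

DISCARD_NO_ADAPTER = "no_adapter"
DISCARD_AMBIGUOUS = "adapter_on_both_mates"
DISCARD_READ5 = "read5_failed_validation"


@dataclass(frozen=True)
class ReadPair:
    """A raw mate pair, before role assignment."""

    read_id: str
    mate1: Read
    mate2: Read


@dataclass(frozen=True)
class ClassifiedPair:
    """A pair whose mates have been assigned 5'/3' roles."""

    read_id: str
    read5: Read
    read3: Read
    adapter_hit: "AdapterHit"


@dataclass(frozen=True)
class AdapterHit:
    """Best local alignment of the full adapter against a read."""

    identity: float
    adapter_coverage: float
    read_start: int
    read_end: int
    score: float


_ADAPTER_ALIGNER = make_local_aligner(match=1, mismatch=-1, gap=-2)
_READ5_ALIGNER = make_local_aligner(match=1, mismatch=-1, gap=-2)


def find_adapter(read_seq: str, adapter: str) -> AdapterHit | None:
    """Locate the adapter in a read by local alignment.

    identity = matches / alignment columns; adapter_coverage = extent of
    the adapter involved in the alignment / adapter length.  ``None`` when
    no positive-scoring alignment exists.
    """
    if len(adapter) < 10:
        raise ValueError("adapter must be at least 10 nt")
    summary = best_alignment(_ADAPTER_ALIGNER, read_seq, adapter)
    if summary is None:
        return None
    return AdapterHit(
        identity=summary.identity,
        adapter_coverage=(summary.query_end - summary.query_start) / len(adapter),
        read_start=summary.target_start,
        read_end=summary.target_end,
        score=summary.score,
    )


def accept_adapter(hit: AdapterHit | None, min_identity: float = 0.90,
                   max_head_offset: int = 0) -> bool:
    """Adapter acceptance rule: >=90% identity, full coverage, at the read head."""
    if hit is None:
        return False
    return (hit.identity >= min_identity
            and hit.adapter_coverage >= 1.0
            and hit.read_start <= max_head_offset)


def classify_pair(pair: ReadPair, adapter: str, min_identity: float = 0.90,
                  max_head_offset: int = 0) -> ClassifiedPair | str:
    """Assign 5'/3' roles, or return a discard reason string.

    The mate with an accepted adapter hit becomes the 3' read.  Pairs with
    the adapter on neither mate are discarded; pairs with the adapter on
    both are discarded as ambiguous rather than guessed.
    """
    hit1 = find_adapter(pair.mate1.seq, adapter)
    hit2 = find_adapter(pair.mate2.seq, adapter)
    ok1 = accept_adapter(hit1, min_identity, max_head_offset)
    ok2 = accept_adapter(hit2, min_identity, max_head_offset)
    if ok1 and ok2:
        return DISCARD_AMBIGUOUS
    if not ok1 and not ok2:
        return DISCARD_NO_ADAPTER
    if ok1:
        return ClassifiedPair(pair.read_id, read5=pair.mate2,
                              read3=pair.mate1, adapter_hit=hit1)
    return ClassifiedPair(pair.read_id, read5=pair.mate1,
                          read3=pair.mate2, adapter_hit=hit2)


def validate_read5(read5_seq: str, ref: ReferenceAmplicon,
                   min_identity: float = 0.90, min_aln_len: int = 200) -> bool:
    """5' read passes when it aligns to the target mRNA at >=90% identity
    over >=200 alignment columns."""
    summary = best_alignment(_READ5_ALIGNER, ref.sequence, read5_seq)
    if summary is None:
        return False
    return summary.identity >= min_identity and summary.columns >= min_aln_len


def extract_pairs(pairs: Iterable[ReadPair], adapter: str,
                  ref: ReferenceAmplicon, min_identity: float = 0.90,
                  max_head_offset: int = 0, min_aln_len: int = 200,
                  ) -> tuple[list[ClassifiedPair], list[tuple[str, str]]]:
    """Run the full extraction filter.

    Returns the surviving classified pairs and a discard log of
    (read_id, reason) tuples.
    """
    kept: list[ClassifiedPair] = []
    discards: list[tuple[str, str]] = []
    for pair in pairs:
        result = classify_pair(pair, adapter, min_identity, max_head_offset)
        if isinstance(result, str):
            discards.append((pair.read_id, result))
            continue
        if not validate_read5(result.read5.seq, ref, min_identity, min_aln_len):
            discards.append((pair.read_id, DISCARD_READ5))
            continue
        kept.append(result)
    return kept, discards
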