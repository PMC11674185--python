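"""Majority-vote correction of the targeted mRNA reference sequence.

The amplicon reference (e.g. a database mRNA accession) can differ from
the individual animal's transcript by occasional substitutions, which
would both lose mapped reads and fake 3'-end modifications.  The fix is a
simple consensus pass over the sample's own mRNA-body (5') reads:

1. pad the reference 3' end with a 50 nt poly(A) run in silico, so reads
   running into the tail still align instead of dangling;
2. randomly downsample the reads to ~1000x mean coverage;
3. align them end-gap-free to the padded reference and pile up bases;
4. replace each reference base by the strict majority base of its pileup
   column (ties and uncovered positions keep the original base);
5. strip the poly(A) pad again.

Only substitutions are corrected; the consensus is per-position and not
indel-aware.
"""

from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from ._align import best_alignment, make_semiglobal_aligner

BASES = "ACGTN"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class ReferenceAmplicon:
    """A targeted mRNA 3'-region reference with correction bookkeeping."""

    gene_id: str
    sequence: str
    padded: bool = False
    pad_len: int = 0
    correction_log: tuple[tuple[int, str, str], ...] = ()

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Pileup:
    """Per-position base counts (A, C, G, T, N) from aligned reads."""

    counts: np.ndarray  # shape (ref_len, 5), dtype int64

    @classmethod
    def empty(cls, ref_len: int) -> "Pileup":
        return cls(np.zeros((ref_len, 5), dtype=np.int64))

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def add(self, position: int, base: str, count: int = 1) -> None:
        self.counts[position, _BASE_INDEX.get(base.upper(), 4)] += count

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.counts, columns=list(BASES))
        df.insert(0, "position", np.arange(len(df)))
        df["depth"] = self.depth
        return df


def pad_polyA(ref: ReferenceAmplicon, pad_len: int = 50) -> ReferenceAmplicon:
    """Append ``pad_len`` A's to the 3' end (in silico, to protect alignment)."""
    if ref.padded:
        raise ValueError(f"reference {ref.gene_id} is already padded")
    return replace(ref, sequence=ref.sequence + "A" * pad_len,
                   padded=True, pad_len=pad_len)


def strip_pad(ref: ReferenceAmplicon) -> ReferenceAmplicon:
    """Remove the in-silico poly(A) pad; corrections inside it are discarded."""
    if not ref.padded:
        raise ValueError(f"reference {ref.gene_id} is not padded")
    body_len = len(ref.sequence) - ref.pad_len
    log = tuple(entry for entry in ref.correction_log if entry[0] < body_len)
    return replace(ref, sequence=ref.sequence[:body_len], padded=False,
                   pad_len=0, correction_log=log)


def downsample_reads(reads: Sequence, ref_len: int, target_depth: int = 1000,
                     seed: int = 0) -> list:
    """Sample reads without replacement until mean coverage reaches the target.

    Coverage is defined as cumulative sampled bases / reference length.
    Deterministic for a fixed seed; returns everything when the pool is
    too small to reach the target.
    """
    if target_depth <= 0:
        raise ValueError("target_depth must be positive")
    order = list(range(len(reads)))
    random.Random(seed).shuffle(order)
    chosen: list = []
    sampled_bases = 0
    for idx in order:
        if sampled_bases / ref_len >= target_depth:
            break
        chosen.append(reads[idx])
        sampled_bases += len(_read_seq(reads[idx]))
    return chosen


def _read_seq(read) -> str:
    return read.seq if hasattr(read, "seq") else str(read)


def align_and_pileup(ref: ReferenceAmplicon, reads: Iterable,
                     min_identity: float = 0.8) -> Pileup:
    """Align reads end-gap-free to the reference and tally per-position bases.

    Reads whose best alignment identity falls below ``min_identity`` are
    skipped (chimeras/contaminants).  Identical sequences are aligned once
    and counted with their multiplicity.  Among co-optimal alignments the
    one with the fewest gap columns is used: the consensus is
    substitution-only, so a tie between a terminal mismatch and an
    equally-scoring gap slide (e.g. into the poly(A) pad) must resolve to
    the gapless interpretation.
    """
    import itertools

    pileup = Pileup.empty(len(ref.sequence))
    aligner = make_semiglobal_aligner(match=1, mismatch=-1,
                                      gap_open=-2, gap_extend=-1)
    multiplicity = Counter(_read_seq(r) for r in reads)
    for seq, count in multiplicity.items():
        if not seq:
            continue
        alignments = aligner.align(ref.sequence, seq)
        best = None  # (n_gap_columns, -matches, t_blocks, q_blocks, columns)
        for aln in itertools.islice(alignments, 8):
            t_blocks, q_blocks = aln.aligned
            if len(t_blocks) == 0:
                continue
            matches = sum(
                1
                for (ts, te), (qs, qe) in zip(t_blocks, q_blocks)
                for a, b in zip(ref.sequence[ts:te], seq[qs:qe])
                if a == b
            )
            aligned_cols = sum(te - ts for ts, te in t_blocks)
            gap_cols = 0
            for i in range(1, len(t_blocks)):
                gap_cols += t_blocks[i][0] - t_blocks[i - 1][1]
                gap_cols += q_blocks[i][0] - q_blocks[i - 1][1]
            key = (gap_cols, -matches)
            if best is None or key < best[0]:
                best = (key, t_blocks, q_blocks, matches, aligned_cols + gap_cols)
        if best is None:
            continue
        _, t_blocks, q_blocks, matches, columns = best
        if columns == 0 or matches / columns < min_identity:
            continue
        for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
            for offset in range(te - ts):
                pileup.add(ts + offset, seq[qs + offset], count)
    return pileup


def majority_correct(ref: ReferenceAmplicon, pileup: Pileup) -> ReferenceAmplicon:
    """Replace each base by the strict pileup majority (A/C/G/T only).

    A position changes only when a single base has strictly the highest
    count and the column has coverage; ties and zero-depth columns keep
    the original base.  Changes are appended to the correction log.
    """
    if pileup.counts.shape[0] != len(ref.sequence):
        raise ValueError("pileup length does not match reference length")
    seq = list(ref.sequence)
    log = list(ref.correction_log)
    acgt = pileup.counts[:, :4]
    for pos in range(len(seq)):
        column = acgt[pos]
        top = column.max()
        if top == 0:
            continue
        winners = np.flatnonzero(column == top)
        if len(winners) != 1:
            continue
        new_base = BASES[winners[0]]
        if new_base != seq[pos]:
            log.append((pos, seq[pos], new_base))
            seq[pos] = new_base
    return replace(ref, sequence="".join(seq), correction_log=tuple(log))


def correct_reference(ref: ReferenceAmplicon, reads: Sequence,
                      target_depth: int = 1000, pad_len: int = 50,
                      seed: int = 0,
                      min_identity: float = 0.8) -> ReferenceAmplicon:
    """Full correction pass: pad, downsample, pile up, majority-vote, strip."""
    padded = pad_polyA(ref, pad_len)
    subset = downsample_reads(reads, len(padded.sequence), target_depth, seed)
    pileup = align_and_pileup(padded, subset, min_identity=min_identity)
    corrected = majority_correct(padded, pileup)
    return strip_pad(corrected)
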