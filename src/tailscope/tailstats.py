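"""Aggregate tail statistics and Sanger-clone terminal-uridine statistics.

All read-level statistics operate on :class:`~tailscope.tailcall.TailCall`
records.  The "tail" of a read is its called poly(A) region concatenated
with its 3'-end modification region; only reads with a called poly(A)
contribute.  Bases with Phred < 20 are masked out of composition and
positional statistics (numerator and denominator), but never out of
region detection.

Frequencies are reported in percent.  Poly(A) lengths >= 40 nt are pooled
into a single ">=40" bin, because long homopolymer lengths are
systematically overestimated by base calling and the exact values are not
trustworthy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as scipy_stats

from .tailcall import MASK, TailCall, mask_low_quality

GE_CAP_LABEL = ">=40"

LENCLASS_SHORT = "<=40"
LENCLASS_LONG = ">40"


def _with_polyA(calls: Iterable[TailCall]) -> list[TailCall]:
    return [c for c in calls if c.has_polyA]


def _masked_tail(call: TailCall, threshold: int) -> str:
    if call.tail_quals and len(call.tail_quals) == len(call.tail_seq):
        return mask_low_quality(call.tail_seq, call.tail_quals, threshold)
    return call.tail_seq


def length_distribution(calls: Iterable[TailCall], cap: int = 40,
                        ) -> dict[int | str, float]:
    """Relative frequency (%) of poly(A) lengths, capped into a ">=cap" bin.

    The denominator is the number of reads with a called poly(A); reads
    without one do not enter.  Returns an empty dict for an empty batch.
    """
    lengths = [c.polyA_len for c in _with_polyA(calls)]
    if not lengths:
        return {}
    hist: dict[int | str, float] = {i: 0.0 for i in range(cap)}
    hist[GE_CAP_LABEL] = 0.0
    unit = 100.0 / len(lengths)
    for length in lengths:
        key: int | str = length if length < cap else GE_CAP_LABEL
        hist[key] += unit
    return hist


def mod_class_frequencies(calls: Iterable[TailCall], lenclass_cut: int = 40,
                          ) -> dict[str, dict[str, float]]:
    """Modification-class frequencies (%) for short (<=cut) vs long (>cut) tails.

    Only reads with a called poly(A) are partitioned; the "none" class
    (poly(A) with no trailing modification) is included.  A length class
    with no reads is simply absent from the result.
    """
    short = [c for c in _with_polyA(calls) if c.polyA_len <= lenclass_cut]
    long_ = [c for c in _with_polyA(calls) if c.polyA_len > lenclass_cut]
    out: dict[str, dict[str, float]] = {}
    for label, group in ((LENCLASS_SHORT, short), (LENCLASS_LONG, long_)):
        if not group:
            continue
        freqs: dict[str, float] = {}
        unit = 100.0 / len(group)
        for call in group:
            freqs[call.mod_class] = freqs.get(call.mod_class, 0.0) + unit
        out[label] = freqs
    return out


def positional_nonA(calls: Iterable[TailCall], direction: str = "5to3",
                    mask_threshold: int = 20) -> pd.DataFrame:
    """Per-position non-A frequency (%) along tails, 5'->3' or 3'->5'.

    Position i (1-based in the output) counts every read whose tail is at
    least i bases long; its frequency is the fraction of those reads with
    a non-A base there.  Masked bases are excluded from both counts, so a
    position's denominator can be smaller than the number of reads
    reaching it.
    """
    if direction not in ("5to3", "3to5"):
        raise ValueError("direction must be '5to3' or '3to5'")
    tails = [_masked_tail(c, mask_threshold) for c in _with_polyA(calls)]
    tails = [t for t in tails if t]
    if not tails:
        return pd.DataFrame(columns=["position", "pct_nonA", "n_reads"])
    max_len = max(len(t) for t in tails)
    non_a = np.zeros(max_len, dtype=np.int64)
    denom = np.zeros(max_len, dtype=np.int64)
    for tail in tails:
        if direction == "3to5":
            tail = tail[::-1]
        for i, base in enumerate(tail):
            if base == MASK:
                continue
            denom[i] += 1
            if base.upper() != "A":
                non_a[i] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(denom > 0, 100.0 * non_a / np.maximum(denom, 1), np.nan)
    return pd.DataFrame({
        "position": np.arange(1, max_len + 1),
        "pct_nonA": pct,
        "n_reads": denom,
    })


def composition_nonA(calls: Iterable[TailCall],
                     mask_threshold: int = 20) -> dict[str, float]:
    """Pooled % of U, G and C among all unmasked tail bases.

    Empty input (or fully masked tails) yields an empty dict.
    """
    counts = {"U": 0, "G": 0, "C": 0}
    total = 0
    for call in _with_polyA(calls):
        for base in _masked_tail(call, mask_threshold):
            if base == MASK:
                continue
            total += 1
            base = base.upper()
            if base == "T":
                counts["U"] += 1
            elif base in counts:
                counts[base] += 1
    if total == 0:
        return {}
    return {b: 100.0 * c / total for b, c in counts.items()}


@dataclass(frozen=True)
class CloneGroupStats:
    """Terminal-uridine summary for one group of Sanger clone sequences."""

    group_label: str
    counts: tuple[int, ...]
    mean: float
    se: float
    k: int
    flags: tuple[str, ...] = ()


def terminal_uridine_stats(clone_seqs: Sequence[str], k: int = 5,
                           group_label: str = "") -> CloneGroupStats:
    """Mean +/- SE of the number of U/T residues in each clone's last k nt.

    SE is the sample standard deviation / sqrt(n).  Clones shorter than k
    are counted over their full length and flagged; a single-clone group
    reports SE = 0 with a flag.
    """
    if not clone_seqs:
        raise ValueError("empty clone group")
    counts = []
    flags: list[str] = []
    for seq in clone_seqs:
        window = seq[-k:] if len(seq) >= k else seq
        if len(seq) < k:
            flags.append(f"clone_shorter_than_k:{len(seq)}")
        counts.append(sum(1 for b in window.upper() if b in "TU"))
    n = len(counts)
    mean = float(np.mean(counts))
    if n == 1:
        se = 0.0
        flags.append("n=1:SE_undefined_reported_as_0")
    else:
        se = float(np.std(counts, ddof=1) / math.sqrt(n))
    return CloneGroupStats(group_label, tuple(counts), mean, se, k, tuple(flags))


def tukey_hsd(groups: Mapping[str, Sequence[float]], alpha: float = 0.05,
              ) -> pd.DataFrame:
    """Pairwise Tukey honestly-significant-difference comparisons.

    Standard one-way-ANOVA-style studentized-range comparisons across all
    group pairs; every group needs at least two observations.  Returns
    one row per unordered pair with the mean difference, adjusted p-value
    and significance at ``alpha``.

    Degenerate input with zero within-group variance makes the
    studentized range undefined; the limiting convention is used instead
    (p = 0 for differing means, p = 1 for equal means).
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("tukey_hsd needs at least two groups")
    samples = [np.asarray(groups[lab], dtype=float) for lab in labels]
    for lab, sample in zip(labels, samples):
        if len(sample) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 observations")
    zero_mse = all(np.ptp(sample) == 0 for sample in samples)
    if not zero_mse:
        result = scipy_stats.tukey_hsd(*samples)
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            if zero_mse:
                p = 0.0 if samples[i].mean() != samples[j].mean() else 1.0
            else:
                p = float(result.pvalue[i, j])
            rows.append({
                "group1": labels[i],
                "group2": labels[j],
                "mean_diff": float(samples[i].mean() - samples[j].mean()),
                "p_adj": p,
                "significant": p < alpha,
            })
    return pd.DataFrame(rows)


@dataclass
class TailProfile:
    """Bundle of the standard summary statistics for one call batch."""

    n_reads_with_polyA: int
    length_hist: dict
    mod_class_freq_by_lenclass: dict
    positional_nonA_5to3: pd.DataFrame
    positional_nonA_3to5: pd.DataFrame
    composition_nonA: dict

    def to_json_dict(self) -> dict:
        return {
            "n_reads_with_polyA": self.n_reads_with_polyA,
            "length_hist": {str(k): v for k, v in self.length_hist.items()},
            "mod_class_freq_by_lenclass": self.mod_class_freq_by_lenclass,
            "positional_nonA_5to3": self.positional_nonA_5to3.to_dict("list"),
            "positional_nonA_3to5": self.positional_nonA_3to5.to_dict("list"),
            "composition_nonA": self.composition_nonA,
        }


def profile(calls: Sequence[TailCall], mask_threshold: int = 20,
            lenclass_cut: int = 40) -> TailProfile:
    """Compute the full statistics bundle for a batch of calls."""
    return TailProfile(
        n_reads_with_polyA=sum(1 for c in calls if c.has_polyA),
        length_hist=length_distribution(calls, cap=lenclass_cut),
        mod_class_freq_by_lenclass=mod_class_frequencies(calls, lenclass_cut),
        positional_nonA_5to3=positional_nonA(calls, "5to3", mask_threshold),
        positional_nonA_3to5=positional_nonA(calls, "3to5", mask_threshold),
        composition_nonA=composition_nonA(calls, mask_threshold),
    )
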