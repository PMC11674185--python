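"""Synthetic targeted-amplicon read simulator with ground truth.

The generator emulates the statistical structure the tail caller assumes
for a maturing-oocyte mRNA population:

* a bimodal poly(A) length mixture — a ``p_long`` fraction of transcripts
  carry long tails (>= 40 nt, e.g. 45-60) and the rest short tails
  (10-20 nt);
* terminal oligo(U) on a configurable fraction of short tails, with
  geometric U-run lengths (support >= 1);
* optional non-canonical tails, in which each tail position is non-A with
  a probability interpolated linearly from a 5' value (e.g. 0.30) down to
  a 3' value (e.g. 0.05), the non-A base drawn from U/G/C weights;
* per-base Gaussian Phred qualities clamped to a floor/ceiling, so a
  configurable share of bases drops below the Q20 masking threshold;
* uniform substitution sequencing error.

Read pairs mimic a 2x300 nt MiSeq amplicon run: the 5' mate is the
reference sense strand read from its start, the 3' mate is the ligated
3' adapter followed by the reverse complement of the transcript 3' end
(tail first).  Every read records its ground truth so that each pipeline
stage can be verified exactly.

Tail sequences are emitted in DNA space (U as T); the "U" naming is kept
for class labels only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._align import revcomp
from .extract import ReadPair
from .refcorrect import ReferenceAmplicon
from .seqio import Read
from .tailcall import EMPTY_SPAN, TailCall, classify_mod

MIN_REF_LEN = 260
_NON_A = np.array(list("TGC"))


@dataclass(frozen=True)
class StageConfig:
    """Tail-state parameters for one developmental stage.

    Defaults describe an immature (GV) oocyte population: half the
    transcripts with long (45-60 nt) tails, half with short (10-20 nt)
    tails of which 60% carry a terminal oligo(U) of mean length 3.
    """

    stage_label: str = "GV"
    p_long: float = 0.5
    long_len_range: tuple[int, int] = (45, 60)
    short_len_range: tuple[int, int] = (10, 20)
    p_uridylated: float = 0.6
    u_tail_len_mean: float = 3.0
    noncanonical: bool = False
    nonA_5prime: float = 0.30
    nonA_3prime: float = 0.05
    nonA_base_weights: tuple[float, float, float] = (0.6, 0.3, 0.1)

    def __post_init__(self):
        for name in ("p_long", "p_uridylated", "nonA_5prime", "nonA_3prime"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} is not a fraction in [0, 1]")
        for name in ("long_len_range", "short_len_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}=({lo}, {hi}) is not ordered low <= high")
        if self.long_len_range[0] < 40:
            raise ValueError("long tails are defined as >= 40 nt")
        if self.u_tail_len_mean < 1:
            raise ValueError("u_tail_len_mean must be >= 1")
        if any(w < 0 for w in self.nonA_base_weights):
            raise ValueError("nonA_base_weights must be nonnegative")
        if abs(sum(self.nonA_base_weights) - 1.0) > 1e-9:
            raise ValueError("nonA_base_weights must sum to 1")


@dataclass(frozen=True)
class ErrorModel:
    """Substitution-only sequencing error plus a Gaussian quality model."""

    sub_rate: float = 0.003
    q_mean: float = 32.0
    q_sd: float = 6.0
    q_floor: int = 2
    q_ceiling: int = 41

    def __post_init__(self):
        if not 0.0 <= self.sub_rate <= 1.0:
            raise ValueError("sub_rate must be a fraction in [0, 1]")
        if not (2 <= self.q_floor <= self.q_ceiling <= 41):
            raise ValueError("quality bounds must satisfy 2 <= floor <= ceiling <= 41")


ERROR_FREE = ErrorModel(sub_rate=0.0, q_mean=38.0, q_sd=0.0)

# Stage presets mirroring the tail regimes seen across oocyte maturation
# and early development: GV = bimodal long/short with uridylated short
# tails; mature (post-hormone) = short, highly uridylated; blastula =
# re-elongated non-canonical tails with a 5'-skewed non-A gradient.
STAGE_PRESETS: dict[str, StageConfig] = {
    "GV": StageConfig(),
    "mature": StageConfig(stage_label="mature", p_long=0.05,
                          short_len_range=(0, 12), p_uridylated=0.7),
    "blastula": StageConfig(stage_label="blastula", p_long=0.4,
                            long_len_range=(40, 70), short_len_range=(10, 25),
                            p_uridylated=0.3, noncanonical=True),
}


@dataclass(frozen=True)
class TailTruth:
    """Ground truth for one simulated read's tail."""

    read_id: str
    polyA_len: int
    tail_seq: str
    mod_seq: str
    stage_label: str


def gen_reference(length: int = 300, gc_fraction: float = 0.5,
                  seed: int = 0, gene_id: str = "synthetic") -> ReferenceAmplicon:
    """Random reference amplicon with no internal A-run of >= 8 nt.

    The minimum length of 260 nt guarantees that a 5' read can reach the
    200-column alignment the extraction filter demands while leaving a
    >= 30 nt UTR anchor on the 3' read.  The no-long-A-run constraint is
    a fixture guarantee (genomic A-runs must not masquerade as tails in
    tests), not a claim about real transcripts.
    """
    if length < MIN_REF_LEN:
        raise ValueError(
            f"reference length {length} < {MIN_REF_LEN}: the 5' read could "
            "not satisfy the 200 nt alignment-length requirement")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc_fraction) / 2, gc_fraction / 2,
                      gc_fraction / 2, (1 - gc_fraction) / 2])
    bases = list("ACGT")
    seq: list[str] = []
    a_run = 0
    for _ in range(length):
        base = rng.choice(bases, p=probs)
        if base == "A" and a_run >= 7:
            non_a_probs = probs[1:].copy()
            if non_a_probs.sum() == 0:  # gc_fraction 0: fall back to T
                base = "T"
            else:
                base = rng.choice(["C", "G", "T"], p=non_a_probs / non_a_probs.sum())
        a_run = a_run + 1 if base == "A" else 0
        seq.append(base)
    return ReferenceAmplicon(gene_id=gene_id, sequence="".join(seq))


def _geometric_len(rng: np.random.Generator, mean: float) -> int:
    # geometric with support >= 1 and the requested mean
    return int(rng.geometric(1.0 / max(mean, 1.0)))


def gen_tail(config: StageConfig, rng: np.random.Generator,
             read_id: str = "") -> TailTruth:
    """Draw one tail state from a stage configuration.

    With probability ``p_long`` the A-region length is uniform over the
    long range and no modification is added; otherwise it is uniform over
    the short range, with a terminal oligo(U) appended with probability
    ``p_uridylated``.  If the stage is non-canonical, each A-region
    position is flipped to a non-A base with the linearly interpolated
    probability.  ``polyA_len`` records the generated A-region length.
    """
    if rng.random() < config.p_long:
        lo, hi = config.long_len_range
        a_len = int(rng.integers(lo, hi + 1))
        mod = ""
    else:
        lo, hi = config.short_len_range
        a_len = int(rng.integers(lo, hi + 1))
        mod = ("T" * _geometric_len(rng, config.u_tail_len_mean)
               if rng.random() < config.p_uridylated else "")
    tail = ["A"] * a_len
    if config.noncanonical and a_len > 0:
        weights = np.asarray(config.nonA_base_weights)
        for i in range(a_len):
            frac = i / (a_len - 1) if a_len > 1 else 0.0
            p_non_a = config.nonA_5prime + frac * (config.nonA_3prime
                                                   - config.nonA_5prime)
            if rng.random() < p_non_a:
                tail[i] = str(rng.choice(_NON_A, p=weights))
    return TailTruth(read_id=read_id, polyA_len=a_len,
                     tail_seq="".join(tail) + mod, mod_seq=mod,
                     stage_label=config.stage_label)


def _apply_errors(seq: str, err: ErrorModel, rng: np.random.Generator) -> str:
    if err.sub_rate == 0.0 or not seq:
        return seq
    chars = np.array(list(seq))
    hits = np.flatnonzero(rng.random(len(chars)) < err.sub_rate)
    for i in hits:
        alternatives = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alternatives[int(rng.integers(3))]
    return "".join(chars)


def _draw_quals(n: int, err: ErrorModel, rng: np.random.Generator) -> tuple[int, ...]:
    q = rng.normal(err.q_mean, err.q_sd, size=n)
    return tuple(int(v) for v in np.clip(np.rint(q), err.q_floor, err.q_ceiling))


def gen_read_pair(ref: ReferenceAmplicon, truth: TailTruth, adapter: str,
                  err: ErrorModel, rng: np.random.Generator,
                  read_len: int = 300) -> ReadPair:
    """Emit the 2x``read_len`` mate pair for one transcript.

    The 5' mate is the first ``read_len`` nt of the reference sense
    strand; the 3' mate is the adapter followed by the reverse complement
    of (reference + tail), i.e. tail first, truncated to ``read_len``.
    Substitution errors and Gaussian qualities are applied to both mates.
    """
    if len(adapter) < 10:
        raise ValueError("adapter must be at least 10 nt")
    r5_seq = _apply_errors(ref.sequence[:read_len], err, rng)
    transcript = ref.sequence + truth.tail_seq
    r3_seq = (adapter + revcomp(transcript))[:read_len]
    r3_seq = _apply_errors(r3_seq, err, rng)
    mate1 = Read(f"{truth.read_id}/1", r5_seq, _draw_quals(len(r5_seq), err, rng))
    mate2 = Read(f"{truth.read_id}/2", r3_seq, _draw_quals(len(r3_seq), err, rng))
    return ReadPair(read_id=truth.read_id, mate1=mate1, mate2=mate2)


def simulate_batch(ref: ReferenceAmplicon, config: StageConfig, adapter: str,
                   n_reads: int, seed: int = 0,
                   err: ErrorModel = ERROR_FREE, read_len: int = 300,
                   ) -> tuple[list[ReadPair], list[TailTruth]]:
    """Generate ``n_reads`` mate pairs plus their ground truth records."""
    rng = np.random.default_rng(seed)
    pairs: list[ReadPair] = []
    truths: list[TailTruth] = []
    for i in range(n_reads):
        truth = gen_tail(config, rng, read_id=f"sim_{config.stage_label}_{i}")
        truths.append(truth)
        pairs.append(gen_read_pair(ref, truth, adapter, err, rng, read_len))
    return pairs, truths


def calls_from_truth(truths: Iterable[TailTruth]) -> list[TailCall]:
    """Build TailCall records directly from ground truth.

    This bypasses read-level calling and represents the generator's own
    segmentation (A-region = poly(A) span, terminal U-run = modification
    span).  It is the reference point for statistics-recovery checks that
    should not inherit the caller's boundary behaviour.
    """
    calls = []
    for t in truths:
        n = len(t.tail_seq)
        a_len = n - len(t.mod_seq)
        has_tail = n > 0 and a_len > 0
        calls.append(TailCall(
            read_id=t.read_id,
            polyA_span=(0, a_len) if has_tail else EMPTY_SPAN,
            mod_span=(a_len, n) if has_tail and t.mod_seq else EMPTY_SPAN,
            polyA_score=a_len if has_tail else 0,
            mod_class=classify_mod(t.mod_seq if has_tail else ""),
            tail_seq=t.tail_seq if has_tail else "",
            tail_quals=tuple([40] * n) if has_tail else (),
        ))
    return calls


_TRUTH_COLUMNS = ["read_id", "polyA_len", "tail_seq", "mod_seq", "stage_label"]


def write_truth(truths: Iterable[TailTruth], path: str | Path) -> None:
    rows = [{
        "read_id": t.read_id,
        "polyA_len": t.polyA_len,
        "tail_seq": t.tail_seq,
        "mod_seq": t.mod_seq,
        "stage_label": t.stage_label,
    } for t in truths]
    pd.DataFrame(rows, columns=_TRUTH_COLUMNS).to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> list[TailTruth]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
    return [TailTruth(read_id=r.read_id, polyA_len=int(r.polyA_len),
                      tail_seq=r.tail_seq, mod_seq=r.mod_seq,
                      stage_label=r.stage_label)
            for r in df.itertuples(index=False)]
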