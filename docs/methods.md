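# Methods

This note documents the models, parameter choices and numerical
conventions behind `tailscope`, and what the synthetic-data tests do and
do not establish about real data.

## Input model and assumptions

The pipeline assumes targeted amplicon TAIL-seq input: 2×300 nt
MiSeq-style paired-end reads of a single known mRNA 3′ region, with a
ligated 3′ adapter at the head of one mate. The 3′ mate reads the
transcript end in reverse complement, so the tail appears as poly(T)
immediately after the adapter. Barcode demultiplexing and removal of
spike-in reads from other organisms are assumed done upstream. No quality
filtering is applied anywhere on input: poly(A) stretches systematically
base-call poorly, and dropping low-quality reads would bias tail
recovery. Low quality is instead handled locally, by masking sub-Q20
bases out of composition statistics only.

## Reference correction

Per-sample consensus correction of the reference amplicon:

* **Poly(A) pad, 50 nt.** Reads running from the UTR into the tail would
  otherwise soft-fail at the reference 3′ end; the in-silico pad absorbs
  them. Corrections landing inside the pad are discarded when the pad is
  stripped — the pad exists purely to stabilise alignment, and consensus
  within a synthetic homopolymer is meaningless.
* **Downsampling to 1000×.** Coverage is defined as cumulative sampled
  bases / reference length (mean depth); sampling is uniform without
  replacement in seeded order, so a fixed seed reproduces the subset.
* **Alignment.** Because the input is a single known amplicon, a
  full-matrix end-gap-free (semi-global) pairwise alignment with match
  +1 / mismatch −1 / gap open −2 / gap extend −1 replaces a general-purpose
  short-read mapper; the mapping contract (each read placed on the one
  reference at its best location) is unchanged. Reads under 80 % alignment
  identity are skipped as chimeras/contaminants. Identical read sequences
  are aligned once and counted with multiplicity — with amplicon data
  most reads are duplicates, and the pileup is unchanged. Among
  co-optimal alignments the one with the fewest gap columns wins: a
  terminal mismatch and a one-base gap slide into the poly(A) pad can
  score identically, and a substitution-only consensus must take the
  gapless reading or a substitution at the reference's 3′ boundary
  becomes uncorrectable.
* **Majority vote.** A position changes only when a single base (A/C/G/T;
  N never wins) has strictly the highest count at non-zero depth. Ties
  keep the original base — the conservative reading of "majority".
  Per-position substitution consensus only; indels are out of scope.

The recovery property (≤ 10 planted substitutions, error-free reads at
≥ 1000×, 100 trials) restores the true sequence exactly; with real,
error-bearing reads the guarantee is statistical, not exact.

## Tail calling

Oriented reads are mRNA-sense, 0-based half-open coordinates throughout.

* **UTR first.** The ≥ 30-column local alignment to the reference is
  labelled 3′ UTR and excluded from tail search, so genomic A-runs cannot
  be called as tails. No identity cut-off is applied here (low-quality
  reads must still anchor); co-optimal alignments resolve to the earliest
  read interval.
* **Maximum-scoring substring.** Per-base scores A +1, N −1, T/G/C −2.
  The single best-scoring substring of the post-UTR suffix (computed in
  O(n) by prefix-sum scan; verified against an O(n²) enumeration) is the
  poly(A) candidate. Ties on score resolve to the larger end coordinate
  (the tail abuts the read's 3′ end), then to the greater length. The
  candidate is accepted only if score > 0 and it ends ≤ 15 nt from the
  read's 3′ end; distance is measured on the adapter-trimmed read, since
  the adapter is not part of the transcript.
* **Consequences of the scorer.** A called region always begins and ends
  with A: any flanking non-A or N strictly lowers the score and is
  trimmed. Leading non-A residues of a true mixed tail therefore fall
  into the "other" gap between UTR and poly(A), and a terminal
  modification longer than 15 nt pushes the poly(A) end past the distance
  threshold, so the read is called no-poly(A). Both are documented
  limitations of the printed rule, deliberately not patched around.
* **Modification classification.** The residues between the poly(A) end
  and the read end vote by their major base among T, G, C (reported U, G,
  C); two-way ties are "≥2". A residues in the modification region do not
  vote, since only T/G/C define the classification.
* **Masking.** Sub-Q20 bases are replaced by a mask symbol for
  composition statistics only — interpreted as masking *bases*, not
  dropping whole reads; masked bases leave both numerator and
  denominator.

## Statistics

* A read's "tail" is the called poly(A) region concatenated with its
  modification region; only reads with a called poly(A) contribute.
* Length histograms pool ≥ 40 nt into one bin, because long-homopolymer
  lengths are systematically overestimated by base calling; no long-tail
  length estimation is attempted beyond the cap.
* Positional non-A frequencies use per-position denominators (reads whose
  unmasked tail reaches that position), so positions beyond most reads'
  tails are still defined; the same tails feed both the 5′→3′ and the
  3′→5′ profile, making total non-A counts direction-invariant.
* Clone statistics report mean ± SE (sample SD/√n) of U counts in the
  terminal k = 5 nt. Clones shorter than k are used in full and flagged;
  an n = 1 group reports SE = 0 with an explicit flag. Tukey HSD uses
  scipy's studentized-range implementation; degenerate input with zero
  within-group variance falls back to the limiting convention (p = 0 for
  differing means, p = 1 for equal means).

## Simulator

The generator emulates the tail regimes of a maturing oocyte population:
a `p_long` mixture of long (default 45–60 nt) and short (10–20 nt) tails;
terminal oligo(U) on a fraction (default 0.6) of short tails with
geometric run lengths (support ≥ 1, mean 3 — the simplest memoryless
model consistent with short observed U-runs; no empirical distribution is
available); optional non-canonical tails whose per-position non-A
probability interpolates linearly from a 5′ value (default 0.30) to a 3′
value (0.05), with non-A bases drawn U:G:C = 0.6:0.3:0.1 (U and G
dominate mixed tails, C is rare). Errors are substitution-only (the
caller's scoring already absorbs substitutions; no indel model is
claimed) and qualities are per-base Gaussian (mean 32, SD 6, clamped to
[2, 41]) so a realistic share of bases falls under the Q20 mask.
References are random sequences of length ≥ 260 nt with no ≥ 8 nt A-run —
a fixture guarantee so genomic A-runs cannot masquerade as tails, not a
claim about real transcripts. Stage presets (GV / mature / blastula) are
illustrative parameterisations of these regimes, not fitted models.

What passing recovery tests shows: the extraction rules, the
maximum-scoring-substring caller and the aggregation arithmetic are
mutually consistent and recover known parameters from data that matches
the model's assumptions. What it does not show: robustness to PCR
duplication, indels, cluster crosstalk, adapter chimeras or base-calling
artefacts in long homopolymers, none of which the simulator models.

## Verification design

Every stage is checked against an independent oracle where one exists:
the poly(A) caller against an exhaustive all-substrings enumeration
(1,000 random strings ≤ 60 nt), the adapter aligner against a plain
Smith–Waterman DP, Tukey HSD against statsmodels. Parameter-recovery
checks run the full simulate → extract → call → aggregate path at
n = 5,000 error-free reads (tail-length mixture within 3 binomial SD of
p_long = 0.5; uridylation within 3 SD of 60 %). The positional non-A
recovery check compares against the generator's own interpolation
schedule and is computed on ground-truth segmentations rather than
read-level calls: the caller provably trims leading non-A residues (see
above), so position-1 frequencies are structurally unrecoverable through
the caller and the check would otherwise measure that known bias rather
than the statistics' correctness. The expected positional profile under a
length mixture is itself length-weighted (each tail interpolates over its
own length), and the oracle expectation accounts for this.

Problem sizes (5,000-read batches, 100 correction trials at 1000× over a
300 nt reference, 200 constructed reads) were chosen as the smallest
sizes at which 3-SD binomial bands are a few percent wide and the checks
remain sharp.
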