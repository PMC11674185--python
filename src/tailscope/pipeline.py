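"""End-to-end orchestration: reference correction -> extraction -> tail calling -> statistics.

The pipeline takes paired FASTQ files, a reference FASTA for the targeted
mRNA 3' region and the 3' adapter sequence, and produces a per-read call
table, a statistics report and a per-stage count log.  Counts along the
filter chain (pairs in >= adapter-accepted >= read5-validated >=
poly(A)-called) are monotone by construction.  No quality filter is
applied at import.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import extract, refcorrect, seqio, tailcall, tailstats


@dataclass
class PipelineConfig:
    """All thresholds and paths of one pipeline run (defaults are the method's)."""

    adapter: str = ""
    reference: str = ""
    r1: str = ""
    r2: str = ""
    out_dir: str = "tailscope_out"
    gene_id: str | None = None
    # extraction
    min_adapter_identity: float = 0.90
    max_head_offset: int = 0
    min_read5_identity: float = 0.90
    min_read5_aln_len: int = 200
    # reference correction
    correct_reference: bool = True
    pad_len: int = 50
    target_depth: int = 1000
    seed: int = 0
    # tail calling
    scoring: tailcall.ScoringParams = field(default_factory=tailcall.ScoringParams)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        scoring = data.pop("scoring", None)
        config = cls(**data)
        if scoring:
            config.scoring = tailcall.ScoringParams(**scoring)
        return config


@dataclass
class PipelineReport:
    """Stage counts and output paths of one run."""

    counts: dict[str, int]
    outputs: dict[str, str]
    corrections: tuple[tuple[int, str, str], ...] = ()

    def to_json_dict(self) -> dict:
        return {
            "counts": self.counts,
            "outputs": self.outputs,
            "corrections": [list(c) for c in self.corrections],
        }


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run every stage on the configured inputs and write the report bundle."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    ref = seqio.read_fasta(config.reference, config.gene_id)
    reads1 = list(seqio.read_fastq(config.r1))
    reads2 = list(seqio.read_fastq(config.r2))
    if len(reads1) != len(reads2):
        raise ValueError(
            f"stage extract: R1 has {len(reads1)} reads but R2 has {len(reads2)}")
    pairs = [extract.ReadPair(r1.name.split("/")[0].split()[0], r1, r2)
             for r1, r2 in zip(reads1, reads2)]
    counts: dict[str, int] = {"pairs_in": len(pairs)}

    corrections: tuple[tuple[int, str, str], ...] = ()
    if config.correct_reference and pairs:
        all_reads = reads1 + reads2
        ref = refcorrect.correct_reference(
            ref, all_reads, target_depth=config.target_depth,
            pad_len=config.pad_len, seed=config.seed)
        corrections = ref.correction_log
    ref_out = out_dir / "reference.corrected.fasta"
    seqio.write_fasta(ref, ref_out)

    classified, discards = extract.extract_pairs(
        pairs, config.adapter, ref,
        min_identity=config.min_adapter_identity,
        max_head_offset=config.max_head_offset,
        min_aln_len=config.min_read5_aln_len)
    n_adapter = len(pairs) - sum(
        1 for _, reason in discards
        if reason in (extract.DISCARD_NO_ADAPTER, extract.DISCARD_AMBIGUOUS))
    counts["adapter_accepted"] = n_adapter
    counts["read5_validated"] = len(classified)

    discard_path = out_dir / "discards.tsv"
    with open(discard_path, "w") as fh:
        fh.write("read_id\treason\n")
        for read_id, reason in discards:
            fh.write(f"{read_id}\t{reason}\n")

    calls = tailcall.call_batch(
        (pair.read3 for pair in classified), config.adapter, ref,
        config.scoring, max_head_offset=config.max_head_offset)
    counts["polyA_called"] = sum(1 for c in calls if c.has_polyA)
    calls_path = out_dir / "tailcalls.tsv"
    tailcall.write_calls(calls, calls_path)

    stats = tailstats.profile(
        calls, mask_threshold=config.scoring.quality_mask_threshold,
        lenclass_cut=config.scoring.long_tail_cap)
    stats_path = out_dir / "tailstats.json"
    with open(stats_path, "w") as fh:
        json.dump(stats.to_json_dict(), fh, indent=2)

    report = PipelineReport(
        counts=counts,
        outputs={
            "reference": str(ref_out),
            "tailcalls": str(calls_path),
            "tailstats": str(stats_path),
            "discards": str(discard_path),
        },
        corrections=corrections,
    )
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report.to_json_dict(), fh, indent=2)
    return report
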