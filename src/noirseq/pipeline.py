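"""End-to-end orchestration: simulate -> extract -> denoise -> consensus -> call.

Everything is deterministic given the run seed; each stage writes its
standard report (TSV/FASTQ/JSON) into the run directory and the run log
records read counts at every filter stage so conservation can be audited.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import denoise, detect, noir, tagio
from .regions import DEFAULT_REGIONS, TargetRegion, write_reference_fasta
from .simlib import BDHV15, BDHV_PATTERN, FastqRead


@dataclass
class RunConfig:
    """All pipeline thresholds, at their standard defaults, overridable."""

    out_dir: str = "noirseq_run"
    fastq: str | None = None
    reference: str | None = None
    spacer_length: int = 20
    regions: dict[str, TargetRegion] = field(default_factory=lambda: dict(DEFAULT_REGIONS))
    index_table: dict[str, str] = field(default_factory=lambda: {"ACGTA": "sample1"})
    scheme: str = "N12"
    min_prop: float = 0.90
    window: int = 11
    min_tag_len: int = 9
    consensus_alt_frac: float = 0.80
    max_reads_per_consensus: int = 50
    payload_min: int = 70
    unmapped_end_max: float = 0.10
    er_noir: float = detect.ER_NOIR
    er_deep: float = detect.ER_DEEP
    alpha: float = detect.ALPHA
    seed: int = 0

    @property
    def correct_tag_len(self) -> int:
        return len(BDHV_PATTERN) if self.scheme == BDHV15 else 12

    def correctness(self):
        if self.scheme == BDHV15:
            return denoise.is_bdhv_clean
        return self.correct_tag_len


@dataclass
class RunResult:
    stats: tagio.ProcessStats
    thresholds: dict[str, int]
    molecule_counts: dict[str, int]
    calls: dict[str, detect.RegionCall]
    summary: dict


def run_pipeline(
    config: RunConfig, reads: list[FastqRead] | None = None
) -> RunResult:
    """Run the full pipeline and write all reports under ``config.out_dir``.

    ``reads`` may be passed in-memory (e.g. straight from the simulator);
    otherwise ``config.fastq`` is read.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if reads is None:
        if config.fastq is None:
            raise FileNotFoundError("no input reads: set config.fastq")
        reads = tagio.read_fastq(config.fastq)
    if config.reference is not None:
        from .regions import read_reference_fasta

        config.regions = read_reference_fasta(config.reference, config.spacer_length)
    if not config.regions:
        raise ValueError("no target regions configured")

    by_sample, stats = tagio.process_reads(
        reads,
        list(config.regions.values()),
        config.index_table,
        expected_tag_len=config.correct_tag_len,
        payload_min=config.payload_min,
        max_unmapped_frac=config.unmapped_end_max,
    )

    thresholds: dict[str, int] = {}
    molecule_counts: dict[str, int] = {}
    calls: dict[str, detect.RegionCall] = {}
    correctness = config.correctness()
    all_consensuses = []
    for sample, per_region in sorted(by_sample.items()):
        for target_id, region_reads in sorted(per_region.items()):
            region = config.regions[target_id]
            families = denoise.group_and_merge(
                [(r.read_id, r.tag) for r in region_reads],
                correct_len=config.correct_tag_len,
            )
            if not families:
                continue
            hist = denoise.smooth_proportions(
                denoise.build_histogram(families, correctness), config.window
            )
            M = denoise.find_threshold(hist, config.min_prop)
            accepted, _removed = denoise.remove_erroneous(families, M)
            thresholds[target_id] = M
            molecule_counts[target_id] = len(accepted)
            hist.to_frame().to_csv(out / f"histogram_{sample}_{target_id}.tsv",
                                   sep="\t", index=False)
            denoise.families_to_frame(families, M, config.correct_tag_len).to_csv(
                out / f"families_{sample}_{target_id}.tsv", sep="\t", index=False
            )
            consensuses = noir.build_all_consensuses(
                accepted, region_reads, region,
                max_reads=config.max_reads_per_consensus,
                alt_fraction=config.consensus_alt_frac,
            )
            all_consensuses.extend(consensuses)
            pileup = noir.pileup_consensus(consensuses, region)
            pileup.to_frame(region).to_csv(
                out / f"pileup_{sample}_{target_id}.tsv", sep="\t", index=False
            )
            calls[target_id] = detect.call_region(
                pileup, region, er=config.er_noir, alpha=config.alpha
            )
    noir.emit_consensus_fastq(all_consensuses, out / "noir_consensus.fastq")
    write_reference_fasta(config.regions, out / "reference_used.fasta")

    summary = {
        "seed": config.seed,
        "reads_total": stats.total,
        "reads_unassigned": stats.unassigned,
        "reads_rejected": dict(sorted(stats.rejected.items())),
        "reads_assigned": dict(sorted(stats.assigned.items())),
        "conservation_ok": stats.check_conservation(),
        "thresholds_M": thresholds,
        "molecule_counts": molecule_counts,
        "calls": {
            t: {
                "l": c.l, "m": c.m, "n": c.n, "lambda": c.lam, "P": c.p_value,
                "variant_positive": c.variant_positive,
                "clustering": c.clustering_label,
                "mutant_fraction_pct": c.mutant_fraction_pct,
            }
            for t, c in sorted(calls.items())
        },
    }
    with open(out / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return RunResult(stats, thresholds, molecule_counts, calls, summary)


def subsample_reads(
    reads: list[FastqRead], fraction: float | None = None,
    count: int | None = None, seed: int = 0,
) -> list[FastqRead]:
    """Uniform without-replacement subsample for saturation analysis."""
    if (fraction is None) == (count is None):
        raise ValueError("give exactly one of fraction or count")
    if fraction is not None:
        if not 0.0 <= fraction <= 1.0:
            raise ValueError("fraction must be in [0, 1]")
        if fraction == 1.0:
            return list(reads)
        count = int(round(fraction * len(reads)))
    if count > len(reads):
        raise ValueError(f"cannot subsample {count} of {len(reads)} reads")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(reads), size=count, replace=False)
    return [reads[i] for i in sorted(idx)]
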