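"""Shared fixtures: two realistic simulated libraries, processed once.

``ion_run``: an Ion-profile (indel-dominant) N12 library at production-like
scale with a 1% mutant fraction — exercises tag-length-based denoising,
molecule counting and mutant detection.

``deep_run``: a deeply amplified (mean ~300 reads/tag) mutation-free
library — exercises consensus error suppression and the removed-error-free
bound at depth well above twice any plausible threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pytest

from noirseq import denoise, detect, noir, simlib, tagio


@dataclass
class ProcessedRun:
    cfg: simlib.SimConfig
    reads: list
    truth: list
    region_reads: list  # RawReads assigned to the library's region
    stats: tagio.ProcessStats
    families: list
    hist: denoise.TagHistogram
    threshold_M: int
    accepted: list
    removed: list
    consensuses: list
    pileup: noir.Pileup
    call: detect.RegionCall


def run_library(cfg: simlib.SimConfig) -> ProcessedRun:
    reads, truth = simlib.simulate_library(cfg)
    by_sample, stats = tagio.process_reads(
        reads, [cfg.region], {cfg.index5: "s1"}
    )
    region_reads = by_sample["s1"][cfg.target_id]
    families = denoise.group_and_merge(
        [(r.read_id, r.tag) for r in region_reads]
    )
    hist = denoise.smooth_proportions(denoise.build_histogram(families, 12))
    M = denoise.find_threshold(hist)
    accepted, removed = denoise.remove_erroneous(families, M)
    consensuses = noir.build_all_consensuses(accepted, region_reads, cfg.region)
    pileup = noir.pileup_consensus(consensuses, cfg.region)
    call = detect.call_region(pileup, cfg.region)
    return ProcessedRun(cfg, reads, truth, region_reads, stats, families,
                        hist, M, accepted, removed, consensuses, pileup, call)


@pytest.fixture(scope="session")
def ion_run() -> ProcessedRun:
    cfg = simlib.SimConfig(
        n_molecules=2000, target_id="TK102U", mutant_fraction=0.01,
        platform="ion", per_base_error_rate=0.005, seed=11,
    )
    return run_library(cfg)


@pytest.fixture(scope="session")
def deep_run() -> ProcessedRun:
    cfg = simlib.SimConfig(
        n_molecules=800, target_id="KRAS", mutant_fraction=0.0,
        platform="ion", per_base_error_rate=0.005, seed=7,
        reads_per_tag_model=("lognormal", {"mu": math.log(300.0), "sigma": 0.6}),
    )
    return run_library(cfg)
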