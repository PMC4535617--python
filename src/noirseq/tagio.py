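"""Read-level processing: demultiplexing, tag extraction and filtering.

The 5' structure of every read is

    [5-bp sample index][random barcode tag][fixed spacer][target]

The barcode tag is whatever lies between the index and the best
approximate spacer match; indels inside the tag therefore shift the
spacer and change the extracted tag length, which is exactly the signal
the denoising stage exploits. Reads are then aligned to the panel of
spacer+target references and dropped if too short, unmappable, or mostly
soft-clipped.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import Alignment, align_payload_to_ref
from .regions import TargetRegion
from .simlib import FastqRead

INDEX_LEN = 5
UNASSIGNED = "unassigned"

# rejection reason codes
NO_SPACER = "no_spacer"
TAG_TOO_SHORT = "tag_too_short"  # applied later, in denoise; kept for logs
SHORT_PAYLOAD = "short_payload"
UNMAPPED_ENDS = "unmapped_ends"
LOW_IDENTITY = "low_identity"


@dataclass
class RawRead:
    """One read after extraction: index, tag, payload and (later) alignment."""

    read_id: str
    sequence: str
    sample_index: str
    tag: str
    payload: str
    target_id: str | None = None
    alignment: Alignment | None = None
    rejected: str | None = None


@dataclass
class ProcessStats:
    """Per-disposition read counts; every read lands in exactly one bucket."""

    total: int = 0
    unassigned: int = 0
    rejected: dict[str, int] = field(default_factory=dict)
    assigned: dict[str, int] = field(default_factory=dict)

    def check_conservation(self) -> bool:
        return self.total == (
            self.unassigned + sum(self.rejected.values()) + sum(self.assigned.values())
        )


# ---------------------------------------------------------------------------
# FASTQ I/O (Biopython-backed; plain or gzip)

def _open(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> list[FastqRead]:
    with _open(path) as fh:
        return [
            FastqRead(
                rec.id,
                str(rec.seq),
                "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"]),
            )
            for rec in SeqIO.parse(fh, "fastq")
        ]


def write_fastq(reads: Iterable[FastqRead], path) -> None:
    def records():
        for r in reads:
            rec = SeqRecord(Seq(r.seq), id=r.id, description="")
            rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in r.qual]
            yield rec

    with _open(path, "wt") as fh:
        SeqIO.write(records(), fh, "fastq")


# ---------------------------------------------------------------------------
# demultiplexing and tag extraction

def demultiplex(read: FastqRead, index_table: dict[str, str]) -> str:
    """Exact 5-mer match of the leading index; anything else is unassigned."""
    return index_table.get(read.seq[:INDEX_LEN], UNASSIGNED)


def extract_tag(
    sequence: str,
    spacer: str,
    *,
    expected_tag_len: int = 12,
    window: int = 4,
    max_edit: int = 2,
) -> str | None:
    """Locate the spacer and return the bases between index and spacer.

    The spacer is searched as the lowest-edit-distance match whose start
    lies within ``expected_tag_len - 3 .. expected_tag_len + window``
    bases of the index (ties broken leftmost); if no match has edit
    distance <= ``max_edit`` the read cannot be anchored and None is
    returned.
    """
    lo = INDEX_LEN + max(0, expected_tag_len - 3)
    hi = INDEX_LEN + expected_tag_len + window  # last allowed spacer start
    segment = sequence[lo : hi + len(spacer) + max_edit]
    if not segment:
        return None
    res = edlib.align(spacer, segment, mode="HW", task="locations", k=max_edit)
    if res["editDistance"] < 0:
        return None
    start = lo + min(loc[0] for loc in res["locations"])
    if start > hi:
        return None
    return sequence[INDEX_LEN:start]


def filter_payload_length(payload: str, spacer_plus_target_min: int = 70) -> bool:
    """Keep the read iff spacer + following sequence exceeds the minimum."""
    return len(payload) > spacer_plus_target_min


def align_payload(
    payload: str,
    regions: Sequence[TargetRegion],
    *,
    max_unmapped_frac: float = 0.10,
    min_identity: float = 0.50,
) -> tuple[TargetRegion | None, Alignment | None, str | None]:
    """Align against every region, pick the best, apply mapping filters.

    Returns (region, alignment, rejection reason); exactly one of region
    or reason is set.
    """
    best: Alignment | None = None
    best_region: TargetRegion | None = None
    for region in regions:
        aln = align_payload_to_ref(payload, region.reference)
        if best is None or aln.score > best.score:
            best, best_region = aln, region
    assert best is not None and best_region is not None
    if best.span_length == 0 or best.identity < min_identity:
        return None, None, LOW_IDENTITY
    if (best.lead_clip + best.trail_clip) > max_unmapped_frac * len(payload):
        return None, None, UNMAPPED_ENDS
    return best_region, best, None


def process_reads(
    reads: Iterable[FastqRead],
    regions: Sequence[TargetRegion],
    index_table: dict[str, str],
    *,
    expected_tag_len: int = 12,
    payload_min: int = 70,
    max_unmapped_frac: float = 0.10,
) -> tuple[dict[str, dict[str, list[RawRead]]], ProcessStats]:
    """Run every read through demux -> tag extraction -> filters -> alignment.

    Returns reads grouped by sample then target_id, plus disposition
    counts. Alignments are cached by payload string: identical payloads
    (the common case for error-free reads of one molecule) are aligned
    once.
    """
    regions = list(regions)
    spacer = regions[0].spacer
    stats = ProcessStats()
    by_sample: dict[str, dict[str, list[RawRead]]] = {}
    cache: dict[str, tuple[TargetRegion | None, Alignment | None, str | None]] = {}
    for read in reads:
        stats.total += 1
        sample = demultiplex(read, index_table)
        if sample == UNASSIGNED:
            stats.unassigned += 1
            continue
        tag = extract_tag(read.seq, spacer, expected_tag_len=expected_tag_len)
        if tag is None:
            stats.rejected[NO_SPACER] = stats.rejected.get(NO_SPACER, 0) + 1
            continue
        payload = read.seq[INDEX_LEN + len(tag) :]
        if not filter_payload_length(payload, payload_min):
            stats.rejected[SHORT_PAYLOAD] = stats.rejected.get(SHORT_PAYLOAD, 0) + 1
            continue
        hit = cache.get(payload)
        if hit is None:
            hit = align_payload(payload, regions, max_unmapped_frac=max_unmapped_frac)
            cache[payload] = hit
        region, aln, reason = hit
        if reason is not None:
            stats.rejected[reason] = stats.rejected.get(reason, 0) + 1
            continue
        raw = RawRead(read.id, read.seq, read.seq[:INDEX_LEN], tag, payload,
                      region.target_id, aln)
        by_sample.setdefault(sample, {}).setdefault(region.target_id, []).append(raw)
        stats.assigned[region.target_id] = stats.assigned.get(region.target_id, 0) + 1
    return by_sample, stats
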