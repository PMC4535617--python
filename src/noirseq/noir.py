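"""Per-molecule consensus reads (NOIR) and consensus pileups.

Each accepted tag family yields exactly one consensus sequence, so the
final read set represents every sequenced molecule once — the basis for
both absolute quantitation and the Poisson error model downstream. Within
a family, a position is called as an alternative base (or deletion) only
when more than 80% of the reads covering it agree on that alternative;
otherwise the reference base is called. Families larger than 50 reads are
downsampled to their 50 longest reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .align import BASES, DEL_CODE
from .denoise import TagFamily
from .regions import TargetRegion
from .simlib import FastqRead
from .tagio import RawRead, write_fastq

Q57_CHAR = chr(57 + 33)  # 'Z'

MAX_READS_PER_CONSENSUS = 50
ALT_FRACTION = 0.80


@dataclass
class NoirConsensus:
    """One consensus read; ``codes`` has one entry per target position
    (0..3 base, 4 deletion, -1 not covered by any kept read)."""

    canonical_tag: str
    target_id: str
    codes: np.ndarray
    support: np.ndarray  # reads supporting the called symbol
    depth: np.ndarray  # reads covering the position
    n_reads_used: int
    variant_positions: list[tuple[int, str]] = field(default_factory=list)
    insertion_reads: int = 0  # kept reads carrying >=1 insertion

    @property
    def sequence(self) -> str:
        """Called bases over covered positions; deletions omitted."""
        return "".join(
            BASES[c] for c in self.codes if 0 <= c < DEL_CODE
        )


@dataclass
class Pileup:
    """Per-position symbol counts (A/C/G/T/del) over a set of sequences,
    each contributing at most once per position."""

    target_id: str
    counts: np.ndarray  # shape (l, 5)
    n_molecules: int

    @property
    def coverage(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self, region: TargetRegion) -> pd.DataFrame:
        l = region.length_l
        return pd.DataFrame(
            {
                "target_id": self.target_id,
                "pos": np.arange(1, l + 1),  # 1-based in reports
                "ref": list(region.target_seq),
                "A": self.counts[:, 0],
                "C": self.counts[:, 1],
                "G": self.counts[:, 2],
                "T": self.counts[:, 3],
                "del": self.counts[:, 4],
                "coverage": self.coverage,
            }
        )


def _target_codes(read: RawRead, region: TargetRegion) -> np.ndarray:
    """Per-target-position codes of one aligned read (spacer stripped)."""
    return read.alignment.codes[len(region.spacer) :]


def build_consensus(
    family: TagFamily,
    reads_by_id: dict,
    region: TargetRegion,
    *,
    max_reads: int = MAX_READS_PER_CONSENSUS,
    alt_fraction: float = ALT_FRACTION,
) -> NoirConsensus | None:
    """Collapse one accepted family into a consensus sequence.

    Keeps the ``max_reads`` longest reads (ties broken by input order),
    tallies aligned bases per target position, and calls an alternative
    symbol only where it exceeds ``alt_fraction`` of the covering reads.
    Returns None when no member read has an alignment (family dropped).
    """
    members = [reads_by_id[rid] for rid in family.member_read_ids
               if rid in reads_by_id and reads_by_id[rid].alignment is not None]
    if not members:
        return None
    if len(members) > max_reads:
        keep = sorted(
            range(len(members)), key=lambda i: (-len(members[i].payload), i)
        )[:max_reads]
        members = [members[i] for i in sorted(keep)]
    l = region.length_l
    ref_codes = np.array(["ACGT".index(b) for b in region.target_seq], dtype=np.int8)
    tallies = np.zeros((l, 5), dtype=np.int64)
    ins_reads = 0
    for read in members:
        codes = _target_codes(read, region)
        cov = codes >= 0
        np.add.at(tallies, (np.nonzero(cov)[0], codes[cov]), 1)
        if read.alignment.insertions:
            ins_reads += 1
    depth = tallies.sum(axis=1)
    called = np.full(l, -1, dtype=np.int8)
    support = np.zeros(l, dtype=np.int64)
    variants: list[tuple[int, str]] = []
    covered = np.nonzero(depth > 0)[0]
    best_sym = tallies[covered].argmax(axis=1)
    best_cnt = tallies[covered, best_sym]
    for pos, sym, cnt in zip(covered, best_sym, best_cnt):
        if sym != ref_codes[pos] and cnt > alt_fraction * depth[pos]:
            called[pos] = sym
            support[pos] = cnt
            variants.append((int(pos), BASES[sym]))
        else:
            called[pos] = ref_codes[pos]
            support[pos] = tallies[pos, ref_codes[pos]]
    return NoirConsensus(
        family.canonical_tag, region.target_id, called, support, depth,
        len(members), variants, ins_reads,
    )


def build_all_consensuses(
    families: Sequence[TagFamily],
    reads: Sequence[RawRead],
    region: TargetRegion,
    *,
    max_reads: int = MAX_READS_PER_CONSENSUS,
    alt_fraction: float = ALT_FRACTION,
) -> list[NoirConsensus]:
    reads_by_id = {r.read_id: r for r in reads}
    out = []
    for fam in families:
        cons = build_consensus(
            fam, reads_by_id, region, max_reads=max_reads, alt_fraction=alt_fraction
        )
        if cons is not None:
            out.append(cons)
    return out


def emit_consensus_fastq(consensuses: Iterable[NoirConsensus], path) -> None:
    """Write consensus reads as FASTQ with every base at Q57."""
    records = [
        FastqRead(f"{c.target_id}:{c.canonical_tag}", c.sequence,
                  Q57_CHAR * len(c.sequence))
        for c in consensuses
        if c.sequence
    ]
    write_fastq(records, path)


def pileup_consensus(
    consensuses: Sequence[NoirConsensus], region: TargetRegion
) -> Pileup:
    """Per-position symbol counts over consensus reads (one per molecule)."""
    counts = np.zeros((region.length_l, 5), dtype=np.int64)
    n = 0
    for cons in consensuses:
        if cons.target_id != region.target_id:
            continue
        cov = cons.codes >= 0
        np.add.at(counts, (np.nonzero(cov)[0], cons.codes[cov]), 1)
        n += 1
    return Pileup(region.target_id, counts, n)


def pileup_reads(reads: Sequence[RawRead], region: TargetRegion) -> Pileup:
    """Per-position symbol counts over raw aligned reads (deep mode)."""
    counts = np.zeros((region.length_l, 5), dtype=np.int64)
    for read in reads:
        codes = _target_codes(read, region)
        cov = codes >= 0
        np.add.at(counts, (np.nonzero(cov)[0], codes[cov]), 1)
    return Pileup(region.target_id, counts, len(reads))
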