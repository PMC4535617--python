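"""Target region definitions and reference I/O.

A target region is the unit of analysis: a short genomic interval reached
from a restriction site, sequenced as [5-bp sample index][random barcode
tag][fixed spacer][target]. The reference record for a region is the
spacer plus the target sequence; the spacer is adaptor-derived and shared
by all regions of a panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Adaptor-derived spacer separating the barcode tag from the target.
DEFAULT_SPACER = "CAGGAAAGCTCCAATTATGG"


@dataclass(frozen=True)
class TargetRegion:
    """One amplicon target.

    ``excluded_positions`` are 0-based target offsets masked from error-rate
    and variant tallies (known germline SNP sites such as rs1800372).
    """

    target_id: str
    spacer: str
    target_seq: str
    excluded_positions: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.spacer:
            raise ValueError("spacer must be nonempty")
        bad = [p for p in self.excluded_positions if not 0 <= p < self.length_l]
        if bad:
            raise ValueError(f"excluded positions outside target: {bad}")

    @property
    def length_l(self) -> int:
        """Region length l in bp (the l of the Poisson error model)."""
        return len(self.target_seq)

    @property
    def effective_length(self) -> int:
        """l minus masked germline positions (the positions actually counted)."""
        return self.length_l - len(self.excluded_positions)

    @property
    def reference(self) -> str:
        """Alignment reference: spacer + target."""
        return self.spacer + self.target_seq


# Built-in demonstration panel: a TP53-DNA-binding-domain-like region with a
# masked common-SNP position, and KRAS/CTNNB1 hotspot regions of 73 and 63 bp.
DEFAULT_REGIONS: dict[str, TargetRegion] = {
    r.target_id: r
    for r in (
        TargetRegion(
            "TK102U",
            DEFAULT_SPACER,
            "CATCACTCCGCCATCCCTTAAGAGCAGAGGATCGTCGATAACTCCAGCTCCGGGCCATG"
            "TTAGTTCTTATGCCAAATCTCTTTCGGGCATCGTACCGGCGGGAGAATCGA",
            excluded_positions=frozenset({58}),
        ),
        TargetRegion(
            "KRAS",
            DEFAULT_SPACER,
            "ATCTCTAGTCAAGAATACTCGGGCTAATCCAGGAGGGGTACTCGCTACTGAAGTAAACTG"
            "ACATAATGAGCAG",
        ),
        TargetRegion(
            "CTNNB1",
            DEFAULT_SPACER,
            "CGGACATCCGTCGCCCCTTAGGCCGCTGATCAACCAAGTTACAGGATTCCCTCATCCGCGCCT",
        ),
    )
}

#: Default hotspot used when a simulation asks for mutant molecules but gives
#: no explicit mutation: (0-based target offset, alternative base).
DEFAULT_MUTATIONS: dict[str, tuple[int, str]] = {
    "TK102U": (33, "A"),
    "KRAS": (11, "T"),
    "CTNNB1": (32, "A"),
}


def write_reference_fasta(regions: dict[str, TargetRegion], path) -> None:
    """Write one record per region; sequence is spacer + target."""
    records = [
        SeqRecord(Seq(r.reference), id=r.target_id, description="")
        for r in regions.values()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_reference_fasta(
    path,
    spacer_length: int,
    excluded_positions: dict[str, set[int]] | None = None,
) -> dict[str, TargetRegion]:
    """Load regions from a FASTA of spacer+target records.

    ``spacer_length`` states how many leading bases of each record are
    spacer; ``excluded_positions`` maps target_id to masked target offsets.
    """
    excluded_positions = excluded_positions or {}
    regions: dict[str, TargetRegion] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if len(seq) <= spacer_length:
            raise ValueError(f"record {rec.id} shorter than spacer length")
        regions[rec.id] = TargetRegion(
            rec.id,
            seq[:spacer_length],
            seq[spacer_length:],
            excluded_positions=frozenset(excluded_positions.get(rec.id, ())),
        )
    return regions
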