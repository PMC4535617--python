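"""Synthetic barcoded amplicon libraries with known ground truth.

The generator emulates the statistical structure the downstream pipeline
assumes: a finite pool of input molecules, each ligated to one random
barcode (N12, or the error-detecting BDHV15 degenerate scheme), uneven
amplification (lognormal reads per tag with a heavy low-count tail once
read errors create spurious tags), and a platform error profile —
indel-dominant for Ion Torrent, substitution-dominant for Illumina.
Erroneous tags are *not* injected as a separate channel: they arise, as in
real data, from per-base read errors falling inside the barcode region.

Every emitted read is traceable to its molecule through the truth table,
so tests can score the pipeline's recovery exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple

import numpy as np

from .regions import DEFAULT_MUTATIONS, DEFAULT_REGIONS, TargetRegion

N12 = "N12"
BDHV15 = "BDHV15"

#: BDHV degenerate pattern: at position i the base BANNED[i] never occurs,
#: so observing it certifies a read error at that position.
BDHV_PATTERN = "BDHVBDHVBDHVBDH"
_ALLOWED = {"B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG"}
_BANNED = {"B": "A", "D": "C", "H": "G", "V": "T"}

DEFAULT_INDEL_FRACTION = {"ion": 0.92, "illumina": 0.05}


def barcode_space(scheme: str) -> int:
    """Number of distinct barcodes the scheme can produce."""
    if scheme == N12:
        return 4**12
    if scheme == BDHV15:
        return 3 ** len(BDHV_PATTERN)
    raise ValueError(f"unknown barcode scheme: {scheme}")


class FastqRead(NamedTuple):
    """One FASTQ record (plain strings; qualities are Phred+33)."""

    id: str
    seq: str
    qual: str


class ErrorEvent(NamedTuple):
    """One injected error: 0-based position in the uncorrupted read."""

    position: int
    kind: str  # 'sub' | 'ins' | 'del'
    ref: str
    alt: str


@dataclass
class TruthRecord:
    molecule_id: int
    barcode: str
    is_mutant: bool
    reads: int = 0
    events: dict[int, list[ErrorEvent]] = field(default_factory=dict)


@dataclass
class SimConfig:
    """Simulation conditions for one library."""

    n_molecules: int
    target_id: str = "TK102U"
    mutant_fraction: float = 0.0
    mutation_spec: tuple[int, str] | None = None
    reads_per_tag_model: tuple[str, dict] = ("lognormal", {"mu": math.log(60.0), "sigma": 0.6})
    platform: str = "ion"
    per_base_error_rate: float = 0.005
    indel_fraction_of_errors: float | None = None  # default set by platform
    index5: str = "ACGTA"
    barcode_scheme: str = N12
    seed: int = 0
    region: TargetRegion | None = None

    def __post_init__(self) -> None:
        if self.n_molecules < 0:
            raise ValueError("n_molecules must be >= 0")
        if not 0.0 <= self.mutant_fraction <= 1.0:
            raise ValueError("mutant_fraction must be in [0, 1]")
        if self.platform not in DEFAULT_INDEL_FRACTION:
            raise ValueError(f"unknown platform: {self.platform}")
        if not 0.0 <= self.per_base_error_rate < 1.0:
            raise ValueError("per_base_error_rate must be in [0, 1)")
        if self.indel_fraction_of_errors is None:
            self.indel_fraction_of_errors = DEFAULT_INDEL_FRACTION[self.platform]
        if not 0.0 <= self.indel_fraction_of_errors <= 1.0:
            raise ValueError("indel_fraction_of_errors must be in [0, 1]")
        if len(self.index5) != 5:
            raise ValueError("index5 must be 5 bases")
        barcode_space(self.barcode_scheme)  # validates the scheme name
        if self.region is None:
            if self.target_id not in DEFAULT_REGIONS:
                raise ValueError(f"unknown target_id: {self.target_id}")
            self.region = DEFAULT_REGIONS[self.target_id]
        if self.mutation_spec is None:
            self.mutation_spec = DEFAULT_MUTATIONS.get(self.target_id, (0, "A"))
        pos, alt = self.mutation_spec
        if not 0 <= pos < self.region.length_l:
            raise ValueError("mutation position outside target")
        if alt not in "ACGT":
            raise ValueError("mutation alt base must be one of ACGT")

    @property
    def n_mutant(self) -> int:
        # round-half-even would surprise here; use round-half-up
        return int(math.floor(self.mutant_fraction * self.n_molecules + 0.5))


def random_barcode(scheme: str, rng: np.random.Generator) -> str:
    if scheme == N12:
        return "".join("ACGT"[i] for i in rng.integers(0, 4, 12))
    return "".join(
        _ALLOWED[c][i] for c, i in zip(BDHV_PATTERN, rng.integers(0, 3, 15))
    )


def draw_molecules(cfg: SimConfig) -> list[tuple[int, str, str]]:
    """Assign each input molecule a barcode and a haplotype.

    Barcodes are sampled with replacement from the scheme's space, so
    collisions are possible (and detectable from the returned list).
    Exactly ``round(mutant_fraction * n_molecules)`` molecules carry the
    configured mutation.
    """
    rng = np.random.default_rng(cfg.seed)
    region = cfg.region
    pos, alt = cfg.mutation_spec
    wild = region.target_seq
    mutant = wild[:pos] + alt + wild[pos + 1 :]
    n_mut = cfg.n_mutant
    out = []
    for mol_id in range(cfg.n_molecules):
        barcode = random_barcode(cfg.barcode_scheme, rng)
        out.append((mol_id, barcode, mutant if mol_id < n_mut else wild))
    return out


def _draw_read_counts(cfg: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    name, params = cfg.reads_per_tag_model
    if name == "constant":
        return np.full(n, int(params["k"]), dtype=np.int64)
    if name == "lognormal":
        draws = rng.lognormal(params["mu"], params["sigma"], size=n)
        return np.maximum(1, np.rint(draws)).astype(np.int64)
    raise ValueError(f"unknown reads_per_tag_model: {name}")


def _corrupt(seq: str, rng: np.random.Generator, rate: float,
             indel_frac: float) -> tuple[str, list[ErrorEvent]]:
    """Apply independent per-base errors; indels are single-base."""
    hit = np.nonzero(rng.random(len(seq)) < rate)[0]
    if hit.size == 0:
        return seq, []
    events: list[ErrorEvent] = []
    chars = list(seq)
    for pos in hit[::-1]:  # right-to-left keeps earlier positions valid
        pos = int(pos)
        ref = chars[pos]
        if rng.random() < indel_frac:
            if rng.random() < 0.5:
                del chars[pos]
                events.append(ErrorEvent(pos, "del", ref, ""))
            else:
                ins = "ACGT"[rng.integers(0, 4)]
                chars.insert(pos, ins)
                events.append(ErrorEvent(pos, "ins", "", ins))
        else:
            alt = "ACGT".replace(ref, "")[rng.integers(0, 3)] if ref in "ACGT" else "A"
            chars[pos] = alt
            events.append(ErrorEvent(pos, "sub", ref, alt))
    events.reverse()
    return "".join(chars), events


def amplify_and_read(
    molecules: Iterable[tuple[int, str, str]], cfg: SimConfig
) -> tuple[list[FastqRead], list[TruthRecord]]:
    """Emit reads per molecule and corrupt them with the platform profile.

    Each read is index5 + barcode + spacer + target haplotype, then
    corrupted base-by-base; the truth records log every error event so
    downstream recovery can be scored exactly.
    """
    molecules = list(molecules)
    rng = np.random.default_rng((cfg.seed, 1))
    region = cfg.region
    pos, _ = cfg.mutation_spec
    counts = _draw_read_counts(cfg, len(molecules), rng)
    reads: list[FastqRead] = []
    truth: list[TruthRecord] = []
    rate = cfg.per_base_error_rate
    indel_frac = cfg.indel_fraction_of_errors
    for (mol_id, barcode, haplotype), k in zip(molecules, counts):
        rec = TruthRecord(mol_id, barcode, haplotype[pos] != region.target_seq[pos],
                          reads=int(k))
        template = cfg.index5 + barcode + region.spacer + haplotype
        for ridx in range(int(k)):
            if rate > 0.0:
                seq, events = _corrupt(template, rng, rate, indel_frac)
                if events:
                    rec.events[ridx] = events
            else:
                seq = template
            reads.append(
                FastqRead(f"sim:{mol_id}:{ridx}", seq, "I" * len(seq))
            )
        truth.append(rec)
    return reads, truth


# ---------------------------------------------------------------------------
# truth table I/O (TSV; events in a companion table)

def write_truth(truth: Iterable[TruthRecord], path, events_path=None) -> None:
    truth = list(truth)
    with open(path, "w") as fh:
        fh.write("molecule_id\tbarcode\tis_mutant\treads\n")
        for rec in truth:
            fh.write(f"{rec.molecule_id}\t{rec.barcode}\t{int(rec.is_mutant)}\t{rec.reads}\n")
    if events_path is not None:
        with open(events_path, "w") as fh:
            fh.write("molecule_id\tread_index\tposition\tkind\tref\talt\n")
            for rec in truth:
                for ridx in sorted(rec.events):
                    for ev in rec.events[ridx]:
                        fh.write(
                            f"{rec.molecule_id}\t{ridx}\t{ev.position}\t"
                            f"{ev.kind}\t{ev.ref}\t{ev.alt}\n"
                        )


def read_truth(path, events_path=None) -> list[TruthRecord]:
    records: dict[int, TruthRecord] = {}
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("molecule_id")
        for line in fh:
            mol, barcode, is_mut, reads = line.rstrip("\n").split("\t")
            records[int(mol)] = TruthRecord(int(mol), barcode, bool(int(is_mut)),
                                            int(reads))
    if events_path is not None:
        with open(events_path) as fh:
            fh.readline()
            for line in fh:
                mol, ridx, pos, kind, ref, alt = (line.rstrip("\n").split("\t") + [""])[:6]
                rec = records[int(mol)]
                rec.events.setdefault(int(ridx), []).append(
                    ErrorEvent(int(pos), kind, ref, alt)
                )
    return [records[k] for k in sorted(records)]


def expected_distinct_barcodes(n: int, space: int) -> float:
    """Birthday expectation: E[distinct] = S * (1 - (1 - 1/S)^n)."""
    return space * (1.0 - (1.0 - 1.0 / space) ** n)


def simulate_library(cfg: SimConfig) -> tuple[list[FastqRead], list[TruthRecord]]:
    """Convenience wrapper: draw molecules then amplify and read."""
    return amplify_and_read(draw_molecules(cfg), cfg)


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    return replace(cfg, seed=seed)
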