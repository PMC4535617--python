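"""Erroneous-tag removal by read-count thresholding.

Reads sharing a barcode tag form a tag family. Tags created by read
errors inside the barcode region are characterised by very few reads per
tag, and — on indel-dominant platforms — by a wrong tag length. The
procedure:

1. discard tags shorter than 9 bp; merge single-indel length variants
   (11/13 bp for the 12-bp N12 scheme) back into their parent family;
2. bin families by reads-per-tag into 2-read bins and compute, per bin,
   the proportion of correct families (12-bp length for N12; length 15
   with no disallowed base for BDHV15);
3. smooth the proportions with an 11-bin centred moving average;
4. the lower read-count bound of the first bin whose smoothed proportion
   reaches 90% becomes the threshold M; families with fewer than M reads
   are removed as erroneous.

The surviving family count is the absolute molecule count m. Two
monitoring estimators accompany the threshold: an upper bound on
error-free tags lost to it (correct-length families with M <= reads < 2M)
and, for BDHV barcodes, total erroneous tags as 3x the count of tags
containing a disallowed base.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .simlib import BDHV_PATTERN, _BANNED

MIN_TAG_LEN = 9


@dataclass
class TagFamily:
    canonical_tag: str
    member_read_ids: list = field(default_factory=list)
    merged_from: list[str] = field(default_factory=list)

    @property
    def n_reads(self) -> int:
        return len(self.member_read_ids)

    def length_class(self, correct_len: int = 12) -> str:
        n = len(self.canonical_tag)
        if n < MIN_TAG_LEN:
            return f"<{MIN_TAG_LEN}"
        if n < correct_len:
            return f"{MIN_TAG_LEN}-{correct_len - 1}"
        if n == correct_len:
            return str(correct_len)
        if n == correct_len + 1:
            return str(correct_len + 1)
        return f">={correct_len + 2}"


@dataclass
class TagHistogram:
    """Reads-per-tag distribution in 2-read bins.

    Bin k (1-based) covers reads-per-tag in {2k-1, 2k}. Proportions of
    empty bins are missing (NaN), and missing values are excluded from
    the smoothing average rather than treated as zero.
    """

    totals: np.ndarray
    correct: np.ndarray
    raw_proportion: np.ndarray
    smoothed_proportion: np.ndarray | None = None
    threshold_M: int | None = None

    @property
    def n_bins(self) -> int:
        return len(self.totals)

    @staticmethod
    def bin_of(n_reads: int) -> int:
        return (n_reads + 1) // 2  # 1-based

    @staticmethod
    def bin_lower_bound(k: int) -> int:
        return 2 * k - 1

    def to_frame(self) -> pd.DataFrame:
        k = np.arange(1, self.n_bins + 1)
        return pd.DataFrame(
            {
                "bin": k,
                "reads_low": 2 * k - 1,
                "reads_high": 2 * k,
                "n_tags_total": self.totals,
                "n_tags_correct": self.correct,
                "raw_proportion": self.raw_proportion,
                "smoothed_proportion": self.smoothed_proportion,
                "is_threshold_bin": (
                    (2 * k - 1) == self.threshold_M
                    if self.threshold_M is not None
                    else False
                ),
            }
        )


class ThresholdNotFound(RuntimeError):
    """No bin reaches the required smoothed proportion (sequence deeper)."""


# ---------------------------------------------------------------------------
# grouping and single-indel merging

def single_deletions(tag: str) -> set[str]:
    return {tag[:i] + tag[i + 1 :] for i in range(len(tag))}


def single_insertions(tag: str) -> set[str]:
    return {
        tag[:i] + b + tag[i:] for i in range(len(tag) + 1) for b in "ACGT"
    }


def group_and_merge(
    tagged_reads: Iterable[tuple[str, str]], *, correct_len: int = 12
) -> list[TagFamily]:
    """Group (read_id, tag) pairs into families and merge length variants.

    Tags shorter than 9 bp are discarded outright. A tag one base shorter
    (longer) than the correct length is absorbed into a correct-length
    family obtainable from it by one insertion (deletion); with several
    candidate parents the one with most reads wins, ties going to the
    lexicographically smaller canonical tag. Correct-length families are
    never merged with each other.
    """
    families: dict[str, TagFamily] = {}
    for read_id, tag in tagged_reads:
        if len(tag) < MIN_TAG_LEN:
            continue
        fam = families.get(tag)
        if fam is None:
            fam = families[tag] = TagFamily(tag)
        fam.member_read_ids.append(read_id)

    def parents(tag: str) -> list[TagFamily]:
        if len(tag) == correct_len - 1:
            cands = single_insertions(tag)
        else:  # correct_len + 1
            cands = single_deletions(tag)
        return [families[c] for c in cands if c in families]

    for tag in sorted(families):
        if len(tag) not in (correct_len - 1, correct_len + 1):
            continue
        cand = parents(tag)
        if not cand:
            continue
        parent = min(cand, key=lambda f: (-f.n_reads, f.canonical_tag))
        child = families.pop(tag)
        parent.member_read_ids.extend(child.member_read_ids)
        parent.merged_from.append(tag)
    return sorted(families.values(), key=lambda f: f.canonical_tag)


# ---------------------------------------------------------------------------
# histogram, smoothing, threshold

def is_correct_length(correct_len: int = 12) -> Callable[[TagFamily], bool]:
    return lambda fam: len(fam.canonical_tag) == correct_len


def bdhv_flagged(tag: str) -> bool:
    """True iff any position shows its scheme-banned base (certain error)."""
    return any(
        base == _BANNED[sym] for base, sym in zip(tag, BDHV_PATTERN)
    )


def is_bdhv_clean(fam_or_tag) -> bool:
    """Correctness test for the BDHV scheme: full length, no banned base."""
    tag = fam_or_tag.canonical_tag if isinstance(fam_or_tag, TagFamily) else fam_or_tag
    return len(tag) == len(BDHV_PATTERN) and not bdhv_flagged(tag)


def build_histogram(
    families: Sequence[TagFamily],
    is_correct: Callable[[TagFamily], bool] | int = 12,
) -> TagHistogram:
    """Count families per 2-read bin, total and 'correct'.

    ``is_correct`` is either the correct tag length (int) or a predicate
    on families (the BDHV scheme uses :func:`is_bdhv_clean`).
    """
    if not families:
        raise ValueError("no tag families")
    if isinstance(is_correct, int):
        is_correct = is_correct_length(is_correct)
    n_bins = TagHistogram.bin_of(max(f.n_reads for f in families))
    totals = np.zeros(n_bins, dtype=np.int64)
    correct = np.zeros(n_bins, dtype=np.int64)
    for fam in families:
        k = TagHistogram.bin_of(fam.n_reads) - 1
        totals[k] += 1
        if is_correct(fam):
            correct[k] += 1
    with np.errstate(invalid="ignore"):
        raw = np.where(totals > 0, correct / np.maximum(totals, 1), np.nan)
    return TagHistogram(totals, correct, raw)


def smooth_proportions(hist: TagHistogram, window: int = 11) -> TagHistogram:
    """Centred moving average over ``window`` bins (the bin +/- 5 neighbours).

    At the edges the average runs over the bins that exist; empty bins
    (missing proportions) are excluded from the average. Non-empty bins
    are weighted by their tag counts, so the smoothed value estimates the
    probability that a tag in the window is correct; on dense histograms
    (all window bins similarly occupied) this coincides with the plain
    mean of the bin proportions, but it keeps bins holding one or two
    tags from dominating sparse windows.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    half = window // 2
    raw = hist.raw_proportion
    weights = hist.totals.astype(float)
    n = len(raw)
    smoothed = np.full(n, np.nan)
    for k in range(n):
        lo, hi = max(0, k - half), min(n, k + half + 1)
        win = raw[lo:hi]
        w = weights[lo:hi]
        ok = ~np.isnan(win)
        if not ok.any():
            continue
        if w[ok].sum() > 0:
            smoothed[k] = np.average(win[ok], weights=w[ok])
        else:
            smoothed[k] = win[ok].mean()
    hist.smoothed_proportion = smoothed
    return hist


def find_threshold(
    hist: TagHistogram, min_prop: float = 0.90, *, strict: bool = False
) -> int:
    """Read-count threshold M from the smoothed histogram.

    M is the lower read-count bound (2k-1) of the lowest-index bin whose
    smoothed proportion reaches ``min_prop``. With ``strict=True`` the
    bin must additionally be followed only by qualifying (or empty) bins.
    """
    if hist.smoothed_proportion is None:
        smooth_proportions(hist)
    sm = hist.smoothed_proportion
    qualifies = ~np.isnan(sm) & (sm >= min_prop)
    for k in np.nonzero(qualifies)[0]:
        if strict:
            later = sm[k + 1 :]
            if np.any(~np.isnan(later) & (later < min_prop)):
                continue
        hist.threshold_M = TagHistogram.bin_lower_bound(int(k) + 1)
        return hist.threshold_M
    raise ThresholdNotFound(
        f"no bin reaches a smoothed correct-tag proportion of {min_prop:.0%}; "
        "sequence deeper or lower min_prop"
    )


def remove_erroneous(
    families: Sequence[TagFamily], threshold_M: int
) -> tuple[list[TagFamily], list[TagFamily]]:
    """Split families into (accepted, removed) at the read-count threshold."""
    accepted = [f for f in families if f.n_reads >= threshold_M]
    removed = [f for f in families if f.n_reads < threshold_M]
    return accepted, removed


def estimate_removed_error_free(
    families: Sequence[TagFamily],
    threshold_M: int,
    is_correct: Callable[[TagFamily], bool] | int = 12,
) -> tuple[int, float]:
    """Upper bound on error-free tags lost to the threshold.

    The error-free reads-per-tag distribution is unimodal with its peak
    far above M, so the count of correct families in [0, M) cannot
    exceed the count in [M, 2M). Returns that count and its fraction of
    accepted families.
    """
    if isinstance(is_correct, int):
        is_correct = is_correct_length(is_correct)
    bound = sum(
        1
        for f in families
        if threshold_M <= f.n_reads < 2 * threshold_M and is_correct(f)
    )
    n_accepted = sum(1 for f in families if f.n_reads >= threshold_M)
    return bound, bound / n_accepted if n_accepted else math.nan


def estimate_bdhv_errors(families: Sequence[TagFamily]) -> int:
    """Total erroneous tags estimated from the BDHV design.

    Each BDHV position draws from 3 allowed bases; a uniform substitution
    therefore lands on the single banned base with probability 1/3, so
    total erroneous tags ~= 3 x (tags showing a banned base).
    """
    flagged = sum(
        1
        for f in families
        if len(f.canonical_tag) == len(BDHV_PATTERN) and bdhv_flagged(f.canonical_tag)
    )
    return 3 * flagged


def families_to_frame(
    families: Sequence[TagFamily], threshold_M: int | None = None,
    correct_len: int = 12,
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "canonical_tag": [f.canonical_tag for f in families],
            "n_reads": [f.n_reads for f in families],
            "length_class": [f.length_class(correct_len) for f in families],
            "n_merged_variants": [len(f.merged_from) for f in families],
            "accepted": [
                f.n_reads >= threshold_M if threshold_M is not None else True
                for f in families
            ],
        }
    )


# ---------------------------------------------------------------------------
# saturation analysis

def saturation_curve(
    tagged_reads: Sequence[tuple[str, str]],
    depths: Sequence[float],
    *,
    correct_len: int = 12,
    is_correct: Callable[[TagFamily], bool] | int | None = None,
    min_prop: float = 0.90,
    window: int = 11,
    fixed_cutoff: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Accepted-family counts vs read depth, adaptive vs fixed cutoff.

    Reads are shuffled once and depths are nested prefixes, so the
    fixed-cutoff count (families with more than ``fixed_cutoff`` reads)
    is non-decreasing by construction. The adaptive count re-derives M at
    every depth; None (NaN) where no threshold qualifies. ``is_correct``
    defaults to the length test at ``correct_len`` (pass
    :func:`is_bdhv_clean` for BDHV libraries).
    """
    if is_correct is None:
        is_correct = correct_len
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(tagged_reads))
    rows = []
    for depth in depths:
        k = int(round(depth * len(tagged_reads)))
        subset = [tagged_reads[i] for i in order[:k]]
        families = group_and_merge(subset, correct_len=correct_len)
        fixed = sum(1 for f in families if f.n_reads > fixed_cutoff)
        try:
            hist = smooth_proportions(
                build_histogram(families, is_correct), window
            )
            M = find_threshold(hist, min_prop)
            adaptive = sum(1 for f in families if f.n_reads >= M)
        except (ThresholdNotFound, ValueError):
            M, adaptive = None, None
        rows.append(
            {"depth": depth, "n_reads": k, "threshold_M": M,
             "adaptive_accepted": adaptive, "fixed_cutoff_accepted": fixed}
        )
    return pd.DataFrame(rows)
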