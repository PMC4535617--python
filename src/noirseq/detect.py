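"""Error rates, Poisson anomaly detection and mutant-fraction quantitation.

Because every consensus read represents one molecule, base changes in a
target region can be tested against a Poisson model of residual
sequencing error: with region length l (bp), m sequenced molecules and a
per-base error rate ER, the expected number of error base changes is

    lambda = l * m * ER

and the probability of observing n or more changes by error alone is the
upper Poisson tail P = 1 - sum_{k=0}^{n-1} lambda^k e^-lambda / k!. A
region is variant-positive when P <= alpha (default 1e-3, one false
positive per 1000 samples); the criterion evaluates the whole region, not
individual positions. ER defaults to 1e-5 for consensus (NOIR) calls and
5e-4 for raw-read deep-sequencing calls.

True mutations pile up at one position across molecules, while residual
errors scatter; a clustered/scattered annotation records this without
overriding the Poisson verdict.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .noir import Pileup
from .regions import TargetRegion
from .tagio import RawRead

ER_NOIR = 1e-5
ER_DEEP = 5e-4
ALPHA = 1e-3

_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


@dataclass
class ErrorRateEstimate:
    n_nonref_bases: int
    n_total_bases: int
    ci_low: float
    ci_high: float
    excluded_positions: int = 0

    @property
    def rate(self) -> float:
        return self.n_nonref_bases / self.n_total_bases if self.n_total_bases else math.nan


@dataclass
class RegionCall:
    target_id: str
    l: int
    m: int
    n: int
    n_deletions: int
    er: float
    lam: float
    p_value: float
    variant_positive: bool
    positional_changes: dict[int, int] = field(default_factory=dict)
    clustering_label: str = "indeterminate"
    mutant_fraction_pct: float | None = None
    modal_position: int | None = None
    modal_alt: str | None = None


def _sub_masks(pileup: Pileup, region: TargetRegion):
    """(nonref substitution counts, base-call totals) per position, with
    excluded positions zeroed."""
    ref_idx = np.array([_BASE_INDEX[b] for b in region.target_seq])
    base_counts = pileup.counts[:, :4]
    totals = base_counts.sum(axis=1)
    nonref = totals - base_counts[np.arange(region.length_l), ref_idx]
    if region.excluded_positions:
        mask = np.array(sorted(region.excluded_positions))
        totals = totals.copy()
        nonref = nonref.copy()
        totals[mask] = 0
        nonref[mask] = 0
    return nonref, totals


def error_rate(pileup: Pileup, region: TargetRegion,
               confidence: float = 0.95) -> ErrorRateEstimate:
    """Non-reference base calls / all base calls over non-excluded positions.

    Deletion calls are outside both counts (the rate is a substitution
    error rate); the exact (Clopper-Pearson) binomial CI is attached for
    reporting.
    """
    nonref, totals = _sub_masks(pileup, region)
    k, n = int(nonref.sum()), int(totals.sum())
    if n:
        ci = stats.binomtest(k, n).proportion_ci(confidence, method="exact")
        lo, hi = float(ci.low), float(ci.high)
    else:
        lo = hi = math.nan
    return ErrorRateEstimate(k, n, lo, hi, len(region.excluded_positions))


def poisson_p(l: int, m: int, er: float, n: int) -> float:
    """Upper-tail probability of >= n error base changes under Poisson.

    lambda = l*m*ER; P = 1 - sum_{k=0}^{n-1} lambda^k e^-lambda / k!,
    evaluated with a numerically stable survival function.
    """
    if l < 0 or m < 0 or n < 0:
        raise ValueError("l, m and n must be non-negative")
    if not 0.0 <= er <= 1.0:
        raise ValueError("ER must be in [0, 1]")
    if n == 0:
        return 1.0
    lam = float(l) * float(m) * er
    p = float(stats.poisson.sf(n - 1, lam))
    if p < 1e-8 and n > lam:
        # deep in the upper tail the incomplete-gamma route degrades;
        # the pmf sum from k=n is decreasing there and cancellation-free
        p = _poisson_tail_direct(lam, n)
    return p


def _poisson_tail_direct(lam: float, n: int) -> float:
    """sum_{k>=n} e^-lam lam^k / k!, leading term via logs; requires n > lam."""
    if lam == 0.0:
        return 0.0
    log_term = n * math.log(lam) - lam - math.lgamma(n + 1)
    if log_term < -745.0:  # below exp underflow: tail not representable
        return 0.0
    term = math.exp(log_term)
    total = 0.0
    k = n
    while term > 0.0 and term > total * 1e-18:
        total += term
        k += 1
        term *= lam / k
    return total


def classify_changes(
    positional_changes: dict[int, int],
    *,
    min_modal_fraction: float = 0.5,
    min_changes: int = 2,
) -> str:
    """'clustered' when the modal position holds at least half of all
    changes (a mutation signature), 'scattered' otherwise; fewer than
    ``min_changes`` changes are 'indeterminate'."""
    total = sum(positional_changes.values())
    if total < min_changes:
        return "indeterminate"
    modal = max(positional_changes.values())
    return "clustered" if modal >= min_modal_fraction * total else "scattered"


def mutant_fraction(
    pileup: Pileup, region: TargetRegion, position: int, alt: str, m: int
) -> float | None:
    """Percentage of molecules carrying ``alt`` at the 0-based target
    ``position``; None when the position is uncovered."""
    if pileup.coverage[position] == 0:
        return None
    return 100.0 * pileup.counts[position, _BASE_INDEX[alt]] / m


def call_region(
    pileup: Pileup,
    region: TargetRegion,
    er: float = ER_NOIR,
    alpha: float = ALPHA,
) -> RegionCall:
    """Region-level Poisson variant call from a pileup.

    n counts every non-reference base call (substitutions) over
    non-excluded positions; deletions are tallied separately and do not
    enter the Poisson test. l is the effective region length (excluded
    positions are not counted in n, so they do not contribute to lambda).
    """
    m = pileup.n_molecules
    nonref, _ = _sub_masks(pileup, region)
    n = int(nonref.sum())
    dels = pileup.counts[:, 4].copy()
    if region.excluded_positions:
        dels[np.array(sorted(region.excluded_positions))] = 0
    l_eff = region.effective_length
    p = poisson_p(l_eff, m, er, n)
    lam = l_eff * m * er
    positions = {int(i): int(c) for i, c in enumerate(nonref) if c > 0}
    label = classify_changes(positions)
    modal_pos = modal_alt = frac = None
    if positions:
        modal_pos = max(positions, key=lambda i: (positions[i], -i))
        base_counts = pileup.counts[modal_pos, :4].copy()
        base_counts[_BASE_INDEX[region.target_seq[modal_pos]]] = 0
        modal_alt = "ACGT"[int(base_counts.argmax())]
        frac = mutant_fraction(pileup, region, modal_pos, modal_alt, m)
    return RegionCall(
        target_id=region.target_id,
        l=region.length_l,
        m=m,
        n=n,
        n_deletions=int(dels.sum()),
        er=er,
        lam=lam,
        p_value=p,
        variant_positive=p <= alpha,
        positional_changes=positions,
        clustering_label=label,
        mutant_fraction_pct=frac,
        modal_position=modal_pos,
        modal_alt=modal_alt,
    )


def deep_mode_subsample(
    reads: list[RawRead], k: int, seed: int, region: TargetRegion
) -> Pileup:
    """Pileup of k randomly chosen raw reads (pre-consensus), the
    deep-sequencing comparison arm; call with er=ER_DEEP."""
    from .noir import pileup_reads

    if k > len(reads):
        raise ValueError(f"cannot subsample {k} of {len(reads)} reads")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(reads), size=k, replace=False) if k else np.empty(0, int)
    return pileup_reads([reads[i] for i in sorted(idx)], region)
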