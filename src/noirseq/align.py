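"""Affine-gap semi-global alignment of read payloads to short references.

Targets here are short (~80-130 bp) and known, so a dedicated Gotoh
aligner is both simpler and faster than shelling out to a general-purpose
mapper. Scoring: match +1, mismatch -5, gap open -2, gap extend -1 (a gap
of length L costs 2 + L). End gaps on the *read* are free (soft clips);
the reference must be consumed in full, so reference overhangs against a
truncated read are charged as ordinary gaps.

The aligner reports, for every reference position, the read base aligned
to it (or a deletion), which is exactly what consensus building and
pileups need; insertions relative to the reference are counted but kept
out of the per-position code array.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

MATCH = 1
MISMATCH = -5
GAP_OPEN = -2
GAP_EXTEND = -1

_NEG = -(10**7)

# base encoding shared across the package
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i
DEL_CODE = 4  # deletion relative to the reference
BASES = "ACGT-"


def encode(seq: str) -> np.ndarray:
    """Encode a base string as int8 codes (A,C,G,T -> 0..3; other -> -1)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def _gotoh(q, r):  # pragma: no cover - exercised via align_payload_to_ref
    n = q.shape[0]
    m = r.shape[0]
    S = np.full((n + 1, m + 1), _NEG, dtype=np.int32)
    E = np.full((n + 1, m + 1), _NEG, dtype=np.int32)  # gap in read (del)
    F = np.full((n + 1, m + 1), _NEG, dtype=np.int32)  # gap in ref (ins)
    for i in range(n + 1):
        S[i, 0] = 0  # leading read bases are free (soft clip)
    for j in range(1, m + 1):
        E[0, j] = GAP_OPEN + GAP_EXTEND * j
        S[0, j] = E[0, j]
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            e = E[i, j - 1] + GAP_EXTEND
            eo = S[i, j - 1] + GAP_OPEN + GAP_EXTEND
            E[i, j] = e if e > eo else eo
            f = F[i - 1, j] + GAP_EXTEND
            fo = S[i - 1, j] + GAP_OPEN + GAP_EXTEND
            F[i, j] = f if f > fo else fo
            sub = MATCH if (qi == r[j - 1] and qi >= 0) else MISMATCH
            best = S[i - 1, j - 1] + sub
            if E[i, j] > best:
                best = E[i, j]
            if F[i, j] > best:
                best = F[i, j]
            S[i, j] = best
    # free trailing read bases: best score in the last column
    best_i = n
    best = S[n, m]
    for i in range(n, -1, -1):  # prefer the longest aligned prefix on ties
        if S[i, m] > best:
            best = S[i, m]
            best_i = i
    # traceback
    codes = np.full(m, np.int8(-1))
    i = best_i
    j = m
    state = 0  # 0=S, 1=E, 2=F
    matches = 0
    insertions = 0
    first_pair = -1
    last_pair = -1
    while j > 0:
        if state == 0:
            if i > 0:
                sub = MATCH if (q[i - 1] == r[j - 1] and q[i - 1] >= 0) else MISMATCH
                if S[i, j] == S[i - 1, j - 1] + sub:
                    codes[j - 1] = q[i - 1] if q[i - 1] >= 0 else np.int8(-1)
                    if q[i - 1] == r[j - 1] and q[i - 1] >= 0:
                        matches += 1
                    if last_pair < 0:
                        last_pair = j - 1
                    first_pair = j - 1
                    i -= 1
                    j -= 1
                    continue
            if S[i, j] == E[i, j]:
                state = 1
                continue
            state = 2
            continue
        if state == 1:
            codes[j - 1] = DEL_CODE
            if E[i, j] != S[i, j - 1] + GAP_OPEN + GAP_EXTEND:
                state = 1
            else:
                state = 0
            j -= 1
            continue
        # state == 2: insertion in the read
        insertions += 1
        if F[i, j] == S[i - 1, j] + GAP_OPEN + GAP_EXTEND:
            state = 0
        i -= 1
    lead_clip = i
    trail_clip = n - best_i
    # reference positions consumed only by terminal deletion runs are not
    # covered by the read at all: mark them uncovered rather than deleted
    if first_pair >= 0:
        for jj in range(first_pair):
            if codes[jj] == DEL_CODE:
                codes[jj] = -1
        for jj in range(last_pair + 1, m):
            if codes[jj] == DEL_CODE:
                codes[jj] = -1
    else:
        codes[:] = -1
    return best, lead_clip, trail_clip, matches, insertions, first_pair, last_pair, codes


@dataclass
class Alignment:
    """Alignment of one payload against one reference.

    ``codes`` has one entry per reference position: 0..3 an aligned read
    base, 4 a deletion, -1 not covered. ``span`` is the 0-based half-open
    reference interval covered by aligned read bases.
    """

    score: int
    lead_clip: int
    trail_clip: int
    matches: int
    insertions: int
    span: tuple[int, int]
    codes: np.ndarray

    @property
    def span_length(self) -> int:
        return self.span[1] - self.span[0]

    @property
    def identity(self) -> float:
        return self.matches / self.span_length if self.span_length else 0.0


def align_payload_to_ref(payload: str, ref: str) -> Alignment:
    """Align a read payload to one reference (spacer+target) string."""
    score, lead, trail, matches, ins, first, last, codes = _gotoh(
        encode(payload), encode(ref)
    )
    span = (first, last + 1) if first >= 0 else (0, 0)
    return Alignment(int(score), int(lead), int(trail), int(matches),
                     int(ins), span, codes)
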