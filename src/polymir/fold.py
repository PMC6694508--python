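"""RNA hairpin folding by base-pair maximization, and precursor acceptance criteria.

miRNA precursor candidates are scored with a Nussinov-style dynamic program
that maximizes the number of nested base pairs (Watson-Crick plus G:U wobble,
minimum hairpin loop of 3 nt).  Maximum pairing is a deliberately simple,
fully deterministic stand-in for free-energy folding: every criterion applied
downstream (mature-arm placement, duplex pairing, bulge size, overall pairing
fraction) only needs the pair set, and the DP optimum is checkable against
exhaustive enumeration on short sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}

# allowed pairs between coded bases: A:U, C:G, G:U
_PAIRABLE = np.zeros((4, 4), dtype=np.bool_)
for _a, _b in [(0, 3), (1, 2), (2, 3)]:
    _PAIRABLE[_a, _b] = True
    _PAIRABLE[_b, _a] = True

MIN_LOOP = 3  # minimum unpaired bases enclosed by a pair


def encode(seq: str) -> np.ndarray:
    """Encode an RNA/DNA string as int8 codes (A=0, C=1, G=2, T/U=3)."""
    try:
        return np.array([_CODE[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as exc:  # pragma: no cover - message only
        raise ValueError(f"non-ACGTU character in sequence: {exc}") from None


@njit(cache=False)
def _fill_dp(codes, pairable):  # pragma: no cover - compiled
    n = codes.shape[0]
    dp = np.zeros((n, n), dtype=np.int32)
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i + 1, j]
            if dp[i, j - 1] > best:
                best = dp[i, j - 1]
            if pairable[codes[i], codes[j]]:
                v = dp[i + 1, j - 1] + 1
                if v > best:
                    best = v
            for k in range(i + MIN_LOOP + 1, j):
                v = dp[i, k] + dp[k + 1, j]
                if v > best:
                    best = v
            dp[i, j] = best
    return dp


@dataclass(frozen=True)
class HairpinStructure:
    """A nested secondary structure: sequence plus its base-pair set.

    ``pairs`` holds 0-based (i, j) index pairs with i < j, sorted by i; the
    structure is nested (no pseudoknots) and every base joins at most one pair.
    """

    sequence: str
    pairs: tuple[tuple[int, int], ...]

    @property
    def pair_count(self) -> int:
        return len(self.pairs)

    def partner(self) -> np.ndarray:
        """Partner index per base, -1 for unpaired."""
        p = np.full(len(self.sequence), -1, dtype=np.int64)
        for i, j in self.pairs:
            p[i] = j
            p[j] = i
        return p


def fold_hairpin(precursor: str) -> HairpinStructure:
    """Fold a precursor into its maximum-base-pair nested structure.

    Allowed pairs are A:U, G:C and G:U with a minimum hairpin loop of
    ``MIN_LOOP`` unpaired bases.  Among co-optimal structures the traceback
    prefers pairing the outermost closable pair first, which extends helices
    and therefore breaks ties toward the longest contiguous stem.
    """
    codes = encode(precursor)
    n = codes.shape[0]
    if n == 0:
        return HairpinStructure(precursor, ())
    dp = _fill_dp(codes, _PAIRABLE)
    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= MIN_LOOP:
            continue
        if (
            _PAIRABLE[codes[i], codes[j]]
            and dp[i + 1, j - 1] + 1 == dp[i, j]
        ):
            pairs.append((i, j))
            stack.append((i + 1, j - 1))
        elif dp[i + 1, j] == dp[i, j]:
            stack.append((i + 1, j))
        elif dp[i, j - 1] == dp[i, j]:
            stack.append((i, j - 1))
        else:
            for k in range(i + MIN_LOOP + 1, j):
                if dp[i, k] + dp[k + 1, j] == dp[i, j]:
                    stack.append((i, k))
                    stack.append((k + 1, j))
                    break
    pairs.sort()
    return HairpinStructure(precursor, tuple(pairs))


@dataclass
class HairpinParams:
    """Acceptance thresholds for a folded precursor carrying a mature miRNA.

    Defaults are explicit, configurable plant-miRNA criteria: the mature must
    be 18-26 nt, sit entirely on one arm, pair at >=14 of its bases, tolerate
    bulges of at most 4 nt inside the mature duplex, and the precursor overall
    must pair at least a third of its bases.
    """

    min_mature_len: int = 18
    max_mature_len: int = 26
    min_mature_paired: int = 14
    max_bulge: int = 4
    min_pair_fraction: float = 0.33


@dataclass
class HairpinCall:
    valid: bool
    reasons: tuple[str, ...]
    arm: str | None = None  # "5p" | "3p"
    mature_paired: int = 0
    largest_bulge: int = 0
    pair_fraction: float = 0.0


def is_valid_hairpin(
    structure: HairpinStructure,
    mature_span: tuple[int, int],
    params: HairpinParams | None = None,
) -> HairpinCall:
    """Decide whether a folded precursor supports a mature miRNA at ``mature_span``.

    ``mature_span`` is 0-based half-open on the precursor.  Failure returns
    reason codes rather than raising: "mature-length", "loop-overlap" (the
    mature straddles a terminal loop, i.e. pairs on both sides of it),
    "low-pairing", "bulge", "low-structure", "unpaired".
    """
    if params is None:
        params = HairpinParams()
    s, e = mature_span
    n = len(structure.sequence)
    if not (0 <= s < e <= n):
        raise ValueError(f"mature span {mature_span} outside precursor of length {n}")
    reasons: list[str] = []
    mlen = e - s
    if not (params.min_mature_len <= mlen <= params.max_mature_len):
        reasons.append("mature-length")

    partner = structure.partner()
    paired_idx = [i for i in range(s, e) if partner[i] >= 0]
    arm: str | None = None
    largest_bulge = 0
    if not paired_idx:
        reasons.append("unpaired")
    else:
        on_5p = [i for i in paired_idx if partner[i] > i]
        on_3p = [i for i in paired_idx if partner[i] < i]
        if on_5p and on_3p:
            reasons.append("loop-overlap")
        else:
            arm = "5p" if on_5p else "3p"
        if len(paired_idx) < params.min_mature_paired:
            reasons.append("low-pairing")
        for a, b in zip(paired_idx, paired_idx[1:]):
            gap_m = b - a - 1
            gap_star = abs(int(partner[a]) - int(partner[b])) - 1
            largest_bulge = max(largest_bulge, gap_m, gap_star)
        if largest_bulge > params.max_bulge:
            reasons.append("bulge")

    pair_fraction = 2.0 * structure.pair_count / n if n else 0.0
    if pair_fraction < params.min_pair_fraction:
        reasons.append("low-structure")

    return HairpinCall(
        valid=not reasons,
        reasons=tuple(reasons),
        arm=arm,
        mature_paired=len(paired_idx),
        largest_bulge=largest_bulge,
        pair_fraction=pair_fraction,
    )
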