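"""Whole-string SMILES similarity functions.

Implements edit (Levenshtein) similarity, the normalized longest common
subsequence (NLCS), the CLCS combination of three LCS variants, and the
substring-spectrum string kernel.  All operate on normalized SMILES
(see :mod:`smilesim.prep`) and are symmetric in their two arguments.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

#: Guard against pathological inputs: substring profiles are O(n^2).
MAX_STRING_LENGTH = 2000


def _check_length(*strings: str) -> None:
    for s in strings:
        if len(s) > MAX_STRING_LENGTH:
            raise ValueError(f"string of length {len(s)} exceeds cap {MAX_STRING_LENGTH}")


def edit_distance(s1: str, s2: str) -> int:
    """Levenshtein distance with unit-cost insert/delete/substitute."""
    if s1 == s2:
        return 0
    if len(s1) < len(s2):  # iterate over the longer, keep the shorter row
        s1, s2 = s2, s1
    b = np.frombuffer(s2.encode("utf-32-le"), dtype=np.uint32)
    row = np.arange(len(b) + 1)
    for i, ch in enumerate(s1, 1):
        prev = row.copy()
        row[0] = i
        sub = prev[:-1] + (b != ord(ch))
        np.minimum(sub, prev[1:] + 1, out=row[1:])
        # insertions need a sequential pass
        for j in range(1, len(row)):
            if row[j - 1] + 1 < row[j]:
                row[j] = row[j - 1] + 1
    return int(row[-1])


def edit_similarity(s1: str, s2: str) -> float:
    """``1 - edit/max(len)``; 1 iff the strings are equal."""
    if not s1 and not s2:
        logger.warning("edit_similarity of two empty strings; returning 1 by convention")
        return 1.0
    return 1.0 - edit_distance(s1, s2) / max(len(s1), len(s2))


def lcs_length(s1: str, s2: str) -> int:
    """Length of the classic (non-contiguous) longest common subsequence."""
    if not s1 or not s2:
        return 0
    a = np.frombuffer(s1.encode("utf-32-le"), dtype=np.uint32)
    b = np.frombuffer(s2.encode("utf-32-le"), dtype=np.uint32)
    prev = np.zeros(len(b) + 1, dtype=np.int64)
    for ca in a:
        cur = np.empty_like(prev)
        cur[0] = 0
        match = prev[:-1] + (b == ca)
        for j in range(1, len(cur)):
            cur[j] = max(match[j - 1], prev[j], cur[j - 1])
        prev = cur
    return int(prev[-1])


def _norm(length: int, s1: str, s2: str) -> float:
    return length * length / (len(s1) * len(s2))


def nlcs(s1: str, s2: str) -> float:
    """Normalized LCS: ``len(LCS)^2 / (len(s1) * len(s2))``."""
    if not s1 or not s2:
        logger.warning("nlcs with an empty string; returning 0")
        return 0.0
    return _norm(lcs_length(s1, s2), s1, s2)


def longest_common_substring_length(s1: str, s2: str) -> int:
    """Length of the longest common contiguous substring."""
    if not s1 or not s2:
        return 0
    if len(s1) > len(s2):
        s1, s2 = s2, s1
    # grow candidate length; all length-k substrings of s1 vs s2
    best = 0
    for k in range(1, len(s1) + 1):
        grams = {s1[i : i + k] for i in range(len(s1) - k + 1)}
        if any(g in s2 for g in grams):
            best = k
        else:
            break
    return best


def _prefix_in(shorter: str, longer: str) -> int:
    """Longest prefix of ``shorter`` occurring contiguously in ``longer``."""
    best = 0
    for k in range(1, len(shorter) + 1):
        if shorter[:k] in longer:
            best = k
        else:
            break
    return best


def nmclcs1(s1: str, s2: str) -> float:
    """Normalized maximal consecutive LCS anchored at the first character.

    The longest prefix of the shorter string that occurs as a contiguous
    substring of the longer string, normalized as ``len^2/(n1*n2)``.
    For equal-length strings the larger of the two directions is taken
    so the function stays symmetric.
    """
    if not s1 or not s2:
        logger.warning("nmclcs1 with an empty string; returning 0")
        return 0.0
    if len(s1) < len(s2):
        length = _prefix_in(s1, s2)
    elif len(s2) < len(s1):
        length = _prefix_in(s2, s1)
    else:
        length = max(_prefix_in(s1, s2), _prefix_in(s2, s1))
    return _norm(length, s1, s2)


def nmclcsn(s1: str, s2: str) -> float:
    """Normalized maximal consecutive LCS starting anywhere."""
    if not s1 or not s2:
        logger.warning("nmclcsn with an empty string; returning 0")
        return 0.0
    return _norm(longest_common_substring_length(s1, s2), s1, s2)


@dataclass(frozen=True)
class ClcsWeights:
    """Weights for the CLCS combination.

    Defaults are the literal 0.33 of the original combination (not 1/3),
    so identical strings score 0.99.
    """

    w1: float = 0.33  # NLCS
    w2: float = 0.33  # NMCLCS1
    w3: float = 0.33  # NMCLCSn

    def __post_init__(self) -> None:
        if min(self.w1, self.w2, self.w3) < 0:
            raise ValueError("CLCS weights must be non-negative")


def clcs_similarity(s1: str, s2: str, weights: ClcsWeights | None = None) -> float:
    """Weighted sum of NLCS, NMCLCS1 and NMCLCSn (unrounded components)."""
    w = weights or ClcsWeights()
    return w.w1 * nlcs(s1, s2) + w.w2 * nmclcs1(s1, s2) + w.w3 * nmclcsn(s1, s2)


@dataclass
class SubstringProfile:
    """Occurrence counts of every contiguous substring of length >= min_len."""

    counts: Counter
    min_len: int


def substring_profile(s: str, min_len: int = 2) -> SubstringProfile:
    """Count all contiguous substrings of ``s`` with length >= ``min_len``."""
    _check_length(s)
    if len(s) < min_len:
        logger.warning("string %r shorter than min_len=%d; empty profile", s, min_len)
        return SubstringProfile(Counter(), min_len)
    counts = Counter(
        s[i:j] for i in range(len(s)) for j in range(i + min_len, len(s) + 1)
    )
    return SubstringProfile(counts, min_len)


def substring_kernel(s1: str, s2: str, min_len: int = 2, normalize: bool = False) -> float:
    """Inner product of substring-frequency profiles.

    By default the raw inner product; with ``normalize=True`` the cosine
    normalization ``K(a,b)/sqrt(K(a,a)K(b,b))`` is applied, which is what
    the interaction predictor consumes (raw inner products are not
    comparable across molecule sizes).
    """
    p1 = substring_profile(s1, min_len).counts
    p2 = substring_profile(s2, min_len).counts
    small, big = (p1, p2) if len(p1) <= len(p2) else (p2, p1)
    k12 = sum(c * big[sub] for sub, c in small.items())
    if not normalize:
        return float(k12)
    k11 = sum(c * c for c in p1.values())
    k22 = sum(c * c for c in p2.values())
    if k11 == 0 or k22 == 0:
        logger.warning("substring_kernel normalization with an empty profile; returning 0")
        return 0.0
    return k12 / float(np.sqrt(k11) * np.sqrt(k22))
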