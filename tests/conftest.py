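"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive quantities by the most naive route
(full DP matrices, quadratic scans) so they stay independent of the library
code paths they check.
"""

from __future__ import annotations

import random

import pytest

CANONICAL_11MER = [1, 2, 3, 4, 5, 6, 7, 8, 5, 9, 10]
VARIANT_9MER = [1, 2, 3, 4, 5, 6, 11, 9, 10]


def levenshtein_dp(a: str, b: str) -> int:
    """Textbook O(|a||b|) Levenshtein distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def md_bruteforce(type_ids: list[int]) -> list[tuple[int, int]]:
    """Quadratic next-same-type scan: (index, period) pairs."""
    out = []
    for i, t in enumerate(type_ids):
        for j in range(i + 1, len(type_ids)):
            if type_ids[j] == t:
                out.append((i, j - i))
                break
    return out


def random_dna(length: int, rng: random.Random) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


@pytest.fixture
def canonical_plan() -> list[int]:
    return list(CANONICAL_11MER)


@pytest.fixture
def triplet_plan() -> list[list[int]]:
    """Canonical / deletion-variant / canonical triplet (31 monomers)."""
    return [list(CANONICAL_11MER), list(VARIANT_9MER), list(CANONICAL_11MER)]
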