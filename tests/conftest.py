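"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from typing import Dict, List, Optional, Set, Tuple

import numpy as np
import pytest

from ssrkit.genotypes import GenotypeMatrix
from ssrkit.mining import MiningThresholds, is_primitive

ACGT = set("ACGT")


def brute_force_ssrs(
    sequence: str, thresholds: Optional[MiningThresholds] = None
) -> Set[Tuple[int, int, str, int, int]]:
    """Quadratic reference scanner: tests every (start, period, extension).

    Returns {(start_1based, end_1based, motif, period, repeats)} for every
    maximal perfect array with a primitive motif meeting its period's
    threshold; the reported span is the first period*repeats bases of the
    maximal periodic segment.
    """
    if thresholds is None:
        thresholds = MiningThresholds()
    s = sequence.upper()
    n = len(s)
    out: Set[Tuple[int, int, str, int, int]] = set()
    for p in range(1, 7):
        thr = thresholds[p]
        for i in range(n - p * thr + 1):
            motif = s[i : i + p]
            if not ACGT.issuperset(motif) or not is_primitive(motif):
                continue
            # left-maximality: cannot extend the periodicity one base left
            if i > 0 and s[i - 1] in ACGT and s[i - 1] == s[i + p - 1]:
                continue
            j = i + p
            while j < n and s[j] in ACGT and s[j] == s[j - p]:
                j += 1
            repeats = (j - i) // p
            if repeats >= thr:
                out.add((i + 1, i + repeats * p, motif, p, repeats))
    return out


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.4) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def matrix_from_codes(
    codes: List[List[Optional[Tuple[str, str]]]],
    individuals: Optional[List[str]] = None,
    loci: Optional[List[str]] = None,
) -> GenotypeMatrix:
    n, m = len(codes), len(codes[0])
    return GenotypeMatrix(
        individuals or [f"ind{i+1}" for i in range(n)],
        loci or [f"M{j+1}" for j in range(m)],
        codes,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240626)


@pytest.fixture
def two_pop_freqs() -> List[np.ndarray]:
    """30 biallelic loci, frequencies 0.9 vs 0.1 between two populations."""
    return [np.array([[0.9, 0.1], [0.1, 0.9]]) for _ in range(30)]
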