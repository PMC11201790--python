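"""Primer-pair candidate enumeration around an SSR locus.

Candidates are exhaustive window scans over the flanks under the classic
marker-development constraints: product 100-250 bp spanning the repeat
array, primer length 18-24 bp, melting temperature 50-60 C, GC 40-60 %,
and a capped Tm difference between the two primers.  No secondary-structure
screening is applied.  Melting temperature uses the Wallace rule for short
oligos and the GC fraction formula for >= 14-mers; the function is a
parameter of :func:`design_primers` so a nearest-neighbour model can be
slotted in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional, Tuple

from .errors import CoordinateError, InvalidAlphabetError, SSRKitError, ValidationError
from .mining import SSRLocus, _VALID, reverse_complement


@dataclass(frozen=True)
class PrimerConstraints:
    product_bp: Tuple[int, int] = (100, 250)
    primer_len: Tuple[int, int] = (18, 24)
    tm_celsius: Tuple[float, float] = (50.0, 60.0)
    gc_percent: Tuple[float, float] = (40.0, 60.0)
    max_tm_diff: float = 3.0

    def __post_init__(self) -> None:
        for name in ("product_bp", "primer_len", "tm_celsius", "gc_percent"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValidationError(f"{name}: empty range [{lo}, {hi}]")
        if self.product_bp[0] <= 2 * self.primer_len[0]:
            raise ValidationError("minimum product must exceed twice the minimum primer length")


@dataclass(frozen=True)
class PrimerPair:
    """A left/right primer pair; positions are 1-based on the template.

    ``right_start`` is the 1-based position of the *first* template base of
    the right primer's binding site; ``right_seq`` is the reverse
    complement of that template segment.
    """

    left_seq: str
    right_seq: str
    left_start: int
    right_start: int
    product_bp: int
    left_tm: float
    right_tm: float
    left_gc: float
    right_gc: float


def gc_percent(seq: str) -> float:
    return 100.0 * sum(1 for c in seq if c in "GC") / len(seq)


def melting_temperature(seq: str) -> float:
    """Tm in Celsius: Wallace 2(A+T)+4(G+C) below 14 nt, else the GC rule
    64.9 + 41*(GC - 16.4)/len."""
    seq = seq.upper()
    if not _VALID.issuperset(seq):
        raise InvalidAlphabetError("primer contains non-ACGT characters")
    n = len(seq)
    if n < 8:
        raise SSRKitError(f"primer too short for Tm estimate ({n} < 8 nt)")
    gc = sum(1 for c in seq if c in "GC")
    if n < 14:
        return 2.0 * (n - gc) + 4.0 * gc
    return 64.9 + 41.0 * (gc - 16.4) / n


def design_primers(
    locus: SSRLocus,
    template: str,
    constraints: Optional[PrimerConstraints] = None,
    max_candidates: int = 3,
    tm_func: Callable[[str], float] = melting_temperature,
) -> List[PrimerPair]:
    """Enumerate primer pairs whose product fully contains the SSR array.

    All windows in the allowed flank regions are scanned; survivors are
    ranked by |left_tm - right_tm|, then by distance of the product size
    from the middle of the allowed product range, then by coordinates, and
    the top ``max_candidates`` returned.  Deterministic.
    """
    if constraints is None:
        constraints = PrimerConstraints()
    if max_candidates < 1:
        raise ValidationError("max_candidates must be >= 1")
    template = template.upper()
    n = len(template)
    if not (1 <= locus.start <= locus.end <= n):
        raise CoordinateError(
            f"locus {locus.start}-{locus.end} outside template of length {n}"
        )
    c = constraints
    pmin, pmax = c.product_bp
    lmin, lmax = c.primer_len

    def window_ok(seq: str) -> Optional[Tuple[float, float]]:
        if not _VALID.issuperset(seq):
            return None
        gc = gc_percent(seq)
        if not (c.gc_percent[0] <= gc <= c.gc_percent[1]):
            return None
        tm = tm_func(seq)
        if not (c.tm_celsius[0] <= tm <= c.tm_celsius[1]):
            return None
        return tm, gc

    # left primers: 0-based start a, length La, must end before the array
    lefts = []
    for a in range(max(0, locus.start - 1 - (pmax - (locus.end - locus.start + 1))), locus.start - 1):
        for La in range(lmin, lmax + 1):
            if a + La > locus.start - 1:
                break
            res = window_ok(template[a : a + La])
            if res is not None:
                lefts.append((a, La, *res))
    rights = []
    for b_end in range(locus.end, min(n, locus.end + (pmax - (locus.end - locus.start + 1)))):
        # b_end is 0-based index of the last base of the right binding site
        for Lb in range(lmin, lmax + 1):
            b = b_end - Lb + 1
            if b < locus.end:  # binding site must start after the array
                continue
            seg = template[b : b + Lb]
            res = window_ok(reverse_complement(seg))
            if res is not None:
                rights.append((b, Lb, *res))

    mid = (pmin + pmax) / 2.0
    pairs: List[PrimerPair] = []
    for a, La, tml, gcl in lefts:
        for b, Lb, tmr, gcr in rights:
            product = (b + Lb) - a
            if not (pmin <= product <= pmax):
                continue
            if abs(tml - tmr) > c.max_tm_diff:
                continue
            pairs.append(
                PrimerPair(
                    left_seq=template[a : a + La],
                    right_seq=reverse_complement(template[b : b + Lb]),
                    left_start=a + 1,
                    right_start=b + 1,
                    product_bp=product,
                    left_tm=tml,
                    right_tm=tmr,
                    left_gc=gcl,
                    right_gc=gcr,
                )
            )
    pairs.sort(
        key=lambda p: (
            abs(p.left_tm - p.right_tm),
            abs(p.product_bp - mid),
            p.left_start,
            p.right_start,
        )
    )
    return pairs[:max_candidates]
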