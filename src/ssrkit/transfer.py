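"""In-silico PCR and cross-species marker transferability.

A primer pair "transfers" to another genome when both primers find
convergently oriented, ungapped binding sites under mismatch rules modelled
on wet-lab primer tolerance: mismatches are allowed only in the 5' part of
each primer (up to ``max_5prime_mismatches``), the 3' terminus (a fixed
``three_prime_anchor_bp`` window) must match perfectly, per-primer identity
must reach ``min_identity``, and the amplicon is capped at
``max_product_bp``.  Both strands of the target are searched.  Filtered,
deduplicated hits become synteny links countable per chromosome pair.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np

from .errors import ConsistencyError, ValidationError
from .mining import SSRLocus, _encode, reverse_complement
from .primers import PrimerPair


@dataclass(frozen=True)
class MatchRules:
    max_5prime_mismatches: int = 5
    three_prime_anchor_bp: int = 5
    min_identity: float = 0.90
    max_product_bp: int = 2000

    def __post_init__(self) -> None:
        if self.three_prime_anchor_bp < 1:
            raise ValidationError("3' anchor must be >= 1 bp")
        if not (0.0 < self.min_identity <= 1.0):
            raise ValidationError("min_identity must be in (0, 1]")
        if self.max_5prime_mismatches < 0:
            raise ValidationError("max_5prime_mismatches must be >= 0")


@dataclass(frozen=True)
class Amplicon:
    marker_id: str
    target_seq_id: str
    start: int  # 1-based inclusive, forward-strand coordinates
    end: int
    strand: str  # strand carrying the left primer: '+' or '-'
    product_bp: int
    left_mismatches: int
    right_mismatches: int

    @property
    def total_mismatches(self) -> int:
        return self.left_mismatches + self.right_mismatches


@dataclass(frozen=True)
class SyntenyLink:
    source_seq_id: str
    source_start: int
    source_end: int
    target_seq_id: str
    target_start: int
    target_end: int
    marker_id: str


def _primer_sites(primer: str, target_codes: np.ndarray, rules: MatchRules) -> List[Tuple[int, int]]:
    """All ungapped sites (0-based start, mismatches) where *primer* can
    anneal to the forward strand of the encoded target.

    Primer position ``len-1`` is the 3' end; the anchor is the last
    ``three_prime_anchor_bp`` primer bases.
    """
    L = len(primer)
    n = len(target_codes)
    if n < L:
        return []
    p = _encode(primer.upper())
    windows = np.lib.stride_tricks.sliding_window_view(target_codes, L)
    mm = windows != p  # non-ACGT target bases (255) always mismatch
    anchor = rules.three_prime_anchor_bp
    anchor = min(anchor, L)
    anchor_mm = mm[:, L - anchor :].any(axis=1)
    total_mm = mm.sum(axis=1)
    five_mm = total_mm - mm[:, L - anchor :].sum(axis=1)
    identity = (L - total_mm) / L
    ok = (
        ~anchor_mm
        & (five_mm <= rules.max_5prime_mismatches)
        & (identity >= rules.min_identity)
    )
    return [(int(i), int(total_mm[i])) for i in np.flatnonzero(ok)]


def epcr(
    pair: PrimerPair,
    target: str,
    target_id: str = "target",
    rules: Optional[MatchRules] = None,
    marker_id: str = "marker",
) -> List[Amplicon]:
    """Every predicted amplicon of *pair* on *target* (both strands).

    On the '+' strand the left primer anneals to the forward strand and the
    right primer to the reverse strand downstream; '-' amplicons are the
    mirror arrangement.  No placement yields an empty list, not an error.
    """
    if rules is None:
        rules = MatchRules()
    if not target:
        return []
    codes = _encode(target.upper())
    n = len(codes)
    amplicons: List[Amplicon] = []
    # forward-strand annealing sites of each primer, and of their reverse
    # complements (which mark reverse-strand annealing sites).
    left_f = _primer_sites(pair.left_seq, codes, rules)
    right_site = reverse_complement(pair.right_seq)
    # right primer anneals to the reverse strand where the forward strand
    # reads revcomp(right).  Its 3' end maps to the *leftmost* base of that
    # segment, so mismatch bookkeeping needs the primer reversed onto
    # forward coordinates: compare revcomp(right) directly but with the
    # anchor at the segment start.  Easiest correct route: scan the reverse
    # complement of the target for the right primer, then flip coordinates.
    rc_codes = _encode(reverse_complement(target))
    right_r = _primer_sites(pair.right_seq, rc_codes, rules)  # sites on '-' strand
    Lr = len(pair.right_seq)
    Ll = len(pair.left_seq)
    for i, mml in left_f:
        for j_rc, mmr in right_r:
            # right primer occupies rc coords [j_rc, j_rc+Lr) -> forward
            # coords [n - j_rc - Lr, n - j_rc)
            seg_start = n - j_rc - Lr
            end = n - j_rc  # exclusive forward end of the amplicon
            if seg_start < i + Ll:  # primers must not invert / overlap
                continue
            product = end - i
            if product > rules.max_product_bp:
                continue
            amplicons.append(
                Amplicon(marker_id, target_id, i + 1, end, "+", product, mml, mmr)
            )
    # '-' orientation: left primer on the reverse strand, right on forward.
    left_r = _primer_sites(pair.left_seq, rc_codes, rules)
    right_f = _primer_sites(pair.right_seq, codes, rules)
    for j, mmr in right_f:
        for i_rc, mml in left_r:
            seg_start = n - i_rc - Ll  # forward coords of left primer site
            end = n - i_rc
            if seg_start < j + Lr:
                continue
            product = end - j
            if product > rules.max_product_bp:
                continue
            amplicons.append(
                Amplicon(marker_id, target_id, j + 1, end, "-", product, mml, mmr)
            )
    amplicons.sort(key=lambda a: (a.start, a.end, a.strand))
    return amplicons


def build_synteny_links(
    amplicons: List[Amplicon],
    source_loci: Mapping[str, SSRLocus],
    scaffold_pattern: str = r"(?i)scaffold|contig",
) -> Tuple[List[SyntenyLink], Dict[Tuple[str, str], int]]:
    """Collapse amplicons to one link per (marker, target chromosome).

    Amplicons on targets matching ``scaffold_pattern`` are dropped, as are
    markers whose *source* locus sits on a scaffold.  Duplicates of a
    marker on one target chromosome collapse to the best hit (fewest total
    mismatches, then smallest start).  Returns sorted links plus counts per
    (source chromosome, target chromosome) pair.
    """
    pat = re.compile(scaffold_pattern)
    best: Dict[Tuple[str, str], Amplicon] = {}
    for amp in amplicons:
        if amp.marker_id not in source_loci:
            raise ConsistencyError(f"amplicon references unknown marker {amp.marker_id!r}")
        if pat.search(amp.target_seq_id):
            continue
        if pat.search(source_loci[amp.marker_id].seq_id):
            continue
        key = (amp.marker_id, amp.target_seq_id)
        cur = best.get(key)
        if cur is None or (amp.total_mismatches, amp.start) < (cur.total_mismatches, cur.start):
            best[key] = amp
    links = [
        SyntenyLink(
            source_seq_id=source_loci[m].seq_id,
            source_start=source_loci[m].start,
            source_end=source_loci[m].end,
            target_seq_id=t,
            target_start=amp.start,
            target_end=amp.end,
            marker_id=m,
        )
        for (m, t), amp in best.items()
    ]
    links.sort(key=lambda L: (L.source_seq_id, L.source_start, L.target_seq_id, L.target_start, L.marker_id))
    counts: Dict[Tuple[str, str], int] = {}
    for L in links:
        key = (L.source_seq_id, L.target_seq_id)
        counts[key] = counts.get(key, 0) + 1
    return links, counts
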