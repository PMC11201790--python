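"""Perfect microsatellite (SSR) mining and genome-wide summaries.

A simple sequence repeat is a perfect tandem array of a 1-6 bp motif.  The
miner reports every maximal perfect array whose *primitive* period is at
most six and whose repeat count reaches the per-period minimum (defaults:
ten repeats for mononucleotides, six for dinucleotides, five for tri-
through hexanucleotides).  Motifs are folded into canonical classes so that
strand and phase variants (poly-T vs poly-A, GA/TC/CT vs AG, ...) count as
one class, which is how genome-scale SSR surveys report motif composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np

from .errors import (
    DegenerateInputError,
    EmptyInputError,
    InvalidAlphabetError,
    InvalidMotifError,
    ValidationError,
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an ACGT string (case preserved as upper)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def is_primitive(motif: str) -> bool:
    """True if *motif* is not a repetition of a shorter unit.

    Uses the classic rotation trick: a string is non-primitive iff it occurs
    in its own doubling at an offset other than 0 and len.
    """
    return (motif + motif).find(motif, 1) == len(motif)


def canonical_motif(motif: str, period: Optional[int] = None) -> str:
    """Canonical class of a repeat motif.

    The class is the lexicographically smallest string among all cyclic
    rotations of the motif and all cyclic rotations of its reverse
    complement, so that phase shifts and strand flips fold together
    (T -> A, TC -> AG, ATT -> AAT).  Idempotent by construction.
    """
    motif = motif.upper()
    if not motif:
        raise InvalidMotifError("motif is empty")
    if not _VALID.issuperset(motif):
        bad = sorted(set(motif) - _VALID)
        raise InvalidAlphabetError(f"motif contains non-ACGT characters: {bad}")
    if not is_primitive(motif):
        raise InvalidMotifError(f"motif {motif!r} is a repetition of a shorter unit")
    if period is not None and period != len(motif):
        raise InvalidMotifError(f"period {period} does not match motif length {len(motif)}")
    k = len(motif)
    rc = reverse_complement(motif)
    candidates = [(s + s)[i : i + k] for s in (motif, rc) for i in range(k)]
    return min(candidates)


@dataclass(frozen=True)
class SSRLocus:
    """One perfect tandem repeat on the forward strand.

    Coordinates are 1-based inclusive; ``length == period * repeats``.
    """

    seq_id: str
    start: int
    end: int
    motif: str
    motif_class: str
    period: int
    repeats: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def __post_init__(self) -> None:
        if self.length != self.period * self.repeats:
            raise ValidationError(
                f"locus {self.seq_id}:{self.start}-{self.end}: length "
                f"{self.length} != period {self.period} x repeats {self.repeats}"
            )


@dataclass(frozen=True)
class MiningThresholds:
    """Minimum repeat count per motif period (keys exactly 1..6)."""

    min_repeats: Mapping[int, int] = field(
        default_factory=lambda: {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}
    )

    def __post_init__(self) -> None:
        if set(self.min_repeats) != {1, 2, 3, 4, 5, 6}:
            raise ValidationError("thresholds must have keys exactly 1..6")
        if any(v < 2 for v in self.min_repeats.values()):
            raise ValidationError("all minimum repeat counts must be >= 2")

    def __getitem__(self, period: int) -> int:
        return self.min_repeats[period]


@dataclass
class MiningSummary:
    """Genome-wide mining statistics (the content of an SSR survey table)."""

    counts_by_period: Dict[int, int]
    total_count: int
    total_length_bp: int
    mean_length_bp: float
    relative_abundance: float  # loci / Mb
    relative_density: float  # bp / Mb
    per_sequence_counts: Dict[str, int]
    motif_class_frequencies: Dict[Tuple[int, str], float]
    length_count_correlation: Optional[float]


def _encode(sequence: str) -> np.ndarray:
    """uint8 codes: A=0 C=1 G=2 T=3, anything else 255 (breaks arrays)."""
    table = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        table[b] = i
    for i, b in enumerate(b"acgt"):
        table[b] = i
    return table[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def find_ssrs(
    sequence: str,
    seq_id: str = "seq",
    thresholds: Optional[MiningThresholds] = None,
    skip_lowercase: bool = False,
) -> List[SSRLocus]:
    """Detect every maximal perfect SSR in *sequence*.

    An array is reported once, under its primitive period (a run of A x 12
    is one mononucleotide locus, never a dinucleotide "AA" locus).  Arrays
    never cross non-ACGT characters; lowercase (soft-masked) bases are
    treated as uppercase unless ``skip_lowercase``.  The reported span is
    the first ``period * repeats`` bases of the maximal periodic segment,
    so partial trailing repeats are trimmed.  Loci are sorted by start,
    then period.
    """
    if thresholds is None:
        thresholds = MiningThresholds()
    if not sequence:
        raise EmptyInputError("empty sequence")
    codes = _encode(sequence)
    if skip_lowercase:
        lower = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8) >= ord("a")
        codes = codes.copy()
        codes[lower] = 255
    n = len(codes)
    loci: List[SSRLocus] = []
    upper = sequence.upper()
    for period in range(1, 7):
        thr = thresholds[period]
        min_len = period * thr
        if n < min_len:
            continue
        # b[k] True where s[k] == s[k+period] and both are ACGT
        b = (codes[:-period] == codes[period:]) & (codes[:-period] != 255)
        # maximal runs of True in b
        padded = np.concatenate(([False], b, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)  # exclusive in b
        for s, e in zip(starts.tolist(), ends.tolist()):
            seg_len = (e - s) + period  # segment [s, s + seg_len) is periodic
            repeats = seg_len // period
            if repeats < thr:
                continue
            motif = upper[s : s + period]
            if not is_primitive(motif):
                continue  # reported under its primitive period instead
            loci.append(
                SSRLocus(
                    seq_id=seq_id,
                    start=s + 1,
                    end=s + period * repeats,
                    motif=motif,
                    motif_class=canonical_motif(motif),
                    period=period,
                    repeats=repeats,
                )
            )
    loci.sort(key=lambda L: (L.start, L.period))
    return loci


def mine_fasta(
    records: Iterable[Tuple[str, str]],
    thresholds: Optional[MiningThresholds] = None,
    skip_lowercase: bool = False,
) -> Tuple[List[SSRLocus], Dict[str, int]]:
    """Mine an iterable of (seq_id, sequence) pairs.

    Returns the combined locus list and a map of sequence lengths (needed
    by :func:`summarize_ssrs`).
    """
    all_loci: List[SSRLocus] = []
    lengths: Dict[str, int] = {}
    for seq_id, seq in records:
        if seq_id in lengths:
            raise ValidationError(f"duplicate sequence id {seq_id!r}")
        lengths[seq_id] = len(seq)
        if seq:
            all_loci.extend(find_ssrs(seq, seq_id, thresholds, skip_lowercase))
    return all_loci, lengths


def summarize_ssrs(
    loci: List[SSRLocus],
    sequence_lengths: Mapping[str, int],
    exclude_n: bool = False,
    n_counts: Optional[Mapping[str, int]] = None,
) -> MiningSummary:
    """Genome-wide summary of a mined locus set.

    relative_abundance = loci per Mb scanned; relative_density = SSR bp per
    Mb scanned.  The denominator includes ambiguous (N) bases by default;
    pass ``exclude_n=True`` with per-sequence N counts to remove them.  The
    length/count correlation is the Pearson r between per-sequence SSR
    count and sequence length, reported only when >= 3 sequences exist.
    """
    unknown = {L.seq_id for L in loci} - set(sequence_lengths)
    if unknown:
        raise ValidationError(f"loci on sequences missing from lengths: {sorted(unknown)}")
    genome_bp = sum(sequence_lengths.values())
    if exclude_n:
        if n_counts is None:
            raise ValidationError("exclude_n requires per-sequence N counts")
        genome_bp -= sum(n_counts.get(sid, 0) for sid in sequence_lengths)
    if genome_bp <= 0:
        raise DegenerateInputError("zero total genome length")
    mb = genome_bp / 1e6

    counts_by_period: Dict[int, int] = {p: 0 for p in range(1, 7)}
    per_seq: Dict[str, int] = {sid: 0 for sid in sequence_lengths}
    class_counts: Dict[Tuple[int, str], int] = {}
    total_len = 0
    for L in loci:
        counts_by_period[L.period] += 1
        per_seq[L.seq_id] += 1
        total_len += L.length
        key = (L.period, L.motif_class)
        class_counts[key] = class_counts.get(key, 0) + 1
    total = len(loci)
    class_freqs = {
        (p, c): v / counts_by_period[p] for (p, c), v in class_counts.items()
    }

    corr: Optional[float] = None
    if len(sequence_lengths) >= 3:
        lens = np.array([sequence_lengths[s] for s in sequence_lengths], dtype=float)
        cnts = np.array([per_seq[s] for s in sequence_lengths], dtype=float)
        if lens.std() > 0 and cnts.std() > 0:
            corr = float(np.corrcoef(lens, cnts)[0, 1])
    return MiningSummary(
        counts_by_period=counts_by_period,
        total_count=total,
        total_length_bp=total_len,
        mean_length_bp=(total_len / total) if total else 0.0,
        relative_abundance=total / mb,
        relative_density=total_len / mb,
        per_sequence_counts=per_seq,
        motif_class_frequencies=class_freqs,
        length_count_correlation=corr,
    )


def period_proportions(counts_by_period: Mapping[int, int]) -> Dict[int, float]:
    """Percent of loci in each period class (mono, di, ... hexa)."""
    total = sum(counts_by_period.values())
    if total == 0:
        raise DegenerateInputError("no loci")
    return {p: 100.0 * c / total for p, c in counts_by_period.items()}
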