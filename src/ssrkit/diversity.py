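"""Per-locus genetic-diversity statistics for co-dominant SSR markers.

For allele frequencies p_i estimated from the 2n non-missing allele copies
at a locus:

* Na — observed allele count
* Ne — effective allele number, 1 / sum(p_i^2)
* Ho — fraction of heterozygous individuals among typed individuals
* H  — Nei's gene diversity, 1 - sum(p_i^2)
* He — unbiased expected heterozygosity, (2n / (2n - 1)) * H
* I  — Shannon information index, -sum(p_i ln p_i)
* PIC — Botstein polymorphism information content,
        1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2

Markers classify as highly polymorphic (PIC >= 0.5), moderately
polymorphic (0.25 < PIC < 0.5) or low polymorphic (PIC <= 0.25), on the
unrounded PIC.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .genotypes import GenotypeMatrix

STAT_COLUMNS = ["Na", "Ne", "Ho", "He", "I", "H", "PIC"]


@dataclass(frozen=True)
class LocusSummary:
    marker: str
    Na: int
    Ne: float
    Ho: float
    He: float
    I: float
    H: float
    PIC: float
    n_typed: int


def allele_frequencies(
    calls: Sequence[Optional[Tuple[str, str]]]
) -> Tuple[Dict[str, float], int, int]:
    """(frequencies, n_typed, n_het) from one locus column."""
    counts: Dict[str, int] = {}
    n_typed = 0
    n_het = 0
    for c in calls:
        if c is None:
            continue
        n_typed += 1
        a, b = c
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
        if a != b:
            n_het += 1
    total = 2 * n_typed
    freqs = {a: k / total for a, k in counts.items()} if total else {}
    return freqs, n_typed, n_het


def pic_from_frequencies(p: np.ndarray) -> float:
    """Botstein et al. PIC: 1 - sum p^2 - sum_{i<j} 2 p_i^2 p_j^2."""
    sq = p * p
    s2 = sq.sum()
    # sum_{i<j} 2 p_i^2 p_j^2 = (sum p^2)^2 - sum p^4
    return float(1.0 - s2 - (s2 * s2 - (sq * sq).sum()))


def locus_summary(
    calls: Sequence[Optional[Tuple[str, str]]], marker: str = "locus"
) -> LocusSummary:
    """Diversity statistics for one locus (>= 2 typed individuals)."""
    freqs, n_typed, n_het = allele_frequencies(calls)
    if n_typed < 2:
        raise InsufficientDataError(
            f"{marker}: {n_typed} typed individual(s); need at least 2"
        )
    p = np.array(sorted(freqs.values(), reverse=True))
    s2 = float((p * p).sum())
    H = 1.0 - s2
    He = (2 * n_typed / (2 * n_typed - 1)) * H
    I = float(-(p * np.log(p)).sum())
    return LocusSummary(
        marker=marker,
        Na=len(p),
        Ne=1.0 / s2,
        Ho=n_het / n_typed,
        He=He,
        I=I,
        H=H,
        PIC=pic_from_frequencies(p),
        n_typed=n_typed,
    )


def classify_pic(pic: float) -> str:
    """'high' (PIC >= 0.5), 'moderate' (0.25 < PIC < 0.5) or 'low'."""
    if pic >= 0.5:
        return "high"
    if pic > 0.25:
        return "moderate"
    return "low"


def summary_table(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus statistics plus a 'Mean' row.

    Columns: Na, Ne, Ho, He, I, H, PIC, n_typed, class; indexed by marker.
    The Mean row holds arithmetic column means over loci (class empty).
    """
    rows = []
    for j, marker in enumerate(matrix.loci):
        s = locus_summary(matrix.column(j), marker)
        rows.append(
            {
                "marker": s.marker,
                "Na": s.Na,
                "Ne": s.Ne,
                "Ho": s.Ho,
                "He": s.He,
                "I": s.I,
                "H": s.H,
                "PIC": s.PIC,
                "n_typed": s.n_typed,
                "class": classify_pic(s.PIC),
            }
        )
    df = pd.DataFrame(rows).set_index("marker")
    mean = df[STAT_COLUMNS + ["n_typed"]].mean()
    df.loc["Mean"] = {**mean.to_dict(), "class": ""}
    return df


def polymorphism_class_counts(pic_values: Sequence[float]) -> Dict[str, int]:
    """Counts of high / moderate / low polymorphism classes."""
    out = {"high": 0, "moderate": 0, "low": 0}
    for v in pic_values:
        out[classify_pic(v)] += 1
    return out


def load_reference_marker_table() -> pd.DataFrame:
    """Published per-locus diversity survey of 42 polymorphic SSR markers
    genotyped on a 35-accession chayote germplasm panel (statistics at 2 dp
    as printed), indexed by marker."""
    path = resources.files("ssrkit.data").joinpath("diversity_42markers.tsv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", index_col=0)


def stats_from_table(df: pd.DataFrame) -> Dict[str, float]:
    """Aggregate a per-locus statistics table (no Mean row expected):
    summed Na, column means, max PIC and class counts."""
    classes = polymorphism_class_counts(df["PIC"])
    out = {
        "total_alleles": float(df["Na"].sum()),
        "max_PIC": float(df["PIC"].max()),
        "n_high": float(classes["high"]),
        "n_moderate": float(classes["moderate"]),
        "n_low": float(classes["low"]),
    }
    for c in STAT_COLUMNS:
        if c in df.columns:
            out[f"mean_{c}"] = float(df[c].mean())
    return out
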