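"""Diploid co-dominant genotype matrix and its TSV interchange format.

The canonical table layout is one header row of marker IDs, one row per
individual, cells like ``120/124`` (two allele labels, order-free) and
``./.`` for missing.  Allele labels are arbitrary strings per locus;
fragment sizes and letters both work.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ParseError, ValidationError

MISSING = "./."


@dataclass
class GenotypeMatrix:
    """individuals x loci diploid calls; ``calls[i][j]`` is a (a1, a2)
    tuple of allele labels or None for missing."""

    individuals: List[str]
    loci: List[str]
    calls: List[List[Optional[Tuple[str, str]]]]

    def __post_init__(self) -> None:
        n, m = len(self.individuals), len(self.loci)
        if len(set(self.individuals)) != n:
            raise ValidationError("duplicate individual IDs")
        if len(set(self.loci)) != m:
            raise ValidationError("duplicate marker IDs")
        if len(self.calls) != n or any(len(row) != m for row in self.calls):
            raise ValidationError("calls shape does not match individuals x loci")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def column(self, j: int) -> List[Optional[Tuple[str, str]]]:
        return [row[j] for row in self.calls]

    def missing_mask(self) -> np.ndarray:
        return np.array(
            [[c is None for c in row] for row in self.calls], dtype=bool
        )

    def encoded(self) -> Tuple[np.ndarray, List[List[str]]]:
        """Integer-coded alleles for numeric work.

        Returns an (n, m, 2) int array with -1 for missing copies plus the
        per-locus allele label list (code -> label), labels sorted.
        """
        n, m = self.n_individuals, self.n_loci
        codes = np.full((n, m, 2), -1, dtype=np.int64)
        allele_lists: List[List[str]] = []
        for j in range(m):
            labels = sorted({a for c in self.column(j) if c is not None for a in c})
            lut = {a: k for k, a in enumerate(labels)}
            allele_lists.append(labels)
            for i, c in enumerate(self.column(j)):
                if c is not None:
                    codes[i, j, 0] = lut[c[0]]
                    codes[i, j, 1] = lut[c[1]]
        return codes, allele_lists

    def subset_loci(self, marker_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.loci.index(m) for m in marker_ids]
        return GenotypeMatrix(
            individuals=list(self.individuals),
            loci=list(marker_ids),
            calls=[[row[j] for j in idx] for row in self.calls],
        )


def parse_call(cell: str, line: int, col: int) -> Optional[Tuple[str, str]]:
    cell = cell.strip()
    if cell == MISSING or cell in (".", "", "NA"):
        return None
    if "/" not in cell:
        raise ParseError(f"line {line}, column {col}: malformed cell {cell!r} (expected 'a/b')")
    a, b = cell.split("/", 1)
    if not a or not b or "/" in b:
        raise ParseError(f"line {line}, column {col}: malformed cell {cell!r}")
    if a == "." or b == ".":
        return None  # half-missing treated as missing
    return (a, b)


def read_genotype_table(path: str) -> GenotypeMatrix:
    """Read the genotype TSV format (see module docstring)."""
    with open(path, "rt", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty genotype table")
    header = lines[0].split("\t")
    loci = header[1:]
    if not loci:
        raise ParseError(f"{path}: header has no marker columns")
    individuals: List[str] = []
    calls: List[List[Optional[Tuple[str, str]]]] = []
    for li, ln in enumerate(lines[1:], start=2):
        fields = ln.split("\t")
        if len(fields) != len(header):
            raise ParseError(
                f"line {li}: expected {len(header)} columns, found {len(fields)}"
            )
        individuals.append(fields[0])
        calls.append([parse_call(c, li, ci + 2) for ci, c in enumerate(fields[1:])])
    if len(set(individuals)) != len(individuals):
        dup = sorted({i for i in individuals if individuals.count(i) > 1})
        raise ParseError(f"duplicate individual IDs: {dup}")
    return GenotypeMatrix(individuals, loci, calls)


def write_genotype_table(matrix: GenotypeMatrix, path: str) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("individual\t" + "\t".join(matrix.loci) + "\n")
        for ind, row in zip(matrix.individuals, matrix.calls):
            cells = [MISSING if c is None else f"{c[0]}/{c[1]}" for c in row]
            fh.write(ind + "\t" + "\t".join(cells) + "\n")
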