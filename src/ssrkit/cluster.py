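"""Germplasm clustering: band-based similarity, UPGMA, and PCoA.

Co-dominant genotypes are binarised to allele presence/absence "bands"
(one band per observed allele per locus, the way gel-based datasets are
scored), pairwise similarity is computed over bands scored in both
individuals, and 1 - similarity feeds UPGMA and principal coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .errors import InsufficientDataError, ValidationError
from .genotypes import GenotypeMatrix


@dataclass
class DistanceMatrix:
    ids: List[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValidationError("distance matrix shape does not match ids")
        if np.isnan(v).any():
            raise ValidationError("distance matrix contains NaN")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal is not zero")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)


def band_matrix(matrix: GenotypeMatrix) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    """Binarise genotypes to allele-presence bands.

    Returns (bands, scored, band_names): bands is individuals x bands 0/1,
    scored marks bands whose locus was typed in that individual (missing
    loci leave all their bands unscored for that individual).
    """
    presence: List[np.ndarray] = []
    scored: List[np.ndarray] = []
    names: List[str] = []
    n = matrix.n_individuals
    for j, marker in enumerate(matrix.loci):
        col = matrix.column(j)
        alleles = sorted({a for c in col if c is not None for a in c})
        for a in alleles:
            names.append(f"{marker}:{a}")
            pres = np.zeros(n, dtype=bool)
            sc = np.zeros(n, dtype=bool)
            for i, c in enumerate(col):
                if c is None:
                    continue
                sc[i] = True
                pres[i] = a in c
            presence.append(pres)
            scored.append(sc)
    return np.array(presence).T, np.array(scored).T, names


def similarity_matrix(
    matrix: GenotypeMatrix, method: str = "simple_matching"
) -> DistanceMatrix:
    """Pairwise band similarity, returned as distance 1 - s.

    simple matching = (a + d) / (a + b + c + d); Dice = 2a / (2a + b + c);
    Jaccard = a / (a + b + c), with a/b/c/d the usual 2x2 band-count cells
    over bands scored in both individuals.  Individuals with no scored
    bands are excluded with a warning.
    """
    if matrix.n_individuals < 2:
        raise InsufficientDataError("need at least 2 individuals")
    bands, scored, _ = band_matrix(matrix)
    keep = scored.any(axis=1)
    if not keep.all():
        dropped = [matrix.individuals[i] for i in np.flatnonzero(~keep)]
        warnings.warn(f"excluding individuals with all-missing data: {dropped}")
    ids = [ind for ind, k in zip(matrix.individuals, keep) if k]
    B = bands[keep]
    S = scored[keep]
    n = len(ids)
    sim = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = S[i] & S[j]
            tot = int(both.sum())
            if tot == 0:
                raise InsufficientDataError(
                    f"{ids[i]} and {ids[j]} share no scored bands"
                )
            bi, bj = B[i][both], B[j][both]
            a = int((bi & bj).sum())
            b = int((bi & ~bj).sum())
            c = int((~bi & bj).sum())
            d = tot - a - b - c
            if method == "simple_matching":
                s = (a + d) / tot
            elif method == "dice":
                s = 1.0 if (2 * a + b + c) == 0 else 2 * a / (2 * a + b + c)
            elif method == "jaccard":
                s = 1.0 if (a + b + c) == 0 else a / (a + b + c)
            else:
                raise ValidationError(f"unknown similarity method {method!r}")
            sim[i, j] = sim[j, i] = s
    return DistanceMatrix(ids, 1.0 - sim)


@dataclass
class UPGMANode:
    """Binary tree node; height is the ultrametric merge height."""

    height: float
    label: Optional[str] = None
    left: Optional["UPGMANode"] = None
    right: Optional["UPGMANode"] = None
    size: int = 1
    min_index: int = 0  # earliest original taxon index; fixes child order

    @property
    def is_leaf(self) -> bool:
        return self.label is not None

    def leaves(self) -> List[str]:
        if self.is_leaf:
            return [self.label]
        return self.left.leaves() + self.right.leaves()

    def newick(self, precision: int = 6) -> str:
        def fmt(node: "UPGMANode", parent_height: float) -> str:
            bl = parent_height - node.height
            if node.is_leaf:
                return f"{node.label}:{bl:.{precision}f}"
            inner = f"({fmt(node.left, node.height)},{fmt(node.right, node.height)})"
            return f"{inner}:{bl:.{precision}f}"

        if self.is_leaf:
            return f"({self.label}:0.0);"
        return (
            f"({fmt(self.left, self.height)},{fmt(self.right, self.height)});"
        )

    def cophenetic(self) -> Tuple[List[str], np.ndarray]:
        """Leaf labels and the tree-implied distance matrix (2 x height of
        the lowest common ancestor)."""
        labels = self.leaves()
        idx = {l: i for i, l in enumerate(labels)}
        n = len(labels)
        d = np.zeros((n, n))

        def walk(node: "UPGMANode") -> List[str]:
            if node.is_leaf:
                return [node.label]
            L, R = walk(node.left), walk(node.right)
            for a in L:
                for b in R:
                    d[idx[a], idx[b]] = d[idx[b], idx[a]] = 2.0 * node.height
            return L + R

        walk(self)
        return labels, d


def upgma(dist: DistanceMatrix) -> UPGMANode:
    """Unweighted pair-group (arithmetic average) agglomeration.

    The closest pair merges at height d/2; cluster-cluster distance is the
    size-weighted average (i.e. the mean over all leaf pairs).  Ties break
    on the smallest (row, column) index pair in the original label order.
    """
    n = dist.n
    if n < 2:
        raise InsufficientDataError("UPGMA needs >= 2 taxa")
    nodes: Dict[int, UPGMANode] = {
        i: UPGMANode(height=0.0, label=dist.ids[i], min_index=i) for i in range(n)
    }
    d = {
        (i, j): float(dist.values[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    active = list(range(n))
    next_id = n
    while len(active) > 1:
        (i, j) = min(
            ((a, b) for ai, a in enumerate(active) for b in active[ai + 1 :]),
            key=lambda p: (d[p], p),
        )
        h = d[(i, j)] / 2.0
        ni, nj = nodes.pop(i), nodes.pop(j)
        size_i, size_j = ni.size, nj.size
        if nj.min_index < ni.min_index:
            ni, nj = nj, ni  # child order only; weights stay keyed to i/j
        merged = UPGMANode(
            height=h, left=ni, right=nj, size=size_i + size_j,
            min_index=min(ni.min_index, nj.min_index),
        )
        active = [a for a in active if a not in (i, j)]
        for a in active:
            da = d.pop((min(a, i), max(a, i)))
            db = d.pop((min(a, j), max(a, j)))
            d[(min(a, next_id), max(a, next_id))] = (
                size_i * da + size_j * db
            ) / (size_i + size_j)
        del d[(i, j)]
        nodes[next_id] = merged
        active.append(next_id)
        next_id += 1
    return nodes[active[0]]


@dataclass
class PCoAResult:
    ids: List[str]
    coordinates: np.ndarray  # individuals x retained axes
    eigenvalues: np.ndarray  # retained (positive) eigenvalues, descending
    percent_explained: np.ndarray  # sums to 100 over retained axes


def pcoa(dist: DistanceMatrix, eps: float = 1e-10) -> PCoAResult:
    """Principal coordinates: Gower double-centering of -d^2/2, symmetric
    eigendecomposition, coordinates = eigenvectors * sqrt(eigenvalue).

    Negative eigenvalues (non-Euclidean input) are dropped from both the
    coordinates and the percent-explained denominator.
    """
    if dist.n < 3:
        raise InsufficientDataError("PCoA needs >= 3 individuals")
    D2 = dist.values**2
    n = dist.n
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > eps * max(1.0, abs(evals[0]))
    evals, evecs = evals[pos], evecs[:, pos]
    coords = evecs * np.sqrt(evals)
    pct = 100.0 * evals / evals.sum() if evals.size else evals
    return PCoAResult(list(dist.ids), coords, evals, pct)
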