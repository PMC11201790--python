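"""Marker-trait association by GLM and MLM scans.

GLM: for each marker, ordinary least squares of the trait on
genotype-class indicators plus optional structure covariates (K-1 columns
of a Q matrix) and an intercept; the marker block is tested by a partial
F-test and its contribution reported as PVE = 100 (RSS_reduced -
RSS_full) / TSS.

MLM: adds a polygenic random effect u with cov(u) = sigma_g^2 * 2K for an
identity-by-state kinship K.  The variance ratio delta = sigma_g^2 /
sigma_e^2 is estimated by REML through a one-dimensional optimisation on
the eigen-spectrum of 2K (computed once and reused for every marker,
EMMA-style); marker effects are then tested by a partial F-test on the
generalised-least-squares fit, with PVE from the GLS sums of squares.
With kinship = I the GLS rotation is orthogonal and the MLM scan equals
the GLM scan exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import InsufficientDataError, ValidationError
from .genotypes import GenotypeMatrix


@dataclass
class TraitVector:
    individuals: List[str]
    values: np.ndarray
    name: str = "trait"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.individuals) != len(self.values):
            raise ValidationError("trait IDs and values differ in length")
        if np.ptp(self.values) == 0:
            raise ValidationError(f"trait {self.name!r} is constant")

    def aligned_to(self, ids: Sequence[str]) -> np.ndarray:
        lut = {i: v for i, v in zip(self.individuals, self.values)}
        missing = [i for i in ids if i not in lut]
        if missing:
            raise ValidationError(f"trait {self.name!r} missing individuals: {missing}")
        return np.array([lut[i] for i in ids])


# Default ordinal encodings for the fruit traits; configurable at the call
# sites that parse trait tables.
PEEL_COLOR_CODES = {"white": 0, "light green": 1, "green": 2, "dark green": 3}
SPINE_CODES = {"none": 0, "very low": 1}


@dataclass(frozen=True)
class AssociationResult:
    marker: str
    model: str  # "GLM" | "MLM"
    p_value: float
    pve: float  # percent
    effects: Dict[str, float]
    df_marker: int


def ibs_kinship(matrix: GenotypeMatrix) -> np.ndarray:
    """Identity-by-state allele-sharing kinship.

    Pairwise mean over jointly typed loci of: 1 for an identical unordered
    genotype, 0.5 for one shared allele, 0 otherwise.  Diagonal is 1.
    """
    n, m = matrix.n_individuals, matrix.n_loci
    K = np.eye(n)
    cols = [matrix.column(j) for j in range(m)]
    for i in range(n):
        for j in range(i + 1, n):
            score = 0.0
            typed = 0
            for col in cols:
                a, b = col[i], col[j]
                if a is None or b is None:
                    continue
                typed += 1
                if sorted(a) == sorted(b):
                    score += 1.0
                elif set(a) & set(b):
                    score += 0.5
            if typed < 2:
                raise InsufficientDataError(
                    f"{matrix.individuals[i]} / {matrix.individuals[j]}: "
                    f"fewer than 2 jointly typed loci"
                )
            K[i, j] = K[j, i] = score / typed
    return K


def bend_psd(K: np.ndarray, floor: float = 0.0) -> np.ndarray:
    """Clip negative eigenvalues to *floor* (standard bending)."""
    w, v = np.linalg.eigh((K + K.T) / 2.0)
    if w.min() >= floor:
        return K
    w = np.maximum(w, floor)
    return (v * w) @ v.T


def marker_design(
    calls: Sequence[Optional[Tuple[str, str]]], coding: str = "genotype"
) -> Tuple[Optional[np.ndarray], np.ndarray, List[str]]:
    """Design columns for one marker.

    ``genotype`` coding: one indicator per observed genotype class minus a
    reference (multi-allelic safe, Tassel-like).  ``dosage``: one column
    counting copies of the minor allele (biallelic loci only).  Returns
    (X_marker | None, typed mask, column names); None when the marker has
    a single class (no testable contrast).
    """
    typed = np.array([c is not None for c in calls])
    if coding == "genotype":
        classes = sorted({tuple(sorted(c)) for c in calls if c is not None})
        if len(classes) < 2:
            return None, typed, []
        ref = classes[0]
        cols, names = [], []
        for g in classes[1:]:
            cols.append(
                np.array(
                    [1.0 if (c is not None and tuple(sorted(c)) == g) else 0.0 for c in calls]
                )
            )
            names.append("/".join(g))
        return np.column_stack(cols), typed, names
    if coding == "dosage":
        alleles = sorted({a for c in calls if c is not None for a in c})
        if len(alleles) != 2:
            raise ValidationError("dosage coding requires a biallelic locus")
        minor = alleles[1]
        col = np.array(
            [float(c.count(minor)) if c is not None else 0.0 for c in calls]
        )
        if len(np.unique(col[typed])) < 2:
            return None, typed, []
        return col[:, None], typed, [f"dosage({minor})"]
    raise ValidationError(f"unknown marker coding {coding!r}")


def _partial_f(
    y: np.ndarray, X_full: np.ndarray, X_red: np.ndarray
) -> Tuple[float, float, float]:
    """(p, PVE%, F) for the block X_full \\ X_red by partial F-test (OLS)."""
    n = len(y)
    q = X_full.shape[1] - X_red.shape[1]
    df_full = n - np.linalg.matrix_rank(X_full)
    if df_full <= 0 or q <= 0:
        return np.nan, np.nan, np.nan
    rss_full = float(np.sum((y - X_full @ np.linalg.lstsq(X_full, y, rcond=None)[0]) ** 2))
    rss_red = float(np.sum((y - X_red @ np.linalg.lstsq(X_red, y, rcond=None)[0]) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    if rss_full <= 0:
        return 0.0, 100.0 * (rss_red - rss_full) / tss, np.inf
    F = ((rss_red - rss_full) / q) / (rss_full / df_full)
    p = float(stats.f.sf(F, q, df_full))
    pve = 100.0 * max(0.0, rss_red - rss_full) / tss if tss > 0 else np.nan
    return p, min(pve, 100.0), F


def glm_scan(
    matrix: GenotypeMatrix,
    trait: TraitVector,
    Q: Optional[np.ndarray] = None,
    coding: str = "genotype",
) -> List[AssociationResult]:
    """Per-marker GLM association (fixed effects only).

    Q, if given, is an individuals x K membership matrix; its first K-1
    columns enter as covariates (rows sum to one, so one column is
    redundant with the intercept).  Individuals untyped at a marker are
    dropped for that marker.
    """
    y_all = trait.aligned_to(matrix.individuals)
    n = matrix.n_individuals
    covar = np.empty((n, 0))
    if Q is not None:
        Q = np.asarray(Q, dtype=float)
        if Q.shape[0] != n:
            raise ValidationError("Q rows do not match individuals")
        covar = Q[:, :-1] if Q.shape[1] > 1 else np.empty((n, 0))
    results: List[AssociationResult] = []
    for j, marker in enumerate(matrix.loci):
        Xm, typed, names = marker_design(matrix.column(j), coding)
        if Xm is None:
            warnings.warn(f"{marker}: single genotype class, skipped")
            continue
        y = y_all[typed]
        if len(y) <= 1 + covar.shape[1] + Xm.shape[1]:
            warnings.warn(f"{marker}: too few typed individuals, skipped")
            continue
        base = np.column_stack([np.ones(typed.sum()), covar[typed]])
        X_full = np.column_stack([base, Xm[typed]])
        if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
            # drop linearly dependent marker columns; skip if none survive
            keep = _independent_columns(base, Xm[typed])
            if not keep:
                warnings.warn(f"{marker}: marker coding rank-deficient, skipped")
                continue
            Xm_t = Xm[typed][:, keep]
            names = [names[k] for k in keep]
            X_full = np.column_stack([base, Xm_t])
        p, pve, _ = _partial_f(y, X_full, base)
        beta = np.linalg.lstsq(X_full, y, rcond=None)[0]
        eff = dict(zip(names, map(float, beta[base.shape[1]:])))
        results.append(
            AssociationResult(marker, "GLM", p, pve, eff, X_full.shape[1] - base.shape[1])
        )
    return results


def _independent_columns(base: np.ndarray, Xm: np.ndarray) -> List[int]:
    keep: List[int] = []
    cur = base
    for k in range(Xm.shape[1]):
        cand = np.column_stack([cur, Xm[:, k]])
        if np.linalg.matrix_rank(cand) > np.linalg.matrix_rank(cur):
            keep.append(k)
            cur = cand
    return keep


def _reml_delta(y: np.ndarray, X: np.ndarray, d: np.ndarray) -> float:
    """REML estimate of delta = sigma_g^2/sigma_e^2 on the rotated model
    with eigenvalues d of 2K (cov = sigma_e^2 (delta D + I))."""
    n, p = X.shape

    def neg_reml(log_delta: float) -> float:
        w = np.exp(log_delta) * d + 1.0
        Xw = X / w[:, None]
        XtWX = X.T @ Xw
        try:
            beta = np.linalg.solve(XtWX, Xw.T @ y)
        except np.linalg.LinAlgError:
            return np.inf
        r = y - X @ beta
        rss = float(np.sum(r * r / w))
        if rss <= 0:
            return np.inf
        sign, logdet_xtwx = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return np.inf
        return 0.5 * (
            (n - p) * np.log(rss / (n - p)) + np.sum(np.log(w)) + logdet_xtwx
        )

    res = optimize.minimize_scalar(neg_reml, bounds=(-12.0, 12.0), method="bounded")
    return float(np.exp(res.x))


def mlm_scan(
    matrix: GenotypeMatrix,
    trait: TraitVector,
    Q: Optional[np.ndarray] = None,
    kinship: Optional[np.ndarray] = None,
    coding: str = "genotype",
) -> List[AssociationResult]:
    """Per-marker mixed-linear-model association.

    The kinship eigendecomposition is computed once and reused; for each
    marker the variance ratio is re-estimated by REML under the full model
    and the marker block tested by an F-test on the whitened (GLS) fit.
    Individuals untyped at a marker are dropped for that marker; since
    dropping rows breaks the shared rotation, such markers trigger an
    eigendecomposition of the typed submatrix (nothing is imputed).
    """
    if kinship is None:
        kinship = ibs_kinship(matrix)
    n = matrix.n_individuals
    kinship = np.asarray(kinship, dtype=float)
    if kinship.shape != (n, n):
        raise ValidationError("kinship shape does not match individuals")
    S = bend_psd(2.0 * kinship)
    w_all, U_all = np.linalg.eigh(S)
    if w_all.min() < -1e-8:
        raise ValidationError("kinship not PSD after bending")
    w_all = np.maximum(w_all, 0.0)
    y_all = trait.aligned_to(matrix.individuals)
    covar = np.empty((n, 0))
    if Q is not None:
        Q = np.asarray(Q, dtype=float)
        covar = Q[:, :-1] if Q.shape[1] > 1 else np.empty((n, 0))
    results: List[AssociationResult] = []
    for j, marker in enumerate(matrix.loci):
        Xm, typed, names = marker_design(matrix.column(j), coding)
        if Xm is None:
            warnings.warn(f"{marker}: single genotype class, skipped")
            continue
        if typed.all():
            d, U = w_all, U_all
            idx = np.arange(n)
        else:
            # missing individuals: eigendecompose the typed submatrix
            idx = np.flatnonzero(typed)
            d, U = np.linalg.eigh(S[np.ix_(idx, idx)])
            d = np.maximum(d, 0.0)
        y = U.T @ y_all[idx]
        base = np.column_stack([np.ones(len(idx)), covar[idx]])
        Xm_t = Xm[idx]
        full_raw = np.column_stack([base, Xm_t])
        if np.linalg.matrix_rank(full_raw) < full_raw.shape[1]:
            keep = _independent_columns(base, Xm_t)
            if not keep:
                warnings.warn(f"{marker}: marker coding rank-deficient, skipped")
                continue
            Xm_t = Xm_t[:, keep]
            names = [names[k] for k in keep]
        Xf = U.T @ np.column_stack([base, Xm_t])
        Xr = U.T @ base
        if len(y) <= Xf.shape[1]:
            warnings.warn(f"{marker}: too few typed individuals, skipped")
            continue
        delta = _reml_delta(y, Xf, d)
        wts = delta * d + 1.0
        sw = np.sqrt(wts)
        yw, Xfw, Xrw = y / sw, Xf / sw[:, None], Xr / sw[:, None]
        p, pve, _ = _partial_f_weighted(yw, Xfw, Xrw)
        beta = np.linalg.lstsq(Xfw, yw, rcond=None)[0]
        eff = dict(zip(names, map(float, beta[Xr.shape[1]:])))
        results.append(
            AssociationResult(marker, "MLM", p, pve, eff, Xf.shape[1] - Xr.shape[1])
        )
    return results


def _partial_f_weighted(
    yw: np.ndarray, Xfw: np.ndarray, Xrw: np.ndarray
) -> Tuple[float, float, float]:
    """Partial F on pre-whitened (rotated + scaled) data; PVE from the GLS
    sums of squares around the whitened intercept-only fit (the intercept
    is the first column of the reduced design)."""
    n = len(yw)
    q = Xfw.shape[1] - Xrw.shape[1]
    df_full = n - np.linalg.matrix_rank(Xfw)
    if df_full <= 0 or q <= 0:
        return np.nan, np.nan, np.nan
    rss_full = float(np.sum((yw - Xfw @ np.linalg.lstsq(Xfw, yw, rcond=None)[0]) ** 2))
    rss_red = float(np.sum((yw - Xrw @ np.linalg.lstsq(Xrw, yw, rcond=None)[0]) ** 2))
    icol = Xrw[:, :1]
    rss_mean = float(np.sum((yw - icol @ np.linalg.lstsq(icol, yw, rcond=None)[0]) ** 2))
    if rss_full <= 0:
        return 0.0, 100.0, np.inf
    F = ((rss_red - rss_full) / q) / (rss_full / df_full)
    p = float(stats.f.sf(F, q, df_full))
    pve = 100.0 * max(0.0, rss_red - rss_full) / rss_mean if rss_mean > 0 else np.nan
    return p, min(pve, 100.0), F


class AssociationScan:
    """Model-object front end over :func:`glm_scan` / :func:`mlm_scan`.

    ``AssociationScan(matrix, trait, Q=..., kinship=...).fit(model="both")``
    returns an :class:`AssociationScanResults` whose ``summary()`` is the
    trait/model/marker/p/PVE table.
    """

    def __init__(
        self,
        matrix: GenotypeMatrix,
        trait: TraitVector,
        Q: Optional[np.ndarray] = None,
        kinship: Optional[np.ndarray] = None,
        coding: str = "genotype",
    ):
        self.matrix = matrix
        self.trait = trait
        self.Q = Q
        self.kinship = kinship
        self.coding = coding

    def fit(self, model: str = "both") -> "AssociationScanResults":
        results: List[AssociationResult] = []
        if model in ("GLM", "both"):
            results += glm_scan(self.matrix, self.trait, self.Q, self.coding)
        if model in ("MLM", "both"):
            results += mlm_scan(self.matrix, self.trait, self.Q, self.kinship, self.coding)
        if model not in ("GLM", "MLM", "both"):
            raise ValidationError(f"unknown model {model!r}")
        return AssociationScanResults(self.trait.name, results)


@dataclass
class AssociationScanResults:
    trait_name: str
    results: List[AssociationResult]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "trait": self.trait_name,
                    "model": r.model,
                    "marker": r.marker,
                    "p_value": r.p_value,
                    "PVE_percent": r.pve,
                }
                for r in self.results
            ]
        )

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        df = self.summary()
        return df[df["p_value"] < alpha].sort_values("p_value")
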