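"""Synthetic inputs with known truth for every pipeline stage.

Three generators, all bit-reproducible under (spec, seed):

* genomes — i.i.d. background at a chosen GC content with perfect SSR
  arrays planted at known coordinates (truth table included), emulating a
  chromosome-scale assembly at desk scale;
* structured diploid genotypes — individuals drawn from K ancestral
  populations under the admixture model (Q ~ Dirichlet(alpha); allele
  copies from population frequency vectors, optionally drifted from shared
  ancestral frequencies by a Balding-Nichols divergence parameter F), with
  an i.i.d. missing-data mask; emulates a small germplasm panel such as a
  few dozen accessions typed at a few dozen SSR loci with two source
  populations;
* phenotypes — a linear marker-effect model with Gaussian noise scaled to
  a target heritability, with the realised per-marker variance shares
  recorded as truth.

Background sequence is i.i.d., so spurious SSRs can and do occur; miner
tests score planted-locus recovery, not absence of extra finds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import PlacementError, ValidationError
from .genotypes import GenotypeMatrix
from .mining import SSRLocus, canonical_motif, is_primitive
from .association import TraitVector

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedLocus:
    seq_id: str
    position: int  # 1-based start
    motif: str
    repeats: int


@dataclass
class GenomeSpec:
    sequence_lengths: Dict[str, int]
    gc: float = 0.38
    planted: List[PlantedLocus] = field(default_factory=list)
    scaffold_ids: List[str] = field(default_factory=list)
    min_separation: int = 50

    def __post_init__(self) -> None:
        if not (0.0 < self.gc < 1.0):
            raise ValidationError("GC fraction must be in (0, 1)")
        for pl in self.planted:
            if pl.seq_id not in self.sequence_lengths:
                raise ValidationError(f"planted locus on unknown sequence {pl.seq_id!r}")
            if not is_primitive(pl.motif.upper()):
                raise ValidationError(f"planted motif {pl.motif!r} is not primitive")
        # pairwise separation check per sequence
        by_seq: Dict[str, List[Tuple[int, int]]] = {}
        for pl in self.planted:
            ln = len(pl.motif) * pl.repeats
            end = pl.position + ln - 1
            if pl.position < 2 or end >= self.sequence_lengths[pl.seq_id]:
                raise PlacementError(
                    f"{pl.seq_id}:{pl.position}: planted array must leave >= 1 bp flanks"
                )
            by_seq.setdefault(pl.seq_id, []).append((pl.position, end))
        for sid, spans in by_seq.items():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                if s2 - e1 - 1 < self.min_separation:
                    raise PlacementError(
                        f"planted loci on {sid} closer than {self.min_separation} bp"
                    )


def _background(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p)


def generate_genome(
    spec: GenomeSpec, seed: int = 0
) -> Tuple[Dict[str, str], List[SSRLocus]]:
    """Sequences plus the truth locus table for every planted array.

    Flanking bases that would extend a planted array (making the mined
    locus longer than planted, hence shifting its coordinates) are
    resampled, so planted loci are maximal by construction.
    """
    rng = np.random.default_rng(seed)
    base_idx = {b: i for i, b in enumerate("ACGT")}
    sequences: Dict[str, str] = {}
    truth: List[SSRLocus] = []
    for sid in spec.sequence_lengths:
        n = spec.sequence_lengths[sid]
        arr = _background(rng, n, spec.gc)
        for pl in spec.planted:
            if pl.seq_id != sid:
                continue
            motif = pl.motif.upper()
            p = len(motif)
            s0 = pl.position - 1  # 0-based
            array = np.array([base_idx[c] for c in motif * pl.repeats])
            arr[s0 : s0 + len(array)] = array
            # left flank base must not extend the period-p array...
            if s0 >= 1:
                while arr[s0 - 1] == arr[s0 + p - 1]:
                    arr[s0 - 1] = rng.integers(0, 4)
            # ...nor may it extend a mononucleotide run into the array
            end0 = s0 + len(array) - 1
            if end0 + 1 < n:
                while arr[end0 + 1] == arr[end0 + 1 - p]:
                    arr[end0 + 1] = rng.integers(0, 4)
            truth.append(
                SSRLocus(
                    seq_id=sid,
                    start=pl.position,
                    end=pl.position + p * pl.repeats - 1,
                    motif=motif,
                    motif_class=canonical_motif(motif),
                    period=p,
                    repeats=pl.repeats,
                )
            )
        sequences[sid] = "".join(_BASES[arr])
    truth.sort(key=lambda L: (L.seq_id, L.start))
    return sequences, truth


@dataclass
class PopulationSpec:
    """Structured-panel design.  Defaults mirror a small two-population
    germplasm collection: 35 diploid individuals typed at 42 SSR loci."""

    K: int = 2
    n_individuals: int = 35
    n_loci: int = 42
    n_alleles: int = 4
    alpha: float = 0.2
    divergence_F: float = 0.15
    allele_freqs: Optional[List[np.ndarray]] = None  # per locus: K x alleles
    missing_rate: float = 0.02
    individual_prefix: str = "ind"
    locus_prefix: str = "SSR"

    def __post_init__(self) -> None:
        if self.K < 1 or self.n_individuals < 1 or self.n_loci < 1:
            raise ValidationError("K, n_individuals, n_loci must be positive")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValidationError("missing rate must be in [0, 1)")
        if self.alpha <= 0:
            raise ValidationError("alpha must be positive")
        if not (0.0 < self.divergence_F < 1.0) and self.allele_freqs is None:
            raise ValidationError("divergence_F must be in (0, 1)")
        if self.allele_freqs is not None:
            for j, fr in enumerate(self.allele_freqs):
                fr = np.asarray(fr, dtype=float)
                if fr.shape[0] != self.K or np.any(fr <= 0) or not np.allclose(fr.sum(axis=1), 1.0):
                    raise ValidationError(f"locus {j}: invalid frequency matrix")


def _drift_frequencies(
    rng: np.random.Generator, spec: PopulationSpec
) -> List[np.ndarray]:
    """Balding-Nichols drift: per population, Dirichlet around shared
    ancestral frequencies with concentration (1-F)/F."""
    freqs = []
    conc = (1.0 - spec.divergence_F) / spec.divergence_F
    for _ in range(spec.n_loci):
        anc = rng.dirichlet(np.full(spec.n_alleles, 2.0))
        anc = np.clip(anc, 1e-3, None)
        anc /= anc.sum()
        fr = rng.dirichlet(anc * conc, size=spec.K)
        fr = np.clip(fr, 1e-6, None)
        fr /= fr.sum(axis=1, keepdims=True)
        freqs.append(fr)
    return freqs


def generate_structured_genotypes(
    spec: PopulationSpec, seed: int = 0
) -> Tuple[GenotypeMatrix, np.ndarray]:
    """Genotype matrix plus the true Q (individuals x K).

    Each individual's Q row ~ Dirichlet(alpha); each allele copy picks a
    source population from Q, then an allele from that population's
    frequency vector; missing cells i.i.d. at ``missing_rate``.
    """
    rng = np.random.default_rng(seed)
    freqs = (
        [np.asarray(f, dtype=float) for f in spec.allele_freqs]
        if spec.allele_freqs is not None
        else _drift_frequencies(rng, spec)
    )
    n, m, K = spec.n_individuals, spec.n_loci, spec.K
    Q = rng.dirichlet(np.full(K, spec.alpha), size=n)
    individuals = [f"{spec.individual_prefix}{i+1:03d}" for i in range(n)]
    loci = [f"{spec.locus_prefix}{j+1:03d}" for j in range(m)]
    calls: List[List[Optional[Tuple[str, str]]]] = []
    for i in range(n):
        row: List[Optional[Tuple[str, str]]] = []
        for j in range(m):
            if rng.random() < spec.missing_rate:
                row.append(None)
                continue
            pair = []
            for _ in range(2):
                k = rng.choice(K, p=Q[i])
                a = rng.choice(freqs[j].shape[1], p=freqs[j][k])
                pair.append(str(100 + 2 * a))  # fragment-size style labels
            row.append((pair[0], pair[1]))
        calls.append(row)
    return GenotypeMatrix(individuals, loci, calls), Q


@dataclass
class PhenotypeSpec:
    causal_effects: Dict[str, float]  # marker id -> additive effect
    heritability: float = 0.5  # 1.0 means a noise-free trait
    trait_name: str = "trait"

    def __post_init__(self) -> None:
        if not (0.0 <= self.heritability <= 1.0):
            raise ValidationError("heritability must be in [0, 1]")
        if not self.causal_effects:
            raise ValidationError("at least one causal marker required")


def _genotype_code(call: Optional[Tuple[str, str]], alleles: List[str]) -> float:
    """Additive code: count of the reference (largest-label) allele;
    missing -> locus mean handled by caller."""
    if call is None:
        return np.nan
    ref = alleles[-1]
    return float(call[0] == ref) + float(call[1] == ref)


def generate_phenotype(
    matrix: GenotypeMatrix, spec: PhenotypeSpec, seed: int = 0
) -> Tuple[TraitVector, Dict[str, float]]:
    """Phenotype = sum(effect x genotype code) + Gaussian noise scaled so
    the genetic share of variance equals the target heritability.

    Returns the trait plus truth: realised per-marker PVE (percent) and
    the realised heritability under key ``_heritability``.
    """
    rng = np.random.default_rng(seed)
    missing_loci = [m for m in spec.causal_effects if m not in matrix.loci]
    if missing_loci:
        raise ValidationError(f"causal markers not in matrix: {missing_loci}")
    n = matrix.n_individuals
    g = np.zeros(n)
    parts: Dict[str, np.ndarray] = {}
    for marker, eff in spec.causal_effects.items():
        j = matrix.loci.index(marker)
        col = matrix.column(j)
        alleles = sorted({a for c in col if c is not None for a in c})
        codes = np.array([_genotype_code(c, alleles) for c in col])
        codes = np.where(np.isnan(codes), np.nanmean(codes), codes)
        part = eff * codes
        parts[marker] = part
        g = g + part
    var_g = float(g.var())
    h2 = spec.heritability
    if var_g == 0:
        if h2 > 0:
            raise ValidationError("zero genetic variance with nonzero target heritability")
        noise_var = 1.0
    elif h2 == 0:
        noise_var = var_g * 1e6
    else:
        noise_var = var_g * (1.0 - h2) / h2
    e = rng.normal(0.0, np.sqrt(noise_var), size=n) if noise_var > 0 else np.zeros(n)
    y = g + e
    var_y = float(y.var())
    # realised PVE: variance removed by subtracting the marker's true
    # contribution, so the in-sample covariance between genetic part and
    # noise draw is accounted for (what an unbiased scan should estimate)
    truth = {
        m: 100.0 * (var_y - float((y - p).var())) / var_y for m, p in parts.items()
    }
    truth["_heritability"] = (var_y - float(e.var())) / var_y if var_y > 0 else 0.0
    return TraitVector(list(matrix.individuals), y, spec.trait_name), truth
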