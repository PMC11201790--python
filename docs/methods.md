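# Methods

This note documents the models and procedures `ssrkit` implements, the
parameters that matter, the conventions chosen where several defensible
options existed, and what the synthetic-data generators do and do not
emulate.

## SSR mining

A locus is a maximal perfect tandem array whose *primitive* period is
1–6 bp and whose repeat count reaches the per-period minimum
(`MiningThresholds`, default 10/6/5/5/5/5 for mono- through
hexanucleotides — the standard settings for genome-wide SSR surveys in
cucurbits). Conventions:

* **Primitive-period assignment.** An array is classified by its smallest
  period: a run of A×12 is one mononucleotide locus and is never
  re-described as an "AA" dinucleotide. This keeps per-period counts
  disjoint. Overlapping maximal arrays of *different* primitive periods
  (a poly-A run abutting an AT array) are both reported; there is no
  compound/interrupted-SSR merging.
* **Trimming.** The reported span is the first `period × repeats` bases of
  the maximal periodic segment, so a dangling partial repeat is excluded
  and `length = period × repeats` always holds.
* **Canonical motif class.** The lexicographically smallest string among
  all cyclic rotations of the motif and of its reverse complement. This
  folds strand and phase (T→A, TC/GA/CT→AG, ATT→AAT) and reproduces the
  folded classes conventionally reported (A, AT, AG, AAT, AAAT, …).
* **Non-ACGT and case.** Arrays never extend across non-ACGT characters.
  Soft-masked (lowercase) bases count as their uppercase equivalents by
  default; `skip_lowercase=True` treats them as breaks.
* **Summary denominators.** Relative abundance (loci/Mb) and density
  (bp/Mb) divide by total scanned length including N bases by default;
  `exclude_n=True` with per-sequence N counts removes them. Published
  abundance figures are sometimes internally inconsistent about this
  denominator, which is why both are exposed. The per-sequence
  count-vs-length Pearson r is reported only when ≥ 3 sequences exist.

The miner is validated against an independent quadratic brute-force
scanner (every start × period × extension) on random sequences, by a
strand-symmetry property, and by planted-locus recovery.

## Primer design

All windows in the flanks are enumerated under the classic
marker-development constraint set (product 100–250 bp containing the
array, primer 18–24 nt, Tm 50–60 °C, GC 40–60 %, pair Tm difference
≤ 3 °C). Melting temperature uses the Wallace rule `2(A+T) + 4(G+C)`
below 14 nt and `64.9 + 41(GC − 16.4)/len` otherwise; the Tm function is
an injectable parameter so a nearest-neighbour model can be substituted.
The published 50–60 °C "annealing temperature" window is treated as a Tm
window. Candidates are ranked by |ΔTm|, then closeness of the product to
the middle of the allowed range, then coordinates — a stated tie-break so
output is reproducible. No dimer/hairpin screening is performed.

## In-silico PCR and transferability

A primer binds where an ungapped alignment has (i) zero mismatches inside
a fixed-length 3′ anchor (default 5 bp — "no mismatches at the 3′ end"
needs an anchor length, and 5 bp is the conventional choice), (ii) at
most 5 mismatches elsewhere, and (iii) per-primer identity ≥ 90 %.
Identity is computed per primer over its full length — the stricter
reading of a pair-level homology threshold. Amplicons require convergent
orientation and product ≤ 2,000 bp (an explicit cap, since cross-species
placements otherwise have no size limit); both target strands are
searched. This replaces a BLAST pre-screen entirely: the decisive filters
are the mismatch/anchor/identity rules, which are exactly implementable
without an aligner. Gapped binding sites are therefore invisible — a
known limitation relative to BLAST-based protocols.

Synteny links drop amplicons on scaffold-matching sequence IDs (pattern
configurable, default `scaffold|contig`, case-insensitive) on either end,
and collapse multiple placements of one marker on one target chromosome
to the best hit (fewest total mismatches, then smallest start).

## Diversity statistics

With allele frequencies `p_i` from the `2n` non-missing copies at a
locus: `Na` (allele count), `Ne = 1/Σp²`, `Ho` (observed heterozygote
fraction), Nei's `H = 1 − Σp²`, unbiased `He = (2n/(2n−1)) H`, Shannon
`I = −Σ p ln p`, and Botstein `PIC = 1 − Σpᵢ² − Σ_{i<j} 2pᵢ²pⱼ²`
(computed via `(Σp²)² − Σp⁴`). Missing data are excluded per locus
(pairwise-complete); a locus needs ≥ 2 typed individuals. Classification:
high `PIC ≥ 0.5`, moderate `0.25 < PIC < 0.5`, low `PIC ≤ 0.25`, decided
on unrounded values (display rounding is 2 dp). The identities
`Ne = 1/(1−H)` and `PIC ≤ H ≤ I` are enforced by property tests.

A packaged reference table (`ssrkit.diversity.load_reference_marker_table`)
carries a published 42-marker survey of a 35-accession chayote panel
(2 dp, as printed) and is used as *input* for aggregate checks. Note that
in that published table every row satisfies He = 1 − Ho exactly, which no
standard He estimator produces; `ssrkit` implements the standard unbiased
estimator and does not imitate that artefact, so only the Na/Ne/Ho/PIC
columns and the classification are checked against it.

## Clustering

Genotypes are binarised to allele presence/absence "bands" (one band per
observed allele per locus — the encoding gel-scored SSR datasets use), and
pairwise similarity is computed over bands whose locus is typed in both
individuals: simple matching `(a+d)/n` (the default, matching common
NTSYS practice for band data), Dice `2a/(2a+b+c)` or Jaccard `a/(a+b+c)`.
Distance is `1 − s`.

UPGMA merges the closest pair at height `d/2` with size-weighted
(leaf-pair mean) cluster distances; ties break on the smallest
(row, column) index pair in input order, and children are ordered by the
earliest original taxon so Newick output is deterministic (branch lengths
are height differences, 6 dp). Output is cross-checked against SciPy
average linkage on tie-free inputs and reproduces ultrametric inputs
exactly.

PCoA applies Gower double-centering to `−d²/2`, takes a symmetric
eigendecomposition, and scales eigenvectors by √eigenvalue. Negative
eigenvalues (non-Euclidean inputs) are dropped from both the coordinates
and the percent-explained denominator — the simplest defensible
convention; no Cailliez correction is applied. Agreement with
scikit-bio's PCoA is verified in tests.

## Admixture model

The classic admixture model with independent allele frequencies:
`Q_i ~ Dirichlet(α·1_K)` per individual, `P_{k,l} ~ Dirichlet(λ·1)` per
population × locus, and each allele copy drawn by first choosing an
origin population from `Q_i`, then an allele from `P`. The Gibbs sweep
alternates origins `Z | P,Q` (vectorised Gumbel-max categorical
sampling), `P | Z` and `Q | Z` (Dirichlet-gamma draws). Missing copies
are skipped, not imputed. α is fixed (default 1.0); the correlated-
frequencies prior and α-sampling are not implemented.

`lnP(D)` is estimated as `mean(lnL) − var(lnL)/2` over the post-burn-in
likelihood trace — the estimator the Evanno/Harvester model-choice
procedure relies on. `ΔK = mean|L(K+1) − 2L(K) + L(K−1)| / sd(L(K))`,
with the second difference computed per replicate before averaging; ΔK is
defined only for interior K with positive replicate sd, and a flat ΔK
profile is flagged. Identical seed + config gives bitwise-identical
results.

Defaults are desk-scale: burn-in 1,000, 10,000 kept sweeps, 10
replicates, K = 1–10 — one tenth of a typical published STRUCTURE
protocol (10,000 / 100,000), which remains one `MCMCConfig` away. On the
planted two-population benchmark (40 individuals × 30 biallelic loci at
0.9/0.1 frequencies, 200 + 1,000 sweeps, 3 replicates), ΔK selects K = 2
in ≥ 9/10 seeds. For unadmixed panels the posterior-mean max-Q
concentration depends on α: with α = 1.0 it plateaus near 0.93 on that
benchmark, while α = 0.1 — the natural setting when individuals are not
admixed — exceeds 0.95 with the planted partition recovered exactly;
tests of that scenario use α = 0.1.

## Association scans

Traits are ordinal-coded numerics (the convention of Tassel-style
pipelines; e.g. fruit-skin colour white/light-green/green/dark-green →
0–3, spine none/very-low → 0–1; encodings are plain dictionaries the
caller can replace). Markers enter as genotype-class indicators
(multi-allelic safe; reference class dropped), with allele-dosage coding
available for biallelic loci. Structure covariates are the first K−1
columns of a Q matrix.

* **GLM.** Per marker, OLS of trait on intercept + Q columns + marker
  indicators; the marker block is tested by a partial F-test;
  `PVE = 100 (RSS_reduced − RSS_full)/TSS`. Rank-deficient marker columns
  are pruned; markers with a single genotype class are skipped with a
  warning.
* **MLM.** Adds a polygenic effect with covariance `σ_g² · 2K` for the
  IBS kinship `K` (pairwise mean allele-sharing: 1 / 0.5 / 0 per locus;
  diagonal 1; negative eigenvalues bent to zero). The spectrum of `2K` is
  eigendecomposed once; per marker, the variance ratio
  `δ = σ_g²/σ_e²` is estimated by bounded one-dimensional REML on
  `log δ ∈ [−12, 12]` (EMMA-style), and the marker block is F-tested on
  the whitened fit, with PVE from the GLS sums of squares around the
  whitened intercept-only fit. Markers with missing genotypes trigger an
  eigendecomposition of the typed submatrix. With `2K = I` the whitening
  is a scalar, so MLM reproduces GLM to machine precision — used as an
  equivalence oracle.

Raw p-values are reported; no multiple-testing correction is applied by
default, matching plain-threshold usage. Under a null simulation the GLM
empirical type-I error at 0.05 sits inside 0.05 ± 0.02 (checked over 150
datasets × 40 markers at n = 80, ~6,000 p-values — enough for a
Monte-Carlo s.e. of ~0.003); under a structured (polygenic) null the MLM
rejection rate is closer to nominal than the GLM's inflated rate.

## Synthetic data

* **Genomes.** i.i.d. background at a target GC (default 0.38, an
  AT-rich plant-genome value) with perfect arrays planted at fixed
  coordinates, ≥ 50 bp apart; flank bases that would extend a planted
  array are resampled, so planted loci are maximal and recovered at exact
  coordinates. Background sequence is *not* repeat-free: spurious SSRs
  legitimately occur, so miner tests score planted-locus recovery and
  oracle agreement, never "no other loci".
* **Genotypes.** `Q_i ~ Dirichlet(α)` (default α = 0.2, giving mostly
  assigned individuals with some admixture); population allele
  frequencies either supplied directly or drifted from shared ancestral
  frequencies by a Balding–Nichols Dirichlet with concentration
  `(1−F)/F` (default F = 0.15, moderate between-population divergence);
  missing calls i.i.d. (default 2 %). Defaults mirror a small germplasm
  panel: 35 individuals × 42 loci, K = 2. The generator draws each allele
  copy independently given Q — no linkage, no null alleles, no
  genotyping-error model, and no microsatellite mutation process — so
  passing tests show method correctness under the admixture model's own
  assumptions, not robustness to those real-data complications.
* **Phenotypes.** `y = Σ effect × dosage + ε` with ε scaled so the
  genetic variance share equals the target heritability
  (`heritability=1.0` gives a noise-free trait). The recorded per-marker
  "realised PVE" is the variance removed by subtracting that marker's
  true contribution, `100·(var(y) − var(y − g_m))/var(y)`, which includes
  the in-sample covariance between genetic part and noise draw — the
  quantity an unbiased in-sample scan estimates.

All generators are bit-reproducible given (spec, seed).

## Problem sizes and numerical choices

Simulation-backed checks run at desk scale chosen to keep the full suite
around 1–2 minutes while leaving Monte-Carlo margins well inside the
asserted bands: 100 × 10 kb sequences for oracle equivalence, 10 seeds ×
(K = 1–4 × 3 replicates × 1,200 sweeps) for ΔK recovery, 150 null
datasets for GLM calibration, n = 500 × 20 seeds for heritability
calibration. Degenerate inputs are handled explicitly rather than
silently: empty sequences, zero genome length, loci with < 2 typed
individuals, all-missing individuals, constant traits, zero-sd ΔK and
flat ΔK profiles all raise or warn as documented in the API. Floating-
point tolerances in tests are 1e-12 for algebraic identities, 1e-8 for
eigen-reconstructions, and 1e-6 relative for the MLM/GLM collapse.

## Known limitations

Imperfect/compound SSRs are out of scope; e-PCR is ungapped; the
admixture sampler has no linkage or correlated-frequencies model and no
CLUMPP-style multi-run alignment (label matching is done per test);
association offers no compressed-MLM/P3D approximations and is not tuned
for GWAS-scale marker counts; He's published-table artefact (He = 1 − Ho)
is documented, not reproduced.
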