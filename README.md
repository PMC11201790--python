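# ssrkit

Genome-wide SSR (microsatellite) marker development and germplasm
genetic-diversity analysis in one tested Python package.

Simple sequence repeats — perfect tandem arrays of 1–6 bp motifs — are the
workhorse co-dominant markers for characterising germplasm collections of
under-studied crops such as chayote (*Sechium edule*) and its cucurbit
relatives. A typical study mines SSRs from a genome assembly, designs
flanking primers, checks which primers transfer to related species,
genotypes a few dozen accessions at a few dozen polymorphic loci, and then
asks three questions of the genotype table: how diverse is each marker,
how do the accessions cluster, and which markers associate with phenotypes
of interest. `ssrkit` implements that entire chain:

| Stage | Module | Core method |
|---|---|---|
| SSR mining | `ssrkit.mining` | maximal perfect tandem arrays, primitive periods 1–6, canonical motif classes (min over rotations and reverse-complement rotations) |
| Primer design | `ssrkit.primers` | exhaustive flank scan under product 100–250 bp, length 18–24 bp, Tm 50–60 °C, GC 40–60 % |
| Transferability | `ssrkit.transfer` | in-silico PCR: ≤ 5 mismatches in the 5′ region, zero in a 5 bp 3′ anchor, ≥ 90 % per-primer identity; scaffold/duplicate filtering; synteny link counts |
| Diversity statistics | `ssrkit.diversity` | Na, Ne = 1/Σp², Ho, unbiased He, Shannon I, Nei's H = 1 − Σp², Botstein PIC = 1 − Σpᵢ² − Σ_{i<j} 2pᵢ²pⱼ² |
| Clustering | `ssrkit.cluster` | allele-band similarity (simple matching / Dice / Jaccard), UPGMA, PCoA with per-axis % variance |
| Population structure | `ssrkit.admixture` | Gibbs-sampled Bayesian admixture (Q, P, lnP(D)), Evanno ΔK = mean\|L″(K)\| / sd(L(K)) |
| Marker–trait association | `ssrkit.association` | GLM (marker + Q covariates, partial F-test, PVE) and EMMA-style MLM with an IBS-kinship polygenic effect |
| Synthetic data | `ssrkit.simulate` | genomes with planted SSR truth, structured diploid genotypes with known Q, phenotypes with known marker effects |

Admixture and association follow a statsmodels-style pattern: a model
object built from data whose `fit()` returns a results object with
estimates and a `summary()` table (`AdmixtureModel(...).fit()`,
`AssociationScan(...).fit()`).

## Worked example

Simulate a two-population panel shaped like a small germplasm collection
(35 accessions × 42 SSR loci), then run the analysis chain:

```sh
ssrkit simulate genotypes --n 35 --loci 42 --k 2 --seed 11 --out-prefix panel
ssrkit diversity --genotypes panel.genotypes.tsv --out diversity.tsv
ssrkit cluster   --genotypes panel.genotypes.tsv --newick upgma.nwk --pcoa pcoa.tsv
ssrkit structure --genotypes panel.genotypes.tsv --kmin 1 --kmax 4 \
                 --reps 3 --burnin 200 --iters 1000 --seed 11 --out-prefix str
```

prints

```
35 individuals x 42 loci, K=2
42 loci; mean PIC 0.54; high 29, moderate 11, low 2
PCoA axes 1-2 explain 20.83% and 8.45%
best K by delta-K: 2
```

`diversity.tsv` holds one row per locus plus a means row; for example

```
marker  Na   Ne      Ho     He     I       H       PIC     n_typed  class
SSR001  4.0  2.4476  0.6    0.6    1.1017  0.5914  0.5442  35.0     high
...
Mean    3.8333  2.6578  0.5721  0.6073  1.0673  0.5985  0.5379  34.5
```

Reading the output: `Ne` is the effective allele number (how many
equally-frequent alleles would give the same homozygosity), `PIC ≥ 0.5`
marks a highly polymorphic marker, the PCoA percentages are each axis'
share of the total positive eigenvalue mass, and `best K` is the Evanno
ΔK peak over the replicate STRUCTURE-style runs — here correctly
recovering the two simulated source populations.

Genome-side stages work the same way (`ssrkit simulate genome`,
`ssrkit mine`, `ssrkit design`, `ssrkit transfer`); `ssrkit run-all`
chains the genotype-side stages. Every command is a thin wrapper over
library functions importable from `ssrkit`.

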