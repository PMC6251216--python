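# bsamap

Map-by-sequencing of a monogenic recessive trait in a selfing diploid crop:
segregation genetics, F2 cross-population association mapping, dual variant
screening against a diversity panel and a bulked-segregant pool, and
splice-aware molecular consequence prediction — plus simulators for every
input, so the whole workflow runs and is testable without any external data.

## Who this is for

Geneticists cloning a qualitative (fully penetrant, single-locus) trait from
a biparental cross with whole-genome resequencing rather than a genetic map.
The package implements the integrated strategy: establish the inheritance
mode from segregation tables, locate the locus by per-marker association in
an F2 population, then intersect two orthogonal screens — the causal
recessive allele must be *absent* from every normal-phenotype accession of a
diversity (germplasm) panel and *fixed* in pooled reads of
recessive-phenotype segregants — and finally reconstruct what the candidate
mutation does to the gene product.

## The statistics and models

**Segregation.** Pearson goodness of fit without continuity correction,
χ² = Σᵢ (Oᵢ − Eᵢ)²/Eᵢ with Eᵢ = N·ratioᵢ/Σratio, df = k − 1; a trait is
called monogenic recessive when the F1 is uniformly normal, the backcross to
the mutant parent fits 1:1 and the F2 fits 3:1 (all at P > 0.05, i.e.
χ² ≤ 3.84 for two classes).

**Association.** For each biallelic marker, the Pearson chi-square on the
2 (phenotype) × k (genotype class) contingency table, df = k − 1. For a
fully penetrant recessive trait the phenotype is a deterministic function of
the causal genotype, and then χ² = N exactly — the statistic's ceiling at
population size N. A general-linear-model route (one-way ANOVA F of the
phenotype on genotype-class indicators) is available as an alternative. The
mapped locus is reported as the lowest-P marker plus a ±200 kb window whose
bounds are the outermost scanned markers inside it.

**Screening.** Panel screen: retain markers whose mutant allele has zero
carriers among the panel accessions (optionally: zero homozygotes, since a
heterozygous carrier of a recessive allele still shows the normal
phenotype). Pool screen: retain markers with read depth ≥ 10 and alt-read
fraction ≥ 0.95 in the recessive bulk. Candidates are the intersection,
placed against gene models with priority exon > intron > 5′-flanking >
3′-flanking (±10 kb, strand-aware) > intergenic; the gene hosting the
plurality of candidates is nominated.

**Consequence.** Gene-level edits (e.g. a 20 nt → 6 nt replacement that
removes a GT splice donor) are applied to a strand-aware gene model. A
donor- or acceptor-destroyed intron is retained into the mature transcript
(an optional policy rescues a cryptic downstream GT instead); the mutant ORF
is translated, and the report gives the first altered codon, the substituted
residue run, the premature terminator and which protein domains are lost or
disrupted.

**Simulation.** F2 gametes recombine under the Haldane map function
r(d) = (1 − e^(−2d/100))/2 with no interference; parents are fully
homozygous and opposite at every marker; the panel lacks the causal allele
by construction; pooled read counts are Poisson depth with binomial allele
sampling at the bulk allele frequency.

## Worked example

```bash
bsamap run-all --demo --out demo --seed 42
```

prints

```
{"causal_variant": "C8_1200000", "in_intersection": true, "in_interval": true, "top_candidate": true}
```

and writes `demo/summary.json` with the full funnel; with `-v` the stages
narrate themselves:

```
segregation: F1 (30, 0), BC1 (210, 224) (chi2=0.45), F2 (818, 273) (chi2=0.00) -> monogenic recessive
simulate: 130 F2 x 2601 variants, causal C8_1200000
scan: 2601 variants after QC (of 2601); peak C8_1195713; interval C8:1005025-1370254 (33 members)
screen: 33 interval variants -> 1 after panel screen, 14 after pool screen, 1 in common
consequence: C8.460 -> 299 aa (truncating), stop at residue 300
```

Read: the simulated inheritance study fits one recessive gene; the scan's
peak marker co-segregates perfectly with the phenotype (a near neighbour of
the true locus — both reach the χ² = 130 ceiling); of the 33 markers in the
±200 kb interval only the planted causal variant survives both screens; its
splice-donor deletion retains intron 2, shifts the frame and truncates the
440-aa product to 299 aa inside the MYB domain.

The same stages are available as library calls — see `examples/01` … `05`
for short narrative scripts (segregation tables, association scan, dual
screen, splice consequence, full pipeline), each printing the numbers it
computes and one line on what they mean.

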