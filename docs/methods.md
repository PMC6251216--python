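# Methods

## The workflow in one paragraph

A fully penetrant recessive trait segregating in a biparental cross is
mapped in four moves. First, segregation tables (F1, backcross, F2) are
tested against Mendelian ratios to establish the inheritance mode. Second,
every sequenced variant in the F2 mapping population is tested for
genotype–phenotype association and a physical target interval is defined
around the strongest marker. Third, interval variants are filtered two
independent ways — absence of the mutant allele from a diversity panel of
normal-phenotype accessions, and fixation of the mutant allele in pooled
reads of recessive segregants — and the intersection is assigned to gene
models. Fourth, the surviving candidate's molecular consequence is
reconstructed at the transcript and protein level.

## Statistical models and their assumptions

**Goodness of fit.** Pearson χ² = Σ (O−E)²/E against the expected ratio,
df = k−1, no Yates continuity correction. The uncorrected statistic is the
one whose values reproduce the published two-class tables this package is
checked against (with the correction, 830:261 vs 3:1 gives ≈0.62 rather
than 0.67); for class counts in the hundreds the correction is immaterial
anyway. `fits` means χ² ≤ χ²₀.₀₅,df (3.84 at df = 1), equivalently
P > 0.05. Calibration is verified empirically: over 10,000 multinomial
draws at the null ratio the rejection rate is ~5%.

**Association.** The primary statistic is the genotypic contingency χ² on
the 2 × k phenotype-by-genotype-class table (k ≤ 3 after dropping empty
classes), df = k−1. It assumes independent individuals and a binary,
error-free phenotype; it makes no additivity assumption, which matters for
a recessive trait where het and hom-ref classes are phenotypically
identical. Key identity used throughout testing: when the phenotype is a
deterministic function of genotype, χ² = N (the non-missing sample count).
This also bounds attainable P values: at N = 130, P ≈ 5.9 × 10⁻²⁹ — a
printed genome-scan P far smaller than that must come from a different
model/encoding and is not a target here. The alternative `glm_dosage_F`
route is the one-way ANOVA F of phenotype on genotype-class indicators,
computed in closed form from the same contingency counts; under perfect
separation the residual sum of squares is zero and the P value is clamped
to 10⁻³⁰⁰ to keep it in (0, 1]. Monomorphic markers get statistic 0 and
P = 1. Missing genotypes are dropped marker-wise, never imputed. No
multiple-testing correction is applied: peak selection uses the raw
minimum P, with ties broken by (chromosome, position) for determinism.

**QC filter.** A marker is kept when its non-missing call count is ≥ 100
and its minor-allele frequency is ≥ 0.1, both bounds inclusive. In an F2 of
130 every segregating marker passes; the filter exists for real call sets
with missingness and segregation distortion.

**Interval definition.** Peak ± 200 kb (`flank_bp`, configurable); the
reported bounds are the outermost *scanned markers* inside the window, not
the literal peak ± 200,000 coordinates, so interval endpoints are always
marker positions and the span never exceeds 2·flank.

**Panel screen.** Default rule `no-allele`: a marker survives only if no
panel accession carries its mutant allele at all. Because a fully penetrant
recessive allele could in principle hide in heterozygous carriers with
normal phenotype, `no-homozygote` is provided as a config switch; the
strict rule is the default because it is the sharper filter and the one
consistent with an allele private to the mutant line. Accessions with
missing calls at a site are never counted as carriers; a marker absent from
the panel index raises by default (or is retained with a warning).

**Pool screen.** Depth ≥ 10 and alt fraction ≥ 0.95, defaults chosen to
tolerate sequencing error without admitting genuinely segregating sites
(at 30× a site fixed in the bulk has alt fraction 1 minus error; a site at
true frequency 0.5 essentially never reaches 0.95). Sites below the depth
floor are reported as *unevaluable*, a distinct category from *dropped*,
because absence of reads is not evidence of segregation.

**Gene assignment.** Priority exon > intron > 5′-flanking > 3′-flanking >
intergenic; flanks extend 10 kb and are strand-aware (the 5′ side of a
minus-strand gene is its genomic-right side). Each variant supports only
its highest-priority gene; the nominated gene is the one with the most
supporting variants, ties broken by the gene containing the lowest-P
variant.

## The consequence engine

Coordinates are gene-relative, 1-based, inclusive, on the coding strand;
converters to and from genomic coordinates are provided for anchored genes.
Gene models validate GT..AG intron boundaries unless flagged non-canonical.

**Splice policy.** An intron whose donor (GT) or acceptor (AG) dinucleotide
is deleted or mutated is, by default, *retained*: merged with its flanking
exons up to the next intact splice boundary, while unaffected introns are
spliced normally. This is the parsimonious model for donor loss and is what
produces a frameshift when the retained length plus the net indel is not a
multiple of 3. The alternative `cryptic-gt` policy instead splices a
donor-destroyed intron from the nearest downstream GT before the intact
acceptor, falling back to retention when none exists. Whole-intron
deletions and edits that remove the start codon are rejected explicitly
rather than guessed at.

**Reported frameshift position.** The first nucleotide of the first altered
codon, in ORF coordinates: 3·(first altered residue − 1) + 1. With the
first altered residue at 295 this gives ORF position 883.

**Event composition.** A mutant model remembers its wild-type base and the
cumulative edit. Applying a further edit composes the two into one edit of
the wild type and re-derives the structure from scratch, so an edit that
restores a destroyed donor restores splicing — this is what makes the
round-trip invariant (event then inverse ⇒ wild transcript exactly) hold.
No-op edits (replacement identical to the replaced span) return the model
unchanged.

**Alternative isoforms.** A donor or acceptor shifted by ±k nt emits a
second isoform; k a multiple of 3 inside the CDS changes the protein by
whole residues (the classic NAGNAG acceptor gives a one-residue
difference), any other k is flagged frameshifted.

## Simulators: what they emulate, what they do not

`simulate_f2` draws one recombinant gamete per F1 parent per individual,
with crossovers between adjacent markers at the Haldane recombination
fraction r(d) = (1 − e^(−2d/100))/2 of their map separation — no crossover
interference, and a uniform physical-to-genetic map (position/bp length ×
map length). Parents are fully homozygous and opposite everywhere, so every
marker is informative and segregates 1:2:1. The phenotype is recessive at
the planted causal variant with configurable penetrance (default 1).
`simulate_panel` gives every non-causal marker carriers in a Bernoulli
subset of accessions (default sharing fraction 0.3, a typical frequency for
polymorphisms shared across a diverse collection); the causal allele is
absent from all accessions by construction. `simulate_pool` draws per-site
depth ~ Poisson(mean 30) and alt reads ~ Binomial(depth, bulk allele
frequency) over the 2 × 50 bulk haplotypes.

Not emulated: genotyping error, missing calls, segregation distortion,
reference bias, structural variants, linkage between panel accessions'
genotypes (panel sites are independent), and read-level artefacts. Passing
tests therefore demonstrate the correctness of the statistics and the
screening logic under the stated design, not robustness to dirty real-world
call sets — the QC filter and the unevaluable-site handling are where such
robustness would enter, and they are tested on hand-built corner cases.

## Study-scale defaults and problem sizes

Defaults mirror the emulated study design: 130 F2 individuals, 13
chromosomes, an 822-accession panel, a 50-individual recessive bulk, ±200 kb
interval, QC count ≥ 100 and MAF ≥ 0.1. Because a 130-plant F2 holds only
~32 recessive homozygotes, the bulk is drawn from a separate simulated test
population (default 1231 F2) genotyped over the same markers, matching the
design in which the pool comes from a larger validation cross. Chromosomes
are simulated at 2 Mb / 100 cM with 200 markers each — about 2,600 markers
genome-wide rather than the several hundred thousand of a real call set.
This preserves every structural property the method depends on (marker
density within the ±200 kb interval ≈ 40, realistic linkage decay at
0.5 cM/marker spacing) while keeping a 100-replicate recovery study around
half a minute. The panel is simulated over the mapped interval only, since
the screens never query markers outside it.

## The packaged synthetic gene

The consequence engine's reference fixture is a generated, synthetic
KANADI-like gene (no real sequence is bundled): 2,621 bp, 6 exons /
5 introns, 100-nt 5′UTR, encoding 440 aa (ORF 1,323 nt with stop). Exon 2
ends ...CAG at gene position 1133 and intron 2's GT donor sits at
1134–1135, so positions 1131–1150 read CAGGTAGCTATGTATATGCA. The bundled
event replaces that 20-mer with TCTTTG, destroying the donor; intron 2 is
retained and was engineered so the shifted frame reads five substituted
residues from residue 295 (ORF 883) and a TAA terminator at residue 300,
leaving a 299-aa product (ORF 900 nt) truncated inside the MYB domain
(residues 271–323). All of these numbers are computed by the engine at test
time, not asserted from the generator.

## Numerical and degenerate-input conventions

Genotype codes 0/1/2 = hom-ref (wild-parent allele) / het / hom-alt
(mutant-parent allele), −1 missing; VCF GT 0/0, 0/1, 1/1, ./.. Phenotypes
are the strings `CL` (normal) and `cl` (mutant) in TSVs, 0/1 internally.
Marker identifiers are `C{scaffold}_{position}`, regenerable from
coordinates. P values are clamped to [10⁻³⁰⁰, 1]. Empty populations fail at
the scan stage with an explicit message; an all-one-phenotype sample is an
error (association undefined); zero-depth pool sites are unevaluable, not
dropped. All JSON output is written with sorted keys and every bundle file
carries the config hash and seed, making `run-all` byte-reproducible under
a fixed seed.

## Known limitations

Single-locus, fully qualitative traits only: no mixed models, no
kinship/structure correction, no quantitative-trait support. The
consequence engine handles one edit per call (composed edits excepted) and
does not score splice-site strength or predict nonsense-mediated decay.
Interval definition assumes a single causal region; two linked causal loci
would be folded into one peak. The GLM route reduces to ANOVA on genotype
classes and will not reproduce P values from software using different
encodings or covariates.
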