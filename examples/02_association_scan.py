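"""Single-marker association over a simulated F2 mapping population.

Simulates 130 F2 individuals segregating a planted recessive variant,
tests every marker with the genotypic contingency chi-square, and defines
the +/-200 kb target interval around the lowest-P marker.
"""

from bsamap import (
    CrossDesign,
    associate,
    define_interval,
    phenotype_to_binary,
    qc_filter,
    simulate_f2,
)

design = CrossDesign(
    n_f2=130, n_chromosomes=5, chrom_length_bp=2_000_000,
    variants_per_chrom=200, causal_chrom=3, causal_pos=1_200_000, seed=1,
)
genotypes, phenotypes, variants = simulate_f2(design)
n_recessive = int(phenotype_to_binary(phenotypes).sum())
print(f"{design.n_f2} F2, {len(variants)} variants, {n_recessive} recessive plants")

filtered = qc_filter(genotypes, min_count=100, min_freq=0.1)
results = associate(filtered, phenotype_to_binary(phenotypes))
interval = define_interval(results, flank_bp=200_000)

peak = interval.peak_variant
peak_res = next(r for r in results if r.variant_id == peak.id)
print(f"peak marker  : {peak.id}  chi2={peak_res.statistic:.1f}  P={peak_res.p_value:.2e}")
print(f"interval     : {interval.chrom}:{interval.start}-{interval.end}")
print(f"members      : {len(interval.member_variants)} markers inside the window")
print(
    f"\nThe planted causal variant sits at C3_1200000; chi2 at a perfectly"
    f"\nlinked marker equals the population size ({design.n_f2}), the ceiling"
    f"\nfor a deterministic genotype-phenotype relation."
)
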