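"""Simulators for every input the mapping pipeline consumes.

The generators emulate the study design of a recessive-trait cloning
experiment in a selfing diploid crop: two fully homozygous inbred parents
that differ at every marker, a recombining F2 population carrying a planted
fully penetrant recessive causal variant, a diversity (germplasm) panel from
which the mutant allele is absent by construction, and a bulked-segregant
pool of recessive-phenotype F2 individuals observed through read counts.

Recombination uses the Haldane map function (no crossover interference):
``r(d) = (1 - exp(-2 d / 100)) / 2`` for a map distance of ``d``
centimorgans, so adjacent markers at 0 cM never recombine and far markers
approach r = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variants import MISSING, GenotypeMatrix, VariantRecord

PHENOTYPE_NORMAL = "CL"
PHENOTYPE_MUTANT = "cl"

#: Default causal alleles: a 20-nt wild allele replaced by 6 nt in the mutant,
#: the same shape of event the consequence engine dissects.
CAUSAL_REF = "CAGGTAGCTATGTATATGCA"
CAUSAL_ALT = "TCTTTG"

_BASES = np.array(list("ACGT"))


@dataclass
class CrossDesign:
    """Design of a biparental F2 mapping population."""

    n_f2: int = 130
    n_chromosomes: int = 13
    chrom_length_bp: int = 2_000_000
    chrom_length_cM: float = 100.0
    variants_per_chrom: int = 200
    causal_chrom: int = 8
    causal_pos: int = 1_200_000
    penetrance: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_f2 < 0:
            raise ValueError("n_f2 must be >= 0")
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")
        if self.chrom_length_bp <= 0:
            raise ValueError(f"chromosome length must be positive, got {self.chrom_length_bp}")
        if self.chrom_length_cM <= 0:
            raise ValueError("map length must be positive")
        if not 1 <= self.causal_chrom <= self.n_chromosomes:
            raise ValueError(
                f"causal_chrom {self.causal_chrom} outside 1..{self.n_chromosomes}"
            )
        if not 1 <= self.causal_pos <= self.chrom_length_bp:
            raise ValueError(
                f"causal position {self.causal_pos} outside chromosome of "
                f"length {self.chrom_length_bp} bp"
            )
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError("penetrance must lie in [0, 1]")


@dataclass
class PanelDesign:
    """Design of the germplasm diversity panel used as a background screen."""

    n_accessions: int = 822
    fraction_sharing_background_alleles: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_accessions < 0:
            raise ValueError("n_accessions must be >= 0")
        if not 0.0 <= self.fraction_sharing_background_alleles <= 1.0:
            raise ValueError("sharing fraction must lie in [0, 1]")


@dataclass
class PoolDesign:
    """Design of the bulked-segregant pool of recessive-phenotype F2s."""

    n_individuals: int = 50
    mean_depth: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")


@dataclass
class PanelCallSet:
    """Genotype calls of a diversity panel over a set of variants."""

    accession_ids: list[str]
    variants: list[VariantRecord]
    codes: np.ndarray = field(repr=False)  # accessions x variants, {-1,0,1,2}

    def carrier_counts(self, rule: str = "no-allele") -> np.ndarray:
        """Per-variant count of accessions carrying the mutant allele.

        ``no-allele`` counts het and hom carriers; ``no-homozygote`` counts
        hom-mutant accessions only. Missing calls never count as carriers.
        """
        if rule == "no-allele":
            return (self.codes >= 1).sum(axis=0)
        if rule == "no-homozygote":
            return (self.codes == 2).sum(axis=0)
        raise ValueError(f"unknown panel rule {rule!r}")


@dataclass
class PoolCounts:
    """Per-variant (ref, alt) read support of a sequenced pool."""

    variants: list[VariantRecord]
    ref_count: np.ndarray
    alt_count: np.ndarray

    def __post_init__(self) -> None:
        self.ref_count = np.asarray(self.ref_count, dtype=np.int64)
        self.alt_count = np.asarray(self.alt_count, dtype=np.int64)
        if (self.ref_count < 0).any() or (self.alt_count < 0).any():
            raise ValueError("read counts must be non-negative")

    @property
    def depth(self) -> np.ndarray:
        return self.ref_count + self.alt_count


def haldane_r(d_cM: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction for a map distance in centimorgans."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


def simulate_gametes(rng: np.random.Generator, cm_positions: np.ndarray, n: int) -> np.ndarray:
    """Draw ``n`` recombinant gametes from a heterozygous F1 parent.

    Returns an (n, n_loci) 0/1 array of parental-origin alleles along one
    chromosome; switches between adjacent loci occur with the Haldane
    recombination fraction of their map separation.
    """
    cm_positions = np.asarray(cm_positions, dtype=float)
    n_loci = cm_positions.size
    if n_loci == 0:
        return np.zeros((n, 0), dtype=np.int8)
    start = rng.integers(0, 2, size=(n, 1))
    if n_loci == 1:
        return start.astype(np.int8)
    r = haldane_r(np.diff(cm_positions))
    switch = rng.random((n, n_loci - 1)) < r
    cross = np.concatenate([np.zeros((n, 1), dtype=np.int64), np.cumsum(switch, axis=1)], axis=1)
    return ((start + cross) % 2).astype(np.int8)


def _draw_variants(rng: np.random.Generator, design: CrossDesign) -> list[VariantRecord]:
    """Uniform random biallelic variants per chromosome plus the causal indel."""
    variants: list[VariantRecord] = []
    for c in range(1, design.n_chromosomes + 1):
        chrom = f"C{c}"
        n = design.variants_per_chrom
        pos = np.unique(rng.integers(1, design.chrom_length_bp + 1, size=n))
        if c == design.causal_chrom:
            pos = pos[pos != design.causal_pos]
        refs = _BASES[rng.integers(0, 4, size=pos.size)]
        shifts = rng.integers(1, 4, size=pos.size)
        for p, ref, s in zip(pos, refs, shifts):
            alt = _BASES[(np.flatnonzero(_BASES == ref)[0] + s) % 4]
            variants.append(VariantRecord(chrom, int(p), str(ref), str(alt)))
        if c == design.causal_chrom:
            variants.append(
                VariantRecord(chrom, design.causal_pos, CAUSAL_REF, CAUSAL_ALT)
            )
    variants.sort(key=lambda v: (int(v.chrom[1:]), v.pos))
    return variants


def causal_index(variants: list[VariantRecord], design: CrossDesign) -> int:
    """Index of the planted causal variant in a simulated variant list."""
    target = (f"C{design.causal_chrom}", design.causal_pos)
    for i, v in enumerate(variants):
        if (v.chrom, v.pos) == target:
            return i
    raise ValueError("causal variant not present in variant list")


def simulate_f2(
    design: CrossDesign,
    variants: list[VariantRecord] | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame, list[VariantRecord]]:
    """Simulate an F2 population segregating a recessive causal variant.

    Parents are fully homozygous and opposite at every variant (wild parent
    0/0, mutant parent 1/1); each F2 receives one recombinant gamete from
    each F1, so single-locus genotypes segregate 1:2:1. The phenotype is
    recessive (``"cl"``) iff the individual is homozygous mutant at the
    causal variant, thinned by ``penetrance``.

    Returns (genotypes, phenotype table with columns ``sample_id`` and
    ``phenotype``, variant list).
    """
    rng = np.random.default_rng(design.seed)
    if variants is None:
        variants = _draw_variants(rng, design)
    else:
        variants = list(variants)
    sample_ids = [f"F2_{i + 1:04d}" for i in range(design.n_f2)]

    codes = np.zeros((design.n_f2, len(variants)), dtype=np.int8)
    offset = 0
    for c in range(1, design.n_chromosomes + 1):
        chrom_vars = [v for v in variants if v.chrom == f"C{c}"]
        pos = np.array([v.pos for v in chrom_vars], dtype=float)
        cm = pos / design.chrom_length_bp * design.chrom_length_cM
        g1 = simulate_gametes(rng, cm, design.n_f2)
        g2 = simulate_gametes(rng, cm, design.n_f2)
        codes[:, offset : offset + len(chrom_vars)] = g1 + g2
        offset += len(chrom_vars)

    ci = causal_index(variants, design)
    hom_mut = codes[:, ci] == 2 if design.n_f2 else np.zeros(0, dtype=bool)
    expressed = hom_mut & (rng.random(design.n_f2) < design.penetrance)
    phenotypes = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "phenotype": np.where(expressed, PHENOTYPE_MUTANT, PHENOTYPE_NORMAL),
        }
    )
    gm = GenotypeMatrix(sample_ids=sample_ids, variants=variants, codes=codes)
    return gm, phenotypes, variants


def phenotype_to_binary(phenotypes: pd.DataFrame) -> np.ndarray:
    """Map the CL/cl phenotype column to 0 (normal) / 1 (mutant)."""
    values = phenotypes["phenotype"].to_numpy()
    known = np.isin(values, (PHENOTYPE_NORMAL, PHENOTYPE_MUTANT))
    if not known.all():
        bad = sorted(set(values[~known]))
        raise ValueError(f"unknown phenotype labels {bad}; expected CL or cl")
    return (values == PHENOTYPE_MUTANT).astype(np.int8)


def simulate_panel(
    design: PanelDesign,
    variants: list[VariantRecord],
    causal_id: str,
) -> PanelCallSet:
    """Simulate germplasm-panel genotypes over ``variants``.

    The causal mutant allele is absent from every accession by construction;
    every non-causal variant carries the mutant-parent allele in a seeded
    random subset of accessions at the configured sharing fraction (carriers
    are het or hom with equal probability).
    """
    ids = [v.id for v in variants]
    if causal_id not in ids:
        raise ValueError(f"causal variant {causal_id} not among panel variants")
    rng = np.random.default_rng(design.seed)
    n_acc, n_var = design.n_accessions, len(variants)
    carrier = rng.random((n_acc, n_var)) < design.fraction_sharing_background_alleles
    zygosity = rng.integers(1, 3, size=(n_acc, n_var))
    codes = np.where(carrier, zygosity, 0).astype(np.int8)
    codes[:, ids.index(causal_id)] = 0
    assert not (codes[:, ids.index(causal_id)] > 0).any()
    return PanelCallSet(
        accession_ids=[f"M{i + 1}" for i in range(n_acc)],
        variants=list(variants),
        codes=codes,
    )


def simulate_pool(
    design: PoolDesign,
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
) -> PoolCounts:
    """Simulate pooled read counts over a bulk of recessive-phenotype F2s.

    Per site, depth ~ Poisson(mean_depth) and the alt read count is binomial
    with success probability equal to the pooled alt-allele frequency among
    the 2 x n_individuals bulk haplotypes. Under full penetrance every pooled
    individual is homozygous mutant at the causal variant, so its pooled alt
    frequency is 1.
    """
    binary = phenotype_to_binary(phenotypes)
    recessive = np.flatnonzero(binary == 1)
    if recessive.size < design.n_individuals:
        raise ValueError(
            f"pool needs {design.n_individuals} recessive-phenotype individuals "
            f"but only {recessive.size} are available "
            f"(short by {design.n_individuals - recessive.size})"
        )
    rng = np.random.default_rng(design.seed)
    chosen = rng.choice(recessive, size=design.n_individuals, replace=False)
    bulk = genotypes.codes[np.sort(chosen), :].astype(float)
    bulk[bulk == MISSING] = np.nan
    with np.errstate(invalid="ignore"):
        freq = np.nansum(bulk, axis=0) / (2.0 * np.sum(~np.isnan(bulk), axis=0))
    freq = np.nan_to_num(freq, nan=0.0)
    depth = rng.poisson(design.mean_depth, size=genotypes.n_variants)
    alt = rng.binomial(depth, freq)
    return PoolCounts(
        variants=list(genotypes.variants), ref_count=depth - alt, alt_count=alt
    )


def simulate_inheritance_study(
    seed: int,
    n_f1: int = 30,
    n_bc1: int = 434,
    n_f2: int = 1091,
) -> dict[str, tuple[int, int]]:
    """Simulate (normal, mutant) phenotype tallies for a segregation study.

    F1 of a cross between homozygous parents is uniformly heterozygous, hence
    all normal for a recessive trait; BC1 to the mutant parent segregates
    1:1; F2 segregates 3:1. Defaults use population sizes typical of a
    dedicated inheritance experiment rather than the sequenced mapping
    population.
    """
    rng = np.random.default_rng(seed)
    bc1_mut = int(rng.binomial(n_bc1, 0.5))
    f2_mut = int(rng.binomial(n_f2, 0.25))
    return {
        "F1": (n_f1, 0),
        "BC1": (n_bc1 - bc1_mut, bc1_mut),
        "F2": (n_f2 - f2_mut, f2_mut),
    }
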