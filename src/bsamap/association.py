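"""Per-variant genotype-phenotype association over an F2 genotype matrix.

For a binary trait scored on an F2 population, each variant is tested with a
Pearson chi-square on the 2 (phenotype) x k (genotype class) contingency
table, df = k - 1. For a fully penetrant phenotype that is a deterministic
function of genotype the statistic equals the number of non-missing samples,
which bounds how small the P value can get at a given population size. A
one-way-ANOVA F test of the phenotype on genotype-class indicators (the
general-linear-model route) is provided as an alternative; both are computed
in closed form from the same per-variant contingency counts.

The mapped locus is reported as the variant with the lowest P value plus a
flanking window (default +/-200 kb) whose bounds are the outermost scanned
variants inside the window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .variants import GenotypeMatrix, VariantRecord, parse_marker_id

P_FLOOR = 1e-300  # reported in place of an exact 0 from perfect separation


@dataclass
class AssociationResult:
    variant: VariantRecord
    statistic: float
    df: int
    p_value: float
    method: str

    @property
    def variant_id(self) -> str:
        return self.variant.id


@dataclass
class TargetInterval:
    chrom: str
    peak_variant: VariantRecord
    flank_bp: int
    start: int
    end: int
    member_variants: list[VariantRecord] = field(default_factory=list)

    @property
    def span_bp(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


def qc_filter(
    matrix: GenotypeMatrix, min_count: int = 100, min_freq: float = 0.1
) -> GenotypeMatrix:
    """High-confidence variant filter: call count and minor-allele frequency.

    Retains variants with at least ``min_count`` non-missing genotype calls
    AND minor-allele frequency >= ``min_freq`` (both bounds inclusive),
    preserving variant order.
    """
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    if not 0.0 <= min_freq <= 0.5:
        raise ValueError("min_freq must lie in [0, 0.5]")
    codes = matrix.codes
    called = (codes >= 0).sum(axis=0)
    alt_alleles = (codes == 1).sum(axis=0) + 2 * (codes == 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = np.where(called > 0, alt_alleles / (2.0 * called), 0.0)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    keep = (called >= min_count) & (maf >= min_freq)
    return matrix.subset_variants(keep)


def _contingency_counts(
    codes: np.ndarray, phenotype: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant 2 x 3 contingency counts (phenotype x genotype class)."""
    y0 = phenotype == 0
    y1 = phenotype == 1
    n0 = np.stack([((codes == g) & y0[:, None]).sum(axis=0) for g in (0, 1, 2)])
    n1 = np.stack([((codes == g) & y1[:, None]).sum(axis=0) for g in (0, 1, 2)])
    return n0.astype(float), n1.astype(float)


def associate(
    matrix: GenotypeMatrix,
    phenotype: np.ndarray,
    method: str = "chi2_genotypic",
) -> list[AssociationResult]:
    """Test every variant for association with a binary phenotype.

    ``chi2_genotypic`` is the Pearson chi-square on the phenotype x
    genotype-class table; ``glm_dosage_F`` regresses the phenotype on
    genotype-class indicators and F-tests against the intercept-only model.
    Missing genotypes are dropped variant-wise; monomorphic variants are
    reported with statistic 0 and p = 1.
    """
    phenotype = np.asarray(phenotype)
    if phenotype.shape[0] != matrix.n_samples:
        raise ValueError(
            f"phenotype length {phenotype.shape[0]} != {matrix.n_samples} samples"
        )
    if not np.isin(phenotype, (0, 1)).all():
        raise ValueError("phenotype must be binary 0/1")
    if len(np.unique(phenotype)) < 2:
        raise ValueError(
            "all samples share one phenotype; association is undefined"
        )
    if method not in ("chi2_genotypic", "glm_dosage_F"):
        raise ValueError(f"unknown association method {method!r}")

    n0, n1 = _contingency_counts(matrix.codes, phenotype)
    col = n0 + n1  # genotype-class totals per variant
    n = col.sum(axis=0)
    row0, row1 = n0.sum(axis=0), n1.sum(axis=0)
    k = (col > 0).sum(axis=0)

    testable = (k >= 2) & (row0 > 0) & (row1 > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        if method == "chi2_genotypic":
            e0 = row0 * col / n
            e1 = row1 * col / n
            term0 = np.where(e0 > 0, (n0 - e0) ** 2 / e0, 0.0)
            term1 = np.where(e1 > 0, (n1 - e1) ** 2 / e1, 0.0)
            stat = np.where(testable, (term0 + term1).sum(axis=0), 0.0)
            df = np.maximum(k - 1, 0)
            p = np.where(testable, stats.chi2.sf(stat, np.maximum(df, 1)), 1.0)
        else:
            ybar = row1 / n
            mg = np.where(col > 0, n1 / np.where(col > 0, col, 1), 0.0)
            ssb = (col * (mg - ybar) ** 2).sum(axis=0)
            sst = n * ybar * (1.0 - ybar)
            ssw = np.maximum(sst - ssb, 0.0)
            df1 = np.maximum(k - 1, 1)
            df2 = np.maximum(n - k, 1)
            perfect = testable & (ssw <= 1e-12) & (ssb > 0)
            fstat = np.where(
                ssw > 1e-12, (ssb / df1) / (ssw / df2), np.inf
            )
            stat = np.where(testable, fstat, 0.0)
            df = np.maximum(k - 1, 0)
            p = np.where(testable, stats.f.sf(stat, df1, df2), 1.0)
            p = np.where(perfect, P_FLOOR, p)

    p = np.clip(p, P_FLOOR, 1.0)
    return [
        AssociationResult(
            variant=v,
            statistic=float(stat[i]),
            df=int(df[i]),
            p_value=float(p[i]),
            method=method,
        )
        for i, v in enumerate(matrix.variants)
    ]


def association_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Tabulate association results (one row per variant)."""
    return pd.DataFrame(
        {
            "variant_id": [r.variant_id for r in results],
            "chrom": [r.variant.chrom for r in results],
            "pos": [r.variant.pos for r in results],
            "type": [r.variant.vtype for r in results],
            "statistic": [r.statistic for r in results],
            "df": [r.df for r in results],
            "p_value": [r.p_value for r in results],
        }
    )


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    try:
        return (int(chrom.lstrip("C")), chrom)
    except ValueError:
        return (1 << 30, chrom)


def define_interval(
    results: list[AssociationResult], flank_bp: int = 200_000
) -> TargetInterval:
    """Define the target interval around the lowest-P variant.

    The peak is the variant with the smallest P value (ties broken by lowest
    chromosome then position). The interval bounds are the positions of the
    outermost scanned variants within ``flank_bp`` of the peak on the peak's
    chromosome, so endpoints are always marker positions.
    """
    if not results:
        raise ValueError("cannot define an interval from empty results")
    if any(not np.isfinite(r.p_value) for r in results):
        raise ValueError("association P values must be finite")
    peak = min(
        results,
        key=lambda r: (r.p_value, _chrom_sort_key(r.variant.chrom), r.variant.pos),
    )
    members = sorted(
        (
            r.variant
            for r in results
            if r.variant.chrom == peak.variant.chrom
            and abs(r.variant.pos - peak.variant.pos) <= flank_bp
        ),
        key=lambda v: v.pos,
    )
    return TargetInterval(
        chrom=peak.variant.chrom,
        peak_variant=peak.variant,
        flank_bp=flank_bp,
        start=members[0].pos,
        end=members[-1].pos,
        member_variants=members,
    )


def fold_coverage_per_sample(total_coverage_x: float, n_samples: int) -> float:
    """Per-sample fold coverage from a summed fold coverage."""
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    return total_coverage_x / n_samples


def raw_gb_to_coverage(total_gb: float, genome_mb: float, n_samples: int) -> float:
    """Per-sample fold coverage from raw gigabases and a genome size in Mb."""
    if genome_mb <= 0:
        raise ValueError("genome size must be positive")
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    return total_gb * 1000.0 / genome_mb / n_samples


def manhattan_plot(results: list[AssociationResult], path: str) -> None:
    """Write a Manhattan plot (-log10 P by position, colored by chromosome)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = association_frame(results)
    frame["key"] = [k[0] for k in map(_chrom_sort_key, frame["chrom"])]
    frame = frame.sort_values(["key", "pos"], kind="stable")
    fig, ax = plt.subplots(figsize=(10, 3.5))
    offset = 0
    ticks, labels = [], []
    for i, (chrom, sub) in enumerate(frame.groupby("key", sort=True)):
        x = sub["pos"].to_numpy() + offset
        ax.scatter(x, -np.log10(sub["p_value"]), s=4, color=f"C{i % 10}")
        ticks.append(offset + sub["pos"].max() / 2)
        labels.append(sub["chrom"].iloc[0])
        offset += sub["pos"].max()
    ax.set_xticks(ticks, labels, rotation=90, fontsize=7)
    ax.set_ylabel("-log10 P")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
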