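"""Dual variant screening and candidate-gene assignment.

Variants inside the mapped interval are filtered two independent ways:
against a diversity (germplasm) panel of normal-phenotype accessions, where
a causal recessive allele must be absent, and against a bulked-segregant
pool of recessive-phenotype individuals, where it must be (near-)fixed in
the reads. The intersection of the two retained sets is the candidate list;
candidates are then placed relative to annotated gene models and the gene
hosting the plurality of them is nominated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .simulate import PanelCallSet, PoolCounts
from .variants import VariantRecord, parse_marker_id

REGION_PRIORITY = ("exon", "intron", "5'-flanking", "3'-flanking", "intergenic")


@dataclass
class GeneAnnotation:
    """A stranded gene span with exon intervals, in genomic coordinates."""

    gene_id: str
    chrom: str
    strand: str  # "+" or "-"
    start: int  # 1-based inclusive
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.start > self.end:
            raise ValueError("gene start must not exceed end")


@dataclass
class VariantAnnotation:
    variant: VariantRecord
    region: str  # one of REGION_PRIORITY
    gene_id: str | None  # None for intergenic
    others: list[tuple[str, str]] = field(default_factory=list)  # overlapping genes


@dataclass
class PoolScreenResult:
    retained: list[VariantRecord]
    dropped: list[VariantRecord]
    unevaluable: list[VariantRecord]


@dataclass
class ScreenReport:
    """Record of the screening funnel: inputs, per-filter survivors, outcome."""

    input_variants: list[VariantRecord]
    panel_retained: list[VariantRecord]
    pool_retained: list[VariantRecord]
    pool_unevaluable: list[VariantRecord]
    intersection: list[VariantRecord]
    annotations: list[VariantAnnotation]
    nominated_gene: str | None

    def funnel(self) -> dict[str, int]:
        return {
            "input": len(self.input_variants),
            "panel_retained": len(self.panel_retained),
            "pool_retained": len(self.pool_retained),
            "intersection": len(self.intersection),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ann in self.annotations:
            rows.append(
                {
                    "variant_id": ann.variant.id,
                    "chrom": ann.variant.chrom,
                    "pos": ann.variant.pos,
                    "type": ann.variant.vtype,
                    "region": ann.region,
                    "gene": ann.gene_id or "-",
                }
            )
        return pd.DataFrame(
            rows, columns=["variant_id", "chrom", "pos", "type", "region", "gene"]
        )


def panel_screen(
    interval_variants: list[VariantRecord],
    panel: PanelCallSet,
    rule: str = "no-allele",
    on_missing_variant: str = "error",
) -> list[VariantRecord]:
    """Retain interval variants whose mutant allele no panel accession carries.

    Under ``rule="no-allele"`` any het or hom-mutant accession disqualifies a
    variant; under ``"no-homozygote"`` only hom-mutant accessions do (a
    heterozygous carrier of a recessive allele still shows the normal
    phenotype). Accessions with missing calls at a site never count as
    carriers. A variant absent from the panel index raises by default;
    ``on_missing_variant="retain"`` keeps it with a warning instead.
    """
    if on_missing_variant not in ("error", "retain"):
        raise ValueError("on_missing_variant must be 'error' or 'retain'")
    carriers = panel.carrier_counts(rule=rule)
    index = {v.id: i for i, v in enumerate(panel.variants)}
    retained = []
    for v in interval_variants:
        i = index.get(v.id)
        if i is None:
            if on_missing_variant == "error":
                raise KeyError(f"variant {v.id} is not covered by the panel call set")
            warnings.warn(
                f"variant {v.id} missing from panel; retained without evidence",
                stacklevel=2,
            )
            retained.append(v)
        elif carriers[i] == 0:
            retained.append(v)
    return retained


def pool_screen(
    interval_variants: list[VariantRecord],
    pool: PoolCounts,
    min_depth: int = 10,
    min_alt_fraction: float = 0.95,
) -> PoolScreenResult:
    """Retain variants fixed (or nearly so) for the mutant allele in the pool.

    A variant is retained when its pooled read depth is at least ``min_depth``
    and its alt-read fraction is at least ``min_alt_fraction``. Sites below
    the depth floor cannot be evaluated and are reported separately rather
    than silently dropped.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    if not 0.5 < min_alt_fraction <= 1.0:
        raise ValueError("min_alt_fraction must lie in (0.5, 1]")
    index = {v.id: i for i, v in enumerate(pool.variants)}
    depth = pool.depth
    retained, dropped, unevaluable = [], [], []
    for v in interval_variants:
        i = index.get(v.id)
        if i is None or depth[i] < min_depth:
            unevaluable.append(v)
        elif pool.alt_count[i] / depth[i] >= min_alt_fraction:
            retained.append(v)
        else:
            dropped.append(v)
    return PoolScreenResult(retained=retained, dropped=dropped, unevaluable=unevaluable)


def intersect_and_rank(
    panel_set: list[VariantRecord],
    pool_set: list[VariantRecord],
    p_values: dict[str, float] | None = None,
) -> list[VariantRecord]:
    """Intersect the two retained sets, ordered by ascending P then position."""
    pool_ids = {v.id for v in pool_set}
    common = [v for v in panel_set if v.id in pool_ids]
    p_values = p_values or {}

    def key(v: VariantRecord):
        chrom, pos = parse_marker_id(v.id)
        return (p_values.get(v.id, 1.0), chrom, pos)

    return sorted(common, key=key)


def _classify_one(
    v: VariantRecord, genes: list[GeneAnnotation], flank_bp: int
) -> list[tuple[str, str]]:
    """All (gene, region) assignments of a variant, unordered."""
    hits = []
    for g in genes:
        if g.chrom != v.chrom:
            continue
        if g.start <= v.pos <= g.end:
            in_exon = any(s <= v.pos <= e for s, e in g.exons)
            hits.append((g.gene_id, "exon" if in_exon else "intron"))
        elif 0 < g.start - v.pos <= flank_bp:
            hits.append((g.gene_id, "5'-flanking" if g.strand == "+" else "3'-flanking"))
        elif 0 < v.pos - g.end <= flank_bp:
            hits.append((g.gene_id, "3'-flanking" if g.strand == "+" else "5'-flanking"))
    return hits


def assign_to_genes(
    variants: list[VariantRecord],
    gene_models: list[GeneAnnotation],
    flank_bp: int = 10_000,
    p_values: dict[str, float] | None = None,
) -> tuple[list[VariantAnnotation], str | None]:
    """Place variants relative to gene models and nominate a candidate gene.

    Classification priority is exon > intron > 5'-flanking > 3'-flanking
    (flanks strand-aware within ``flank_bp``) > intergenic. The nominated
    gene hosts the most assigned (non-intergenic) variants; ties are broken
    by the gene containing the lowest-P variant.
    """
    p_values = p_values or {}
    annotations: list[VariantAnnotation] = []
    per_gene: dict[str, list[VariantRecord]] = {}
    for v in variants:
        hits = _classify_one(v, gene_models, flank_bp)
        if not hits:
            annotations.append(VariantAnnotation(v, "intergenic", None))
            continue
        hits.sort(key=lambda h: REGION_PRIORITY.index(h[1]))
        gene_id, region = hits[0]
        annotations.append(VariantAnnotation(v, region, gene_id, others=hits[1:]))
        per_gene.setdefault(gene_id, []).append(v)  # nominate on primary hits
    if not per_gene:
        return annotations, None
    nominated = min(
        per_gene,
        key=lambda g: (
            -len(per_gene[g]),
            min(p_values.get(v.id, 1.0) for v in per_gene[g]),
            g,
        ),
    )
    return annotations, nominated


def run_screen(
    interval_variants: list[VariantRecord],
    panel: PanelCallSet,
    pool: PoolCounts,
    gene_models: list[GeneAnnotation],
    min_depth: int = 10,
    min_alt_fraction: float = 0.95,
    panel_rule: str = "no-allele",
    flank_bp: int = 10_000,
    p_values: dict[str, float] | None = None,
) -> ScreenReport:
    """Run the full dual screen and gene assignment over interval variants."""
    panel_set = panel_screen(interval_variants, panel, rule=panel_rule)
    pool_res = pool_screen(
        interval_variants, pool, min_depth=min_depth, min_alt_fraction=min_alt_fraction
    )
    common = intersect_and_rank(panel_set, pool_res.retained, p_values)
    annotations, nominated = assign_to_genes(
        common, gene_models, flank_bp=flank_bp, p_values=p_values
    )
    return ScreenReport(
        input_variants=list(interval_variants),
        panel_retained=panel_set,
        pool_retained=pool_res.retained,
        pool_unevaluable=pool_res.unevaluable,
        intersection=common,
        annotations=annotations,
        nominated_gene=nominated,
    )
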