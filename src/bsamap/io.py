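"""File formats: VCF v4.2, GFF3, FASTA and phenotype TSV.

Readers go through the standard parsers (cyvcf2, gffutils, Biopython);
writers emit deterministic plain text so that a fixed seed yields
byte-identical output files.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .consequence import GeneModel
from .screen import GeneAnnotation
from .simulate import PanelCallSet, PoolCounts
from .variants import MISSING, GenotypeMatrix, VariantRecord

_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
_FROM_GT_TYPE = {0: 0, 1: 1, 3: 2, 2: MISSING}  # cyvcf2 gt_types encoding


def _vcf_header(variants: list[VariantRecord], sample_ids: list[str], fmt: str) -> str:
    contigs = []
    seen = set()
    for v in variants:
        if v.chrom not in seen:
            seen.add(v.chrom)
            contigs.append(v.chrom)
    lines = ["##fileformat=VCFv4.2", "##source=bsamap"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if "AD" in fmt:
        lines.append(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">'
        )
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids)
    )
    return "\n".join(lines) + "\n"


def write_genotype_vcf(
    path: str | os.PathLike,
    matrix: GenotypeMatrix,
    include_parents: bool = False,
) -> None:
    """Write a multi-sample GT VCF; optionally prepend the two inbred parents.

    The wild parent is homozygous reference and the mutant parent homozygous
    alternate at every variant, matching the biparental-cross model.
    """
    samples = (["P1_cl", "P2_CL"] if include_parents else []) + list(matrix.sample_ids)
    with open(path, "w") as fh:
        fh.write(_vcf_header(matrix.variants, samples, "GT"))
        for j, v in enumerate(matrix.variants):
            cells = (["1/1", "0/0"] if include_parents else []) + [
                _GT[int(c)] for c in matrix.codes[:, j]
            ]
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(cells)
                + "\n"
            )


def read_genotype_vcf(
    path: str | os.PathLike, drop_samples: tuple[str, ...] = ("P1_cl", "P2_CL")
) -> GenotypeMatrix:
    """Read a multi-sample GT VCF into a GenotypeMatrix (parents dropped)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    keep = [i for i, s in enumerate(vcf.samples) if s not in drop_samples]
    sample_ids = [vcf.samples[i] for i in keep]
    variants, rows = [], []
    for rec in vcf:
        if not rec.ALT:
            raise ValueError(f"{path}: record at {rec.CHROM}:{rec.POS} has no ALT allele")
        variants.append(VariantRecord(rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
        rows.append([_FROM_GT_TYPE[int(t)] for t in rec.gt_types[keep]])
    codes = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.zeros((len(sample_ids), 0), dtype=np.int8)
    )
    return GenotypeMatrix(sample_ids=sample_ids, variants=variants, codes=codes)


def write_pool_vcf(path: str | os.PathLike, pool: PoolCounts) -> None:
    """Write pooled allele counts as a single-sample VCF with AD fields."""
    with open(path, "w") as fh:
        fh.write(_vcf_header(pool.variants, ["BSA_pool"], "GT:AD"))
        for j, v in enumerate(pool.variants):
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\tPASS\t.\t"
                f"GT:AD\t./.:{pool.ref_count[j]},{pool.alt_count[j]}\n"
            )


def read_pool_vcf(path: str | os.PathLike) -> PoolCounts:
    from cyvcf2 import VCF

    variants, refs, alts = [], [], []
    for rec in VCF(str(path)):
        ad = rec.format("AD")
        if ad is None:
            raise ValueError(f"{path}: record {rec.CHROM}:{rec.POS} lacks the AD field")
        variants.append(VariantRecord(rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
        refs.append(max(int(ad[0][0]), 0))
        alts.append(max(int(ad[0][1]), 0))
    return PoolCounts(
        variants=variants,
        ref_count=np.array(refs, dtype=np.int64),
        alt_count=np.array(alts, dtype=np.int64),
    )


def write_panel_vcf(path: str | os.PathLike, panel: PanelCallSet) -> None:
    with open(path, "w") as fh:
        fh.write(_vcf_header(panel.variants, panel.accession_ids, "GT"))
        for j, v in enumerate(panel.variants):
            cells = [_GT[int(c)] for c in panel.codes[:, j]]
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(cells)
                + "\n"
            )


def read_panel_vcf(path: str | os.PathLike) -> PanelCallSet:
    gm = read_genotype_vcf(path, drop_samples=())
    return PanelCallSet(
        accession_ids=gm.sample_ids, variants=gm.variants, codes=gm.codes
    )


def write_phenotypes(path: str | os.PathLike, phenotypes: pd.DataFrame) -> None:
    phenotypes[["sample_id", "phenotype"]].to_csv(path, sep="\t", index=False)


def read_phenotypes(
    path: str | os.PathLike, expected_samples: list[str] | None = None
) -> pd.DataFrame:
    """Read the phenotype TSV and verify it matches the genotyped samples."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "phenotype"):
        if col not in df.columns:
            raise ValueError(f"{path}: phenotype table lacks the {col!r} column")
    if expected_samples is not None:
        have = set(df["sample_id"])
        want = set(expected_samples)
        if have != want:
            extra = sorted(have - want)
            missing = sorted(want - have)
            parts = []
            if extra:
                parts.append(f"samples absent from the VCF: {', '.join(extra[:5])}")
            if missing:
                parts.append(f"samples without phenotype: {', '.join(missing[:5])}")
            raise ValueError(f"{path}: phenotype/VCF sample mismatch ({'; '.join(parts)})")
        df = df.set_index("sample_id").loc[expected_samples].reset_index()
    return df


# ---------------------------------------------------------------------------
# FASTA / GFF3
# ---------------------------------------------------------------------------


def write_fasta(path: str | os.PathLike, records: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name in records:
            fh.write(f">{name}\n")
            seq = records[name]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def annotation_of(model: GeneModel) -> GeneAnnotation:
    """Genomic-coordinate annotation of an anchored gene model."""
    if model.genomic_start <= 0:
        raise ValueError(f"gene {model.gene_id} is not genomically anchored")
    g0 = model.genomic_start
    start, end = g0, g0 + model.length - 1
    if model.strand == "+":
        exons = [(g0 + s - 1, g0 + e - 1) for s, e in model.exons]
    else:
        exons = sorted((end - e + 1, end - s + 1) for s, e in model.exons)
    return GeneAnnotation(
        gene_id=model.gene_id,
        chrom=model.chrom,
        strand=model.strand,
        start=start,
        end=end,
        exons=exons,
    )


def write_gff3(
    path: str | os.PathLike, annotations: list[GeneAnnotation], cds: dict[str, list[tuple[int, int]]] | None = None
) -> None:
    """Write gene/mRNA/exon (and optional CDS) features as GFF3."""
    cds = cds or {}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in annotations:
            fh.write(
                f"{g.chrom}\t.\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            mrna = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\t.\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\t.\texon\t{s}\t{e}\t.\t{g.strand}\t.\tParent={mrna}\n"
                )
            for s, e in cds.get(g.gene_id, []):
                fh.write(
                    f"{g.chrom}\t.\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\tParent={mrna}\n"
                )


def read_gene_annotations(path: str | os.PathLike) -> list[GeneAnnotation]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    out = []
    for gene in db.features_of_type("gene"):
        exons = sorted(
            (f.start, f.end) for f in db.children(gene, featuretype="exon")
        )
        out.append(
            GeneAnnotation(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                start=gene.start,
                end=gene.end,
                exons=exons or [(gene.start, gene.end)],
            )
        )
    out.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return out


def read_gene_model(
    fasta_path: str | os.PathLike, gff_path: str | os.PathLike, gene_id: str
) -> GeneModel:
    """Assemble a strand-aware gene model from a genome FASTA and GFF3.

    Exon and CDS features of the gene are converted to gene-relative 1-based
    coordinates on the coding strand; the CDS start is taken from the
    5'-most CDS feature.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    gene = db[gene_id]
    genome = read_fasta(fasta_path)
    if gene.seqid not in genome:
        raise ValueError(f"sequence {gene.seqid!r} absent from {fasta_path}")
    region = genome[gene.seqid][gene.start - 1 : gene.end]
    exons = sorted((f.start, f.end) for f in db.children(gene, featuretype="exon"))
    cds = sorted((f.start, f.end) for f in db.children(gene, featuretype="CDS"))
    if not exons:
        raise ValueError(f"gene {gene_id} has no exon features")
    if not cds:
        raise ValueError(f"gene {gene_id} has no CDS features; cannot place the ORF")
    if gene.strand == "+":
        seq = region
        rel = lambda x: x - gene.start + 1
        rel_exons = [(rel(s), rel(e)) for s, e in exons]
        cds_start = rel(cds[0][0])
    else:
        seq = str(Seq(region).reverse_complement())
        rel = lambda x: gene.end - x + 1
        rel_exons = sorted((rel(e), rel(s)) for s, e in exons)
        cds_start = rel(cds[-1][1])
    return GeneModel(
        gene_id=gene_id,
        sequence=seq,
        exons=rel_exons,
        cds_start_gene=cds_start,
        chrom=gene.seqid,
        strand=gene.strand,
        genomic_start=gene.start,
    )


def model_to_gff3_records(model: GeneModel) -> tuple[GeneAnnotation, dict[str, list[tuple[int, int]]]]:
    """Genomic annotation plus CDS intervals for writing a model to GFF3."""
    ann = annotation_of(model)
    from .consequence import translate_orf

    tr = translate_orf(model.transcript(), model.cds_start)
    cds_len = tr.orf_length_nt
    if model.strand != "+":  # minus-strand CDS emission is not needed here
        return ann, {}
    g0 = model.genomic_start
    cds_spans = []
    tpos = 0
    for s, e in model.exons:
        exon_len = e - s + 1
        t_lo, t_hi = tpos + 1, tpos + exon_len
        lo = max(t_lo, model.cds_start)
        hi = min(t_hi, model.cds_start + cds_len - 1)
        if lo <= hi:
            gs = s + (lo - t_lo)
            ge = s + (hi - t_lo)
            cds_spans.append((g0 + gs - 1, g0 + ge - 1))
        tpos += exon_len
    return ann, {model.gene_id: cds_spans}
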