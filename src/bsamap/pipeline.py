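"""End-to-end orchestration: simulation -> inheritance -> scan -> screen -> consequence.

``run_all`` executes the whole gene-cloning workflow on simulated inputs and
writes per-stage files plus a single ``summary.json``. Every output carries
the config hash and seed; a fixed seed reproduces the bundle byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

from . import io as pio
from .association import (
    associate,
    association_frame,
    define_interval,
    qc_filter,
)
from .config import PipelineConfig
from .consequence import characterize
from .fixtures import KAN1_DOMAINS, KAN1_EVENT, make_kan1_like_gene
from .screen import GeneAnnotation, run_screen
from .segregation import SegregationObservation, classify_inheritance
from .simulate import (
    causal_index,
    phenotype_to_binary,
    simulate_f2,
    simulate_inheritance_study,
    simulate_panel,
    simulate_pool,
)

log = logging.getLogger("bsamap")

#: Gene-relative coordinate of the first edited base in the target gene; the
#: causal variant at genomic position P sits at gene position 1131 of a gene
#: anchored at P - 1130.
_GENE_OFFSET = KAN1_EVENT.start - 1


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _decoy_genes(chrom: str, causal_pos: int, chrom_length: int) -> list[GeneAnnotation]:
    """Deterministic single-exon decoy genes flanking the causal region."""
    genes = []
    k = 1
    for offset in (-480_000, -360_000, -240_000, -120_000, 120_000, 240_000, 360_000, 480_000):
        start = causal_pos + offset
        if start < 1 or start + 5_000 > chrom_length:
            continue
        genes.append(
            GeneAnnotation(
                gene_id=f"{chrom}.d{k}",
                chrom=chrom,
                strand="+" if offset > 0 else "-",
                start=start,
                end=start + 5_000,
                exons=[(start, start + 5_000)],
            )
        )
        k += 1
    return genes


def run_all(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage on simulated data and write the result bundle.

    Returns the summary dictionary (also written to ``summary.json``).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.config_hash(), "seed": config.seed}

    # --- inheritance -------------------------------------------------------
    stage = "segregation"
    try:
        tallies = simulate_inheritance_study(config.seed + 3)
        verdict = classify_inheritance(
            f1_counts=[tallies["F1"]],
            bc1=SegregationObservation(list(tallies["BC1"]), [1, 1], label="BC1"),
            f2=SegregationObservation(list(tallies["F2"]), [3, 1], label="F2"),
        )
        log.info(
            "segregation: F1 %s, BC1 %s (chi2=%.2f), F2 %s (chi2=%.2f) -> %s",
            tallies["F1"], tallies["BC1"], verdict.bc1.chi_square,
            tallies["F2"], verdict.f2.chi_square, verdict.verdict,
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # --- simulate the mapping population -----------------------------------
    stage = "simulate"
    try:
        gm, phenotypes, variants = simulate_f2(config.cross)
        ci = causal_index(variants, config.cross)
        causal = variants[ci]
        pio.write_genotype_vcf(out / "f2.vcf", gm, include_parents=True)
        pio.write_phenotypes(out / "phenotypes.tsv", phenotypes)
        _write_json(
            out / "truth.json",
            {**meta, "causal_variant": causal.id, "design": dataclasses.asdict(config.cross)},
        )
        log.info("simulate: %d F2 x %d variants, causal %s", gm.n_samples, gm.n_variants, causal.id)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # --- association scan ---------------------------------------------------
    stage = "scan"
    try:
        if gm.n_samples == 0:
            raise ValueError("empty population: no F2 individuals to scan")
        filtered = qc_filter(gm, min_count=config.qc_min_count, min_freq=config.qc_min_freq)
        results = associate(filtered, phenotype_to_binary(phenotypes), method=config.assoc_method)
        association_frame(results).to_csv(out / "scan.tsv", sep="\t", index=False)
        interval = define_interval(results, flank_bp=config.flank_bp)
        _write_json(
            out / "interval.json",
            {
                **meta,
                "chrom": interval.chrom,
                "peak_variant": interval.peak_variant.id,
                "peak_p": min(r.p_value for r in results),
                "start": interval.start,
                "end": interval.end,
                "flank_bp": interval.flank_bp,
                "n_members": len(interval.member_variants),
            },
        )
        log.info(
            "scan: %d variants after QC (of %d); peak %s; interval %s:%d-%d (%d members)",
            filtered.n_variants, gm.n_variants, interval.peak_variant.id,
            interval.chrom, interval.start, interval.end, len(interval.member_variants),
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # --- dual screen --------------------------------------------------------
    stage = "screen"
    try:
        members = interval.member_variants
        member_index = [i for i, v in enumerate(variants) if interval.contains(v.chrom, v.pos)]
        panel = simulate_panel(config.panel, members, causal.id)
        pio.write_panel_vcf(out / "panel.vcf", panel)
        # the recessive bulk comes from a larger test population, as a
        # 130-individual F2 holds only ~32 recessive homozygotes
        test_design = dataclasses.replace(
            config.cross, n_f2=config.test_population_n_f2, seed=config.cross.seed + 4
        )
        test_gm, test_phen, _ = simulate_f2(test_design, variants=variants)
        pool = simulate_pool(
            config.pool, test_gm.subset_variants(member_index), test_phen
        )
        pio.write_pool_vcf(out / "pool.vcf", pool)

        target_gene = make_kan1_like_gene(
            gene_id=f"{causal.chrom}.460",
            chrom=causal.chrom,
            genomic_start=config.cross.causal_pos - _GENE_OFFSET,
        )
        genes = [pio.annotation_of(target_gene)] + _decoy_genes(
            causal.chrom, config.cross.causal_pos, config.cross.chrom_length_bp
        )
        ann, cds = pio.model_to_gff3_records(target_gene)
        pio.write_gff3(out / "genes.gff3", genes, cds=cds)
        # gene-level FASTA/GFF3 so the consequence engine can be re-run on
        # the bundle without the (never materialised) chromosome sequence
        gene_level = dataclasses.replace(
            target_gene, chrom=target_gene.gene_id, genomic_start=1
        )
        ann_g, cds_g = pio.model_to_gff3_records(gene_level)
        pio.write_fasta(
            out / "target_gene.fa", {target_gene.gene_id: target_gene.sequence}
        )
        pio.write_gff3(out / "target_gene.gff3", [ann_g], cds=cds_g)

        p_values = {r.variant_id: r.p_value for r in results}
        report = run_screen(
            members, panel, pool, genes,
            min_depth=config.pool_min_depth,
            min_alt_fraction=config.pool_min_alt_fraction,
            panel_rule=config.panel_rule,
            flank_bp=config.gene_flank_bp,
            p_values=p_values,
        )
        report.to_frame().to_csv(out / "screen.tsv", sep="\t", index=False)
        _write_json(
            out / "screen.json",
            {
                **meta,
                "funnel": report.funnel(),
                "intersection": [v.id for v in report.intersection],
                "nominated_gene": report.nominated_gene,
            },
        )
        log.info(
            "screen: %(input)d interval variants -> %(panel_retained)d after panel "
            "screen, %(pool_retained)d after pool screen, %(intersection)d in common",
            report.funnel(),
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # --- consequence --------------------------------------------------------
    stage = "consequence"
    try:
        cons = characterize(target_gene, KAN1_EVENT, KAN1_DOMAINS, policy=config.splice_policy)
        _write_json(
            out / "consequence.json",
            {
                **meta,
                "gene": cons.gene_id,
                "classification": cons.classification,
                "wild_protein_aa": cons.wild_protein_length_aa,
                "mutant_protein_aa": cons.mutant_protein_length_aa,
                "mutant_orf_nt": cons.mutant_orf_length_nt,
                "frameshift_cdna_pos": cons.frameshift_cdna_pos,
                "first_altered_residue": cons.first_altered_residue,
                "premature_stop_residue": cons.premature_stop_residue,
                "premature_stop_codon": cons.premature_stop_codon,
                "retained_introns": cons.retained_introns,
                "domains": [
                    {"name": d.name, "start": d.start, "end": d.end, "status": d.status}
                    for d in cons.domain_overlaps
                ],
            },
        )
        log.info(
            "consequence: %s -> %d aa (%s), stop at residue %s",
            cons.gene_id, cons.mutant_protein_length_aa, cons.classification,
            cons.premature_stop_residue,
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    summary = {
        **meta,
        "config": config.to_dict(),
        "segregation": {
            "verdict": verdict.verdict,
            "bc1_chi2": round(verdict.bc1.chi_square, 4),
            "f2_chi2": round(verdict.f2.chi_square, 4),
        },
        "scan": {
            "peak_variant": interval.peak_variant.id,
            "interval": [interval.chrom, interval.start, interval.end],
            "n_members": len(interval.member_variants),
        },
        "screen": {
            "funnel": report.funnel(),
            "nominated_gene": report.nominated_gene,
            "candidates": [v.id for v in report.intersection],
        },
        "consequence": {
            "classification": cons.classification,
            "mutant_protein_aa": cons.mutant_protein_length_aa,
            "premature_stop_residue": cons.premature_stop_residue,
        },
        "truth": {
            "causal_variant": causal.id,
            "in_interval": interval.contains(causal.chrom, causal.pos),
            "in_intersection": causal.id in {v.id for v in report.intersection},
            "top_candidate": bool(report.intersection)
            and report.intersection[0].id == causal.id,
        },
    }
    _write_json(out / "summary.json", summary)
    return summary


def run_demo(outdir: str | Path, seed: int = 42) -> dict:
    """One-command demonstration on the default simulated study design."""
    return run_all(PipelineConfig().with_seed(seed), outdir)


def _recovery_replicate(config: PipelineConfig) -> tuple[bool, bool, bool]:
    """One in-memory scan -> interval -> dual-screen replicate.

    Returns (causal in interval, causal in intersection, causal top-ranked).
    """
    gm, phenotypes, variants = simulate_f2(config.cross)
    causal = variants[causal_index(variants, config.cross)]
    filtered = qc_filter(gm, min_count=config.qc_min_count, min_freq=config.qc_min_freq)
    results = associate(filtered, phenotype_to_binary(phenotypes), method=config.assoc_method)
    interval = define_interval(results, flank_bp=config.flank_bp)
    if not interval.contains(causal.chrom, causal.pos):
        return False, False, False
    members = interval.member_variants
    member_index = [i for i, v in enumerate(variants) if interval.contains(v.chrom, v.pos)]
    panel = simulate_panel(config.panel, members, causal.id)
    test_design = dataclasses.replace(
        config.cross, n_f2=config.test_population_n_f2, seed=config.cross.seed + 4
    )
    test_gm, test_phen, _ = simulate_f2(test_design, variants=variants)
    pool = simulate_pool(config.pool, test_gm.subset_variants(member_index), test_phen)
    target_gene = make_kan1_like_gene(
        gene_id=f"{causal.chrom}.460",
        chrom=causal.chrom,
        genomic_start=config.cross.causal_pos - _GENE_OFFSET,
    )
    genes = [pio.annotation_of(target_gene)] + _decoy_genes(
        causal.chrom, config.cross.causal_pos, config.cross.chrom_length_bp
    )
    report = run_screen(
        members, panel, pool, genes,
        min_depth=config.pool_min_depth,
        min_alt_fraction=config.pool_min_alt_fraction,
        panel_rule=config.panel_rule,
        flank_bp=config.gene_flank_bp,
        p_values={r.variant_id: r.p_value for r in results},
    )
    in_set = causal.id in {v.id for v in report.intersection}
    top = bool(report.intersection) and report.intersection[0].id == causal.id
    return True, in_set, top


def recovery_study(
    n_replicates: int, base_seed: int = 0, config: PipelineConfig | None = None
) -> dict:
    """Replicate the full mapping workflow and count causal-variant recovery.

    Each replicate re-simulates the cross, panel, test population and pool
    under a distinct seed, runs scan -> interval -> dual screen, and records
    whether the planted causal variant survives to the final intersection
    and whether it ranks first among the candidates.
    """
    base = config or PipelineConfig()
    n_interval = n_recovered = n_top = 0
    for i in range(n_replicates):
        in_interval, in_set, top = _recovery_replicate(base.with_seed(base_seed + i))
        n_interval += in_interval
        n_recovered += in_set
        n_top += top
    return {
        "n_replicates": n_replicates,
        "n_in_interval": n_interval,
        "n_recovered": n_recovered,
        "n_top_ranked": n_top,
    }
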