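"""Synthetic, deterministically generated fixtures.

Nothing here is a real genomic sequence: both builders construct synthetic
stand-ins that are structurally equivalent to the biological objects they
emulate (a KANADI-like 6-exon gene with a splice-donor-destroying
replacement, and a mapped-interval screening scenario with its diversity
panel, pooled read counts and gene annotation), so every downstream stage is
testable without any download.
"""

from __future__ import annotations

import numpy as np

from .consequence import GeneModel, SpliceVariantEvent
from .screen import GeneAnnotation
from .simulate import PanelCallSet, PoolCounts
from .variants import VariantRecord

_SENSE_BY_AA: dict[str, list[str]] = {}
_SENSE_CODONS: list[str] = []


def _codon_tables() -> tuple[list[str], dict[str, list[str]]]:
    global _SENSE_CODONS, _SENSE_BY_AA
    if not _SENSE_CODONS:
        from Bio.Data import CodonTable

        fwd = CodonTable.unambiguous_dna_by_id[1].forward_table
        _SENSE_CODONS = sorted(fwd)
        for codon, aa in fwd.items():
            _SENSE_BY_AA.setdefault(aa, []).append(codon)
        for v in _SENSE_BY_AA.values():
            v.sort()
    return _SENSE_CODONS, _SENSE_BY_AA


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


#: The splice-donor-destroying replacement: 20 nt (spanning the last 3 nt of
#: exon 2 and the first 17 nt of intron 2, including the GT donor) replaced
#: by 6 nt.
KAN1_EVENT = SpliceVariantEvent(start=1131, end=1150, replacement="TCTTTG")

#: MYB DNA-binding domain span in wild-protein residue coordinates.
KAN1_DOMAINS = [("MYB", 271, 323)]


def make_kan1_like_gene(
    gene_id: str = "C29.460",
    chrom: str = "C29",
    genomic_start: int = 0,
    seed: int = 20181122,
) -> GeneModel:
    """Build the synthetic KANADI-like 6-exon gene fixture.

    The wild-type gene encodes a 440-aa protein (ORF 1323 nt incl. stop)
    over 6 exons / 5 introns with a 100-nt 5'UTR. Exon 2 ends at gene
    position 1133 and intron 2's GT donor sits at 1134-1135, so gene
    positions 1131-1150 read CAGGTAGCTATGTATATGCA. Applying ``KAN1_EVENT``
    (that 20-mer -> TCTTTG) destroys the donor; the retained intron 2 was
    engineered so the mutant reading frame diverges at residue 295 (ORF
    position 883), runs through five substituted residues and hits a TAA
    terminator at residue 300, leaving a 299-aa product whose ORF is 900 nt.
    """
    rng = np.random.default_rng(seed)
    sense, by_aa = _codon_tables()

    def pick(exclude_aa: str | None = None) -> str:
        pool = sense if exclude_aa is None else [
            c for c in sense if c not in by_aa.get(exclude_aa, [])
        ]
        return pool[rng.integers(0, len(pool))]

    codons = [pick() for _ in range(440)]
    codons[0] = "ATG"
    codons[294] = "CAG"  # residue 295: exon 2 must end ...CAG before the donor
    # keep the five mutant-frame residues (S,L,N,G,C at 295-299) all different
    # from wild so the substituted run spans exactly residues 295-299
    for idx, mut_aa in zip((295, 296, 297, 298), "LNGC"):
        codons[idx] = pick(exclude_aa=mut_aa)
    cds = "".join(codons) + "TAA"  # 1323 nt

    utr5 = _random_seq(rng, 100)
    utr3 = _random_seq(rng, 120)

    def intron(total: int, interior: str = "") -> str:
        fill = total - 4 - len(interior)
        if fill < 0:
            raise ValueError("intron too short for its fixed interior")
        return "GT" + interior + _random_seq(rng, fill) + "AG"

    # intron 2 interior after its 17 fixed nt: the 9 nt coding the mutant
    # residues 297-299 (N, G, C) and the TAA read in the shifted frame
    intron2 = "GTAGCTATGTATATGCA" + "AATGGATGC" + "TAA" + _random_seq(rng, 369) + "AG"
    assert len(intron2) == 400

    segments = [
        utr5 + cds[0:800],        # exon 1: 1..900
        intron(148),              # intron 1: 901..1048
        cds[800:885],             # exon 2: 1049..1133 (ends ...CAG)
        intron2,                  # intron 2: 1134..1533 (donor GT at 1134)
        cds[885:1035],            # exon 3: 1534..1683
        intron(200),              # intron 3
        cds[1035:1155],           # exon 4
        intron(150),              # intron 4
        cds[1155:1245],           # exon 5
        intron(180),              # intron 5
        cds[1245:1323] + utr3,    # exon 6 (75 nt CDS + TAA + 3'UTR)
    ]
    sequence = "".join(segments)
    exons = []
    pos = 1
    for i, seg in enumerate(segments):
        if i % 2 == 0:
            exons.append((pos, pos + len(seg) - 1))
        pos += len(seg)
    return GeneModel(
        gene_id=gene_id,
        sequence=sequence,
        exons=exons,
        cds_start_gene=101,
        chrom=chrom,
        strand="+",
        genomic_start=genomic_start,
    )


# ---------------------------------------------------------------------------
# Screening-funnel fixture
# ---------------------------------------------------------------------------

#: The six interval markers private to the mutant line, one intergenic and
#: five in or near a single gene. Positions follow the marker-id convention.
SIX_CANDIDATE_POSITIONS = (6674693, 6717525, 6721553, 6721558, 6721563, 6721565)
FUNNEL_INTERVAL = (6522236, 6918901)
FUNNEL_PEAK = 6721563
TARGET_GENE_ID = "C29.460"


def make_funnel_fixture(seed: int = 7, n_accessions: int = 822) -> dict:
    """Build a mapped-interval screening scenario with known truth.

    90 variants span the interval; exactly 6 (the candidate markers) have no
    mutant-allele carrier in the diversity panel, 42 (a superset of the 6)
    are near-fixed for the alt allele in the pooled reads, and of the 6
    candidates five fall in the 5'-flanking/exon/intron territory of one
    gene while one is intergenic.
    """
    rng = np.random.default_rng(seed)
    lo, hi = FUNNEL_INTERVAL
    others: set[int] = set()
    while len(others) < 82:  # 84 background markers incl. the two endpoints
        p = int(rng.integers(lo + 1, hi))
        if p not in SIX_CANDIDATE_POSITIONS:
            others.add(p)
    positions = sorted({lo, hi} | others | set(SIX_CANDIDATE_POSITIONS))
    assert len(positions) == 90
    six = set(SIX_CANDIDATE_POSITIONS)
    variants = [
        VariantRecord(
            "C29",
            p,
            "CAGGTAGCTATGTATATGCA" if p == FUNNEL_PEAK else "A",
            "TCTTTG" if p == FUNNEL_PEAK else "G",
        )
        for p in positions
    ]

    # panel: every non-candidate variant has at least one carrier accession
    codes = np.zeros((n_accessions, len(variants)), dtype=np.int8)
    for j, v in enumerate(variants):
        if v.pos in six:
            continue
        carriers = rng.random(n_accessions) < 0.3
        carriers[int(rng.integers(0, n_accessions))] = True
        codes[carriers, j] = rng.integers(1, 3, size=int(carriers.sum()))
    panel = PanelCallSet(
        accession_ids=[f"M{i + 1}" for i in range(n_accessions)],
        variants=list(variants),
        codes=codes,
    )

    # pool: the 6 candidates plus 36 linked background markers are fixed in
    # the recessive bulk; the rest sit near the unlinked expectation
    non_candidates = [j for j, v in enumerate(variants) if v.pos not in six]
    fixed_extra = set(rng.choice(non_candidates, size=36, replace=False).tolist())
    depth = np.full(len(variants), 40, dtype=np.int64)
    alt = np.where(
        [v.pos in six or j in fixed_extra for j, v in enumerate(variants)],
        depth,
        (depth * 0.6).astype(np.int64),
    )
    pool = PoolCounts(variants=list(variants), ref_count=depth - alt, alt_count=alt)

    genes = [
        GeneAnnotation("C29.300", "C29", "+", 6_550_000, 6_555_000,
                       exons=[(6_550_000, 6_555_000)]),
        GeneAnnotation(TARGET_GENE_ID, "C29", "+", 6_721_000, 6_727_835,
                       exons=[(6_721_000, 6_721_560), (6_722_401, 6_727_835)]),
        GeneAnnotation("C29.520", "C29", "-", 6_800_000, 6_805_000,
                       exons=[(6_800_000, 6_805_000)]),
    ]

    p_values = {
        v.id: (abs(v.pos - FUNNEL_PEAK) + 1) * 1e-25 for v in variants
    }
    return {
        "variants": variants,
        "panel": panel,
        "pool": pool,
        "genes": genes,
        "p_values": p_values,
        "expected_panel_retained": [v for v in variants if v.pos in six],
        "expected_pool_retained_n": 42,
        "target_gene": TARGET_GENE_ID,
    }
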