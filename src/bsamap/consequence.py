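"""Molecular consequence of gene-level sequence edits, centred on splice loss.

The motivating event class: a deletion (or unbalanced replacement) that
removes the GT splice-donor dinucleotide of an intron. Without its donor the
intron can no longer be excised, so the default model retains it in the
mature transcript up to the next intact acceptor; intronic sequence then
enters the reading frame, typically shifting it (when the retained length
plus the net indel is not a multiple of 3) and raising a premature stop.
The engine rebuilds the mutant mature transcript, translates both alleles,
locates the first altered codon, the substituted residue run and the new
terminator, and reports which annotated protein domains are lost or
disrupted by the truncation.

Coordinates are gene-relative, 1-based, inclusive, on the coding strand
throughout; the reported frameshift position is the first nucleotide of the
first altered codon in ORF coordinates (3*(first altered residue - 1) + 1).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_TABLE.stop_codons)
DONOR = "GT"
ACCEPTOR = "AG"


@dataclass
class GeneModel:
    """A gene: its sequence (coding strand, 5'->3') and exon structure."""

    gene_id: str
    sequence: str
    exons: list[tuple[int, int]]  # gene-relative 1-based inclusive, 5'->3'
    cds_start_gene: int  # gene coordinate of the A of the start ATG
    chrom: str = ""
    strand: str = "+"
    genomic_start: int = 0  # genomic coordinate of gene position 1 (0 = unanchored)
    noncanonical: bool = False  # skip GT..AG intron boundary validation
    #: provenance of a derived (mutant) model: the wild-type it was edited
    #: from and the cumulative edit, so that further edits compose against
    #: the wild structure (an edit that undoes a donor loss re-splices)
    base: "GeneModel | None" = field(default=None, repr=False, compare=False)
    base_event: "SpliceVariantEvent | None" = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        L = len(self.sequence)
        prev_end = 0
        for s, e in self.exons:
            if not (1 <= s <= e <= L):
                raise ValueError(f"exon ({s},{e}) outside gene of length {L}")
            if s <= prev_end:
                raise ValueError("exons must be ordered 5'->3' and non-overlapping")
            prev_end = e
        if not self.noncanonical:
            for s, e in self.introns():
                donor = self.sequence[s - 1 : s + 1]
                acceptor = self.sequence[e - 2 : e]
                if donor != DONOR or acceptor != ACCEPTOR:
                    raise ValueError(
                        f"intron {s}-{e} boundaries {donor}..{acceptor} are not "
                        "GT..AG; pass noncanonical=True to accept"
                    )
        self.transcript_pos(self.cds_start_gene)  # must be exonic
        if self.transcript()[self.cds_start - 1 : self.cds_start + 2] != "ATG":
            raise ValueError("CDS start does not sit on an ATG in the mature transcript")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        ]

    def transcript(self) -> str:
        return "".join(self.sequence[s - 1 : e] for s, e in self.exons)

    def transcript_pos(self, gene_pos: int) -> int:
        """Mature-transcript coordinate of an exonic gene position."""
        offset = 0
        for s, e in self.exons:
            if s <= gene_pos <= e:
                return offset + (gene_pos - s) + 1
            offset += e - s + 1
        raise ValueError(f"gene position {gene_pos} is intronic or outside exons")

    @property
    def cds_start(self) -> int:
        return self.transcript_pos(self.cds_start_gene)


@dataclass
class SpliceVariantEvent:
    """Replacement of a gene-relative span by a (possibly empty) sequence."""

    start: int  # 1-based inclusive
    end: int
    replacement: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid event span {self.start}-{self.end}")
        if any(c not in "ACGT" for c in self.replacement.upper()):
            raise ValueError("replacement must contain only A/C/G/T")
        self.replacement = self.replacement.upper()

    @property
    def net_change(self) -> int:
        return len(self.replacement) - (self.end - self.start + 1)


@dataclass
class TranslationResult:
    protein: str
    stop_codon: str | None
    stop_residue: int | None  # residue index of the terminator (= len + 1)
    orf_length_nt: int
    non_stop: bool


@dataclass
class ProteinDiff:
    first_diff: int | None  # 1-based residue index, None if identical prefix
    wild_run: str
    mutant_run: str
    truncation: int  # wild length - mutant length (negative if elongating)
    classification: str  # synonymous-length | truncating | elongating


@dataclass
class DomainOverlap:
    name: str
    start: int
    end: int
    status: str  # lost | disrupted | intact


@dataclass
class ConsequenceReport:
    gene_id: str
    wild_gene_length_bp: int
    mutant_gene_length_bp: int
    wild_orf_length_nt: int
    mutant_orf_length_nt: int
    wild_protein_length_aa: int
    mutant_protein_length_aa: int
    frameshift_cdna_pos: int | None
    first_altered_residue: int | None
    wild_run: str
    mutant_run: str
    premature_stop_codon: str | None
    premature_stop_residue: int | None
    classification: str
    retained_introns: list[int]
    domain_overlaps: list[DomainOverlap] = field(default_factory=list)


def translate_orf(transcript: str, cds_start: int) -> TranslationResult:
    """Translate from an ATG with the standard code until the first stop."""
    transcript = transcript.upper()
    if transcript[cds_start - 1 : cds_start + 2] != "ATG":
        raise ValueError(
            f"no ATG at transcript position {cds_start} "
            f"(found {transcript[cds_start - 1:cds_start + 2]!r})"
        )
    protein = []
    for i in range(cds_start - 1, len(transcript) - 2, 3):
        codon = transcript[i : i + 3]
        if codon in _STOPS:
            n = len(protein)
            return TranslationResult(
                protein="".join(protein),
                stop_codon=codon,
                stop_residue=n + 1,
                orf_length_nt=3 * (n + 1),
                non_stop=False,
            )
        protein.append(_TABLE.forward_table[codon])
    return TranslationResult(
        protein="".join(protein),
        stop_codon=None,
        stop_residue=None,
        orf_length_nt=3 * len(protein),
        non_stop=True,
    )


def _map_pos(p: int, event: SpliceVariantEvent) -> int | None:
    """Map a wild gene position through an edit; None if it was replaced."""
    if p < event.start:
        return p
    if p > event.end:
        return p + event.net_change
    return None


def _validate_event(model: GeneModel, event: SpliceVariantEvent) -> None:
    if event.end > model.length:
        raise ValueError(
            f"event span {event.start}-{event.end} exceeds gene length {model.length}"
        )
    for s, e in model.introns():
        if event.start <= s and e <= event.end:
            raise ValueError(
                f"event deletes intron {s}-{e} entirely; whole-intron loss is unsupported"
            )
    if _map_pos(model.cds_start_gene, event) is None or _map_pos(
        model.cds_start_gene + 2, event
    ) is None:
        raise ValueError("event overlaps the start codon; translation start is lost")


def _mutant_sequence(model: GeneModel, event: SpliceVariantEvent) -> str:
    seq = model.sequence
    return seq[: event.start - 1] + event.replacement + seq[event.end :]


def _disruption_flags(
    model: GeneModel, event: SpliceVariantEvent, mut_seq: str
) -> list[tuple[bool, bool]]:
    """Per-intron (donor disrupted, acceptor disrupted) after the edit."""

    def span_hits(a: int, b: int) -> bool:
        return not (b < event.start or a > event.end)

    flags: list[tuple[bool, bool]] = []
    for s, e in model.introns():
        donor_hit = span_hits(s, s + 1)
        acceptor_hit = span_hits(e - 1, e)
        if not donor_hit:
            d = _map_pos(s, event)
            donor_hit = mut_seq[d - 1 : d + 1] != DONOR
        if not acceptor_hit:
            a = _map_pos(e - 1, event)
            acceptor_hit = mut_seq[a - 1 : a + 1] != ACCEPTOR
        flags.append((donor_hit, acceptor_hit))
    return flags


def retained_introns(
    model: GeneModel, event: SpliceVariantEvent, policy: str = "retain"
) -> list[int]:
    """1-based indices of introns an edit forces into the mature transcript."""
    _validate_event(model, event)
    mut_seq = _mutant_sequence(model, event)
    return [
        i + 1
        for i, junction in enumerate(_junctions(model, event, mut_seq, policy))
        if junction is None
    ]


def _junctions(
    model: GeneModel, event: SpliceVariantEvent, mut_seq: str, policy: str
) -> list[tuple[int, int] | None]:
    """Mutant-coordinate (intron start, intron end) per wild intron.

    ``None`` means the intron is retained in the mature transcript. Under
    ``policy="cryptic-gt"`` a donor-destroyed intron with an intact acceptor
    is rescued by the nearest downstream GT in the mutant sequence, if any.
    """
    if policy not in ("retain", "cryptic-gt"):
        raise ValueError(f"unknown splice policy {policy!r}")
    out: list[tuple[int, int] | None] = []
    for (s, e), (donor_bad, acceptor_bad) in zip(
        model.introns(), _disruption_flags(model, event, mut_seq)
    ):
        if not donor_bad and not acceptor_bad:
            out.append((_map_pos(s, event), _map_pos(e, event)))
        elif donor_bad and not acceptor_bad and policy == "cryptic-gt":
            end_m = _map_pos(e, event)
            search_from = _map_pos(s, event)
            if search_from is None:  # donor deleted: scan from the replacement
                search_from = event.start
            d = mut_seq.find(DONOR, search_from - 1, end_m - 2)
            out.append((d + 1, end_m) if d >= 0 else None)
        else:
            out.append(None)
    return out


def apply_gene_variant(
    model: GeneModel, event: SpliceVariantEvent, policy: str = "retain"
) -> GeneModel:
    """Apply an edit to a gene and recompute its effective exon structure.

    Any intron whose donor (or acceptor) dinucleotide is deleted or no
    longer reads GT (AG) in the mutant sequence is, under the default
    ``retain`` policy, kept in the mature transcript: it is merged with its
    flanking exons up to the next intact splice boundary. Under
    ``cryptic-gt`` a donor-destroyed intron is instead spliced from the
    nearest downstream GT when one exists before the acceptor. Introns left
    intact are spliced normally. Deleting an entire intron is unsupported
    and raises.

    Edits to an already-edited model compose with the original edit and are
    re-evaluated against the wild-type structure, so an edit that restores
    a destroyed splice site restores splicing.
    """
    if model.base is not None:
        composite = _compose_events(model.base, model.base_event, model, event)
        return apply_gene_variant(model.base, composite, policy=policy)
    if event.end > model.length:
        raise ValueError(
            f"event span {event.start}-{event.end} exceeds gene length {model.length}"
        )
    if model.sequence[event.start - 1 : event.end] == event.replacement:
        return dataclasses.replace(model)  # no-op edit: identical model
    _validate_event(model, event)
    mut_seq = _mutant_sequence(model, event)
    junctions = _junctions(model, event, mut_seq, policy)

    mut_exons: list[tuple[int, int]] = []
    open_start = _map_pos(model.exons[0][0], event)
    if open_start is None:
        raise ValueError("edit removes the transcription start; unsupported")
    for junction in junctions:
        if junction is not None:
            a, b = junction
            mut_exons.append((open_start, a - 1))
            open_start = b + 1
    last_end = _map_pos(model.exons[-1][1], event)
    if last_end is None:
        raise ValueError("edit removes the transcript 3' end; unsupported")
    mut_exons.append((open_start, last_end))

    return GeneModel(
        gene_id=model.gene_id,
        sequence=mut_seq,
        exons=mut_exons,
        cds_start_gene=_map_pos(model.cds_start_gene, event),
        chrom=model.chrom,
        strand=model.strand,
        genomic_start=model.genomic_start,
        noncanonical=True,
        base=model,
        base_event=event,
    )


def _compose_events(
    wild: GeneModel,
    first: SpliceVariantEvent,
    mutant: GeneModel,
    second: SpliceVariantEvent,
) -> SpliceVariantEvent:
    """Collapse an edit of an edited gene into one edit of the wild type.

    The combined event spans from the leftmost to the rightmost wild
    position either edit touches; its replacement is read off the final
    sequence, which makes the composition exact even when the second edit
    overlaps the first replacement partially.
    """
    if second.end > mutant.length:
        raise ValueError(
            f"event span {second.start}-{second.end} exceeds gene length {mutant.length}"
        )
    final_seq = _mutant_sequence(mutant, second)
    len1 = len(first.replacement)
    w_start = second.start if second.start < first.start else first.start
    if second.end > first.start + len1 - 1:
        w_end = max(first.end, second.end - first.net_change)
    else:
        w_end = first.end
    replacement = final_seq[w_start - 1 : len(final_seq) - (len(wild.sequence) - w_end)]
    return SpliceVariantEvent(w_start, w_end, replacement)


def diff_proteins(wild: str, mutant: str) -> ProteinDiff:
    """Locate the first altered residue and the substituted run.

    The run is the maximal stretch of consecutive differing residues from
    the first difference, bounded by the shorter protein. Classification
    compares lengths only: truncating, elongating or synonymous-length.
    """
    if not wild or not mutant:
        raise ValueError("both proteins must be non-empty")
    n = min(len(wild), len(mutant))
    first = next((i + 1 for i in range(n) if wild[i] != mutant[i]), None)
    if first is None and len(wild) != len(mutant):
        first = n + 1  # pure truncation/extension: diverges right after the prefix
    run_w = run_m = ""
    if first is not None:
        j = first - 1
        while j < n and wild[j] != mutant[j]:
            j += 1
        run_w = wild[first - 1 : j]
        run_m = mutant[first - 1 : j]
    if len(mutant) < len(wild):
        cls = "truncating"
    elif len(mutant) > len(wild):
        cls = "elongating"
    else:
        cls = "synonymous-length"
    return ProteinDiff(
        first_diff=first,
        wild_run=run_w,
        mutant_run=run_m,
        truncation=len(wild) - len(mutant),
        classification=cls,
    )


def domain_overlap(
    domains: list[tuple[str, int, int]],
    mutant_length: int,
    first_diff: int | None,
    stop_residue: int | None,
) -> list[DomainOverlap]:
    """Classify each wild-protein domain span as lost, disrupted or intact.

    Lost: the domain lies entirely beyond the mutant protein. Disrupted: the
    first altered residue or the premature terminator falls inside the span.
    Intact otherwise.
    """
    out = []
    for name, start, end in domains:
        if start > end or start < 1:
            raise ValueError(f"invalid domain span {name} {start}-{end}")
        if start > mutant_length:
            status = "lost"
        elif any(x is not None and start <= x <= end for x in (first_diff, stop_residue)):
            status = "disrupted"
        else:
            status = "intact"
        out.append(DomainOverlap(name=name, start=start, end=end, status=status))
    return out


def characterize(
    model: GeneModel,
    event: SpliceVariantEvent,
    domains: list[tuple[str, int, int]] | None = None,
    policy: str = "retain",
) -> ConsequenceReport:
    """Full consequence report of an edit: transcript, ORF, protein, domains."""
    wild_tr = translate_orf(model.transcript(), model.cds_start)
    mutant = apply_gene_variant(model, event, policy=policy)
    mut_tr = translate_orf(mutant.transcript(), mutant.cds_start)
    diff = diff_proteins(wild_tr.protein, mut_tr.protein) if (
        wild_tr.protein and mut_tr.protein
    ) else ProteinDiff(None, "", "", 0, "synonymous-length")
    frameshift_pos = 3 * (diff.first_diff - 1) + 1 if diff.first_diff else None
    retained = retained_introns(model, event, policy=policy)
    overlaps = domain_overlap(
        domains or [], len(mut_tr.protein), diff.first_diff, mut_tr.stop_residue
    )
    return ConsequenceReport(
        gene_id=model.gene_id,
        wild_gene_length_bp=model.length,
        mutant_gene_length_bp=mutant.length,
        wild_orf_length_nt=wild_tr.orf_length_nt,
        mutant_orf_length_nt=mut_tr.orf_length_nt,
        wild_protein_length_aa=len(wild_tr.protein),
        mutant_protein_length_aa=len(mut_tr.protein),
        frameshift_cdna_pos=frameshift_pos,
        first_altered_residue=diff.first_diff,
        wild_run=diff.wild_run,
        mutant_run=diff.mutant_run,
        premature_stop_codon=mut_tr.stop_codon,
        premature_stop_residue=mut_tr.stop_residue,
        classification=diff.classification,
        retained_introns=retained,
        domain_overlaps=overlaps,
    )


@dataclass
class AlternativeSpliceSite:
    """A shifted donor or acceptor producing an alternative isoform."""

    intron_index: int  # 1-based
    shift_nt: int  # positive = junction moves downstream (3') in gene coords
    end: str = "acceptor"  # "acceptor" or "donor"

    def __post_init__(self) -> None:
        if self.intron_index < 1:
            raise ValueError("intron_index is 1-based")
        if self.end not in ("acceptor", "donor"):
            raise ValueError("end must be 'acceptor' or 'donor'")


@dataclass
class IsoformReport:
    name: str
    model: GeneModel
    translation: TranslationResult
    frameshifted: bool


def alternative_splice_isoforms(
    model: GeneModel, site: AlternativeSpliceSite
) -> list[IsoformReport]:
    """Emit the primary isoform and, if the shift is non-zero, the alternative.

    A 3-nt acceptor shift inside the CDS removes (or restores) exactly one
    codon, so the two isoforms differ by a single residue; shifts that are
    not a multiple of 3 change the reading frame downstream and the
    alternative isoform is flagged frameshifted.
    """
    primary = IsoformReport(
        name="isoform-1",
        model=model,
        translation=translate_orf(model.transcript(), model.cds_start),
        frameshifted=False,
    )
    if site.shift_nt == 0:
        return [primary]
    i = site.intron_index - 1
    introns = model.introns()
    if i >= len(introns):
        raise ValueError(
            f"gene {model.gene_id} has {len(introns)} introns; index {site.intron_index} invalid"
        )
    exons = list(model.exons)
    if site.end == "acceptor":
        s, e = exons[i + 1]
        exons[i + 1] = (s + site.shift_nt, e)
    else:
        s, e = exons[i]
        exons[i] = (s, e + site.shift_nt)
    alt_model = GeneModel(
        gene_id=model.gene_id,
        sequence=model.sequence,
        exons=exons,
        cds_start_gene=model.cds_start_gene,
        chrom=model.chrom,
        strand=model.strand,
        genomic_start=model.genomic_start,
        noncanonical=True,
    )
    alt_tr = translate_orf(alt_model.transcript(), alt_model.cds_start)
    junction_in_cds = alt_model.transcript_pos(alt_model.exons[i + 1][0] if site.end == "acceptor" else alt_model.exons[i][1]) >= alt_model.cds_start
    return [
        primary,
        IsoformReport(
            name="isoform-2",
            model=alt_model,
            translation=alt_tr,
            frameshifted=(site.shift_nt % 3 != 0) and junction_in_cds,
        ),
    ]
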